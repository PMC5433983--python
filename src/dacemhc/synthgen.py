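"""Synthetic amplicon data with known truth.

Everything downstream of the sequencer — allele calling, diversity,
structure and selection statistics — is exercised against data produced
here, where the true allele catalog and every individual's genotype are
known.  The generator emulates the study design this package targets:
a 236-bp MHC class II beta amplicon (207 bp exon + 29 bp intron), small
allele catalogs (~8 alleles, ~16 segregating sites), diploid individuals
carrying at most two alleles, per-sample read depths in the hundreds to
thousands, and 454-style errors (random substitutions plus single-base
indels concentrated in homopolymer runs).  A fraction of individuals is
amplified twice so the end-to-end repeatability rate can be estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .catalog import AlleleCatalog, CatalogError

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}

#: read-depth range observed per amplicon in the motivating data set
DEPTH_RANGE = (101, 14027)


class ParameterError(ValueError):
    """Raised for impossible or invalid generator parameters."""


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth genotype for one amplified sample."""

    individual_id: str
    site_code: str
    true_alleles: tuple[str, ...]
    replicate_of: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.true_alleles) <= 2:
            raise ParameterError("true_alleles must hold one or two allele ids")

    @property
    def allele_set(self) -> frozenset[str]:
        return frozenset(self.true_alleles)


@dataclass
class SampleReadSet:
    """Reads obtained for one amplified sample."""

    individual_id: str
    reads: list[str]
    replicate_of: str | None = None

    @property
    def depth(self) -> int:
        return len(self.reads)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.Generator(np.random.PCG64(seed))


# ---------------------------------------------------------------------------
# allele catalog generation
# ---------------------------------------------------------------------------

def _random_sense_exon(rng: np.random.Generator, n_codons: int) -> str:
    """Random exon made of sense codons (no in-frame stops)."""
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(BASES), size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    return "".join(codons)


def _translate(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def _alt_base(rng: np.random.Generator, seq: str, pos: int, exon_end: int,
              want_nonsyn: bool | None = None) -> str | None:
    """Pick an alternative base at ``pos`` that keeps the exon stop-free.

    When ``want_nonsyn`` is True, only amino-acid-changing substitutions are
    considered; when False, only silent ones.  Returns None if no candidate
    base satisfies the constraints.
    """
    ref = seq[pos]
    candidates = [b for b in BASES if b != ref]
    rng.shuffle(candidates)
    for b in candidates:
        if pos < exon_end:
            codon_i = pos // 3
            codon = seq[3 * codon_i:3 * codon_i + 3]
            mut = codon[:pos % 3] + b + codon[pos % 3 + 1:]
            if mut in STOP_CODONS:
                continue
            if want_nonsyn is True and _translate(mut) == _translate(codon):
                continue
            if want_nonsyn is False and _translate(mut) != _translate(codon):
                continue
        elif want_nonsyn is True:
            continue  # intron positions cannot be nonsynonymous
        return b
    return None


def gen_allele_pool(n_alleles: int, exon_len: int = 207, intron_len: int = 29,
                    n_segregating: int = 16, seed: int = 0) -> AlleleCatalog:
    """Generate a catalog of distinct alleles over biallelic segregating sites.

    The returned sequences are identical except at exactly ``n_segregating``
    positions, each carrying two states across the catalog.  At least one
    exon variant is nonsynonymous, the exon frame is stop-free in every
    allele, and the catalog is deterministic given ``seed``.
    """
    if n_alleles < 2:
        raise ParameterError("need at least two alleles")
    if exon_len % 3 != 0:
        raise ParameterError("exon_len must be a codon multiple (frame offset 0)")
    L = exon_len + intron_len
    if n_segregating > L:
        raise ParameterError("more segregating sites than amplicon positions")
    if n_segregating < 1 or n_alleles > 2 ** n_segregating:
        raise ParameterError(
            f"{n_alleles} alleles cannot be distinguished by "
            f"{n_segregating} biallelic sites")

    rng = _rng(seed)
    base = _random_sense_exon(rng, exon_len // 3) + \
        "".join(rng.choice(list(BASES), size=intron_len))

    # segregating sites land in distinct exon codons so that no combination
    # of variants can assemble an in-frame stop (each variant is validated
    # against the base sequence individually)
    candidates = rng.permutation(L)
    chosen: list[int] = []
    used_codons: set[int] = set()
    for p in candidates:
        p = int(p)
        if p < exon_len:
            if p // 3 in used_codons:
                continue
            used_codons.add(p // 3)
        chosen.append(p)
        if len(chosen) == n_segregating:
            break
    if len(chosen) < n_segregating:
        raise ParameterError(
            "cannot place segregating sites in distinct exon codons")
    positions = np.sort(np.array(chosen))
    # first exon site forced nonsynonymous (if any exon site was drawn)
    exon_sites = [int(p) for p in positions if p < exon_len]
    alts: dict[int, str] = {}
    for p in positions:
        p = int(p)
        want = True if (exon_sites and p == exon_sites[0]) else None
        b = _alt_base(rng, base, p, exon_len, want_nonsyn=want)
        if b is None:  # extremely rare; fall back to any stop-free change
            b = _alt_base(rng, base, p, exon_len)
        if b is None:
            raise ParameterError(f"no valid alternative base at position {p}")
        alts[p] = b

    # haplotype matrix: rows distinct, every column polymorphic
    for _ in range(1000):
        H = rng.integers(0, 2, size=(n_alleles, n_segregating))
        rows = {tuple(r) for r in H}
        if len(rows) < n_alleles:
            continue
        for j in range(n_segregating):
            col = H[:, j]
            if col.min() == col.max():
                i = int(rng.integers(n_alleles))
                H2 = H.copy()
                H2[i, j] = 1 - H2[i, j]
                if len({tuple(r) for r in H2}) == n_alleles:
                    H = H2
        if len({tuple(r) for r in H}) == n_alleles and \
                all(H[:, j].min() != H[:, j].max() for j in range(n_segregating)):
            break
    else:  # pragma: no cover - essentially unreachable
        raise ParameterError("could not construct a valid haplotype matrix")

    alleles = []
    for i in range(n_alleles):
        s = list(base)
        for j, p in enumerate(positions):
            if H[i, j]:
                s[int(p)] = alts[int(p)]
        alleles.append((f"A{i + 1}", "".join(s)))
    return AlleleCatalog(tuple(alleles), exon_span=(0, exon_len), frame_offset=0)


# ---------------------------------------------------------------------------
# population genotypes
# ---------------------------------------------------------------------------

def gen_population(catalog: AlleleCatalog, freqs: Sequence[float], n_ind: int,
                   inbreeding_f: float = 0.0, seed: int = 0,
                   site_code: str = "POP1",
                   id_prefix: str | None = None) -> list[TruthRecord]:
    """Draw diploid genotypes from allele frequencies with optional inbreeding.

    Genotype probabilities follow the inbreeding model
    ``P(hom i) = f p_i + (1 - f) p_i^2`` and
    ``P(het ij) = (1 - f) 2 p_i p_j``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if len(freqs) != len(catalog):
        raise ParameterError("frequency vector length must match catalog size")
    if (freqs < 0).any():
        raise ParameterError("allele frequencies must be non-negative")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ParameterError("allele frequencies must sum to 1")
    if n_ind < 1:
        raise ParameterError("n_ind must be positive")
    if not 0 <= inbreeding_f <= 1:
        raise ParameterError("inbreeding_f must lie in [0, 1]")

    rng = _rng(seed)
    ids = catalog.ids
    prefix = id_prefix if id_prefix is not None else site_code
    out = []
    for i in range(n_ind):
        if rng.random() < inbreeding_f:
            a = rng.choice(len(ids), p=freqs)
            pair = (ids[a], ids[a])
        else:
            a, b = rng.choice(len(ids), size=2, p=freqs)
            pair = tuple(sorted((ids[a], ids[b])))
        out.append(TruthRecord(f"{prefix}_{i + 1:03d}", site_code, pair))
    return out


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _homopolymer_runs(seq: str) -> list[tuple[int, int]]:
    """(start, length) of homopolymer runs of length >= 2."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= 2:
            runs.append((i, j - i))
        i = j
    return runs


def _mutate_read(seq: str, sub_rate: float, hp_indel_rate: float,
                 rng: np.random.Generator) -> str:
    s = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if sub_rate > 0:
        hits = np.nonzero(rng.random(len(s)) < sub_rate)[0]
        for p in hits:
            choices = [b for b in b"ACGT" if b != s[p]]
            s[p] = choices[rng.integers(3)]
    read = s.tobytes().decode()
    if hp_indel_rate > 0:
        # one indel opportunity per homopolymer run, probability scaled by
        # run length (dominant 454 error mode, no flowgram model)
        out, edits = read, []
        for start, length in _homopolymer_runs(read):
            p = min(1.0, hp_indel_rate * length)
            if rng.random() < p:
                edits.append((start, rng.random() < 0.5))
        for start, is_ins in sorted(edits, reverse=True):
            if is_ins:
                out = out[:start] + out[start] + out[start:]
            else:
                out = out[:start] + out[start + 1:]
        read = out
    return read


def gen_reads(truth: TruthRecord, catalog: AlleleCatalog, depth: int,
              sub_rate: float = 0.0, hp_indel_rate: float = 0.0,
              allele_balance: float = 0.5, seed: int = 0) -> SampleReadSet:
    """Simulate an amplicon read set for one sample.

    Each read copies one of the sample's true alleles (the first with
    probability ``allele_balance`` for heterozygotes), then acquires i.i.d.
    substitutions at ``sub_rate`` per base and homopolymer-run indels at
    ``hp_indel_rate`` per run (scaled by run length).
    """
    if depth < 1:
        raise ParameterError("depth must be at least 1")
    for name, r in (("sub_rate", sub_rate), ("hp_indel_rate", hp_indel_rate)):
        if not 0 <= r < 1:
            raise ParameterError(f"{name} must lie in [0, 1)")
    if not 0 < allele_balance < 1:
        raise ParameterError("allele_balance must lie in (0, 1)")

    rng = _rng(seed)
    seqs = [catalog.sequence(a) for a in truth.true_alleles]
    reads = []
    for _ in range(depth):
        if len(seqs) == 2:
            src = seqs[0] if rng.random() < allele_balance else seqs[1]
        else:
            src = seqs[0]
        reads.append(_mutate_read(src, sub_rate, hp_indel_rate, rng))
    return SampleReadSet(truth.individual_id, reads)


def draw_depth(rng: np.random.Generator,
               depth_range: tuple[int, int] = DEPTH_RANGE) -> int:
    """Log-uniform read depth over the observed per-amplicon range."""
    lo, hi = depth_range
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def make_duplicates(samples: list[SampleReadSet], truths: list[TruthRecord],
                    catalog: AlleleCatalog, fraction: float,
                    sub_rate: float = 0.0, hp_indel_rate: float = 0.0,
                    allele_balance: float = 0.5, seed: int = 0,
                    ) -> tuple[list[SampleReadSet], list[TruthRecord]]:
    """Re-amplify a fraction of samples with fresh, independent error draws.

    Returns the replicate read sets and matching truth records; replicates
    are tagged through ``replicate_of`` and an ``_rep`` id suffix.
    """
    if not 0 <= fraction <= 1:
        raise ParameterError("fraction must lie in [0, 1]")
    rng = _rng(seed)
    truth_by_id = {t.individual_id: t for t in truths}
    n_dup = int(round(fraction * len(samples)))
    chosen = sorted(rng.choice(len(samples), size=n_dup, replace=False)) if n_dup else []
    rep_sets, rep_truths = [], []
    for idx in chosen:
        orig = samples[int(idx)]
        t = truth_by_id[orig.individual_id]
        rep_id = f"{orig.individual_id}_rep"
        rs = gen_reads(replace(t, individual_id=rep_id), catalog, orig.depth,
                       sub_rate, hp_indel_rate, allele_balance,
                       seed=rng.integers(2 ** 31))
        rs.replicate_of = orig.individual_id
        rep_sets.append(rs)
        rep_truths.append(replace(t, individual_id=rep_id,
                                  replicate_of=orig.individual_id))
    return rep_sets, rep_truths


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_sample_fasta(readset: SampleReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(readset.reads):
            fh.write(f">{readset.individual_id}_read{i + 1}\n{r}\n")


def write_sample_fastq(readset: SampleReadSet, path: str | Path) -> None:
    """FASTQ with uniform Q40 qualities (no per-base quality model)."""
    with open(path, "w") as fh:
        for i, r in enumerate(readset.reads):
            fh.write(f"@{readset.individual_id}_read{i + 1}\n{r}\n+\n{'I' * len(r)}\n")


def read_sample_file(path: str | Path) -> SampleReadSet:
    """Load one per-sample FASTA/FASTQ file; sample id = file stem."""
    from Bio import SeqIO

    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    reads = [str(r.seq).upper() for r in SeqIO.parse(str(path), fmt)]
    name = path.stem
    rep_of = name[:-4] if name.endswith("_rep") else None
    return SampleReadSet(name, reads, replicate_of=rep_of)


def write_truth_tsv(truths: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\tsite\tallele1\tallele2\treplicate_of\n")
        for t in truths:
            a = list(t.true_alleles)
            if len(a) == 1:
                a = a * 2
            fh.write(f"{t.individual_id}\t{t.site_code}\t{a[0]}\t{a[1]}\t"
                     f"{t.replicate_of or ''}\n")


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            iid, site, a1, a2, rep = (line.rstrip("\n").split("\t") + [""])[:5]
            pair = (a1,) if a1 == a2 else tuple(sorted((a1, a2)))
            out.append(TruthRecord(iid, site, pair, rep or None))
    return out
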