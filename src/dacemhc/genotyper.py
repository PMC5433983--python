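"""Three-step amplicon allele calling with duplicate-based repeatability.

Step 1 (:func:`cluster_within_sample`) aligns the reads of one sample,
computes a pairwise distance matrix and cuts an average-linkage dendrogram
into read clusters, emitting each cluster's majority-rule consensus as a
putative allele.  Step 2 (:func:`build_consensus_alleles`) pools putative
alleles across samples and keeps exact-identity groups supported by enough
distinct samples.  Step 3 (:func:`assign_genotypes`) matches every read back
to its nearest catalog allele and calls the alleles that comprise at least
``min_fraction`` (default 20%) of a sample's reads, with at most two alleles
per diploid individual.  :func:`estimate_repeatability` turns independently
re-amplified samples into an end-to-end error-rate estimate.

Branch-length units.  The dendrogram is built on p-distances and an internal
branch is the difference between the merge heights of a node and its parent.
``min_branch`` is interpreted on a *relative* scale: a branch separates two
clusters when it spans at least ``min_branch`` of the sample's total
dendrogram height.  An absolute p-distance threshold of the same default
(0.1) would merge any alleles differing at fewer than ~10% of sites — far
coarser than real MHC allele divergence — whereas the relative reading keeps
the parameter meaningful across error rates and divergence scales.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .catalog import AlleleCatalog, CatalogError
from .synthgen import SampleReadSet


class GenotypingError(ValueError):
    pass


class EmptyCatalogError(GenotypingError):
    """No putative allele group passed the support threshold."""


@dataclass
class PutativeAlleleSet:
    """Within-sample putative alleles: (consensus sequence, read support)."""

    individual_id: str
    sequences: list[tuple[str, int]]


@dataclass
class GenotypeRow:
    individual_id: str
    site_code: str | None
    called_alleles: tuple[str, ...]
    read_fractions: dict[str, float]
    flag: str  # ok | ambiguous | failed
    replicate_of: str | None = None

    @property
    def allele_set(self) -> frozenset[str]:
        return frozenset(self.called_alleles)


@dataclass
class GenotypeTable:
    rows: list[GenotypeRow] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    def get(self, individual_id: str) -> GenotypeRow:
        for r in self.rows:
            if r.individual_id == individual_id:
                return r
        raise KeyError(individual_id)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "individual_id": [r.individual_id for r in self.rows],
                "site": [r.site_code for r in self.rows],
                "alleles": [",".join(r.called_alleles) for r in self.rows],
                "fractions": [",".join(f"{r.read_fractions[a]:.4f}"
                                        for a in r.called_alleles)
                               for r in self.rows],
                "flag": [r.flag for r in self.rows],
                "replicate_of": [r.replicate_of or "" for r in self.rows],
            }
        )


# ---------------------------------------------------------------------------
# step 1: within-sample clustering
# ---------------------------------------------------------------------------

def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def _p_distance(a: str, b: str) -> float:
    return _edit_distance(a, b) / max(len(a), len(b))


def _dedup(reads: Sequence[str]) -> tuple[list[str], np.ndarray]:
    counts = Counter(reads)
    uniq = sorted(counts)  # deterministic order
    return uniq, np.array([counts[u] for u in uniq])


def _cut_clusters(Z: np.ndarray, n_leaves: int, min_branch: float) -> list[list[int]]:
    """Leaf clusters after removing internal branches spanning at least
    ``min_branch`` of total tree height (merge-height differences)."""
    heights = np.concatenate([np.zeros(n_leaves), Z[:, 2]])
    total = heights.max()
    if total <= 0:
        return [list(range(n_leaves))]
    parent_cut = np.zeros(n_leaves + len(Z), dtype=bool)
    for k, (a, b, h, _) in enumerate(Z):
        node = n_leaves + k
        for child in (int(a), int(b)):
            if (heights[node] - heights[child]) / total >= min_branch:
                parent_cut[child] = True
    # union-find over uncut edges
    parent = list(range(n_leaves + len(Z)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, _, _) in enumerate(Z):
        node = n_leaves + k
        for child in (int(a), int(b)):
            if not parent_cut[child]:
                parent[find(child)] = find(node)
    groups = defaultdict(list)
    for leaf in range(n_leaves):
        groups[find(leaf)].append(leaf)
    return sorted(groups.values())


def _consensus(uniq: list[str], counts: np.ndarray, members: list[int]) -> str:
    """Majority base per column, anchored on the cluster's modal sequence."""
    members = sorted(members, key=lambda i: (-counts[i], uniq[i]))
    ref = uniq[members[0]]
    votes = [Counter() for _ in range(len(ref))]
    insertions: dict[int, Counter] = defaultdict(Counter)
    total = 0
    for i in members:
        seq, w = uniq[i], int(counts[i])
        total += w
        if seq == ref:
            for c, base in enumerate(ref):
                votes[c][base] += w
            continue
        aln = edlib.align(seq, ref, task="path", mode="NW")
        nice = edlib.getNiceAlignment(aln, seq, ref)
        q, t = nice["query_aligned"], nice["target_aligned"]
        col = 0
        pending_ins = ""
        for qc, tc in zip(q, t):
            if tc == "-":
                pending_ins += qc
                continue
            if pending_ins:
                insertions[col][pending_ins] += w
                pending_ins = ""
            votes[col][qc] += w  # qc == "-" records a deletion vote
            col += 1
        if pending_ins:
            insertions[col][pending_ins] += w
    out = []
    for c, base in enumerate(ref):
        if c in insertions:
            ins, n = insertions[c].most_common(1)[0]
            if n * 2 > total:
                out.append(ins)
        winner, n = max(votes[c].items(),
                        key=lambda kv: (kv[1], kv[0] == base, kv[0]))
        if winner != "-":
            out.append(winner)
    if len(ref) in insertions:
        ins, n = insertions[len(ref)].most_common(1)[0]
        if n * 2 > total:
            out.append(ins)
    return "".join(out)


def cluster_within_sample(reads: SampleReadSet, min_branch: float = 0.1,
                          min_reads: int = 2,
                          max_cluster_uniques: int = 300) -> PutativeAlleleSet:
    """Identify putative alleles within one sample by read clustering.

    Reads are deduplicated, pairwise p-distances computed by global
    alignment, and an average-linkage (UPGMA) dendrogram cut wherever an
    internal branch spans at least ``min_branch`` of total tree height.
    Each cluster contributes its majority-rule consensus, supported by the
    cluster's read count; clusters with fewer than ``min_reads`` reads are
    presumed sequencing errors and dropped (unless nothing else remains).

    Deep, error-rich samples can hold thousands of distinct read sequences,
    nearly all seen once.  When more than ``max_cluster_uniques`` distinct
    sequences occur, only those seen at least twice enter the dendrogram
    and each singleton is attached to the cluster whose consensus it is
    nearest to, which leaves consensus calls unchanged (majority voting is
    dominated by the repeated sequences) while keeping the distance matrix
    tractable.
    """
    if reads.depth < 1:
        raise GenotypingError(f"sample {reads.individual_id} has no reads")
    if min_branch <= 0:
        raise GenotypingError("min_branch must be positive")
    uniq, counts = _dedup(reads.reads)
    if len(uniq) == 1:
        return PutativeAlleleSet(reads.individual_id, [(uniq[0], int(counts[0]))])

    singles: list[tuple[str, int]] = []
    if len(uniq) > max_cluster_uniques and int((counts >= 2).sum()) >= 2:
        keep = counts >= 2
        singles = [(u, int(c)) for u, c, k in zip(uniq, counts, keep) if not k]
        uniq = [u for u, k in zip(uniq, keep) if k]
        counts = counts[keep]

    n = len(uniq)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _p_distance(uniq[i], uniq[j])
    Z = linkage(squareform(dm, checks=False), method="average")
    clusters = _cut_clusters(Z, n, min_branch)

    merged: Counter = Counter()
    for members in clusters:
        support = int(counts[list(members)].sum())
        merged[_consensus(uniq, counts, members)] += support
    if singles:
        consensuses = sorted(merged)
        for seq, c in singles:
            dists = [_edit_distance(seq, s) for s in consensuses]
            merged[consensuses[int(np.argmin(dists))]] += c
    kept = [(s, c) for s, c in merged.items() if c >= min_reads]
    if not kept:  # never silently emit nothing for a sample that has reads
        kept = [max(merged.items(), key=lambda kv: kv[1])]
    kept.sort(key=lambda kv: (-kv[1], kv[0]))
    return PutativeAlleleSet(reads.individual_id, kept)


# ---------------------------------------------------------------------------
# step 2: global consensus catalog
# ---------------------------------------------------------------------------

def build_consensus_alleles(all_putative: Iterable[PutativeAlleleSet],
                            min_support_samples: int = 2,
                            allow_singletons: bool = False,
                            exon_span: tuple[int, int] = (0, 207),
                            frame_offset: int = 0) -> AlleleCatalog:
    """Pool putative alleles across samples into a global catalog.

    Sequences are grouped by exact identity; a group becomes a catalog
    allele when seen in at least ``min_support_samples`` distinct samples
    (or in a single sample when ``allow_singletons``).  Alleles are labelled
    A1, A2, ... in order of decreasing sample support.
    """
    all_putative = list(all_putative)
    if not all_putative:
        raise GenotypingError("no putative allele sets supplied")
    samples_by_seq: dict[str, set[str]] = defaultdict(set)
    reads_by_seq: Counter = Counter()
    for pset in all_putative:
        for seq, support in pset.sequences:
            samples_by_seq[seq].add(pset.individual_id)
            reads_by_seq[seq] += support
    threshold = 1 if allow_singletons else min_support_samples
    kept = [s for s, samp in samples_by_seq.items() if len(samp) >= threshold]
    if not kept:
        raise EmptyCatalogError(
            f"no putative allele was seen in >= {threshold} samples")
    kept.sort(key=lambda s: (-len(samples_by_seq[s]), -reads_by_seq[s], s))
    alleles = tuple((f"A{i + 1}", s) for i, s in enumerate(kept))
    return AlleleCatalog(alleles, exon_span=exon_span, frame_offset=frame_offset)


# ---------------------------------------------------------------------------
# step 3: genotype assignment
# ---------------------------------------------------------------------------

def assign_genotypes(reads: SampleReadSet, catalog: AlleleCatalog,
                     min_fraction: float = 0.2, min_depth: int = 20,
                     site_code: str | None = None) -> GenotypeRow:
    """Call a genotype by matching each read to its nearest catalog allele.

    Per-allele read fractions accumulate one unit per read (split equally
    between equally-near alleles); alleles at or above ``min_fraction`` are
    called.  Samples shallower than ``min_depth`` are flagged failed; more
    than two passing alleles flags the call ambiguous.
    """
    if len(catalog) == 0:
        raise GenotypingError("empty catalog")
    if not 0 < min_fraction < 1:
        raise GenotypingError("min_fraction must lie in (0, 1)")
    if reads.depth < min_depth:
        return GenotypeRow(reads.individual_id, site_code, (), {}, "failed",
                           reads.replicate_of)

    uniq, counts = _dedup(reads.reads)
    weights = dict.fromkeys(catalog.ids, 0.0)
    for seq, w in zip(uniq, counts):
        dists = [_edit_distance(seq, s) for s in catalog.sequences]
        best = min(dists)
        ties = [aid for aid, d in zip(catalog.ids, dists) if d == best]
        for aid in ties:
            weights[aid] += float(w) / len(ties)
    fractions = {a: weights[a] / reads.depth for a in catalog.ids}
    passing = [a for a in catalog.ids if fractions[a] >= min_fraction]
    passing.sort(key=lambda a: (-fractions[a], a))
    if not passing:
        flag = "failed"
    elif len(passing) > 2:
        flag = "ambiguous"
    else:
        flag = "ok"
    return GenotypeRow(reads.individual_id, site_code, tuple(passing),
                       {a: fractions[a] for a in passing}, flag,
                       reads.replicate_of)


# ---------------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------------

@dataclass
class RepeatabilityResult:
    percent: float
    n_pairs: int
    discordant: list[tuple[str, str]]


def estimate_repeatability(genotypes: GenotypeTable,
                           pairs: Sequence[tuple[str, str]]) -> RepeatabilityResult:
    """Fraction of replicate pairs receiving identical unordered allele sets.

    ``pairs`` lists ``(original_id, replicate_id)``; both members must be
    present in the genotype table.  The discordant pairs are returned so the
    caller can exclude those individuals from downstream statistics.
    """
    if not pairs:
        raise GenotypingError("need at least one replicate pair")
    discordant = []
    for a, b in pairs:
        ga, gb = genotypes.get(a), genotypes.get(b)
        if ga.allele_set != gb.allele_set:
            discordant.append((a, b))
    pct = 100.0 * (len(pairs) - len(discordant)) / len(pairs)
    return RepeatabilityResult(pct, len(pairs), discordant)
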