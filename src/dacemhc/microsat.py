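"""Neutral-marker analyses: GENEPOP IO, Weir-Cockerham F_ST, rarefied
allelic richness, expected heterozygosity, and (partial) Mantel tests of
isolation by distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


class MicrosatError(ValueError):
    pass


class GenepopParseError(MicrosatError):
    pass


@dataclass
class MicrosatDataset:
    """Codominant multi-locus genotypes grouped by sampling site.

    ``genotypes`` has shape (n_individuals, n_loci, 2) with positive
    integer allele size labels and 0 for missing data.
    """

    loci: list[str]
    populations: list[str]            # site code per individual
    individuals: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        n, L, p = self.genotypes.shape
        if L != len(self.loci) or n != len(self.populations) or p != 2:
            raise MicrosatError("genotype array shape does not match labels")
        if (self.genotypes < 0).any():
            raise MicrosatError("allele labels must be positive (0 = missing)")

    @property
    def population_codes(self) -> list[str]:
        seen = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen

    def pop_mask(self, pop: str) -> np.ndarray:
        return np.array([p == pop for p in self.populations])

    def allele_counts(self, pop: str, locus: str) -> dict[int, int]:
        li = self.loci.index(locus)
        g = self.genotypes[self.pop_mask(pop), li, :].ravel()
        g = g[g > 0]
        vals, cnts = np.unique(g, return_counts=True)
        return dict(zip(vals.tolist(), cnts.tolist()))


# ---------------------------------------------------------------------------
# GENEPOP format
# ---------------------------------------------------------------------------

def _parse_genotype(tok: str, line_no: int) -> tuple[int, int]:
    if len(tok) == 4:
        a, b = int(tok[:2]), int(tok[2:])
    elif len(tok) == 6:
        a, b = int(tok[:3]), int(tok[3:])
    else:
        raise GenepopParseError(
            f"line {line_no}: genotype {tok!r} is not 4 or 6 digits")
    return a, b


def read_genepop(path: str | Path) -> MicrosatDataset:
    """Parse a GENEPOP file (2- or 3-digit alleles, ``Pop`` separators)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("empty file")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        line = lines[i].strip()
        if not line:
            raise GenepopParseError(f"line {i + 1}: blank line in locus list")
        loci.extend(x.strip() for x in line.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise GenepopParseError("no 'Pop' separator found")
    if not loci:
        raise GenepopParseError("no locus names before first 'Pop'")

    pops: list[str] = []
    inds: list[str] = []
    genos: list[list[tuple[int, int]]] = []
    pop_no = 0
    for j in range(i, len(lines)):
        line = lines[j].strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_no += 1
            continue
        if "," not in line:
            raise GenepopParseError(f"line {j + 1}: expected 'name , genotypes'")
        name, rest = line.split(",", 1)
        toks = rest.split()
        if len(toks) != len(loci):
            raise GenepopParseError(
                f"line {j + 1}: {len(toks)} genotypes for {len(loci)} loci")
        genos.append([_parse_genotype(t, j + 1) for t in toks])
        inds.append(name.strip())
        pops.append(f"POP{pop_no}")
    if not inds:
        raise GenepopParseError("no individuals parsed")
    return MicrosatDataset(loci, pops, inds, np.array(genos))


def write_genepop(dataset: MicrosatDataset, path: str | Path,
                  title: str = "dacemhc microsatellite export",
                  digits: int = 3) -> None:
    fmt = f"{{:0{digits}d}}"
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in dataset.loci:
            fh.write(locus + "\n")
        last_pop = None
        for ind, pop, g in zip(dataset.individuals, dataset.populations,
                               dataset.genotypes):
            if pop != last_pop:
                fh.write("Pop\n")
                last_pop = pop
            toks = " ".join(fmt.format(a) + fmt.format(b) for a, b in g)
            fh.write(f"{ind} , {toks}\n")


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components_locus(pop_genos: list[np.ndarray]) -> tuple[float, float, float]:
    """Summed (a, b, c) variance components over alleles for one locus.

    ``pop_genos[i]`` is an (n_i, 2) array of allele labels (missing rows
    removed) for population i.
    """
    r = len(pop_genos)
    n_i = np.array([len(g) for g in pop_genos], dtype=float)
    if (n_i < 1).any() or n_i.sum() < 2:
        return 0.0, 0.0, 0.0
    n_bar = n_i.mean()
    n_c = (n_i.sum() - (n_i ** 2).sum() / n_i.sum()) / (r - 1)
    alleles = sorted(set(np.concatenate(pop_genos).ravel().tolist()))
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p_i = np.array([np.mean(g == al) for g in pop_genos])
        h_i = np.array([np.mean((g[:, 0] == al) ^ (g[:, 1] == al))
                        for g in pop_genos])
        p_bar = (n_i * p_i).sum() / n_i.sum()
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / n_i.sum()
        a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                   - h_bar / 4.0) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                     - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def wc_fst(dataset: MicrosatDataset, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir-Cockerham theta between two populations
    (ratio of summed variance components over loci and alleles)."""
    num = den = 0.0
    used = 0
    for li in range(len(dataset.loci)):
        pg = []
        for pop in (pop_a, pop_b):
            g = dataset.genotypes[dataset.pop_mask(pop), li, :]
            g = g[(g > 0).all(axis=1)]
            pg.append(g)
        if any(len(g) < 2 for g in pg):
            continue
        a, b, c = _wc_components_locus(pg)
        num += a
        den += a + b + c
        used += 1
    if used == 0:
        raise MicrosatError(
            f"no locus typed in >= 2 individuals in both {pop_a} and {pop_b}")
    return num / den if den != 0 else 0.0


def wc_fst_haploid(counts: np.ndarray) -> float:
    """Weir-Cockerham theta for haploid data from a (pop x allele) count
    matrix (method-of-moments one-way ANOVA, ratio of sums over alleles)."""
    counts = np.asarray(counts, dtype=float)
    n_i = counts.sum(axis=1)
    r = len(n_i)
    N = n_i.sum()
    n_c = (N - (n_i ** 2).sum() / N) / (r - 1)
    msp_sum = msg_sum = 0.0
    for al in range(counts.shape[1]):
        p_i = counts[:, al] / n_i
        p_bar = counts[:, al].sum() / N
        msp = (n_i * (p_i - p_bar) ** 2).sum() / (r - 1)
        msg = (n_i * p_i * (1 - p_i)).sum() / (N - r)
        msp_sum += msp
        msg_sum += msg
    den = msp_sum + (n_c - 1) * msg_sum
    return float((msp_sum - msg_sum) / den) if den != 0 else 0.0


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def rarefied_allelic_richness(counts: dict[int, int] | Sequence[int],
                              g: int) -> float:
    """Expected allele count in a subsample of ``g`` gene copies
    (hypergeometric rarefaction)."""
    vals = np.array(list(counts.values()) if isinstance(counts, dict)
                    else list(counts), dtype=int)
    vals = vals[vals > 0]
    N = int(vals.sum())
    if g > N:
        raise MicrosatError(f"rarefaction size {g} exceeds sample size {N}")
    if g < 1:
        raise MicrosatError("rarefaction size must be positive")
    denom = math.comb(N, g)
    return float(sum(1.0 - math.comb(N - na, g) / denom for na in vals))


def expected_heterozygosity(counts: dict[int, int] | Sequence[int]) -> float:
    """Unbiased expected heterozygosity (Nei's gene diversity)."""
    vals = np.array(list(counts.values()) if isinstance(counts, dict)
                    else list(counts), dtype=float)
    n = vals.sum()
    if n < 2:
        raise MicrosatError("need at least two gene copies")
    p = vals / n
    return float(n / (n - 1) * (1 - np.sum(p ** 2)))


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

def _check_matrix(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise MicrosatError(f"{name} must be square")
    if not np.allclose(m, m.T, equal_nan=True):
        raise MicrosatError(f"{name} must be symmetric")
    return m


def _tri(m: np.ndarray) -> np.ndarray:
    return m[np.tril_indices_from(m, k=-1)]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise MicrosatError("Mantel correlation undefined for constant matrix")
    return float(np.corrcoef(x, y)[0, 1])


def mantel(m1: np.ndarray, m2: np.ndarray, n_perm: int = 100_000,
           seed: int = 0) -> tuple[float, float]:
    """Mantel test: Pearson r over lower-triangle entries, one-sided p from
    joint row/column permutations of one matrix (observed included)."""
    m1 = _check_matrix(m1, "m1")
    m2 = _check_matrix(m2, "m2")
    if m1.shape != m2.shape:
        raise MicrosatError("matrices must have matching shapes")
    if m1.shape[0] < 4:
        raise MicrosatError("need at least four taxa for a meaningful test")
    r_obs = _pearson(_tri(m1), _tri(m2))
    rng = np.random.Generator(np.random.PCG64(seed))
    v2 = _tri(m2)
    hits = 0
    n = m1.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = _pearson(_tri(m1[np.ix_(perm, perm)]), v2)
        hits += r >= r_obs - 1e-12
    return r_obs, (hits + 1) / (n_perm + 1)


def _residuals(v: np.ndarray, control: np.ndarray) -> np.ndarray:
    beta = np.polyfit(control, v, 1)
    return v - np.polyval(beta, control)


def partial_mantel(m1: np.ndarray, m2: np.ndarray, control: np.ndarray,
                   n_perm: int = 100_000, seed: int = 0) -> tuple[float, float]:
    """Partial Mantel test: correlation of ``m1`` and ``m2`` after removing
    the linear effect of ``control`` from both; permutations shuffle ``m1``
    jointly by rows and columns and re-residualize."""
    m1 = _check_matrix(m1, "m1")
    m2 = _check_matrix(m2, "m2")
    ctl = _check_matrix(control, "control")
    if not (m1.shape == m2.shape == ctl.shape):
        raise MicrosatError("matrices must have matching shapes")
    if m1.shape[0] < 4:
        raise MicrosatError("need at least four taxa for a meaningful test")
    vc = _tri(ctl)
    r2 = _residuals(_tri(m2), vc)
    if np.std(r2) < 1e-12 * max(1.0, np.abs(_tri(m2)).max()):
        # m2 is (numerically) collinear with the control: nothing left to
        # correlate, partial r is zero by convention
        return 0.0, 1.0
    r_obs = _pearson(_residuals(_tri(m1), vc), r2)
    rng = np.random.Generator(np.random.PCG64(seed))
    hits = 0
    n = m1.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        try:
            r = _pearson(_residuals(_tri(m1[np.ix_(perm, perm)]), vc), r2)
        except MicrosatError:
            continue
        hits += r >= r_obs - 1e-12
    return r_obs, (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# isolation-by-distance transforms
# ---------------------------------------------------------------------------

def linearized_fst(fst: np.ndarray) -> np.ndarray:
    """``F_ST / (1 - F_ST)`` with negative estimates floored at zero."""
    f = np.clip(np.asarray(fst, dtype=float), 0.0, None)
    return f / (1.0 - f)


def log_distance(km: np.ndarray) -> np.ndarray:
    """Natural log of pairwise distances; the diagonal stays zero."""
    d = np.asarray(km, dtype=float).copy()
    off = ~np.eye(d.shape[0], dtype=bool)
    if (d[off] <= 0).any():
        raise MicrosatError("off-diagonal distances must be positive")
    d[off] = np.log(d[off])
    return d
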