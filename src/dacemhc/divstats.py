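"""Within-population diversity descriptors and equilibrium tests.

Covers unbiased haplotype (gene) diversity, DnaSP-style sequence
descriptors (segregating sites S, mean pairwise differences k, nucleotide
diversity pi), observed/expected heterozygosity, a Hardy-Weinberg exact
test (complete enumeration for small samples, Guo-Thompson-style Markov
chain otherwise), the Ewens-Watterson homozygosity test against nulls from
the Ewens sampling formula, and upstream/downstream allele-sharing counts.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import AlleleCatalog, CatalogError, pairwise_differences


class StatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# allele-count table (the hinge between genotyping and statistics)
# ---------------------------------------------------------------------------

@dataclass
class AlleleCountTable:
    """Site x allele copy counts with river and upstream/downstream labels.

    Backed by a DataFrame with columns ``site``, ``river``, ``position``
    (upstream|downstream) and one integer column per allele.
    """

    df: pd.DataFrame

    META_COLS = ("site", "river", "position")

    def __post_init__(self) -> None:
        for c in self.META_COLS:
            if c not in self.df.columns:
                raise StatError(f"counts table is missing column {c!r}")
        if not self.allele_columns:
            raise StatError("counts table has no allele columns")
        counts = self.df[list(self.allele_columns)]
        if (counts.to_numpy() < 0).any():
            raise StatError("allele counts must be non-negative")

    @property
    def allele_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.df.columns
                     if c not in self.META_COLS and c.lower() != "total")

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(self.df["site"])

    def counts(self, site: str) -> np.ndarray:
        row = self.df.loc[self.df["site"] == site]
        if row.empty:
            raise KeyError(site)
        return row[list(self.allele_columns)].to_numpy(dtype=int)[0]

    def total(self, site: str) -> int:
        return int(self.counts(site).sum())

    def pooled(self, sites: Sequence[str]) -> np.ndarray:
        return np.sum([self.counts(s) for s in sites], axis=0)

    def group_sites(self, grouping: str = "position") -> dict[str, list[str]]:
        if grouping not in self.df.columns:
            raise StatError(f"no grouping column {grouping!r}")
        if self.df[grouping].isna().any() or (self.df[grouping] == "").any():
            bad = self.df.loc[self.df[grouping].isna() |
                              (self.df[grouping] == ""), "site"].tolist()
            raise StatError(f"sites without a {grouping!r} label: {bad}")
        out: dict[str, list[str]] = {}
        for _, row in self.df.iterrows():
            out.setdefault(row[grouping], []).append(row["site"])
        return out


# ---------------------------------------------------------------------------
# diversity descriptors
# ---------------------------------------------------------------------------

def haplotype_diversity(counts: Sequence[int]) -> float:
    """Unbiased gene (haplotype) diversity ``(n/(n-1)) (1 - sum p_i^2)``."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n < 2:
        raise StatError("haplotype diversity needs at least two gene copies")
    p = c / n
    return float(n / (n - 1) * (1.0 - np.sum(p ** 2)))


def nucleotide_stats(catalog: AlleleCatalog,
                     counts: Sequence[int]) -> tuple[int, float, float]:
    """Segregating sites S, mean pairwise differences k, and pi = k/L.

    Only alleles with positive copy count contribute.  k averages raw
    nucleotide differences over all ordered pairs of gene copies,
    ``k = sum_{i<j} c_i c_j d_ij / C(n, 2)`` (identical-copy pairs included
    in the denominator), matching the DnaSP convention.
    """
    c = np.asarray(counts, dtype=float)
    if len(c) != len(catalog):
        raise StatError("count vector length must match catalog size")
    present = c > 0
    n = c.sum()
    if n < 2:
        raise StatError("need at least two gene copies")
    seqs = [s for s, keep in zip(catalog.sequences, present) if keep]
    if len({len(s) for s in seqs}) != 1:
        raise CatalogError("nucleotide statistics need equal-length alleles")
    L = len(seqs[0])
    arr = np.array([list(s) for s in seqs])
    S = int(np.sum([len(set(col)) > 1 for col in arr.T])) if len(seqs) > 1 else 0
    cp = c[present]
    d = np.zeros((len(seqs), len(seqs)))
    for i in range(len(seqs)):
        d[i, i + 1:] = (arr[i + 1:] != arr[i]).sum(axis=1)
    d = d + d.T
    k = float(cp @ d @ cp / 2.0 / (n * (n - 1) / 2.0))
    pi = k / L
    return S, k, pi


def heterozygosities(genotypes: Sequence[tuple[str, str]]) -> tuple[float, float]:
    """Observed and unbiased expected heterozygosity from diploid genotypes."""
    if len(genotypes) < 2:
        raise StatError("need at least two diploid genotypes")
    h_obs = sum(a != b for a, b in genotypes) / len(genotypes)
    counts = Counter()
    for a, b in genotypes:
        counts[a] += 1
        counts[b] += 1
    h_exp = haplotype_diversity(list(counts.values()))
    return h_obs, h_exp


def allele_sharing(table: AlleleCountTable, grouping: str = "position",
                   ) -> tuple[int, int, int]:
    """Distinct-allele counts in each of two groups and in their overlap."""
    groups = table.group_sites(grouping)
    if len(groups) != 2:
        raise StatError(f"grouping {grouping!r} must define exactly two groups")
    (g1, s1), (g2, s2) = sorted(groups.items())
    set1 = {a for a, c in zip(table.allele_columns, table.pooled(s1)) if c > 0}
    set2 = {a for a, c in zip(table.allele_columns, table.pooled(s2)) if c > 0}
    return len(set1), len(set2), len(set1 & set2)


@dataclass
class DiversitySummary:
    site: str
    n: int          # diploid individuals
    h: int          # distinct alleles observed
    H_d: float      # haplotype diversity
    S: int          # polymorphic sites
    k: float        # mean pairwise differences
    pi: float       # nucleotide diversity
    H_exp: float | None = None
    H_obs: float | None = None


def diversity_summary(site: str, catalog: AlleleCatalog, counts: Sequence[int],
                      genotypes: Sequence[tuple[str, str]] | None = None,
                      ) -> DiversitySummary:
    c = np.asarray(counts, dtype=int)
    S, k, pi = nucleotide_stats(catalog, c)
    h_obs = h_exp = None
    if genotypes:
        h_obs, h_exp = heterozygosities(genotypes)
    return DiversitySummary(site, int(c.sum() // 2), int((c > 0).sum()),
                            haplotype_diversity(c), S, k, pi, h_exp, h_obs)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _genotype_counts(genotypes: Iterable[tuple[str, str]]) -> Counter:
    return Counter(tuple(sorted(g)) for g in genotypes)


def _allele_counts(gcounts: Mapping[tuple[str, str], int]) -> Counter:
    out: Counter = Counter()
    for (a, b), n in gcounts.items():
        out[a] += n
        out[b] += n
    return out


def _log_cond_prob_numerator(gcounts: Mapping[tuple[str, str], int]) -> float:
    """log of the table-dependent part of the conditional probability
    P(table | allele counts) = n! 2^H prod m_a! / ((2n)! prod f_ij!)."""
    h = sum(n for (a, b), n in gcounts.items() if a != b)
    return h * math.log(2.0) - sum(math.lgamma(n + 1) for n in gcounts.values())


def hwe_exact_enumeration(genotypes: Sequence[tuple[str, str]]) -> float:
    """Exact Hardy-Weinberg test by complete enumeration of genotype tables.

    Feasible for small samples (intended for <= 12 gene copies); the p-value
    is the total conditional probability of tables no more probable than the
    observed one, given the allele counts.
    """
    obs = _genotype_counts(genotypes)
    alleles = sorted(_allele_counts(obs))
    if len(alleles) < 2:
        return 1.0
    m = _allele_counts(obs)
    pairs = [(alleles[i], alleles[j]) for i in range(len(alleles))
             for j in range(i, len(alleles))]

    tables: list[dict] = []

    def recurse(idx: int, remaining: Counter, current: dict) -> None:
        if idx == len(pairs):
            if all(v == 0 for v in remaining.values()):
                tables.append(dict(current))
            return
        a, b = pairs[idx]
        if a == b:
            maxn = remaining[a] // 2
        else:
            maxn = min(remaining[a], remaining[b])
        # prune: remaining copies must be pairable by later pairs
        for n in range(maxn + 1):
            remaining[a] -= n if a == b else n
            if a == b:
                remaining[a] -= n
            else:
                remaining[b] -= n
            current[(a, b)] = n
            recurse(idx + 1, remaining, current)
            if a == b:
                remaining[a] += 2 * n
            else:
                remaining[a] += n
                remaining[b] += n
        del current[(a, b)]

    recurse(0, Counter(m), {})
    logps = np.array([_log_cond_prob_numerator(
        {k: v for k, v in t.items() if v}) for t in tables])
    logZ = _logsumexp(logps)
    obs_lp = _log_cond_prob_numerator(dict(obs))
    keep = logps <= obs_lp + 1e-9
    return float(np.exp(_logsumexp(logps[keep]) - logZ))


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    return float(m + np.log(np.sum(np.exp(x - m))))


def hwe_exact_test(genotypes: Sequence[tuple[str, str]],
                   chain_steps: int = 100_000, dememorization: int = 1_000,
                   seed: int = 0) -> float:
    """Markov-chain exact test of Hardy-Weinberg equilibrium.

    The chain walks over genotype tables with the observed allele counts by
    randomly transposing entries of the underlying allele array; a uniform
    pairing of gene copies induces exactly the conditional distribution of
    tables given allele counts, so no Metropolis correction is needed.  The
    p-value is the fraction of visited states whose conditional probability
    does not exceed the observed table's.
    """
    obs = _genotype_counts(genotypes)
    alleles = _allele_counts(obs)
    if len(alleles) < 2:
        return 1.0
    rng = np.random.Generator(np.random.PCG64(seed))

    arr: list[str] = []
    for (a, b), n in sorted(obs.items()):
        arr.extend([a, b] * n)
    arr = np.array(arr)
    n2 = len(arr)
    obs_lp = _log_cond_prob_numerator(dict(obs))

    current = Counter(obs)
    lp = obs_lp

    def pair_of(i: int) -> int:
        return i + 1 if i % 2 == 0 else i - 1

    hits = 0
    total_steps = dememorization + chain_steps
    idx1 = rng.integers(n2, size=total_steps)
    idx2 = rng.integers(n2, size=total_steps)
    for step in range(total_steps):
        i, j = int(idx1[step]), int(idx2[step])
        if i // 2 != j // 2:
            gi = tuple(sorted((arr[i], arr[pair_of(i)])))
            gj = tuple(sorted((arr[j], arr[pair_of(j)])))
            arr[i], arr[j] = arr[j], arr[i]
            ni = tuple(sorted((arr[i], arr[pair_of(i)])))
            nj = tuple(sorted((arr[j], arr[pair_of(j)])))
            if (gi, gj) != (ni, nj):
                for g in (gi, gj):
                    lp += math.lgamma(current[g] + 1)
                    if g[0] != g[1]:
                        lp -= math.log(2.0)
                    current[g] -= 1
                    lp -= math.lgamma(current[g] + 1)
                for g in (ni, nj):
                    lp += math.lgamma(current[g] + 1)
                    current[g] += 1
                    lp -= math.lgamma(current[g] + 1)
                    if g[0] != g[1]:
                        lp += math.log(2.0)
        if step >= dememorization and lp <= obs_lp + 1e-9:
            hits += 1
    return hits / chain_steps


# ---------------------------------------------------------------------------
# Ewens-Watterson homozygosity test
# ---------------------------------------------------------------------------

def _solve_theta(n: int, k: int) -> float:
    """theta such that the Ewens expectation of the allele number equals k."""
    if k <= 1:
        return 1e-9
    theta = float(k)
    for _ in range(100):
        i = np.arange(n, dtype=float)
        f = np.sum(theta / (theta + i)) - k
        fp = np.sum(i / (theta + i) ** 2)
        if fp == 0:
            break
        step = f / fp
        theta = max(theta - step, 1e-9)
        if abs(step) < 1e-12:
            break
    return theta


def _sample_esf_config(n: int, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Allele configuration of an n-sample under the Ewens sampling formula
    (Chinese-restaurant construction)."""
    counts: list[int] = []
    for i in range(n):
        if rng.random() < theta / (theta + i):
            counts.append(1)
        else:
            r = rng.random() * i
            acc = 0.0
            for j, c in enumerate(counts):
                acc += c
                if r < acc:
                    counts[j] += 1
                    break
    return np.array(counts)


def ewens_watterson_test(counts: Sequence[int], n_sim: int = 1_000,
                         seed: int = 0) -> tuple[float, float]:
    """Watterson's homozygosity test of neutrality.

    ``F_obs = sum p_i^2`` is compared with null samples of the same size and
    allele number drawn under the Ewens sampling formula (rejection on the
    observed allele number k, with theta matched to E[k] = k by Newton
    iteration).  Returns ``(F_obs, one-sided p)`` where p is the fraction of
    null samples at least as homozygous as observed.
    """
    c = np.asarray([x for x in counts if x > 0], dtype=float)
    n = int(c.sum())
    k = len(c)
    if n < 2:
        raise StatError("need at least two gene copies")
    if k < 2:
        raise StatError("Ewens-Watterson test undefined for a single allele")
    F_obs = float(np.sum((c / n) ** 2))
    theta = _solve_theta(n, k)
    rng = np.random.Generator(np.random.PCG64(seed))
    sims = 0
    hits = 0
    attempts = 0
    max_attempts = n_sim * 10_000
    while sims < n_sim and attempts < max_attempts:
        attempts += 1
        cfg = _sample_esf_config(n, theta, rng)
        if len(cfg) != k:
            continue
        F = float(np.sum((cfg / n) ** 2))
        hits += F >= F_obs - 1e-12
        sims += 1
    if sims == 0:
        raise StatError("Ewens null simulation failed to match allele number")
    return F_obs, hits / sims
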