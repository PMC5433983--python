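"""Analysis of molecular variance on sequence-aware genotype data.

Implements pairwise Phi_ST between populations, a four-level hierarchical
AMOVA (within individuals / among individuals within sites / among sites
within rivers / among rivers) with per-level permutation tests, and the
between-population divergence Dxy.  Distances between alleles are raw
nucleotide difference counts, used directly as squared distances in the
Excoffier-style sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .catalog import AlleleCatalog, pairwise_differences


class AmovaError(ValueError):
    pass


@dataclass(frozen=True)
class DiploidRecord:
    """One genotyped individual: river / site labels and two allele indices."""

    individual_id: str
    site: str
    river: str
    a1: int
    a2: int


@dataclass
class AmovaResult:
    levels: tuple[str, ...]
    df: tuple[int, ...]
    sigma2: tuple[float, ...]
    percent: tuple[float, ...]
    p_values: tuple[float, ...]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"level": self.levels, "df": self.df,
                             "sigma2": self.sigma2, "percent": self.percent,
                             "p": self.p_values})


def _pool_ss(count_vec: np.ndarray, d: np.ndarray) -> float:
    """(1/n) sum_{i<j} d_ij over a pool of copies given its allele counts."""
    n = count_vec.sum()
    if n == 0:
        return 0.0
    return float(count_vec @ d @ count_vec / 2.0) / n


def _percent(sigmas: Sequence[float]) -> tuple[float, ...]:
    clipped = np.clip(sigmas, 0.0, None)
    tot = clipped.sum()
    if tot == 0:
        return tuple(0.0 for _ in sigmas)
    return tuple(100.0 * s / tot for s in clipped)


# ---------------------------------------------------------------------------
# pairwise Phi_ST
# ---------------------------------------------------------------------------

def _phi_from_pools(genos: np.ndarray, labels: np.ndarray, d: np.ndarray,
                    n_alleles: int) -> float:
    """Two-level Phi_ST treating every gene copy as one unit."""
    pops = np.unique(labels)
    r = len(pops)
    counts = np.zeros((r, n_alleles))
    for pi, p in enumerate(pops):
        sel = genos[labels == p].ravel()
        counts[pi] = np.bincount(sel, minlength=n_alleles)
    n_p = counts.sum(axis=1)
    N = n_p.sum()
    total_counts = counts.sum(axis=0)
    ss_total = _pool_ss(total_counts, d)
    ss_within = sum(_pool_ss(counts[pi], d) for pi in range(r))
    ss_among = ss_total - ss_within
    df_a, df_w = r - 1, N - r
    if df_w <= 0:
        raise AmovaError("every population needs at least two gene copies")
    sigma_w = ss_within / df_w
    n_c = (N - np.sum(n_p ** 2) / N) / (r - 1)
    sigma_a = (ss_among / df_a - sigma_w) / n_c
    denom = sigma_a + sigma_w
    if denom == 0:
        return 0.0
    return float(sigma_a / denom)


def phi_st(genotypes_a: Sequence[tuple[int, int]],
           genotypes_b: Sequence[tuple[int, int]],
           diffs: np.ndarray, n_perm: int = 110, seed: int = 0,
           ) -> tuple[float, float]:
    """Pairwise Phi_ST between two populations with a permutation p-value.

    Genotypes are pairs of allele indices into ``diffs``.  Permutations
    reassign whole individuals (both gene copies) between the populations;
    the observed value is included in the null set, so p >= 1/(n_perm+1).
    """
    if len(genotypes_a) < 1 or len(genotypes_b) < 1:
        raise AmovaError("both populations must be non-empty")
    genos = np.array(list(genotypes_a) + list(genotypes_b), dtype=int)
    labels = np.array([0] * len(genotypes_a) + [1] * len(genotypes_b))
    K = len(diffs)
    obs = _phi_from_pools(genos, labels, diffs, K)
    rng = np.random.Generator(np.random.PCG64(seed))
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        val = _phi_from_pools(genos, labels[perm], diffs, K)
        hits += val >= obs - 1e-12
    p = (hits + 1) / (n_perm + 1)
    return obs, p


# ---------------------------------------------------------------------------
# hierarchical AMOVA
# ---------------------------------------------------------------------------

LEVELS = ("among rivers", "among sites within rivers",
          "among individuals within sites", "within individuals")


def _decompose(records: Sequence[DiploidRecord], d: np.ndarray,
               n_alleles: int) -> tuple[np.ndarray, np.ndarray]:
    """Variance components (sigma2_a, sigma2_b, sigma2_c, sigma2_e) and dfs."""
    rivers = sorted({r.river for r in records})
    sites = sorted({(r.river, r.site) for r in records})
    G, S, n = len(rivers), len(sites), len(records)
    N = 2 * n
    if G < 2:
        raise AmovaError("need at least two rivers")

    site_counts = {s: np.zeros(n_alleles) for s in sites}
    river_counts = {g: np.zeros(n_alleles) for g in rivers}
    ss_wi = 0.0
    for rec in records:
        for a in (rec.a1, rec.a2):
            site_counts[(rec.river, rec.site)][a] += 1
            river_counts[rec.river][a] += 1
        ss_wi += d[rec.a1, rec.a2] / 2.0

    ss_ws = sum(_pool_ss(c, d) for c in site_counts.values())
    ss_wr = sum(_pool_ss(c, d) for c in river_counts.values())
    total_counts = sum(river_counts.values())
    ss_total = _pool_ss(total_counts, d)

    ss_ai = ss_ws - ss_wi          # among individuals within sites
    ss_as = ss_wr - ss_ws          # among sites within rivers
    ss_ar = ss_total - ss_wr       # among rivers

    N_s = {s: c.sum() for s, c in site_counts.items()}
    N_r = {g: c.sum() for g, c in river_counts.items()}
    sites_in = {g: [s for s in sites if s[0] == g] for g in rivers}

    df = np.array([G - 1, S - G, n - S, N - n], dtype=int)
    if df[1] < 0 or df[2] <= 0:
        raise AmovaError("degenerate stratum layout")

    # method-of-moments coefficients for the nested random-effects model
    # (each individual contributes exactly two copies)
    sigma_e = ss_wi / df[3]
    sigma_c = (ss_ai - df[2] * sigma_e) / (N - 2 * S)
    c_b = N - sum(N_s[s] ** 2 / N_r[s[0]] for s in sites)
    if df[1] > 0 and c_b > 0:
        sigma_b = (ss_as - df[1] * sigma_e - 2 * df[1] * sigma_c) / c_b
    else:
        sigma_b = 0.0
    c_ab = sum(N_s[s] ** 2 / N_r[s[0]] for s in sites) - \
        sum(N_s[s] ** 2 for s in sites) / N
    c_a = N - sum(v ** 2 for v in N_r.values()) / N
    sigma_a = (ss_ar - df[0] * sigma_e - 2 * df[0] * sigma_c
               - c_ab * sigma_b) / c_a
    return np.array([sigma_a, sigma_b, sigma_c, sigma_e]), df


def hierarchical_amova(records: Sequence[DiploidRecord], diffs: np.ndarray,
                       n_perm: int = 3024, seed: int = 0) -> AmovaResult:
    """Four-level AMOVA with per-level permutation tests.

    Permutation schemes (one per tested level):

    * within individuals / among individuals — gene copies are re-paired at
      random among the individuals of each site;
    * among sites within rivers — individuals are reassigned among the
      sites of their river;
    * among rivers — whole sites are reassigned among rivers.

    For the within-individual component the p-value is the fraction of
    permutations with a component at or below the observed one (a deficit of
    within-individual variation signals heterozygote deficiency); for the
    among levels it is the fraction at or above.
    """
    records = list(records)
    K = len(diffs)
    obs, df = _decompose(records, diffs, K)
    rng = np.random.Generator(np.random.PCG64(seed))

    rivers = sorted({r.river for r in records})
    hits = np.zeros(4)

    def perm_copies_within_sites() -> list[DiploidRecord]:
        out = []
        by_site: dict[tuple[str, str], list[DiploidRecord]] = {}
        for rec in records:
            by_site.setdefault((rec.river, rec.site), []).append(rec)
        for (riv, site), recs in sorted(by_site.items()):
            copies = np.array([a for r in recs for a in (r.a1, r.a2)])
            rng.shuffle(copies)
            for i, r in enumerate(recs):
                out.append(DiploidRecord(r.individual_id, site, riv,
                                         int(copies[2 * i]), int(copies[2 * i + 1])))
        return out

    def perm_individuals_within_rivers() -> list[DiploidRecord]:
        out = []
        by_river: dict[str, list[DiploidRecord]] = {}
        for rec in records:
            by_river.setdefault(rec.river, []).append(rec)
        for riv, recs in sorted(by_river.items()):
            site_labels = np.array([r.site for r in recs])
            rng.shuffle(site_labels)
            for r, s in zip(recs, site_labels):
                out.append(DiploidRecord(r.individual_id, str(s), riv, r.a1, r.a2))
        return out

    def perm_sites_among_rivers() -> list[DiploidRecord]:
        sites = sorted({(r.river, r.site) for r in records})
        new_river = {s: rivers[i] for s, i in
                     zip(sites, rng.permutation(
                         [rivers.index(s[0]) for s in sites]))}
        return [DiploidRecord(r.individual_id, r.site,
                              new_river[(r.river, r.site)], r.a1, r.a2)
                for r in records]

    for _ in range(n_perm):
        s_copy, _ = _decompose(perm_copies_within_sites(), diffs, K)
        hits[3] += s_copy[3] <= obs[3] + 1e-12
        hits[2] += s_copy[2] >= obs[2] - 1e-12
        if df[1] > 0:
            s_ind, _ = _decompose(perm_individuals_within_rivers(), diffs, K)
            hits[1] += s_ind[1] >= obs[1] - 1e-12
        s_site, _ = _decompose(perm_sites_among_rivers(), diffs, K)
        hits[0] += s_site[0] >= obs[0] - 1e-12

    p = tuple((h + 1) / (n_perm + 1) for h in hits)
    return AmovaResult(LEVELS, tuple(int(x) for x in df),
                       tuple(float(x) for x in obs), _percent(obs), p)


# ---------------------------------------------------------------------------
# Dxy
# ---------------------------------------------------------------------------

def dxy(counts_a: Sequence[int], counts_b: Sequence[int],
        catalog: AlleleCatalog) -> float:
    """Average number of nucleotide substitutions per site between two
    populations: ``sum_ij x_i y_j d_ij / L`` over allele frequencies."""
    d = pairwise_differences(catalog)
    L = catalog.length
    if L == 0:
        raise AmovaError("alignment length is zero")
    x = np.asarray(counts_a, dtype=float)
    y = np.asarray(counts_b, dtype=float)
    if x.sum() == 0 or y.sum() == 0:
        raise AmovaError("both populations need at least one gene copy")
    x, y = x / x.sum(), y / y.sum()
    return float(x @ d @ y / L)
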