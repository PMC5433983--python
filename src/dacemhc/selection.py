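"""Codon-level selection inference on the exon alignment.

Implements the Nei-Gojobori (1986) pathway method for synonymous and
nonsynonymous sites and differences with Jukes-Cantor correction, a
codon-site-bootstrap Z-test of dN - dS = 0, the Hudson-Kaplan four-gamete
lower bound on recombination events, a permutation-based sliding-window
scan for codon regions with nonsynonymous excess, Jukes-Cantor distances
and a neighbor-joining allele tree.

The window scan is a deliberately simple frequentist stand-in for full
Bayesian variable-omega models: windows are flagged only when their
empirical exceedance probability clears the threshold in two independently
seeded permutation runs, mirroring the two-run agreement rule used with
MCMC samplers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Sequence

import numpy as np
from scipy.stats import norm

BASES = "ACGT"


class SelectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# codon machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def _code(table_id: int = 1) -> dict[str, str]:
    from Bio.Data import CodonTable

    tbl = CodonTable.unambiguous_dna_by_id[table_id]
    code = dict(tbl.forward_table)
    for stop in tbl.stop_codons:
        code[stop] = "*"
    return code


@lru_cache(maxsize=4)
def _codon_tables(table_id: int = 1):
    """Per-codon synonymous site counts and pairwise pathway difference
    counts, cached.  Changes into stop codons count as nonsynonymous for
    site counting; mutational paths through stop codons are excluded."""
    code = _code(table_id)
    codons = [a + b + c for a in BASES for b in BASES for c in BASES]
    idx = {c: i for i, c in enumerate(codons)}

    s_sites = np.zeros(64)
    for c in codons:
        if code[c] == "*":
            s_sites[idx[c]] = np.nan
            continue
        syn = 0.0
        for pos in range(3):
            for b in BASES:
                if b == c[pos]:
                    continue
                m = c[:pos] + b + c[pos + 1:]
                if code[m] == code[c]:  # stop targets are never synonymous
                    syn += 1
        s_sites[idx[c]] = syn / 3.0

    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for c1 in codons:
        if code[c1] == "*":
            continue
        for c2 in codons:
            if code[c2] == "*" or c1 == c2:
                continue
            diff = [p for p in range(3) if c1[p] != c2[p]]
            path_syn, path_non, n_paths = 0.0, 0.0, 0
            all_syn, all_non = 0.0, 0.0
            for order in permutations(diff):
                cur = c1
                syn = non = 0
                valid = True
                for p in order:
                    nxt = cur[:p] + c2[p] + cur[p + 1:]
                    if code[nxt] == "*":
                        valid = False
                        non += 1
                    elif code[nxt] == code[cur]:
                        syn += 1
                    else:
                        non += 1
                    cur = nxt
                all_syn += syn
                all_non += non
                if valid:
                    path_syn += syn
                    path_non += non
                    n_paths += 1
            if n_paths:
                sd[idx[c1], idx[c2]] = path_syn / n_paths
                nd[idx[c1], idx[c2]] = path_non / n_paths
            else:  # every path crosses a stop: average over all paths
                k = math.factorial(len(diff))
                sd[idx[c1], idx[c2]] = all_syn / k
                nd[idx[c1], idx[c2]] = all_non / k
    return idx, s_sites, sd, nd


@dataclass(frozen=True)
class CodonAlignment:
    """Exon-only aligned coding sequences (whole codons, no internal stops)."""

    sequences: tuple[str, ...]
    table_id: int = 1

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise SelectionError("need at least two sequences")
        L = len(self.sequences[0])
        if L % 3 != 0 or L == 0:
            raise SelectionError("alignment length must be a positive codon multiple")
        code = _code(self.table_id)
        for s in self.sequences:
            if len(s) != L:
                raise SelectionError("sequences must be aligned to equal length")
            if not set(s) <= set(BASES):
                raise SelectionError("only A/C/G/T are allowed")
            for i in range(0, L, 3):
                if code[s[i:i + 3]] == "*":
                    raise SelectionError(f"internal stop codon at nt {i}")

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def codon_indices(self) -> np.ndarray:
        idx, *_ = _codon_tables(self.table_id)
        return np.array([[idx[s[i:i + 3]] for i in range(0, len(s), 3)]
                         for s in self.sequences])


def _pair_arrays(aln: CodonAlignment, weights: Sequence[float] | None):
    """Per-(pair, codon) arrays of syn/nonsyn sites and differences, plus
    pair weights (copy-count products; identical-sequence pairs carry
    C(c,2) weight and zero difference)."""
    _, s_sites, sd, nd = _codon_tables(aln.table_id)
    ci = aln.codon_indices()
    n, C = ci.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != n:
        raise SelectionError("weights length must match sequence count")
    pairs, pw = [], []
    for i in range(n):
        if w[i] > 1:
            pairs.append((i, i))
            pw.append(w[i] * (w[i] - 1) / 2.0)
        for j in range(i + 1, n):
            pairs.append((i, j))
            pw.append(w[i] * w[j])
    P = len(pairs)
    S = np.empty((P, C))
    SD = np.empty((P, C))
    ND = np.empty((P, C))
    for p, (i, j) in enumerate(pairs):
        S[p] = (s_sites[ci[i]] + s_sites[ci[j]]) / 2.0
        SD[p] = sd[ci[i], ci[j]]
        ND[p] = nd[ci[i], ci[j]]
    return np.asarray(pw), S, SD, ND


def _jc(p: float) -> float:
    if p >= 0.75:
        raise SelectionError(
            f"proportion {p:.4f} >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _jc_flagged(p: float) -> float:
    """Jukes-Cantor correction, NaN (flagged undefined) when p >= 3/4."""
    return float("nan") if p >= 0.75 else _jc(p)


@dataclass
class NeiGojoboriResult:
    syn_sites: float
    nonsyn_sites: float
    pS: float
    pN: float
    dS: float
    dN: float

    @property
    def ratio(self) -> float:
        """dN/dS, NaN when dS is zero."""
        return self.dN / self.dS if self.dS > 0 else float("nan")


def _weighted_props(pw, S, SD, ND, col_counts=None):
    """Weighted mean pairwise pS and pN (and site totals) over codon
    columns, optionally weighted by per-column multiplicities."""
    if col_counts is None:
        s_tot = S.sum(axis=1)
        sd_tot = SD.sum(axis=1)
        nd_tot = ND.sum(axis=1)
        n_tot = 3.0 * S.shape[1] - s_tot
    else:
        s_tot = S @ col_counts
        sd_tot = SD @ col_counts
        nd_tot = ND @ col_counts
        n_tot = 3.0 * col_counts.sum() - s_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(s_tot > 0, sd_tot / s_tot, 0.0)
        pn = np.where(n_tot > 0, nd_tot / n_tot, 0.0)
    W = pw.sum()
    return (float(pw @ ps / W), float(pw @ pn / W),
            float(pw @ s_tot / W), float(pw @ n_tot / W))


def nei_gojobori(aln: CodonAlignment,
                 weights: Sequence[float] | None = None) -> NeiGojoboriResult:
    """Nei-Gojobori pathway estimates of synonymous/nonsynonymous change.

    Per-pair proportions ``pS = Sd/S`` and ``pN = Nd/N`` are averaged over
    all weighted sequence pairs and Jukes-Cantor corrected
    (``d = -3/4 ln(1 - 4p/3)``).  ``weights`` are per-sequence copy counts;
    a weight of 2 is equivalent to listing the sequence twice.
    """
    pw, S, SD, ND = _pair_arrays(aln, weights)
    ps, pn, s_sites, n_sites = _weighted_props(pw, S, SD, ND)
    return NeiGojoboriResult(s_sites, n_sites, ps, pn, _jc_flagged(ps),
                             _jc_flagged(pn))


def codon_z_test(aln: CodonAlignment, weights: Sequence[float] | None = None,
                 n_boot: int = 500, seed: int = 0) -> tuple[float, float]:
    """Codon-based Z-test of neutrality (H0: dN - dS = 0).

    The standard error of dN - dS comes from bootstrapping codon sites
    (columns resampled with replacement, codon integrity preserved); the
    p-value is two-sided from the normal reference distribution.
    """
    pw, S, SD, ND = _pair_arrays(aln, weights)
    C = S.shape[1]
    ps, pn, *_ = _weighted_props(pw, S, SD, ND)
    d_obs = _jc_flagged(pn) - _jc_flagged(ps)
    if (SD.sum() == 0 and ND.sum() == 0) or not np.isfinite(d_obs):
        return 0.0, 1.0
    rng = np.random.Generator(np.random.PCG64(seed))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        cols = rng.integers(C, size=C)
        counts = np.bincount(cols, minlength=C).astype(float)
        ps_b, pn_b, *_ = _weighted_props(pw, S, SD, ND, counts)
        boots[b] = _jc_flagged(pn_b) - _jc_flagged(ps_b)
    se = float(np.nanstd(boots, ddof=1))
    if not np.isfinite(se) or se == 0:
        warnings.warn("zero bootstrap variance; Z-test degenerate")
        return 0.0, 1.0
    z = d_obs / se
    return z, float(2.0 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# recombination: Hudson-Kaplan Rm
# ---------------------------------------------------------------------------

def four_gamete_rm(sequences: Sequence[str]) -> int:
    """Hudson-Kaplan minimum number of recombination events.

    Site pairs exhibiting all four gametes define intervals that must each
    contain a recombination event; interval culling (keep only pairwise
    disjoint intervals, greedily by right endpoint) gives the lower bound
    Rm.  Only biallelic sites enter the test.
    """
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise SelectionError("sequences must be aligned to equal length")
    cols = [[s[i] for s in sequences] for i in range(L)]
    bi = [i for i, col in enumerate(cols) if len(set(col)) == 2]
    intervals = []
    for a_i in range(len(bi)):
        for b_i in range(a_i + 1, len(bi)):
            i, j = bi[a_i], bi[b_i]
            gametes = {(cols[i][s], cols[j][s]) for s in range(len(sequences))}
            if len(gametes) == 4:
                intervals.append((i, j))
    rm = 0
    last_end = -1
    for i, j in sorted(intervals, key=lambda iv: iv[1]):
        if i >= last_end:  # disjoint: needs its own event
            rm += 1
            last_end = j
    return rm


# ---------------------------------------------------------------------------
# sliding-window nonsynonymous-excess scan
# ---------------------------------------------------------------------------

@dataclass
class SelectionScanResult:
    windows: tuple[tuple[int, int], ...]   # codon intervals, half-open
    statistic: tuple[float, ...]           # observed pN - pS per window
    omega: tuple[float, ...]               # pN/pS per window (NaN if pS = 0)
    exceedance: tuple[tuple[float, ...], ...]  # per run, per window
    flagged: tuple[bool, ...]


def _window_stats(pw, S, SD, ND, order: np.ndarray,
                  windows: Sequence[tuple[int, int]]) -> np.ndarray:
    out = np.empty(len(windows))
    W = pw.sum()
    for wi, (a, b) in enumerate(windows):
        cols = order[a:b]
        s_tot = S[:, cols].sum(axis=1)
        n_tot = 3.0 * len(cols) - s_tot
        sd_tot = SD[:, cols].sum(axis=1)
        nd_tot = ND[:, cols].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ps = np.where(s_tot > 0, sd_tot / s_tot, 0.0)
            pn = np.where(n_tot > 0, nd_tot / n_tot, 0.0)
        out[wi] = float(pw @ (pn - ps) / W)
    return out


def window_dnds_scan(aln: CodonAlignment,
                     weights: Sequence[float] | None = None,
                     window_codons: int = 10, n_perm: int = 200,
                     threshold_prob: float = 0.95,
                     seeds: tuple[int, int] = (1, 2)) -> SelectionScanResult:
    """Permutation scan for windows with excess nonsynonymous change.

    For each window of ``window_codons`` codons the statistic is the
    weighted pairwise ``pN - pS`` restricted to the window.  The null
    shuffles codon columns alignment-wide; a window is flagged only when
    its exceedance probability (fraction of permutations it beats) reaches
    ``threshold_prob`` in both seeded runs.
    """
    C = aln.n_codons
    if window_codons < 1 or window_codons > C:
        raise SelectionError("window length must lie in [1, n_codons]")
    pw, S, SD, ND = _pair_arrays(aln, weights)
    windows = [(a, min(a + window_codons, C))
               for a in range(0, C, window_codons)]
    identity = np.arange(C)
    obs = _window_stats(pw, S, SD, ND, identity, windows)

    exceed = []
    for seed in seeds:
        rng = np.random.Generator(np.random.PCG64(seed))
        beats = np.zeros(len(windows))
        for _ in range(n_perm):
            perm = rng.permutation(C)
            null = _window_stats(pw, S, SD, ND, perm, windows)
            beats += obs > null + 1e-12
        exceed.append(tuple(beats / n_perm))
    flags = tuple(all(run[w] >= threshold_prob for run in exceed)
                  for w in range(len(windows)))
    with np.errstate(divide="ignore", invalid="ignore"):
        omegas = []
        for a, b in windows:
            s_tot = S[:, a:b].sum(axis=1)
            n_tot = 3.0 * (b - a) - s_tot
            ps = float(pw @ np.where(s_tot > 0, SD[:, a:b].sum(axis=1) / s_tot, 0.0) / pw.sum())
            pn = float(pw @ np.where(n_tot > 0, ND[:, a:b].sum(axis=1) / n_tot, 0.0) / pw.sum())
            omegas.append(pn / ps if ps > 0 else float("nan"))
    return SelectionScanResult(tuple(windows), tuple(obs), tuple(omegas),
                               tuple(exceed), flags)


# ---------------------------------------------------------------------------
# distances and trees
# ---------------------------------------------------------------------------

def jc_distance(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor distance assuming uniform rates among sites."""
    if len(seq_a) != len(seq_b):
        raise SelectionError("sequences must have equal length")
    if not (set(seq_a) | set(seq_b)) <= set(BASES):
        raise SelectionError("ambiguity codes are not supported")
    p = sum(a != b for a, b in zip(seq_a, seq_b)) / len(seq_a)
    return _jc(p)


def nj_tree(labels: Sequence[str], d: np.ndarray) -> str:
    """Saitou-Nei neighbor-joining tree, returned as unrooted Newick."""
    d = np.asarray(d, dtype=float)
    if d.shape[0] != d.shape[1] or len(labels) != d.shape[0]:
        raise SelectionError("distance matrix and labels do not match")
    if d.shape[0] < 3:
        raise SelectionError("neighbor joining needs at least three taxa")
    if not np.allclose(d, d.T):
        raise SelectionError("distance matrix must be symmetric")
    from skbio import DistanceMatrix
    from skbio.tree import nj as _nj

    tree = _nj(DistanceMatrix(d, list(labels)))
    return str(tree).strip()
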