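"""Diversity descriptors and equilibrium tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dacemhc import divstats
from dacemhc.catalog import AlleleCatalog
from dacemhc.divstats import StatError


class TestHaplotypeDiversity:
    @pytest.mark.parametrize("counts, expected", [
        ([3, 9, 10, 6, 1, 2, 0, 7], 0.82788),   # Bow upstream
        ([1, 11, 8, 7, 0, 4, 0, 9], 0.81282),   # Oldman upstream
        ([4, 15, 4, 8, 1, 0, 0, 6], 0.77240),   # Oldman downstream
        ([2, 2], 2 / 3),                          # (4/3)(1 - 8/16)
    ])
    def test_known_values(self, counts, expected):
        assert divstats.haplotype_diversity(counts) == pytest.approx(
            expected, abs=5e-6)

    def test_monomorphic_is_zero(self):
        assert divstats.haplotype_diversity([38]) == 0.0

    def test_single_copy_raises(self):
        with pytest.raises(StatError):
            divstats.haplotype_diversity([1])

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=10)
           .filter(lambda c: sum(c) >= 2))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds_and_equality_with_h_exp(self, counts):
        hd = divstats.haplotype_diversity(counts)
        assert 0.0 <= hd <= 1.0 + 1e-12
        # same formula as unbiased expected heterozygosity
        genos = []
        copies = [a for a, c in enumerate(counts) for _ in range(c)]
        for i in range(0, len(copies) - 1, 2):
            genos.append((str(copies[i]), str(copies[i + 1])))
        if len(genos) >= 2:
            _, h_exp = divstats.heterozygosities(genos)
            assert h_exp == pytest.approx(
                divstats.haplotype_diversity(
                    np.bincount([int(a) for g in genos for a in g])), abs=1e-12)


class TestNucleotideStats:
    def test_single_pair_single_difference(self):
        cat = AlleleCatalog((("X", "ACGT"), ("Y", "ACGA")), exon_span=(0, 3))
        S, k, pi = divstats.nucleotide_stats(cat, [1, 1])
        assert (S, k, pi) == (1, 1.0, 0.25)

    def test_monomorphic(self):
        cat = AlleleCatalog((("X", "ACGT"), ("Y", "ACGA")), exon_span=(0, 3))
        S, k, pi = divstats.nucleotide_stats(cat, [5, 0])
        assert (S, k, pi) == (0, 0.0, 0.0)

    def test_full_catalog_segregating_sites(self, catalog8):
        arr = np.array([list(s) for s in catalog8.sequences])
        expected = sum(len(set(col)) > 1 for col in arr.T)
        S, k, pi = divstats.nucleotide_stats(catalog8, [5] * 8)
        assert S == expected == 16
        assert k == pytest.approx(pi * 236)

    def test_relabeling_invariance(self, catalog8):
        counts = [3, 9, 10, 6, 1, 2, 0, 7]
        S1, k1, _ = divstats.nucleotide_stats(catalog8, counts)
        perm = [4, 2, 0, 6, 1, 7, 3, 5]
        cat2 = AlleleCatalog(tuple((f"B{i}", catalog8.sequences[j])
                                   for i, j in enumerate(perm)),
                             exon_span=catalog8.exon_span)
        S2, k2, _ = divstats.nucleotide_stats(
            cat2, [counts[j] for j in perm])
        assert S1 == S2 and k1 == pytest.approx(k2)


class TestHeterozygosities:
    def test_all_homozygous(self):
        h_obs, _ = divstats.heterozygosities([("A", "A")] * 10 + [("B", "B")] * 10)
        assert h_obs == 0.0

    def test_all_heterozygous_two_alleles(self):
        genos = [("A", "B")] * 500
        h_obs, h_exp = divstats.heterozygosities(genos)
        assert h_obs == 1.0
        assert h_exp == pytest.approx(0.5, abs=1e-3)

    def test_bow_up_observed_rounding(self):
        # 19 diploids, 14 heterozygous -> 0.737
        genos = [("A", "B")] * 14 + [("A", "A")] * 5
        h_obs, _ = divstats.heterozygosities(genos)
        assert round(h_obs, 3) == 0.737


class TestHweExact:
    def test_two_homozygotes_enumeration(self):
        # allele counts (2, 2): tables {AA,aa} (p=1/3) and {Aa,Aa} (p=2/3)
        p = divstats.hwe_exact_enumeration([("A", "A"), ("a", "a")])
        assert p == pytest.approx(1 / 3)

    def test_all_heterozygotes_enumeration(self):
        p = divstats.hwe_exact_enumeration([("A", "a")] * 4)
        assert p > 0.05

    def test_monomorphic_is_one(self):
        assert divstats.hwe_exact_test([("A", "A")] * 6, 100, 10, 0) == 1.0
        assert divstats.hwe_exact_enumeration([("A", "A")] * 6) == 1.0

    @pytest.mark.parametrize("genos", [
        [("A", "A"), ("a", "a")],
        [("A", "a")] * 5,
        [("A", "A"), ("A", "a"), ("a", "a"), ("A", "a")],
        [("A", "B"), ("A", "C"), ("B", "C"), ("A", "A"), ("C", "C")],
    ])
    def test_chain_matches_enumeration(self, genos):
        exact = divstats.hwe_exact_enumeration(genos)
        steps = 40_000
        p = divstats.hwe_exact_test(genos, steps, 500, seed=13)
        # Monte-Carlo tolerance; chain samples are autocorrelated, so allow
        # a generous multiple of the iid binomial SE
        se = np.sqrt(exact * (1 - exact) / steps)
        assert abs(p - exact) < max(20 * se, 0.02)


class TestEwensWatterson:
    def test_f_obs_for_bow_up(self):
        F, _ = divstats.ewens_watterson_test([3, 9, 10, 6, 1, 2, 0, 7],
                                             n_sim=100, seed=1)
        assert F == pytest.approx(280 / 1444)

    def test_two_singletons(self):
        F, _ = divstats.ewens_watterson_test([1, 1], n_sim=100, seed=1)
        assert F == pytest.approx(0.5)

    def test_even_configuration_has_high_p(self):
        # maximal evenness minimizes F, so p(F_null >= F_obs) ~ 1
        _, p = divstats.ewens_watterson_test([10] * 4, n_sim=400, seed=2)
        assert p > 0.9

    def test_null_mean_f_decreases_with_k(self):
        rng = np.random.default_rng(5)
        means = []
        for k in (2, 4, 6):
            sims = []
            theta = divstats._solve_theta(40, k)
            while len(sims) < 300:
                cfg = divstats._sample_esf_config(40, theta, rng)
                if len(cfg) == k:
                    sims.append(np.sum((cfg / 40) ** 2))
            means.append(np.mean(sims))
        assert means[0] > means[1] > means[2]

    def test_single_allele_raises(self):
        with pytest.raises(StatError):
            divstats.ewens_watterson_test([10], n_sim=10, seed=0)


class TestAlleleSharing:
    def test_published_upstream_downstream_sharing(self, published_counts):
        assert divstats.allele_sharing(published_counts) == (7, 7, 6)

    def test_identical_compositions_fully_shared(self):
        import pandas as pd

        df = pd.DataFrame({"site": ["a", "b"], "river": ["R", "R"],
                           "position": ["upstream", "downstream"],
                           "A1": [3, 3], "A2": [2, 2]})
        table = divstats.AlleleCountTable(df)
        assert divstats.allele_sharing(table) == (2, 2, 2)

    def test_disjoint_sets_share_nothing(self):
        import pandas as pd

        df = pd.DataFrame({"site": ["a", "b"], "river": ["R", "R"],
                           "position": ["upstream", "downstream"],
                           "A1": [3, 0], "A2": [0, 2]})
        table = divstats.AlleleCountTable(df)
        assert divstats.allele_sharing(table) == (1, 1, 0)
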