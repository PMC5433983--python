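"""Codon-level selection statistics, recombination, trees."""

import itertools
import warnings

import numpy as np
import pytest

from dacemhc import selection
from dacemhc.selection import (CodonAlignment, SelectionError, codon_z_test,
                               four_gamete_rm, jc_distance, nei_gojobori,
                               nj_tree, window_dnds_scan, _code, _codon_tables)

SENSE = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
         if _code(1)[c] != "*"]


class TestCodonSites:
    def test_ttt_sites(self):
        idx, s_sites, _, _ = _codon_tables(1)
        assert s_sites[idx["TTT"]] == pytest.approx(1 / 3)

    def test_sites_sum_to_three_for_all_sense_codons(self):
        idx, s_sites, _, _ = _codon_tables(1)
        for c in SENSE:
            s = s_sites[idx[c]]
            assert 0 <= s <= 3
            # nonsynonymous sites are 3 - s by construction; s must be the
            # synonymous fraction of the 9 single-base changes times 3
            syn = sum(_code(1)[c[:p] + b + c[p + 1:]] == _code(1)[c]
                      for p in range(3) for b in "ACGT" if b != c[p])
            assert s == pytest.approx(syn / 3)


class TestNeiGojobori:
    def test_identical_sequences_are_zero(self):
        aln = CodonAlignment(("TTTGGGAAA", "TTTGGGAAA"))
        r = nei_gojobori(aln)
        assert (r.pS, r.pN, r.dS, r.dN) == (0.0, 0.0, 0.0, 0.0)

    def test_jc_closed_form(self):
        assert selection._jc(0.25) == pytest.approx(0.30410, abs=5e-6)

    def test_weights_equal_duplication(self):
        aln3 = CodonAlignment(("TTTGGGAAACCC", "TTCGGGAAACCC",
                               "TTCGGGAAACCC", "TTTGGAAAACCC"))
        r_listed = nei_gojobori(aln3)
        aln_w = CodonAlignment(("TTTGGGAAACCC", "TTCGGGAAACCC",
                                "TTTGGAAAACCC"))
        r_weighted = nei_gojobori(aln_w, weights=[1, 2, 1])
        assert r_listed.pS == pytest.approx(r_weighted.pS)
        assert r_listed.pN == pytest.approx(r_weighted.pN)
        assert r_listed.dN == pytest.approx(r_weighted.dN, nan_ok=True)

    def test_order_invariance(self):
        seqs = ("TTTGGGAAACCC", "TTCGGGAAACCC", "TTTGTGAAACCC")
        r1 = nei_gojobori(CodonAlignment(seqs))
        r2 = nei_gojobori(CodonAlignment(seqs[::-1]))
        assert r1.pS == pytest.approx(r2.pS)
        assert r1.pN == pytest.approx(r2.pN)

    def test_against_independent_reference_implementation(self):
        # Bio.codonalign implements NG86 but averages mutational pathways
        # through stop codons instead of excluding them; restrict the
        # comparison to pairs where every pathway is stop-free
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        code = _code(1)

        def stop_free(c1, c2):
            diff = [p for p in range(3) if c1[p] != c2[p]]
            for order in itertools.permutations(diff):
                cur = c1
                for p in order:
                    cur = cur[:p] + c2[p] + cur[p + 1:]
                    if code[cur] == "*":
                        return False
            return True

        rng = np.random.default_rng(7)
        checked = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            while checked < 10:
                s1 = "".join(rng.choice(SENSE, 25))
                s2l = list(s1)
                for _ in range(5):
                    i = int(rng.integers(25))
                    s2l[3 * i:3 * i + 3] = rng.choice(SENSE)
                s2 = "".join(s2l)
                pairs_ok = all(
                    stop_free(s1[i:i + 3], s2[i:i + 3])
                    for i in range(0, len(s1), 3) if s1[i:i + 3] != s2[i:i + 3])
                if not pairs_ok:
                    continue
                r = nei_gojobori(CodonAlignment((s1, s2)))
                dn, ds = cal_dn_ds(CodonSeq(s1), CodonSeq(s2), method="NG86")
                assert r.dN == pytest.approx(dn, abs=1e-4)
                assert r.dS == pytest.approx(ds, abs=1e-4)
                checked += 1


class TestCodonZTest:
    def test_identical_sequences_degenerate(self):
        z, p = codon_z_test(CodonAlignment(("TTTGGG", "TTTGGG")), n_boot=50,
                            seed=1)
        assert (z, p) == (0.0, 1.0)

    def test_synonymous_only_gives_negative_z(self):
        # TTT->TTC and GGA->GGG are synonymous; dN = 0 < dS
        aln = CodonAlignment(("TTTGGA" + "AAA" * 10, "TTCGGG" + "AAA" * 10))
        z, p = codon_z_test(aln, n_boot=300, seed=2)
        assert z < 0

    def test_nonsynonymous_only_gives_positive_z(self):
        aln = CodonAlignment(("AAAAAAGGGGGG", "ACAAAAGGGGTG"))
        z, p = codon_z_test(aln, n_boot=300, seed=3)
        assert z > 0


class TestFourGametes:
    def test_three_gamete_types_no_event(self):
        assert four_gamete_rm(["AA", "AT", "TT"]) == 0

    def test_four_gametes_one_event(self):
        assert four_gamete_rm(["AA", "AT", "TA", "TT"]) == 1

    def test_perfect_phylogeny_has_no_events(self):
        # unique-site mutations on a tree (infinite sites, no recombination)
        base = list("A" * 12)
        seqs = []
        for branch_sites in ([0, 1], [0, 2], [3, 4], [3, 5, 6], [7]):
            s = base.copy()
            for pos in branch_sites:
                s[pos] = "T"
            seqs.append("".join(s))
        assert four_gamete_rm(seqs) == 0

    def test_disjoint_incompatible_pairs_add_up(self):
        # sites (0,1) and (2,3) each carry all four gametes
        seqs = ["AAAA", "ATAT", "TATA", "TTTT", "AATT"]
        assert four_gamete_rm(seqs) >= 2


class TestWindowScan:
    def test_monomorphic_alignment_flags_nothing(self):
        aln = CodonAlignment(("TTTGGGAAACCC",) * 3 + ("TTTGGGAAACCC",))
        res = window_dnds_scan(aln, None, window_codons=2, n_perm=50,
                               seeds=(1, 2))
        assert not any(res.flagged)

    def test_contrast_flags_only_nonsynonymous_window(self):
        s1 = "AAA" * 5 + "GGA" * 5
        s2 = "CCA" * 5 + "GGG" * 5  # nonsyn changes left, syn changes right
        res = window_dnds_scan(CodonAlignment((s1, s2)), None, 5,
                               n_perm=300, threshold_prob=0.9, seeds=(1, 2))
        assert res.flagged == (True, False)
        assert res.statistic[0] > 0 > res.statistic[1]

    def test_two_runs_agree_by_construction(self):
        rng = np.random.default_rng(4)
        s1 = "".join(rng.choice(SENSE, 20))
        s2l = list(s1)
        for i in (0, 3, 7, 12):
            s2l[3 * i:3 * i + 3] = rng.choice(SENSE)
        aln = CodonAlignment((s1, "".join(s2l)))
        res = window_dnds_scan(aln, None, 5, n_perm=100, seeds=(10, 20))
        for w, flag in enumerate(res.flagged):
            if flag:
                assert all(run[w] >= 0.95 for run in res.exceedance)

    def test_oversized_window_raises(self):
        with pytest.raises(SelectionError):
            window_dnds_scan(CodonAlignment(("TTT", "TTC")), None, 5)


class TestDistancesAndTree:
    def test_jc_identity_and_symmetry(self):
        assert jc_distance("ACGT", "ACGT") == 0.0
        a, b = "ACGTACGTAAAA", "ACGAACGTAAAT"
        assert jc_distance(a, b) == pytest.approx(jc_distance(b, a))

    def test_jc_saturation_raises(self):
        with pytest.raises(SelectionError):
            jc_distance("AAAA", "TTTT")

    def test_three_taxon_branch_lengths_solve_exactly(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        import io

        from Bio import Phylo

        nwk = nj_tree(["a", "b", "c"], d)
        tree = Phylo.read(io.StringIO(nwk), "newick")
        dist = {t: tree.distance(t) for t in ("a", "b", "c")}
        # three-point equations: x+y=3, x+z=4, y+z=5
        assert dist["a"] + dist["b"] == pytest.approx(3)
        assert dist["a"] + dist["c"] == pytest.approx(4)
        assert dist["b"] + dist["c"] == pytest.approx(5)

    def test_asymmetric_matrix_raises(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(SelectionError):
            nj_tree(["a", "b", "c"], d)

    @staticmethod
    def quartet_matrix(rng):
        """Random additive 4-taxon matrix from topology ((a,b),(c,d))."""
        e = rng.uniform(0.5, 3.0, size=5)  # a, b, c, d, internal
        d = np.zeros((4, 4))
        ext = e[:4]
        d[0, 1] = d[1, 0] = ext[0] + ext[1]
        d[2, 3] = d[3, 2] = ext[2] + ext[3]
        for i in (0, 1):
            for j in (2, 3):
                d[i, j] = d[j, i] = ext[i] + ext[j] + e[4]
        return d

    def test_four_taxon_topology_recovery_sweep(self):
        # 100 random additive quartets; NJ must recover the generating split
        import io

        from Bio import Phylo

        rng = np.random.default_rng(17)
        for case in range(100):
            labels = ["a", "b", "c", "d"]
            d = self.quartet_matrix(rng)
            perm = rng.permutation(4)
            dp = d[np.ix_(perm, perm)]
            names = [labels[i] for i in perm]
            tree = Phylo.read(io.StringIO(nj_tree(names, dp)), "newick")
            # the generating split is {a,b} | {c,d}
            ab = tree.common_ancestor(["a", "b"])
            pair_splits = [frozenset(t.name for t in cl.get_terminals())
                           for cl in tree.get_nonterminals()]
            assert (frozenset("ab") in pair_splits
                    or frozenset("cd") in pair_splits)

    def test_additive_matrix_path_lengths_reproduced(self):
        import io

        from Bio import Phylo

        rng = np.random.default_rng(23)
        d = self.quartet_matrix(rng)
        labels = ["a", "b", "c", "d"]
        tree = Phylo.read(io.StringIO(nj_tree(labels, d)), "newick")
        for i in range(4):
            for j in range(i + 1, 4):
                assert tree.distance(labels[i], labels[j]) == pytest.approx(
                    d[i, j])

    def test_ultrametric_agrees_with_upgma(self):
        # ultrametric distances: NJ topology must match average-linkage
        from scipy.cluster.hierarchy import average, fcluster
        from scipy.spatial.distance import squareform
        import io

        from Bio import Phylo

        d = np.array([[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 3], [6, 6, 3, 0]],
                     dtype=float)
        Z = average(squareform(d, checks=False))
        groups = fcluster(Z, t=2, criterion="maxclust")
        upgma_split = frozenset(l for l, g in zip("abcd", groups)
                                if g == groups[0])
        tree = Phylo.read(io.StringIO(nj_tree(list("abcd"), d)), "newick")
        splits = {frozenset(t.name for t in cl.get_terminals())
                  for cl in tree.get_nonterminals()}
        complement = frozenset("abcd") - upgma_split
        assert upgma_split in splits or complement in splits
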