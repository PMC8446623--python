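import math

import numpy as np
import pytest

from gliascan import phylo, synthetic_data as sd
from tests._helpers import random_additive_tree, tree_distance_matrix


class TestAlignCodons:
    def test_identical_sequences_align_gap_free(self):
        cds = "ATGCAACCGGGGTTTTAA"
        aln = phylo.align_codons({"a": cds, "b": cds})
        assert aln.rows == (cds, cds)

    def test_internal_codon_deletion_gives_one_gap_triple(self):
        aln = phylo.align_codons(
            {"a": "ATGCAACCGGGGTTTTAA", "b": "ATGCAAGGGTTTTAA",
             "c": "ATGCAACCGGGGTTTTAA"}
        )
        row_b = dict(zip(aln.ids, aln.rows))["b"]
        assert row_b.count("-") == 3
        assert "---" in row_b
        assert aln.n_codons == 6

    def test_non_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            phylo.align_codons({"a": "A" * 100, "b": "ATGTTTTAA"})

    def test_gap_triplet_invariant_enforced(self):
        with pytest.raises(ValueError, match="triplet"):
            phylo.CodonAlignment(("a",), ("AT-CAA",))


class TestK2PDistance:
    def build_pair(self, n_ts, n_tv, n_same):
        # transitions A<->G, transversions A<->C, over a codon-sized frame
        a = "A" * (n_ts + n_tv + n_same)
        b = "G" * n_ts + "C" * n_tv + "A" * n_same
        pad = (3 - len(a) % 3) % 3
        a += "A" * pad
        b += "A" * pad
        return phylo.CodonAlignment(("x", "y"), (a, b))

    def test_identical_rows_have_zero_distance(self):
        aln = phylo.CodonAlignment(("x", "y"), ("ATGCAA", "ATGCAA"))
        dm = phylo.k2p_gamma_distance(aln, alpha=math.inf)
        assert dm.matrix[0, 1] == 0.0

    def test_closed_form_at_p02_q01(self):
        # P=0.2, Q=0.1 -> d = 0.4024 (plain K2P, 4 d.p.)
        aln = self.build_pair(24, 12, 84)  # 120 sites
        dm = phylo.k2p_gamma_distance(aln, alpha=math.inf)
        assert round(dm.matrix[0, 1], 4) == 0.4024

    def test_gamma_converges_to_plain_k2p(self):
        aln = self.build_pair(24, 12, 84)
        d_inf = phylo.k2p_gamma_distance(aln, alpha=math.inf).matrix[0, 1]
        d_big = phylo.k2p_gamma_distance(aln, alpha=1e6).matrix[0, 1]
        assert abs(d_big - d_inf) < 1e-4

    def test_gamma_correction_increases_as_alpha_decreases(self):
        aln = self.build_pair(24, 12, 84)
        alphas = [math.inf, 20.0, 5.0, 2.25, 1.0, 0.5]
        dists = [phylo.k2p_gamma_distance(aln, alpha=a).matrix[0, 1]
                 for a in alphas]
        assert dists == sorted(dists)

    def test_saturated_pair_gets_flagged_ceiling(self):
        aln = self.build_pair(60, 48, 12)  # P+Q far past saturation
        dm = phylo.k2p_gamma_distance(aln, alpha=math.inf)
        assert dm.matrix[0, 1] == phylo.DEFAULT_CEILING
        assert ("x", "y") in dm.saturated

    def test_distance_axioms_on_simulated_data(self):
        params = sd.SiteModelParams("M7", p=2.0, q=5.0)
        aln_d, _, _ = sd.simulate_codon_alignment(
            sd.balanced_tree(6, 0.2), params, 100, seed=9
        )
        aln = phylo.CodonAlignment(tuple(aln_d), tuple(aln_d.values()))
        dm = phylo.k2p_gamma_distance(aln)
        m = dm.matrix
        assert (m >= 0).all()
        assert (np.diag(m) == 0).all()
        assert np.abs(m - m.T).max() < 1e-12

    def test_complete_deletion_drops_gapped_codons(self):
        aln = phylo.CodonAlignment(
            ("x", "y", "z"),
            ("ATGCAAGGG", "ATG---GGG", "ATGCAAGGG"),
        )
        dm = phylo.k2p_gamma_distance(aln, deletion="complete")
        assert dm.matrix[0, 2] == 0.0  # only ungapped codons compared


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        ids = ("A", "B", "C", "D")
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = phylo.nj_tree(phylo.DistanceMatrix(ids, d, math.inf))
        paths = phylo.path_length_matrix(tree, ids)
        assert np.abs(paths - d).max() < 1e-12

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_random_additive_matrices_recovered(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for _ in range(5):
            newick, ids = random_additive_tree(rng, n_leaves)
            d = tree_distance_matrix(newick, ids)
            tree = phylo.nj_tree(phylo.DistanceMatrix(tuple(ids), d, math.inf))
            paths = phylo.path_length_matrix(tree, ids)
            assert np.abs(paths - d).max() <= 1e-9

    def test_three_taxa_three_point_formulas(self):
        ids = ("a", "b", "c")
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = phylo.nj_tree(phylo.DistanceMatrix(ids, d, math.inf))
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_identical_leaves_form_zero_length_cherry(self):
        ids = ("a", "b", "c", "d")
        d = np.array(
            [[0, 0, 4, 4], [0, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float
        )
        tree = phylo.nj_tree(phylo.DistanceMatrix(ids, d, math.inf))
        paths = phylo.path_length_matrix(tree, ids)
        assert paths[0, 1] == 0.0

    def test_fewer_than_three_taxa_rejected(self):
        dm = phylo.DistanceMatrix(("a", "b"), np.zeros((2, 2)), math.inf)
        with pytest.raises(ValueError, match="at least 3"):
            phylo.nj_tree(dm)

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            phylo.DistanceMatrix(("a", "b", "c"), m, math.inf)


def two_clade_alignment(seed=0):
    """Two 4-leaf groups, divergent between but identical within."""
    rng = np.random.default_rng(seed)
    base1 = sd._default_template()[:300]
    params = sd.SiteModelParams("M7", p=2.0, q=5.0)
    aln_d, _, _ = sd.simulate_codon_alignment(
        "((a1:0.01,a2:0.01):0.5,(b1:0.01,b2:0.01):0.5,(c1:0.01,"
        "(c2:0.01,c3:0.01):0.01):0.5);",
        params, 120, seed=seed,
    )
    return phylo.CodonAlignment(tuple(aln_d), tuple(aln_d.values()))


class TestBootstrap:
    def test_deep_split_gets_full_support(self):
        aln = two_clade_alignment(1)
        tree, supports = phylo.bootstrap_support(aln, b_replicates=50, seed=4)
        # every deep bipartition separating the three groups is in all
        # replicates
        groups = [frozenset({"b1", "b2"}), frozenset({"c1", "c2", "c3"})]
        for g in groups:
            matching = [s for s in supports if s == g]
            assert matching and supports[matching[0]] == 100.0

    def test_single_replicate_supports_are_binary(self):
        aln = two_clade_alignment(2)
        _, supports = phylo.bootstrap_support(aln, b_replicates=1, seed=1)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_same_seed_reproduces_supports(self):
        aln = two_clade_alignment(3)
        _, s1 = phylo.bootstrap_support(aln, b_replicates=20, seed=9)
        _, s2 = phylo.bootstrap_support(aln, b_replicates=20, seed=9)
        assert s1 == s2


class TestCladeMembership:
    def tree(self, newick):
        import dendropy

        return dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)

    def test_clean_clades_have_no_outliers(self):
        t = self.tree(
            "(((a1:1,a2:1):1,(a3:1,a4:1):1):1,((b1:1,b2:1):1,(b3:1,b4:1):1):1,"
            "((d1:1,d2:1):1,(d3:1,d4:1):1):1);"
        )
        labels = {f"{g}{i}": f"Gli-{g.upper()}2" for g in "abd"
                  for i in range(1, 5)}
        out = phylo.clade_membership(t, labels)
        assert out["outliers"] == []
        assert out["clade_by_leaf"]["a1"] == "Gli-A2"
        assert out["clade_by_leaf"]["d4"] == "Gli-D2"

    def test_misplaced_copy_is_flagged(self):
        t = self.tree(
            "((b1:1,(b2:1,x:1):1):1,b3:1,(d1:1,d2:1):1);"
        )
        labels = {"b1": "Gli-B2", "b2": "Gli-B2", "b3": "Gli-B2",
                  "x": "Gli-D2", "d1": "Gli-D2", "d2": "Gli-D2"}
        out = phylo.clade_membership(t, labels)
        assert out["outliers"] == ["x"]
        assert out["clade_by_leaf"]["x"] == "Gli-B2"

    def test_chrun_leaf_inherits_clade(self):
        t = self.tree("((a1:1,(a2:1,u:1):1):1,a3:1,(d1:1,d2:1):1);")
        labels = {"a1": "Gli-A2", "a2": "Gli-A2", "a3": "Gli-A2",
                  "u": "chrUn", "d1": "Gli-D2", "d2": "Gli-D2"}
        out = phylo.clade_membership(t, labels)
        assert out["clade_by_leaf"]["u"] == "Gli-A2"
        assert "u" not in out["outliers"]

    def test_unlabeled_leaf_rejected(self):
        t = self.tree("(a:1,b:1,c:1);")
        with pytest.raises(ValueError, match="locus label"):
            phylo.clade_membership(t, {"a": "Gli-A2", "b": "Gli-A2"})
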