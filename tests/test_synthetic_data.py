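import hashlib

import numpy as np
import pytest

from gliascan import synthetic_data as sd
from gliascan.gene_discovery import translate_cds


def bipartite_config(**overrides):
    kwargs = dict(
        chromosomes={"chr6B": 200_000},
        loci=(sd.LocusSpec("chr6B", anchors_bp=(43_500, 120_000), copies=(5, 2)),),
        substitution_rate=0.02,
        seed=7,
    )
    kwargs.update(overrides)
    return sd.SimConfig(**kwargs)


class TestGenerateAssembly:
    def test_counts_and_sublocus_labels_follow_config(self):
        _, truth = sd.generate_assembly(bipartite_config())
        assert len(truth) == 7
        assert set(truth.sublocus) == {"Gli-B2-1", "Gli-B2-2"}
        assert truth.sublocus.value_counts().to_dict() == {
            "Gli-B2-1": 5, "Gli-B2-2": 2
        }

    def test_identical_seed_gives_identical_bytes(self):
        a1, t1 = sd.generate_assembly(bipartite_config())
        a2, t2 = sd.generate_assembly(bipartite_config())
        h1 = hashlib.sha256(a1["chr6B"].encode()).hexdigest()
        h2 = hashlib.sha256(a2["chr6B"].encode()).hexdigest()
        assert h1 == h2
        assert t1.equals(t2)

    def test_zero_mutation_limit_plants_template_verbatim(self):
        cfg = bipartite_config(substitution_rate=0.0, pseudogene_prob=0.0)
        assembly, truth = sd.generate_assembly(cfg)
        for row in truth.itertuples():
            assert row.cds == cfg.template_cds
            genomic = assembly[row.chromosome][row.start : row.end]
            if row.strand == "-":
                genomic = sd.reverse_complement(genomic)
            assert genomic == cfg.template_cds
            assert row.intact_orf

    def test_planted_genes_never_overlap(self):
        _, truth = sd.generate_assembly(bipartite_config())
        ordered = truth.sort_values("start")
        assert (ordered.start.to_numpy()[1:] >= ordered.end.to_numpy()[:-1]).all()

    def test_colliding_arrays_rejected_with_gene_names(self):
        cfg = bipartite_config(
            loci=(sd.LocusSpec("chr6B", anchors_bp=(43_500, 44_000),
                               copies=(3, 2)),),
        )
        with pytest.raises(sd.GenerationError, match=r"chr6B\.g"):
            sd.generate_assembly(cfg)

    def test_anchor_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="outside chromosome"):
            bipartite_config(
                loci=(sd.LocusSpec("chr6B", anchors_bp=(500_000,), copies=(1,)),)
            )

    def test_template_validation(self):
        with pytest.raises(ValueError, match="ATG"):
            bipartite_config(template_cds="CCCAAATTT")
        with pytest.raises(ValueError, match="multiple of 3"):
            bipartite_config(template_cds="ATGCC")

    def test_planted_epitopes_retrievable_from_truth_cds(self):
        cfg = bipartite_config(
            pseudogene_prob=0.0,
            epitopes={"a1a": ("PFPQPQLPY", 3), "a2": ("PQPQLPYPQ", 2)},
        )
        _, truth = sd.generate_assembly(cfg)
        planted = 0
        for row in truth.itertuples():
            names = [n for n in str(row.epitopes).split(",") if n and n != "nan"]
            protein = translate_cds(row.cds)
            for name in names:
                peptide = cfg.epitopes[name][0]
                assert peptide in protein
                planted += 1
        assert planted == 5

    def test_pseudogenes_flagged_not_intact(self):
        cfg = bipartite_config(substitution_rate=0.0, pseudogene_prob=1.0)
        _, truth = sd.generate_assembly(cfg)
        assert not truth.intact_orf.any()


class TestSimulateCodonAlignment:
    TREE = sd.balanced_tree(8, 0.3)

    def test_m7_yields_no_positively_selected_sites(self):
        params = sd.SiteModelParams("M7", p=2.0, q=5.0)
        aln, classes, omegas = sd.simulate_codon_alignment(
            self.TREE, params, 300, seed=1
        )
        assert len(classes) == 300
        assert set(classes) == {"beta"}
        assert (omegas < 1).all()
        assert all(len(s) == 900 for s in aln.values())

    def test_m8_positive_fraction_near_expectation(self):
        params = sd.SiteModelParams("M8", p=0.5, q=2.0, p0=0.9, omega_s=3.0)
        _, classes, _ = sd.simulate_codon_alignment(self.TREE, params, 500, seed=2)
        frac = sum(c == "positive" for c in classes) / 500
        assert abs(frac - 0.1) <= 0.05

    def test_class_frequencies_match_mixture_weights(self):
        """Over >=1000 sites the positive-class frequency sits within three
        binomial standard errors of 1 - p0."""
        params = sd.SiteModelParams("M8", p=1.0, q=3.0, p0=0.8, omega_s=2.0)
        n = 1500
        _, classes, _ = sd.simulate_codon_alignment(self.TREE, params, n, seed=3)
        frac = sum(c == "positive" for c in classes) / n
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(frac - 0.2) <= 3 * se

    def test_zero_branch_lengths_give_identical_sequences(self):
        tree = sd.balanced_tree(4, 0.0)
        params = sd.SiteModelParams("M7", p=2.0, q=5.0)
        aln, _, _ = sd.simulate_codon_alignment(tree, params, 50, seed=4)
        assert len(set(aln.values())) == 1

    def test_no_stop_codons_emitted(self):
        from gliascan._codon import STOP_CODONS

        params = sd.SiteModelParams("M8", p=0.5, q=1.0, p0=0.7, omega_s=5.0)
        aln, _, _ = sd.simulate_codon_alignment(self.TREE, params, 200, seed=5)
        for seq in aln.values():
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not codons & set(STOP_CODONS)

    def test_invalid_inputs_rejected(self):
        params = sd.SiteModelParams("M7", p=2.0, q=5.0)
        with pytest.raises(ValueError, match="n_sites"):
            sd.simulate_codon_alignment(self.TREE, params, 0, seed=1)
        with pytest.raises(ValueError, match="branch lengths"):
            sd.simulate_codon_alignment("(a,b,c);", params, 10, seed=1)
        with pytest.raises(ValueError, match="3 leaves"):
            sd.simulate_codon_alignment("(a:1,b:1);", params, 10, seed=1)


class TestSimulateDepthTable:
    def test_zero_noise_depths_are_exact_multiples(self, small_sim):
        cfg, _, truth = small_sim
        truth = truth.copy()
        truth.loc[truth.index[0], "copy_status"] = "collapsed"
        truth.loc[truth.index[1], "copy_status"] = "haplotype_specific"
        depth = sd.simulate_depth_table(truth, median_cov=32.23, noise_sd=0.0,
                                        seed=0)
        assert depth.mean_depth.iloc[0] == pytest.approx(64.46)
        assert depth.mean_depth.iloc[1] == pytest.approx(16.115)
        assert np.allclose(depth.mean_depth.iloc[2:], 32.23)

    def test_seeded_run_reproducible_and_nonnegative(self, small_sim):
        _, _, truth = small_sim
        d1 = sd.simulate_depth_table(truth, noise_sd=50.0, seed=3)
        d2 = sd.simulate_depth_table(truth, noise_sd=50.0, seed=3)
        assert d1.equals(d2)
        assert (d1.mean_depth >= 0).all()

    def test_invalid_median_rejected(self, small_sim):
        _, _, truth = small_sim
        with pytest.raises(ValueError):
            sd.simulate_depth_table(truth, median_cov=0.0, seed=1)
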