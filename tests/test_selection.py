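import numpy as np
import pytest
from scipy.stats import chi2

from gliascan import selection as sel, synthetic_data as sd
from gliascan.phylo import CodonAlignment
from tests._helpers import exhaustive_codon_loglik


def sim_alignment(model_params, n_sites, seed, tree=None):
    tree = tree or sd.balanced_tree(6, 0.3)
    aln_d, classes, _ = sd.simulate_codon_alignment(
        tree, model_params, n_sites, seed=seed
    )
    return CodonAlignment(tuple(aln_d), tuple(aln_d.values())), classes, tree


class TestPrepareSelectionAlignment:
    def codon_rows(self, *rows):
        ids = tuple(f"s{i}" for i in range(len(rows)))
        return CodonAlignment(ids, tuple(rows))

    def test_premature_stop_row_dropped_with_reason(self):
        good = "ATGCAACCGGTTGGGTTTCACTGGAAACGCTGA"  # 10 codons + stop
        bad = "ATGCAATAAGTTGGGTTTCACTGGAAACGCTGA"  # internal TAA
        aln = self.codon_rows(good, bad, good, good)
        cleaned, report = sel.prepare_selection_alignment(aln)
        assert report.dropped_rows == {"s1": "premature stop"}
        assert set(cleaned.ids) == {"s0", "s2", "s3"}

    def test_missing_terminal_stop_row_dropped(self):
        good = "ATGCAACCGGTTGGGTTTCACTGGAAACGCTGA"
        nostop = "ATGCAACCGGTTGGGTTTCACTGGAAACGCGGG"
        aln = self.codon_rows(good, nostop, good, good)
        _, report = sel.prepare_selection_alignment(aln)
        assert report.dropped_rows == {"s1": "no terminal stop"}

    def test_polyglutamine_run_masked(self):
        # 12 consecutive Q codons between two variable octamers
        flank1 = "ATGCGTTGGAAAGTTCACTTTGGG"
        flank2 = "CGCGTTAAATGGCACGGGTTTGCA"
        row = flank1 + "CAA" * 12 + flank2 + "TGA"
        aln = self.codon_rows(row, row, row)
        cleaned, report = sel.prepare_selection_alignment(aln)
        masked = {k for k, v in report.removed_columns.items()
                  if v == "polyglutamine"}
        assert masked == set(range(8, 20))
        assert cleaned.n_codons == 16  # 33 codons - stop - 12 masked - 4?

    def test_clean_alignment_keeps_all_rows_and_columns(self):
        params = sd.SiteModelParams("M7", p=2.0, q=5.0)
        aln, _, _ = sim_alignment(params, 60, seed=1)
        rows = tuple(r + "TAA" for r in aln.rows)
        with_stop = CodonAlignment(aln.ids, rows)
        cleaned, report = sel.prepare_selection_alignment(with_stop)
        assert not report.dropped_rows
        # only the stripped terminal-stop column goes
        assert set(report.removed_columns.values()) <= {"all gap"}
        assert cleaned.n_codons == 60

    def test_too_few_rows_rejected(self):
        good = "ATGCAACCGGTTGGGTTTCACTGGAAACGCTGA"
        bad = "ATGTAACCGGTTGGGTTTCACTGGAAACGCTGA"
        with pytest.raises(ValueError, match="at least 3"):
            sel.prepare_selection_alignment(self.codon_rows(good, bad, bad))


class TestPruningLikelihood:
    def test_matches_exhaustive_state_sum_on_three_taxon_toys(self):
        lengths = {"a": 0.2, "b": 0.3, "c": 0.4}
        tree = "(a:0.2,b:0.3,c:0.4);"
        for seed in (1, 2, 3):
            params = sd.SiteModelParams("M7", p=2.0, q=5.0, kappa=2.0)
            aln, _, _ = sim_alignment(params, 5, seed=seed, tree=tree)
            lik = sel.CodonLikelihood(aln, tree)
            w, om = params.mixture()
            fast = lik.log_likelihood(2.0, w, om, 1.0)
            slow = exhaustive_codon_loglik(aln, lengths, 2.0, w, om,
                                           lik.codon_freqs)
            assert abs(fast - slow) < 1e-8

    def test_site_class_posteriors_normalize(self):
        params = sd.SiteModelParams("M8", p=1.0, q=2.0, p0=0.8, omega_s=3.0)
        aln, _, tree = sim_alignment(params, 40, seed=4)
        lik = sel.CodonLikelihood(aln, tree)
        w, om = params.mixture()
        post = lik.site_class_posteriors(2.0, w, om, 1.0)
        assert post.shape == (40, 11)
        assert np.abs(post.sum(axis=1) - 1.0).max() < 1e-8

    def test_p0_one_gives_zero_positive_posterior(self):
        params = sd.SiteModelParams("M8", p=1.0, q=2.0, p0=1.0, omega_s=3.0)
        aln, _, tree = sim_alignment(params, 30, seed=5)
        lik = sel.CodonLikelihood(aln, tree)
        w, om = params.mixture()
        post = lik.site_class_posteriors(2.0, w, om, 1.0)
        assert (post[:, -1] == 0.0).all()


class TestFitSiteModel:
    def test_m7_recovery_on_simulated_data(self):
        """The fitted likelihood must reach (within optimizer tolerance) the
        likelihood at the generating parameters, and the beta shape must land
        in a broad but bounded region."""
        params = sd.SiteModelParams("M7", p=2.0, q=5.0, kappa=2.0)
        aln, _, tree = sim_alignment(params, 300, seed=6,
                                     tree=sd.balanced_tree(8, 0.3))
        fit = sel.fit_site_model(aln, tree, "M7", starts=1, seed=0)
        lik = sel.CodonLikelihood(aln, tree)
        w, om = params.mixture()
        ll_true = lik.log_likelihood(2.0, w, om, 1.0)
        assert fit.log_likelihood >= ll_true - 2.0
        assert abs(fit.p - 2.0) / 2.0 < 1.0
        assert abs(fit.q - 5.0) / 5.0 < 1.0
        assert fit.converged

    def test_m8_nests_m7(self):
        params = sd.SiteModelParams("M7", p=2.0, q=5.0)
        aln, _, tree = sim_alignment(params, 100, seed=7)
        fit7 = sel.fit_site_model(aln, tree, "M7", starts=1, seed=0)
        fit8 = sel.fit_site_model(
            aln, tree, "M8", starts=1, seed=0,
            extra_starts=[{"kappa": fit7.kappa, "p": fit7.p, "q": fit7.q,
                           "scale": fit7.tree_scale, "p0": 1.0}],
        )
        assert fit8.log_likelihood >= fit7.log_likelihood - 1e-3

    def test_identical_sequences_hit_scale_boundary(self):
        row = sd._default_template()[:120]
        aln = CodonAlignment(("a", "b", "c"), (row, row, row))
        fit = sel.fit_site_model(aln, "(a:0.1,b:0.1,c:0.1);", "M7",
                                 starts=1, seed=0, maxiter=100)
        assert fit.tree_scale == pytest.approx(1e-3)
        assert "scale" in fit.at_boundary

    def test_stop_codons_rejected(self):
        aln = CodonAlignment(("a", "b", "c"), ("ATGTAA",) * 3)
        with pytest.raises(ValueError, match="stop codon"):
            sel.fit_site_model(aln, "(a:0.1,b:0.1,c:0.1);", "M7", starts=1,
                               seed=0)


class TestLrtAndSites:
    def fake_fit(self, model, lnl, data_hash="h"):
        return sel.SiteModelFit(
            model=model, kappa=2.0, p=1.0, q=1.0, p0=0.9, omega_s=2.0,
            tree_scale=1.0, log_likelihood=lnl,
            codon_freqs=np.full(61, 1 / 61), class_weights=np.array([1.0]),
            class_omegas=np.array([0.5]),
            site_class_posterior=np.ones((1, 1)), converged=True,
            n_iterations=1, n_starts=1, at_boundary=[], data_hash=data_hash,
            n_sites=1,
        )

    def test_statistic_and_chi2_pvalue(self):
        rep = sel.lrt_m7_m8(self.fake_fit("M7", -1000.0),
                            self.fake_fit("M8", -995.0))
        assert rep.lrt_statistic == pytest.approx(10.0)
        assert rep.df == 2
        assert rep.p_value == pytest.approx(chi2.sf(10.0, 2))
        assert rep.p_value == pytest.approx(0.0067, abs=5e-4)

    def test_equal_likelihoods_give_unit_pvalue(self):
        rep = sel.lrt_m7_m8(self.fake_fit("M7", -50.0),
                            self.fake_fit("M8", -50.0))
        assert rep.lrt_statistic == 0.0 and rep.p_value == 1.0

    def test_small_negative_clamped_with_note(self):
        rep = sel.lrt_m7_m8(self.fake_fit("M7", -50.0),
                            self.fake_fit("M8", -50.0 - 1e-6))
        assert rep.lrt_statistic == 0.0
        assert rep.notes

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError, match="different data"):
            sel.lrt_m7_m8(self.fake_fit("M7", -1.0, "h1"),
                          self.fake_fit("M8", -1.0, "h2"))

    def test_grid_beb_agrees_with_neb_on_clear_signal(self):
        """Averaging over the (p0, omega_s) grid keeps posteriors valid
        probabilities and preserves the NEB ranking of sites."""
        params = sd.SiteModelParams("M8", p=0.5, q=1.5, p0=0.8, omega_s=4.0)
        aln, _, tree = sim_alignment(params, 80, seed=11)
        fit = sel.fit_site_model(aln, tree, "M8", starts=1, seed=0,
                                 maxiter=150)
        neb = sel.site_posteriors(fit, method="neb")
        beb = sel.site_posteriors(fit, method="beb")
        assert ((beb.site_posterior >= 0) & (beb.site_posterior <= 1)).all()
        top_neb = np.argsort(neb.site_posterior)[-5:]
        top_beb = np.argsort(beb.site_posterior)[-5:]
        assert len(set(top_neb) & set(top_beb)) >= 3

    def test_site_posteriors_flag_threshold(self):
        fit = self.fake_fit("M8", -10.0)
        fit.site_class_posterior = np.array(
            [[0.1, 0.9], [0.02, 0.98], [0.5, 0.5]]
        )
        fit.n_sites = 3
        rep = sel.site_posteriors(fit)
        assert rep.significant_sites == [1]
        assert rep.site_posterior.tolist() == [0.9, 0.98, 0.5]
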