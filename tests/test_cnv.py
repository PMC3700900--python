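"""Four-arm CNV genotyping: fits, model selection, labeling, scoring."""

import numpy as np
import pytest
from scipy.stats import norm

from duocall.cnv import (
    call_marker_cnv,
    detect_outliers,
    fit_one_component,
    fit_two_component,
    label_components,
    partition_arms,
    score_samples,
    select_model,
)
from duocall.config import CnvConfig
from duocall.types import AA, AB, BB, ZERO, GmmFit, bin_scores


def _mk_fit2(weights, means, variances, n=100):
    """Helper GmmFit with uniform posteriors (not used by the op under test)."""
    return GmmFit(
        n_components=2,
        weights=np.asarray(weights, float),
        means=np.asarray(means, float),
        variances=np.asarray(variances, float),
        loglik=0.0,
        posteriors=np.full((n, 2), 0.5),
    )


class TestPartitionArms:
    def test_counts(self):
        geno = np.array([AA] * 10 + [AB] * 5 + [BB] * 10, dtype=np.int8)
        a = np.arange(25.0)
        b = np.arange(25.0) + 100
        arms = {arm.arm_id: arm for arm in partition_arms(geno, a, b)}
        assert len(arms["AA_on_A"].sample_idx) == 10
        assert len(arms["BB_on_B"].sample_idx) == 10
        assert len(arms["AB_on_A"].sample_idx) == 5
        assert len(arms["AB_on_B"].sample_idx) == 5
        # informative channel only
        assert (arms["AA_on_A"].intensities < 100).all()
        assert (arms["BB_on_B"].intensities >= 100).all()

    def test_monomorphic_single_arm(self):
        geno = np.full(8, AA, dtype=np.int8)
        arms = partition_arms(geno, np.ones(8), np.zeros(8))
        sizes = [len(a.sample_idx) for a in arms]
        assert sizes == [8, 0, 0, 0]

    def test_zero_samples_in_no_arm(self):
        geno = np.array([AA, ZERO, AB, ZERO], dtype=np.int8)
        arms = partition_arms(geno, np.ones(4), np.ones(4))
        for arm in arms:
            assert 1 not in arm.sample_idx and 3 not in arm.sample_idx


class TestFitOneComponent:
    def test_degenerate_uses_variance_floor(self):
        fit = fit_one_component(np.full(20, 0.7), var_floor=1e-4)
        assert fit.means[0] == pytest.approx(0.7)
        assert fit.variances[0] == pytest.approx(1e-4)

    def test_loglik_matches_closed_form(self, rng):
        x = rng.normal(1.0, 0.1, 50)
        fit = fit_one_component(x)
        expected = norm.logpdf(x, x.mean(), np.sqrt(x.var())).sum()
        assert fit.loglik == pytest.approx(expected, abs=1e-9)


class TestFitTwoComponent:
    def test_parameter_recovery(self, rng):
        x = np.r_[rng.normal(0.5, 0.05, 250), rng.normal(1.0, 0.05, 250)]
        fit = fit_two_component(x, seed=1)
        np.testing.assert_allclose(fit.means, [0.5, 1.0], atol=0.03)
        np.testing.assert_allclose(fit.weights, [0.5, 0.5], atol=0.03)
        assert fit.converged

    def test_loglik_non_decreasing_every_iteration(self, rng):
        x = np.r_[rng.normal(0.5, 0.08, 60), rng.normal(0.9, 0.08, 40)]
        fit = fit_two_component(x, seed=2, return_trace=True)
        trace = np.asarray(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-9).all()

    def test_mixture_loglik_at_least_single_gaussian(self, rng):
        x = rng.normal(1.0, 0.05, 120)
        fit1 = fit_one_component(x)
        fit2 = fit_two_component(x, seed=3)
        assert fit2.loglik >= fit1.loglik - 1e-6

    def test_agrees_with_sklearn_reference(self, rng):
        sklearn = pytest.importorskip("sklearn.mixture")
        x = np.r_[rng.normal(0.4, 0.06, 150), rng.normal(1.0, 0.06, 150)]
        fit = fit_two_component(x, seed=4)
        gm = sklearn.GaussianMixture(
            2, covariance_type="spherical", n_init=5, random_state=0, reg_covar=1e-6
        ).fit(x[:, None])
        assert fit.loglik == pytest.approx(gm.score(x[:, None]) * len(x), abs=0.5)
        np.testing.assert_allclose(np.sort(fit.means), np.sort(gm.means_.ravel()), atol=0.02)


class TestSelectModel:
    def test_separated_mixture_selected(self, rng):
        x = np.r_[rng.normal(0.5, 0.05, 100), rng.normal(1.0, 0.05, 200)]
        assert select_model(fit_one_component(x), fit_two_component(x, seed=5)) == "two"

    def test_single_cluster_rejected(self, rng):
        x = rng.normal(1.0, 0.05, 500)
        assert select_model(fit_one_component(x), fit_two_component(x, seed=6)) == "one"

    def test_unconverged_forces_one(self, rng):
        x = rng.normal(1.0, 0.05, 50)
        fit2 = fit_two_component(x, seed=7)
        fit2.converged = False
        assert select_model(fit_one_component(x), fit2) == "one"


class TestLabelComponents:
    def test_majority_high_is_diploid_over_deletion(self):
        fit2 = _mk_fit2([0.2, 0.8], [0.5, 1.0], [0.0025, 0.0025])
        labels = label_components(fit2, is_het_arm=False, zero_present=False)
        assert list(labels) == [1.0, 2.0]  # low = hemizygous deletion

    def test_minority_high_with_zero_copies_still_deletion(self):
        fit2 = _mk_fit2([0.8, 0.2], [0.5, 1.0], [0.0025, 0.0025])
        labels = label_components(fit2, is_het_arm=False, zero_present=True)
        assert list(labels) == [1.0, 2.0]

    def test_minority_high_without_zero_copies_is_amplification(self):
        fit2 = _mk_fit2([0.8, 0.2], [1.0, 1.3], [0.0025, 0.0025])
        labels = label_components(fit2, is_het_arm=False, zero_present=False)
        assert list(labels) == [2.0, 3.0]

    def test_het_arm_never_deleted(self):
        # minor high component: allele amplification over the normal dose
        fit2 = _mk_fit2([0.8, 0.2], [0.5, 1.0], [0.0025, 0.0025])
        labels = label_components(fit2, is_het_arm=True, zero_present=False)
        assert list(labels) == [1.0, 2.0]  # per-allele doses, min 1
        # majority high component: both components are normal dose; an AB
        # call can never read as an allele deletion
        fit2 = _mk_fit2([0.2, 0.8], [0.5, 1.0], [0.0025, 0.0025])
        labels = label_components(fit2, is_het_arm=True, zero_present=False)
        assert list(labels) == [1.0, 1.0]


class TestDetectOutliers:
    def test_component_mean_is_not_outlier(self):
        fit = fit_one_component(np.r_[np.full(10, 1.0), 1.01])
        low, high = detect_outliers(np.array([1.0]), fit, z_cut=4.0)
        assert not low[0] and not high[0]

    def test_six_sigma_low_outlier(self, rng):
        x = rng.normal(1.0, 0.05, 100)
        fit = fit_one_component(x)
        sd = float(np.sqrt(fit.variances[0]))
        low, high = detect_outliers(np.array([fit.means[0] - 6 * sd]), fit, z_cut=4.0)
        assert low[0] and not high[0]

    def test_outlier_fraction_matches_gaussian_tail(self):
        # over replicates, the flagged fraction under a pure Gaussian
        # approaches 2*Phi(-z_cut)
        z = 2.5
        fracs = []
        for s in range(200):
            rng = np.random.default_rng(s)
            x = rng.normal(0.0, 1.0, 500)
            fit = fit_one_component(x)
            low, high = detect_outliers(x, fit, z_cut=z)
            fracs.append((low.sum() + high.sum()) / len(x))
        expected = 2 * norm.cdf(-z)
        assert np.mean(fracs) == pytest.approx(expected, rel=0.2)


class TestScoring:
    def _marker(self, rng, n=300, del_freq=0.3):
        from duocall.simulate import MarkerSpec, simulate_marker

        spec = MarkerSpec(maf=0.4, del_freq=del_freq, noise_sd=0.05, seed=11)
        return simulate_marker(spec, n, rng)

    def test_all_diploid_het_scores_two(self, rng):
        geno = np.full(40, AB, dtype=np.int8)
        a = rng.normal(0.5, 0.02, 40)
        b = rng.normal(0.5, 0.02, 40)
        scores, arms = call_marker_cnv(geno, a, b, np.zeros(40, bool), rng=rng)
        np.testing.assert_allclose(scores, 2.0, atol=0.2)
        assert (bin_scores(scores) == 2).all()

    def test_posterior_one_deletion_scores_one(self):
        fit2 = _mk_fit2([0.5, 0.5], [0.5, 1.0], [0.0025, 0.0025], n=2)
        fit2.posteriors = np.array([[1.0, 0.0], [0.0, 1.0]])
        from duocall.cnv import AnalysisArm

        arm = AnalysisArm("AA_on_A", np.array([0, 1]), np.array([0.5, 1.0]))
        arm.fit2 = fit2
        arm.selected = "two"
        arm.labels = np.array([1.0, 2.0])
        arm.outlier_low = np.zeros(2, bool)
        arm.outlier_high = np.zeros(2, bool)
        empty = [
            AnalysisArm(a_id, np.array([], int), np.array([]))
            for a_id in ("BB_on_B", "AB_on_A", "AB_on_B")
        ]
        scores = score_samples([arm] + empty, np.array([AA, AA], np.int8), np.zeros(2, bool))
        assert scores[0] == pytest.approx(1.0)
        assert scores[1] == pytest.approx(2.0)

    def test_half_posterior_is_boundary_score(self):
        fit2 = _mk_fit2([0.5, 0.5], [0.5, 1.0], [0.0025, 0.0025], n=1)
        fit2.posteriors = np.array([[0.5, 0.5]])
        from duocall.cnv import AnalysisArm

        arm = AnalysisArm("AA_on_A", np.array([0]), np.array([0.75]))
        arm.fit2 = fit2
        arm.selected = "two"
        arm.labels = np.array([1.0, 2.0])
        arm.outlier_low = np.zeros(1, bool)
        arm.outlier_high = np.zeros(1, bool)
        empty = [
            AnalysisArm(a_id, np.array([], int), np.array([]))
            for a_id in ("BB_on_B", "AB_on_A", "AB_on_B")
        ]
        scores = score_samples([arm] + empty, np.array([AA], np.int8), np.zeros(1, bool))
        assert scores[0] == pytest.approx(1.5)
        assert bin_scores(scores)[0] == 2  # boundary bins right-closed on the left

    def test_score_category_binning(self):
        s = np.array([0.2, 0.5, 1.2, 1.5, 2.0, 2.5, 2.9])
        assert list(bin_scores(s)) == [0, 1, 1, 2, 2, 3, 3]

    def test_deletion_marker_recovery(self, rng):
        res = self._marker(rng)
        geno_map = {"AA": AA, "AB": AB, "BB": BB, "ZERO": ZERO}
        geno = np.vectorize(geno_map.get)(res["snp_genotype"]).astype(np.int8)
        zero = geno == ZERO
        scores, arms = call_marker_cnv(geno, res["raw_a"], res["raw_b"], zero, rng=rng)
        truth = np.minimum(res["copy_number"], 3)
        concord = (bin_scores(scores) == truth).mean()
        assert concord >= 0.95

    def test_determinism_under_fixed_seed(self, rng):
        res = self._marker(np.random.default_rng(3))
        geno_map = {"AA": AA, "AB": AB, "BB": BB, "ZERO": ZERO}
        geno = np.vectorize(geno_map.get)(res["snp_genotype"]).astype(np.int8)
        zero = geno == ZERO
        s1, _ = call_marker_cnv(geno, res["raw_a"], res["raw_b"], zero,
                                rng=np.random.default_rng(9))
        s2, _ = call_marker_cnv(geno, res["raw_a"], res["raw_b"], zero,
                                rng=np.random.default_rng(9))
        np.testing.assert_array_equal(s1, s2)

    def test_saturated_amplification_no_false_deletions(self):
        # high-frequency amplification markers need not be recovered, but
        # they must not produce deletion calls
        from duocall.simulate import MarkerSpec, simulate_marker

        for s in range(5):
            spec = MarkerSpec(maf=0.4, amp_freq=0.4, noise_sd=0.05, seed=100 + s)
            res = simulate_marker(spec, 300)
            geno_map = {"AA": AA, "AB": AB, "BB": BB, "ZERO": ZERO}
            geno = np.vectorize(geno_map.get)(res["snp_genotype"]).astype(np.int8)
            scores, _ = call_marker_cnv(
                geno, res["raw_a"], res["raw_b"], geno == ZERO,
                rng=np.random.default_rng(s),
            )
            cats = bin_scores(scores)
            del_calls = (cats < 2).sum()
            assert del_calls / len(cats) <= 0.01
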