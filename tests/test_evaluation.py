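"""Concordance r2, chi-square association, ratio metric and LD mining."""

import numpy as np
import pandas as pd
import pytest

from duocall.config import EvalConfig
from duocall.evaluation import (
    best_marker_per_locus,
    cnv_locus_builder,
    genotype_r2,
    ld_pair_candidates,
    locus_min_p,
    population_association,
    pvalue_ratio_metric,
    reference_frequency_filter,
)
from duocall.types import (
    AnnotationIntervals,
    CnvScoreSet,
    MarkerManifest,
    ReferenceLocusSet,
    bin_scores,
)


class TestGenotypeR2:
    def test_identity_is_one(self):
        x = np.array([0, 1, 2, 2, 1, 0])
        assert genotype_r2(x, x) == pytest.approx(1.0)

    def test_anticorrelation_is_one(self):
        x = np.array([0, 1, 2, 3, 2])
        assert genotype_r2(x, 3 - x) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 1000)
        y = rng.integers(0, 3, 1000)
        assert genotype_r2(x, y) < 0.02

    def test_symmetry_and_affine_invariance(self, rng):
        x = rng.integers(0, 4, 60)
        y = rng.integers(0, 4, 60)
        assert genotype_r2(x, y) == pytest.approx(genotype_r2(y, x))
        assert genotype_r2(2 * x + 1, y) == pytest.approx(genotype_r2(x, y))

    def test_zero_variance_is_undefined(self):
        assert np.isnan(genotype_r2(np.full(20, 2), np.arange(20)))

    def test_no_shared_samples_errors(self):
        with pytest.raises(ValueError, match="no shared"):
            genotype_r2(np.array([-1, -1]), np.array([1, 2]))


def _score_set(categories, samples=None):
    categories = np.asarray(categories, dtype=float)
    samples = samples or [f"s{j}" for j in range(categories.shape[1])]
    markers = np.array([f"m{i}" for i in range(categories.shape[0])], dtype=object)
    scores = categories.astype(float)
    return CnvScoreSet(markers, np.asarray(samples, dtype=object), scores, bin_scores(scores))


def _manifest(positions, chrom="1"):
    n = len(positions)
    return MarkerManifest(
        [f"m{i}" for i in range(n)], [chrom] * n, positions, ["A"] * n, ["C"] * n
    )


class TestBestMarkerPerLocus:
    def _ref(self, calls, start=500, end=2500):
        return ReferenceLocusSet(
            np.array(["L0"], dtype=object),
            np.array(["1"], dtype=object),
            np.array([start]),
            np.array([end]),
            np.array([f"s{j}" for j in range(calls.shape[1])], dtype=object),
            calls,
        )

    def test_concordant_marker_found(self, rng):
        truth = rng.integers(1, 3, 40)
        cats = np.vstack([truth, rng.integers(1, 3, 40)])
        res = best_marker_per_locus(
            self._ref(truth[None, :]), _score_set(cats), _manifest([1000, 2000])
        )
        assert res.best_marker_id[0] == "m0"
        assert res.best_r2[0] == pytest.approx(1.0)
        assert res.n_markers_in_region[0] == 2

    def test_uncovered_locus_flagged(self, rng):
        cats = rng.integers(1, 3, (1, 20))
        res = best_marker_per_locus(
            self._ref(cats, start=10_000, end=20_000), _score_set(cats), _manifest([1000])
        )
        assert res.n_markers_in_region[0] == 0
        assert np.isnan(res.best_r2[0])

    def test_extra_marker_never_lowers_best_r2(self, rng):
        truth = rng.integers(1, 3, 40)
        good = np.where(rng.random(40) < 0.9, truth, 3 - truth)
        base = best_marker_per_locus(
            self._ref(truth[None, :]), _score_set(good[None, :]), _manifest([1000])
        )
        extra = np.vstack([good, rng.integers(1, 3, 40)])
        more = best_marker_per_locus(
            self._ref(truth[None, :]), _score_set(extra), _manifest([1000, 2000])
        )
        assert more.best_r2[0] >= base.best_r2[0] - 1e-12

    def test_stratification_percentages(self, rng):
        truth = rng.integers(1, 3, 40)
        res = best_marker_per_locus(
            self._ref(truth[None, :]), _score_set(truth[None, :]), _manifest([1000])
        )
        strat = res.stratify()
        assert strat.loc[strat.stratum == ">0.9", "pct"].iloc[0] == 100.0


class TestPopulationAssociation:
    def test_hand_computed_chi_square(self):
        # category x population table [[25,5],[5,25]]:
        # chi2 = N(ad-bc)^2 / (r1 r2 c1 c2) = 60*600^2/30^4 = 26.666...
        calls = np.r_[np.zeros(25), np.ones(5), np.zeros(5), np.ones(25)]
        pops = np.r_[np.repeat("P1", 30), np.repeat("P2", 30)]
        table, stat, p = population_association(calls, pops)
        np.testing.assert_array_equal(table, [[25, 5], [5, 25]])
        assert stat == pytest.approx(60 * 600**2 / 30**4, abs=1e-6)
        assert p < 1e-5

    def test_identical_distributions_not_significant(self):
        calls = np.r_[np.zeros(15), np.ones(15), np.zeros(15), np.ones(15)]
        pops = np.r_[np.repeat("P1", 30), np.repeat("P2", 30)]
        _, stat, p = population_association(calls, pops)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_degenerate_single_category_p_one(self):
        _, _, p = population_association(
            np.full(40, 2.0), np.r_[np.repeat("P1", 20), np.repeat("P2", 20)]
        )
        assert p == 1.0

    def test_null_type_one_error_calibrated(self):
        # simulated null loci: both populations draw categories from the
        # same distribution; empirical alpha should be near 0.05
        rng = np.random.default_rng(7)
        pops = np.r_[np.repeat("P1", 100), np.repeat("P2", 100)]
        rejections = 0
        n_loci = 1000
        for _ in range(n_loci):
            calls = rng.choice([1, 2, 2, 2, 3], size=200)
            _, _, p = population_association(calls, pops)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_loci <= 0.07


class TestPvalueRatioMetric:
    def test_identity_all_in_window(self):
        p = np.array([1e-8, 1e-3, 0.04])
        ratios, pct_in, pct_missed = pvalue_ratio_metric(p, p)
        np.testing.assert_allclose(ratios, 1.0)
        assert pct_in == 100.0
        assert pct_missed == 0.0

    def test_sqrt_method_all_out_of_window(self):
        ref = np.array([1e-8, 1e-4, 1e-3])
        ratios, pct_in, _ = pvalue_ratio_metric(ref**0.5, ref)
        np.testing.assert_allclose(ratios, 0.5)
        assert pct_in == 0.0

    def test_nonsignificant_reference_loci_excluded(self):
        ref = np.array([1e-6, 0.5, 1.0])
        ratios, pct_in, _ = pvalue_ratio_metric(ref, ref)
        assert len(ratios) == 1

    def test_missed_loci_counted(self):
        ref = np.array([1e-6, 1e-6])
        method = np.array([1e-6, 0.5])
        _, pct_in, pct_missed = pvalue_ratio_metric(method, ref)
        assert pct_missed == 50.0


class TestLocusMinP:
    def test_best_marker_is_min_p(self):
        manifest = _manifest([1000, 1500, 9000])
        ref = ReferenceLocusSet(
            np.array(["L0"], dtype=object), np.array(["1"], dtype=object),
            np.array([900]), np.array([2000]),
            np.array(["s0"], dtype=object), np.array([[2]]),
        )
        out = locus_min_p(np.array([0.2, 0.01, 1e-9]), manifest, ref)
        assert out[0] == pytest.approx(0.01)


class TestReferenceFrequencyFilter:
    def test_rare_loci_dropped(self):
        ref = ReferenceLocusSet(
            np.array(["common", "rare"], dtype=object),
            np.array(["1", "1"], dtype=object),
            np.array([1, 1]), np.array([10, 10]),
            np.array([f"s{j}" for j in range(100)], dtype=object),
            np.vstack([
                np.r_[np.full(90, 2), np.full(10, 1)],
                np.r_[np.full(99, 2), np.full(1, 1)],
            ]),
        )
        kept = reference_frequency_filter(ref, maf_min=0.02)
        assert list(kept.locus_id) == ["common"]


def _annotations():
    return AnnotationIntervals(
        kind=np.array(["gene", "tf_binding"], dtype=object),
        chrom=np.array(["1", "1"], dtype=object),
        start=np.array([90_000, 300_000]),
        end=np.array([95_000, 300_500]),
        name=np.array(["GENE1", "TF1"], dtype=object),
    )


class TestLdPairCandidates:
    def _setup(self, rng, cnv_pos, snp_pos=10_000):
        shared = rng.integers(0, 2, 60)
        dosage = shared.astype(float)  # SNP B-dosage mirrors the CNV
        cats = np.where(shared == 1, 1, 2)[None, :].astype(float)
        cnv = _score_set(cats)
        manifest = MarkerManifest(
            ["m0", "snp1"], ["1", "1"], [cnv_pos, snp_pos], ["A", "A"], ["C", "C"]
        )
        return {"snp1": dosage}, cnv, manifest

    def test_perfect_ld_pair_within_distance(self, rng):
        snps, cnv, manifest = self._setup(rng, cnv_pos=20_000)
        out = ld_pair_candidates(snps, cnv, manifest, _annotations())
        assert len(out) == 1
        assert out.loc[0, "best_r2"] == pytest.approx(1.0)

    def test_distance_filter_excludes_far_pairs(self, rng):
        snps, cnv, manifest = self._setup(rng, cnv_pos=70_000)  # 60 kb away
        out = ld_pair_candidates(snps, cnv, manifest, _annotations())
        assert len(out) == 0

    def test_gene_and_tf_filters(self, rng):
        # CNV at 20 kb: within 100 kb of GENE1 -> kept
        snps, cnv, manifest = self._setup(rng, cnv_pos=20_000)
        cfg = EvalConfig(gene_max_dist=100_000)
        assert len(ld_pair_candidates(snps, cnv, manifest, _annotations(), config=cfg)) == 1
        # shrink the gene window so the CNV is too far and not on a TF site
        cfg2 = EvalConfig(gene_max_dist=1_000)
        assert len(ld_pair_candidates(snps, cnv, manifest, _annotations(), config=cfg2)) == 0
        # but a CNV sitting on the TF interval passes regardless of genes
        snps3, cnv3, manifest3 = self._setup(rng, cnv_pos=300_200, snp_pos=290_000)
        assert len(ld_pair_candidates(snps3, cnv3, manifest3, _annotations(), config=cfg2)) == 1

    def test_low_r2_excluded(self, rng):
        snps, cnv, manifest = self._setup(rng, cnv_pos=20_000)
        snps["snp1"] = rng.integers(0, 3, 60).astype(float)  # decorrelate
        out = ld_pair_candidates(snps, cnv, manifest, _annotations())
        assert len(out) == 0


class TestCnvLocusBuilder:
    def _cnv_set(self, rng, n_markers, correlated=True):
        base = rng.integers(0, 2, 80)
        rows = []
        for i in range(n_markers):
            if correlated:
                rows.append(np.where(base == 1, 1, 2))
            else:
                rows.append(np.where(rng.integers(0, 2, 80) == 1, 1, 2))
        return _score_set(np.asarray(rows, dtype=float))

    def test_three_tight_markers_form_locus(self, rng):
        cnv = self._cnv_set(rng, 3)
        manifest = _manifest([91_000, 92_000, 93_000])
        out = cnv_locus_builder(cnv, manifest, _annotations())
        assert len(out) == 1
        assert out.loc[0, "n_markers"] == 3
        assert out.loc[0, "mean_r2"] == pytest.approx(1.0)
        assert "GENE1" in out.loc[0, "genes"]

    def test_weak_pair_blocks_locus(self, rng):
        cnv = self._cnv_set(rng, 3, correlated=False)
        manifest = _manifest([91_000, 92_000, 93_000])
        assert len(cnv_locus_builder(cnv, manifest, _annotations())) == 0

    def test_gap_over_5kb_breaks_chain(self, rng):
        cnv = self._cnv_set(rng, 3)
        manifest = _manifest([91_000, 92_000, 99_000])  # 7 kb gap
        assert len(cnv_locus_builder(cnv, manifest, _annotations())) == 0

    def test_best_locus_kept_per_gene(self, rng):
        base = rng.integers(0, 2, 80)
        noisy = np.where(rng.random(80) < 0.85, base, 1 - base)
        rows = np.asarray(
            [np.where(base == 1, 1, 2)] * 3 + [np.where(noisy == 1, 1, 2)] * 3,
            dtype=float,
        )
        cnv = _score_set(rows)
        manifest = _manifest([80_000, 81_000, 82_000, 91_000, 92_000, 93_000])
        out = cnv_locus_builder(cnv, manifest, _annotations())
        if len(out) == 1:
            assert out.loc[0, "mean_r2"] == pytest.approx(1.0)
        else:  # noisy chain failed the pairwise filter entirely
            assert (out["mean_r2"] == pytest.approx(1.0)).all()
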