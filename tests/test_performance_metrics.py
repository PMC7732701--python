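"""Tests for the discrimination/calibration metric panel."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from deprisk import performance_metrics as pm
from deprisk import risk_model as rm
from deprisk import synthetic_cohort as sc

from conftest import pairwise_auc


class TestAUC:
    def test_perfect_separation(self):
        assert pm.auc([0.9, 0.2, 0.1], [1, 0, 0]) == 1.0

    def test_constant_scores_are_chance(self):
        assert pm.auc([0.4] * 10, [1, 0] * 5) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pm.auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_pairwise_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = rng.integers(0, 8, size=n) / 7.0  # heavy ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert pm.auc(scores, labels) == pytest.approx(
            pairwise_auc(scores, labels), abs=1e-12)

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 5.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariant_under_strictly_increasing_transforms(self, seed, a):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=60)
        labels = np.r_[np.ones(20), np.zeros(40)].astype(int)
        base = pm.auc(scores, labels)
        for transform in (lambda s: a * s + 1.0,
                          lambda s: np.tanh(s) * a,
                          lambda s: np.exp(a * s)):
            assert pm.auc(transform(scores), labels) == pytest.approx(
                base, abs=1e-12)

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        scores = rng.random(300)
        labels = rng.integers(0, 2, size=300)
        assert pm.auc(scores, labels) == pytest.approx(
            sk.roc_auc_score(labels, scores), abs=1e-12)


class TestBootstrapAUC:
    def test_perfectly_separated_interval_degenerates(self):
        scores = np.r_[np.linspace(0.8, 0.9, 20), np.linspace(0.1, 0.3, 40)]
        labels = np.r_[np.ones(20), np.zeros(40)]
        assert pm.bootstrap_auc_ci(scores, labels, B=300, seed=0) == (1.0, 1.0)

    def test_same_seed_reproduces_interval(self):
        rng = np.random.default_rng(11)
        scores, labels = rng.random(150), rng.integers(0, 2, 150)
        a = pm.bootstrap_auc_ci(scores, labels, B=400, seed=5)
        b = pm.bootstrap_auc_ci(scores, labels, B=400, seed=5)
        assert a == b

    def test_covers_half_for_uninformative_scores(self):
        rng = np.random.default_rng(2)
        scores = rng.random(3000)
        labels = (rng.random(3000) < 0.2).astype(int)
        lo, hi = pm.bootstrap_auc_ci(scores, labels, B=500, seed=1)
        assert lo < 0.5 < hi

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError):
            pm.bootstrap_auc_ci([0.1, 0.9], [0, 1], B=10)


class TestBrier:
    @pytest.mark.parametrize("probs,y,expected", [
        ([0.0, 1.0, 1.0], [0, 1, 1], 0.0),
        ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.25),
        ([0.2, 0.8], [0, 1], 0.04),
    ])
    def test_examples(self, probs, y, expected):
        assert pm.brier(probs, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_prevalence_predictor_identity(self):
        rng = np.random.default_rng(3)
        y = (rng.random(5000) < 0.118).astype(float)
        pbar = y.mean()
        assert pm.brier(np.full_like(y, pbar), y) == pytest.approx(
            pbar * (1 - pbar), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pm.brier([0.5], [1, 0])


@pytest.fixture(scope="module")
def lp_y():
    rng = np.random.default_rng(8)
    lp = rng.normal(-2.0, 0.8, size=20_000)
    y = (rng.random(lp.size) < expit(lp)).astype(float)
    return lp, y


class TestRecalibration:
    """CITL, slope and the 2-df unreliability LR test."""

    def test_citl_near_zero_when_calibrated(self, lp_y):
        lp, y = lp_y
        assert abs(pm.calibration_in_the_large(lp, y)) < 0.1

    def test_citl_recovers_injected_shift(self, lp_y):
        lp, y = lp_y
        assert pm.calibration_in_the_large(lp + 0.8, y) \
            == pytest.approx(-0.8, abs=0.1)

    def test_slope_near_one_when_calibrated(self, lp_y):
        lp, y = lp_y
        assert pm.calibration_slope(lp, y) == pytest.approx(1.0, abs=0.1)

    def test_slope_two_when_lp_halved(self, lp_y):
        lp, y = lp_y
        assert pm.calibration_slope(0.5 * lp, y) \
            == pytest.approx(2.0, abs=0.2)

    def test_in_sample_slope_of_unpenalized_refit_is_one(self):
        gen = sc.generate_validation_cohort(sc.validation_spec(
            n=3000, seed=4))
        X = rm.encode_design(gen.data)
        y = gen.data["depressed_followup"].to_numpy(float)
        fit = rm.fit_penalized(X, y, penalty=0.0)
        lp = rm.linear_predictor(fit, X)
        assert pm.calibration_slope(lp, y) == pytest.approx(1.0, abs=1e-6)
        assert pm.calibration_in_the_large(lp, y) \
            == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_lp_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pm.calibration_slope(np.zeros(100),
                                 np.r_[np.ones(50), np.zeros(50)])

    def test_recalibration_matches_statsmodels(self, lp_y):
        smapi = pytest.importorskip("statsmodels.api")
        lp, y = lp_y
        lp2 = 0.7 * lp + 0.3
        a_ours, b_ours = pm.recalibration_fit(lp2, y)
        ref = smapi.GLM(y, smapi.add_constant(lp2),
                        family=smapi.families.Binomial()).fit()
        assert a_ours == pytest.approx(ref.params[0], abs=1e-6)
        assert b_ours == pytest.approx(ref.params[1], abs=1e-6)
        citl = pm.calibration_in_the_large(lp2, y)
        ref2 = smapi.GLM(y, np.ones((len(y), 1)), offset=lp2,
                         family=smapi.families.Binomial()).fit()
        assert citl == pytest.approx(ref2.params[0], abs=1e-6)

    def test_unreliability_statistic_nonnegative_and_powerful(self, lp_y):
        lp, y = lp_y
        null = pm.unreliability_test(lp, y)
        assert null.chi2 >= 0.0 and null.df == 2
        shifted = pm.unreliability_test(lp + 2.0, y)
        assert shifted.p_value < 1e-3
        assert shifted.chi2 > null.chi2


class TestCalibrationCurve:
    def test_ideal_predictions_hug_identity(self):
        rng = np.random.default_rng(14)
        p = rng.beta(2, 8, size=20_000)
        y = (rng.random(p.size) < p).astype(float)
        curve = pm.flexible_calibration_curve(p, y)
        inside = (curve.band_low <= curve.grid) & (curve.grid
                                                   <= curve.band_high)
        assert inside.mean() >= 0.95
        assert (curve.band_low <= curve.observed).all()
        assert (curve.observed <= curve.band_high).all()
        assert (np.diff(curve.grid) >= 0).all()

    def test_overestimation_detected_below_identity(self):
        rng = np.random.default_rng(15)
        p = rng.uniform(0.05, 0.5, size=8000)
        # true risk is half the prediction: curve must fall below identity
        y = (rng.random(p.size) < 0.5 * p).astype(float)
        curve = pm.flexible_calibration_curve(p, y)
        window = (curve.grid > 0.2) & (curve.grid < 0.4)
        assert (curve.observed[window] < curve.grid[window]).all()

    def test_bands_widen_where_data_sparse(self):
        rng = np.random.default_rng(16)
        p = np.r_[rng.uniform(0.05, 0.15, 4000), rng.uniform(0.55, 0.65, 80)]
        y = (rng.random(p.size) < p).astype(float)
        curve = pm.flexible_calibration_curve(p, y, span=0.3)
        width = curve.band_high - curve.band_low
        dense = width[(curve.grid > 0.05) & (curve.grid < 0.15)].mean()
        sparse = width[(curve.grid > 0.55) & (curve.grid < 0.65)].mean()
        assert sparse > dense

    def test_requested_grid_outside_range_truncates_with_warning(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(0.2, 0.4, 500)
        y = (rng.random(500) < p).astype(float)
        with pytest.warns(UserWarning, match="truncated"):
            curve = pm.flexible_calibration_curve(p, y, grid_range=(0.0, 1.0))
        assert curve.grid.min() >= 0.2 - 1e-9
        assert curve.grid.max() <= 0.4 + 1e-9

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            pm.flexible_calibration_curve([0.5] * 10, [1] * 10)


class TestWilson:
    def test_reproduces_printed_prevalence_interval(self):
        # 227 cases of 1928 (11.8%) -> (10.4%, 13.3%) at one decimal
        lo, hi = pm.wilson_ci(227, 1928)
        assert round(100 * lo, 1) == 10.4
        assert round(100 * hi, 1) == 13.3

    def test_boundary_cases(self):
        assert pm.wilson_ci(0, 10)[0] == 0.0
        assert pm.wilson_ci(10, 10)[1] == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            pm.wilson_ci(0, 0)


class TestComputeReport:
    def test_panel_consistency(self):
        rng = np.random.default_rng(19)
        lp = rng.normal(-2, 0.7, 1500)
        y = (rng.random(1500) < expit(lp)).astype(float)
        rep = pm.compute_report(lp, y, regime="standard", B=300, seed=2)
        assert rep.n == 1500
        assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]
        assert rep.brier == pm.brier(expit(lp), y)
        assert rep.unreliability_df == 2
        d = rep.rounded(2)
        assert d["auc"] == round(rep.auc, 2)
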