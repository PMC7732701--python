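"""Tests for design encoding and penalized-ML logistic fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from deprisk import risk_model as rm
from deprisk import synthetic_cohort as sc
from deprisk.survey_coding import PredictorVector


def iterated_grid_mle(X, y, span=5.0, points=13, rounds=7):
    """Independent brute-force likelihood maximizer: zooming grid search."""
    X1 = np.column_stack([np.ones(len(y)), X])
    p = X1.shape[1]

    def loglik(beta):
        eta = X1 @ beta
        return y @ eta - np.logaddexp(0.0, eta).sum()

    center = np.zeros(p)
    half = span
    for _ in range(rounds):
        axes = [np.linspace(c - half, c + half, points) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        cand = np.stack([g.ravel() for g in grids], axis=1)
        lls = np.array([loglik(b) for b in cand])
        center = cand[lls.argmax()]
        half = 2 * half / (points - 1)   # zoom around the best point
    return center


class TestEncodeDesign:
    def test_all_reference_vector_is_zero_row(self):
        pv = PredictorVector(0, "none", 0, 0, 0, 0, 0)
        row = rm.encode_design(pv)
        assert list(row.columns) == list(rm.DESIGN_TERMS)
        assert (row.to_numpy() == 0).all()

    def test_maltreatment_dummies_mutually_exclusive(self):
        sev = rm.encode_design(PredictorVector(0, "severe", 0, 0, 0, 0, 0))
        assert sev["maltreatment[probable]"].iloc[0] == 0
        assert sev["maltreatment[severe]"].iloc[0] == 1
        prob = rm.encode_design(
            PredictorVector(0, "probable", 0, 0, 0, 0, 1))
        assert prob.to_numpy().sum() == 2  # exactly two nonzero entries

    def test_unknown_level_rejected(self):
        df = pd.DataFrame({"sex_female": [0], "maltreatment": ["extreme"],
                           "school_failure": [0], "social_isolation": [0],
                           "fights": [0], "ran_away": [0], "drug_use": [0]})
        with pytest.raises(ValueError, match="maltreatment"):
            rm.encode_design(df)


class TestFitPenalized:
    def test_intercept_only_recovers_logit_prevalence(self):
        y = np.r_[np.ones(31), np.zeros(969)]
        model = rm.fit_penalized(np.empty((1000, 0)), y, penalty=0.0,
                                 term_names=())
        assert model.intercept == pytest.approx(logit(0.031), abs=1e-6)

    def test_huge_penalty_shrinks_slopes_to_zero(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(500, 3)).astype(float)
        y = (rng.random(500) < expit(-1 + X @ [1.0, 0.5, -0.5])).astype(float)
        model = rm.fit_penalized(X, y, penalty=1e8)
        assert np.abs(model.coefficients).max() < 1e-3
        assert model.intercept == pytest.approx(logit(y.mean()), abs=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_unpenalized_fit_matches_grid_oracle_two_predictors(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, size=(40, 2)).astype(float)
        y = (rng.random(40) < expit(-0.5 + X @ [1.2, -0.8])).astype(float)
        if y.min() == y.max():
            pytest.skip("degenerate draw")
        model = rm.fit_penalized(X, y, penalty=0.0)
        oracle = iterated_grid_mle(X, y)
        fitted = np.r_[model.intercept, model.coefficients]
        assert np.allclose(fitted, oracle, atol=1e-3)

    def test_unpenalized_fit_matches_grid_oracle_tiny_hand_dataset(self):
        X = np.array([0, 0, 0, 1, 1, 1, 1, 0], float)[:, None]
        y = np.array([0, 0, 1, 1, 1, 0, 1, 0], float)
        model = rm.fit_penalized(X, y, penalty=0.0)
        oracle = iterated_grid_mle(X, y)
        assert np.allclose(np.r_[model.intercept, model.coefficients],
                           oracle, atol=1e-3)

    def test_shrinkage_monotone_in_penalty(self):
        gen = sc.generate_development_cohort(sc.development_spec(
            n=4000, seed=9))
        X = rm.encode_design(gen.data)
        y = gen.data["depressed_followup"].to_numpy(float)
        norms = []
        for lam in (0.0, 0.5, 2.0, 8.0, 32.0):
            m = rm.fit_penalized(X, y, lam)
            norms.append(np.abs(m.coefficients))
        for small, big in zip(norms, norms[1:]):
            assert (big <= small + 1e-6).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            rm.fit_penalized(np.zeros((5, 1)), np.ones(5))

    def test_separation_raises_advice(self):
        X = np.r_[np.zeros(10), np.ones(10)][:, None]
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(rm.SeparationError, match="penalty"):
            rm.fit_penalized(X, y, penalty=0.0)
        # and a positive penalty handles the same data
        m = rm.fit_penalized(X, y, penalty=0.5)
        assert np.isfinite(m.coefficients).all()

    def test_matches_sklearn_ridge_logistic(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, size=(600, 4)).astype(float)
        y = (rng.random(600) < expit(-1 + X @ [0.8, -0.4, 0.6, 0.0])
             ).astype(float)
        lam = 2.0
        ours = rm.fit_penalized(X, y, lam)
        ref = sklearn.LogisticRegression(
            C=1.0 / lam, solver="lbfgs", tol=1e-10, max_iter=5000).fit(X, y)
        assert np.allclose(ours.coefficients, ref.coef_[0], atol=1e-4)
        assert ours.intercept == pytest.approx(ref.intercept_[0], abs=1e-4)


class TestPrediction:
    model = rm.LogisticRiskModel(
        intercept=-2.0, terms=("a", "b"), coefficients=np.array([0.5, 0.7]))

    def test_zero_row_gives_intercept(self):
        assert rm.linear_predictor(self.model, [[0, 0]])[0] == -2.0

    def test_hand_arithmetic(self):
        lp = rm.linear_predictor(self.model, [[1, 1]])
        assert lp[0] == pytest.approx(-0.8)
        assert rm.predict_prob(self.model, [[1, 1]])[0] \
            == pytest.approx(0.3100, abs=1e-4)

    def test_identity_pair(self):
        m = rm.LogisticRiskModel(intercept=float(logit(0.031)), terms=(),
                                 coefficients=np.empty(0))
        assert rm.predict_prob(m, np.empty((1, 0)))[0] \
            == pytest.approx(0.031, abs=1e-12)

    def test_term_mismatch_lists_missing_and_extra(self):
        rows = pd.DataFrame({"a": [1], "c": [1]})
        with pytest.raises(rm.TermMismatchError) as err:
            rm.linear_predictor(self.model, rows)
        assert err.value.missing == ["b"] and err.value.extra == ["c"]

    def test_probability_monotone_in_indicator_product(self):
        base = rm.predict_prob(self.model, [[0, 0]])[0]
        one = rm.predict_prob(self.model, [[1, 0]])[0]
        both = rm.predict_prob(self.model, [[1, 1]])[0]
        assert base < one < both


@pytest.fixture(scope="module")
def dev_with_extras():
    gen = sc.generate_development_cohort(
        sc.development_spec(n=50_000, seed=17, n_extra_predictors=4))
    X = rm.encode_design(gen.data)
    y = gen.data["depressed_followup"].to_numpy(float)
    return gen, X, y


class TestRebuild:

    def test_drop_nothing_is_identity(self, dev_with_extras):
        _, X, y = dev_with_extras
        full = rm.fit_penalized(X, y, 1.0)
        rebuilt = rm.rebuild_without_predictors(X, y, drop=[], penalty=1.0)
        assert rebuilt.terms == full.terms
        assert np.allclose(rebuilt.coefficients, full.coefficients)

    def test_drop_all_gives_intercept_only_at_prevalence(self, dev_with_extras):
        _, X, y = dev_with_extras
        with pytest.warns(UserWarning, match="intercept-only"):
            m = rm.rebuild_without_predictors(
                X, y, drop=list(X.columns), penalty=0.0)
        assert m.terms == ()
        assert m.intercept == pytest.approx(logit(y.mean()), abs=1e-6)

    def test_retained_signs_match_generating_model(self, dev_with_extras):
        gen, X, y = dev_with_extras
        rebuilt = rm.rebuild_without_predictors(
            X, y, drop=[f"extra_{i}" for i in range(1, 5)], penalty=0.0)
        truth = {t: c for t, c in zip(gen.generating_model.terms,
                                      gen.generating_model.coefficients)}
        for term, coef in zip(rebuilt.terms, rebuilt.coefficients):
            assert np.sign(coef) == np.sign(truth[term])

    def test_maltreatment_drops_both_dummies(self, dev_with_extras):
        _, X, y = dev_with_extras
        m = rm.rebuild_without_predictors(X, y, drop=["maltreatment"],
                                          penalty=1.0)
        assert not any(t.startswith("maltreatment") for t in m.terms)


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        m = rm.LogisticRiskModel(
            intercept=-3.2, terms=rm.DESIGN_TERMS,
            coefficients=np.linspace(-1, 1, 8), penalty=1.5,
            meta={"n": 100})
        path = tmp_path / "model.json"
        rm.save_model(m, path)
        back = rm.load_model(path)
        assert back.terms == m.terms
        assert np.allclose(back.coefficients, m.coefficients)
        assert back.penalty == m.penalty and back.meta["n"] == 100


class TestPenaltyCV:
    def test_cv_is_deterministic_and_returns_grid_member(self):
        gen = sc.generate_development_cohort(sc.development_spec(
            n=2000, seed=21))
        X = rm.encode_design(gen.data)
        y = gen.data["depressed_followup"].to_numpy(float)
        grid = (0.0, 1.0, 8.0)
        best1, table1 = rm.select_penalty_cv(X, y, grid, n_folds=5, seed=3)
        best2, table2 = rm.select_penalty_cv(X, y, grid, n_folds=5, seed=3)
        assert best1 == best2 and best1 in grid
        pd.testing.assert_frame_equal(table1, table2)
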