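"""Penalized maximum-likelihood logistic risk model.

The model is an ordinary logistic regression whose slope coefficients are
shrunk by a ridge (L2) penalty; the intercept is never penalized.  The fitted
coefficients maximize

    l(b0, b) - (penalty / 2) * sum_j b_j**2

where ``l`` is the Bernoulli log-likelihood.  ``penalty = 0`` recovers plain
maximum likelihood.  Fitting uses Newton/IRLS with step-halving, a convergence
tolerance on the maximum coefficient change (default 1e-8) and at most 100
iterations; optional fixed offsets support recalibration fits elsewhere in the
package.

The seven harmonized predictors enter through a fixed dummy design: six binary
indicators plus two indicators for the ordered maltreatment factor (reference
``none``).  Models serialize to JSON with their term names, coefficients,
penalty, and fit provenance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .survey_coding import MALTREATMENT_LEVELS, PREDICTOR_COLUMNS, PredictorVector

__all__ = [
    "DESIGN_TERMS",
    "LogisticRiskModel",
    "ConvergenceError",
    "SeparationError",
    "TermMismatchError",
    "encode_design",
    "fit_penalized",
    "linear_predictor",
    "predict_prob",
    "rebuild_without_predictors",
    "select_penalty_cv",
    "cv_deviance",
    "save_model",
    "load_model",
]

#: fixed design column order for the seven-predictor model
DESIGN_TERMS = (
    "sex_female",
    "maltreatment[probable]",
    "maltreatment[severe]",
    "school_failure",
    "social_isolation",
    "fights",
    "ran_away",
    "drug_use",
)

_BINARY_PREDICTORS = tuple(p for p in PREDICTOR_COLUMNS if p != "maltreatment")


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the per-iteration step sizes."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(f"{message} (step trace: {trace})")
        self.trace = trace


class SeparationError(RuntimeError):
    """Outcome separation at penalty 0; refit with penalty > 0."""


class TermMismatchError(ValueError):
    """Design columns do not match the model's terms."""

    def __init__(self, missing: Sequence[str], extra: Sequence[str]):
        super().__init__(
            f"design/model term mismatch: missing={list(missing)}, "
            f"extra={list(extra)}")
        self.missing = list(missing)
        self.extra = list(extra)


@dataclass
class LogisticRiskModel:
    """Intercept + per-term log-odds coefficients, with penalty metadata."""

    intercept: float
    terms: tuple[str, ...]
    coefficients: np.ndarray
    penalty: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = tuple(self.terms)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.terms) != len(set(self.terms)):
            raise ValueError("model term names must be unique")
        if self.coefficients.shape != (len(self.terms),):
            raise ValueError("one coefficient per term required")
        if not np.isfinite(self.coefficients).all() \
                or not np.isfinite(self.intercept):
            raise ValueError("model coefficients must be finite")
        if self.penalty < 0:
            raise ValueError("penalty must be non-negative")

    def coefficient(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def replace(self, **kwargs) -> "LogisticRiskModel":
        out = {
            "intercept": self.intercept,
            "terms": self.terms,
            "coefficients": self.coefficients.copy(),
            "penalty": self.penalty,
            "meta": dict(self.meta),
        }
        out.update(kwargs)
        return LogisticRiskModel(**out)

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "terms": [[t, float(c)]
                      for t, c in zip(self.terms, self.coefficients)],
            "penalty": float(self.penalty),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LogisticRiskModel":
        terms = tuple(t for t, _ in d["terms"])
        coefs = np.array([c for _, c in d["terms"]], dtype=float)
        return cls(intercept=float(d["intercept"]), terms=terms,
                   coefficients=coefs, penalty=float(d.get("penalty", 0.0)),
                   meta=dict(d.get("meta", {})))


def save_model(model: LogisticRiskModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def load_model(path: str | Path) -> LogisticRiskModel:
    return LogisticRiskModel.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# design encoding
# ---------------------------------------------------------------------------

def encode_design(predictors) -> pd.DataFrame:
    """Encode predictors into the fixed 0/1 dummy design.

    Accepts a :class:`PredictorVector`, a mapping, or a DataFrame with the
    seven predictor columns (``maltreatment`` as level strings).  Any column
    beyond the seven (e.g. extra simulated predictors already 0/1 coded) is
    passed through unchanged after the standard terms.
    """
    if isinstance(predictors, PredictorVector):
        predictors = {c: getattr(predictors, c) for c in PREDICTOR_COLUMNS}
    if isinstance(predictors, Mapping):
        predictors = pd.DataFrame({k: [v] for k, v in predictors.items()})
    df = predictors
    missing = [c for c in PREDICTOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"predictor table lacks columns: {missing}")
    malt = df["maltreatment"]
    bad = ~malt.isin(MALTREATMENT_LEVELS)
    if bad.any():
        raise ValueError(
            f"maltreatment={malt[bad].iloc[0]!r} is not one of "
            f"{MALTREATMENT_LEVELS}")
    out = pd.DataFrame(index=df.index)
    out["sex_female"] = df["sex_female"].astype(int)
    out["maltreatment[probable]"] = (malt == "probable").astype(int)
    out["maltreatment[severe]"] = (malt == "severe").astype(int)
    for col in ("school_failure", "social_isolation", "fights", "ran_away",
                "drug_use"):
        vals = df[col].astype(int)
        if not vals.isin((0, 1)).all():
            raise ValueError(f"{col} must be 0/1")
        out[col] = vals
    passthrough = [c for c in df.columns
                   if c not in PREDICTOR_COLUMNS
                   and c not in ("id", "age_baseline", "depressed_baseline",
                                 "depressed_followup")]
    for col in passthrough:
        out[col] = df[col].astype(int)
    return out


def _align_design(model: LogisticRiskModel, rows) -> np.ndarray:
    """Return the design matrix in the model's term order, or raise."""
    if isinstance(rows, pd.DataFrame):
        missing = [t for t in model.terms if t not in rows.columns]
        extra = [c for c in rows.columns if c not in model.terms]
        if missing or extra:
            raise TermMismatchError(missing, extra)
        return rows.loc[:, list(model.terms)].to_numpy(dtype=float)
    arr = np.asarray(rows, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != len(model.terms):
        raise TermMismatchError(
            missing=[f"<{len(model.terms)} columns expected>"],
            extra=[f"<{arr.shape[1]} columns given>"])
    return arr


def linear_predictor(model: LogisticRiskModel, rows) -> np.ndarray:
    """log-odds LP = intercept + row . coefficients."""
    X = _align_design(model, rows)
    return model.intercept + X @ model.coefficients


def predict_prob(model: LogisticRiskModel, rows) -> np.ndarray:
    """Predicted probability, the inverse logit of the linear predictor."""
    return expit(linear_predictor(model, rows))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _penalized_loglik(eta: np.ndarray, y: np.ndarray,
                      beta: np.ndarray, penalty_vec: np.ndarray) -> float:
    # log(1 + exp(eta)) via logaddexp for numerical stability
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return ll - 0.5 * float(penalty_vec @ beta**2)


def _irls(X1: np.ndarray, y: np.ndarray, penalty_vec: np.ndarray,
          offset: np.ndarray | None, tol: float, max_iter: int
          ) -> tuple[np.ndarray, list[float], bool]:
    n, p = X1.shape
    beta = np.zeros(p)
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    trace: list[float] = []
    obj = _penalized_loglik(X1 @ beta + off, y, beta, penalty_vec)
    for _ in range(max_iter):
        eta = X1 @ beta + off
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X1.T @ (y - mu) - penalty_vec * beta
        H = (X1 * w[:, None]).T @ X1 + np.diag(penalty_vec)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            H = H + 1e-10 * np.eye(p)
            step = np.linalg.solve(H, grad)
        # step-halving keeps the penalized log-likelihood non-decreasing
        scale = 1.0
        for _half in range(40):
            cand = beta + scale * step
            cand_obj = _penalized_loglik(X1 @ cand + off, y, cand, penalty_vec)
            if cand_obj >= obj - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        obj = _penalized_loglik(X1 @ beta + off, y, beta, penalty_vec)
        delta = float(np.max(np.abs(scale * step)))
        trace.append(delta)
        if delta < tol:
            return beta, trace, True
    return beta, trace, False


def fit_penalized(rows, y, penalty: float = 0.0, *,
                  term_names: Sequence[str] | None = None,
                  offset: np.ndarray | None = None,
                  tol: float = 1e-8, max_iter: int = 100,
                  meta: Mapping | None = None) -> LogisticRiskModel:
    """Fit the ridge-penalized logistic model (intercept unpenalized).

    Parameters
    ----------
    rows
        Design matrix: DataFrame (columns become term names) or 2-D array.
    y
        Binary outcomes.
    penalty
        L2 strength on slope coefficients; 0 is plain maximum likelihood.
    offset
        Optional fixed per-row log-odds offset (used by recalibration fits).
    """
    if isinstance(rows, pd.DataFrame):
        if term_names is None:
            term_names = tuple(rows.columns)
        X = rows.to_numpy(dtype=float)
    else:
        X = np.asarray(rows, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if term_names is None:
            term_names = tuple(f"x{i}" for i in range(X.shape[1]))
    y = np.asarray(y, dtype=float)
    if penalty < 0:
        raise ValueError("penalty must be non-negative")
    if y.min() == y.max():
        raise ValueError("outcomes contain a single class; "
                         "need at least one case and one non-case")

    X1 = np.column_stack([np.ones(len(y)), X])
    penalty_vec = np.r_[0.0, np.full(X.shape[1], float(penalty))]
    beta, trace, converged = _irls(X1, y, penalty_vec, offset, tol, max_iter)
    if np.max(np.abs(beta)) > 30 and penalty == 0:
        raise SeparationError(
            "coefficients diverged, outcome classes appear separable; "
            "refit with penalty > 0")
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations", trace)
    fit_meta = {
        "n": int(len(y)),
        "n_events": int(y.sum()),
        "tol": tol,
        "iterations": len(trace),
        "offset_used": offset is not None,
    }
    if meta:
        fit_meta.update(meta)
    return LogisticRiskModel(
        intercept=float(beta[0]),
        terms=tuple(term_names),
        coefficients=beta[1:],
        penalty=float(penalty),
        meta=fit_meta,
    )


# ---------------------------------------------------------------------------
# penalty selection and model rebuilds
# ---------------------------------------------------------------------------

DEFAULT_PENALTY_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)


def cv_deviance(rows, y, penalty: float, n_folds: int = 10,
                seed: int = 0) -> float:
    """Mean held-out deviance of a penalized fit under stratified K-fold CV."""
    if isinstance(rows, pd.DataFrame):
        X = rows.to_numpy(dtype=float)
        names = tuple(rows.columns)
    else:
        X = np.asarray(rows, dtype=float)
        names = None
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in (0, 1):  # stratify so every fold sees events
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    dev = 0.0
    for k in range(n_folds):
        train, test = folds != k, folds == k
        try:
            model = fit_penalized(X[train], y[train], penalty,
                                  term_names=names)
        except SeparationError:
            # a fold separates at this penalty: rule the penalty out
            return float("inf")
        eta = model.intercept + X[test] @ model.coefficients
        ll = float(y[test] @ eta - np.logaddexp(0.0, eta).sum())
        dev += -2.0 * ll
    return dev / len(y)


def select_penalty_cv(rows, y, penalties: Sequence[float] = DEFAULT_PENALTY_GRID,
                      n_folds: int = 10, seed: int = 0
                      ) -> tuple[float, pd.DataFrame]:
    """Pick the penalty minimizing cross-validated deviance (ties -> smaller)."""
    table = pd.DataFrame({
        "penalty": list(penalties),
        "cv_deviance": [cv_deviance(rows, y, lam, n_folds, seed)
                        for lam in penalties],
    }).sort_values("penalty", ignore_index=True)
    best = float(table.loc[table["cv_deviance"].idxmin(), "penalty"])
    return best, table


def _terms_for_predictor(name: str) -> tuple[str, ...]:
    if name == "maltreatment":
        return ("maltreatment[probable]", "maltreatment[severe]")
    return (name,)


def rebuild_without_predictors(rows: pd.DataFrame, y, drop: Sequence[str],
                               penalty: float = 0.0, **fit_kwargs
                               ) -> LogisticRiskModel:
    """Refit the model on development data without the dropped predictors.

    ``drop`` accepts predictor names (``maltreatment`` removes both dummies)
    or design term names.  This is a genuine refit on the retained columns,
    not a deletion of coefficients from an existing model.
    """
    if not isinstance(rows, pd.DataFrame):
        raise TypeError("rebuild_without_predictors requires a named design "
                        "DataFrame")
    drop_terms: set[str] = set()
    for name in drop:
        terms = _terms_for_predictor(name)
        candidates = [t for t in terms if t in rows.columns]
        if not candidates and name not in rows.columns:
            raise ValueError(f"cannot drop unknown predictor {name!r}")
        drop_terms.update(candidates if candidates else [name])
    kept = [c for c in rows.columns if c not in drop_terms]
    if not kept:
        warnings.warn("all predictors dropped; fitting intercept-only model",
                      stacklevel=2)
        y_arr = np.asarray(y, dtype=float)
        X = np.empty((len(y_arr), 0))
        X1 = np.ones((len(y_arr), 1))
        beta, trace, converged = _irls(
            X1, y_arr, np.zeros(1), None,
            fit_kwargs.get("tol", 1e-8), fit_kwargs.get("max_iter", 100))
        return LogisticRiskModel(
            intercept=float(beta[0]), terms=(), coefficients=np.empty(0),
            penalty=float(penalty),
            meta={"n": int(len(y_arr)), "intercept_only": True})
    return fit_penalized(rows[kept], y, penalty, **fit_kwargs)
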