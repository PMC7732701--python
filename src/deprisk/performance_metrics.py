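"""Discrimination and calibration statistics for binary risk predictions.

The panel reported for each validation regime:

* **Brier score** — mean squared difference between predicted probability and
  the 0/1 outcome; 0 is perfect.
* **AUC (concordance statistic)** — probability that a random case scores
  higher than a random non-case, ties counting one half; computed via the
  rank formula, with a stratified percentile bootstrap CI.
* **Calibration-in-the-large (CITL)** — intercept ``a`` of the logistic
  recalibration model ``logit P(y=1) = a + offset(lp)``; 0 means average
  predicted risk matches observed risk on the log-odds scale.  The
  probability-scale difference ``mean(y) - mean(p)`` is exposed as a
  secondary field.
* **Calibration slope** — coefficient ``b`` from ``logit P(y=1) = a + b*lp``;
  1 for a perfect model, below 1 for over-fitted (too extreme) predictions.
* **Unreliability test** — 2-df likelihood-ratio chi-square comparing the
  free recalibration fit ``(a, b)`` against the fixed ideal ``(0, 1)``.
* **Flexible calibration curve** — local-linear smooth of outcome on
  predicted probability with pointwise 95% bands, plus optional decile
  points, for calibration plots.

Recalibration fits reuse the package's IRLS engine with penalty 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

from .risk_model import fit_penalized

__all__ = [
    "PerformanceReport",
    "CalibrationCurve",
    "UnreliabilityResult",
    "auc",
    "make_bootstrap_indices",
    "bootstrap_auc_ci",
    "brier",
    "calibration_in_the_large",
    "calibration_slope",
    "recalibration_fit",
    "unreliability_test",
    "flexible_calibration_curve",
    "wilson_ci",
    "compute_report",
]


# ---------------------------------------------------------------------------
# report containers
# ---------------------------------------------------------------------------

@dataclass
class UnreliabilityResult:
    chi2: float
    df: int
    p_value: float


@dataclass
class PerformanceReport:
    """The metric panel for one validation regime."""

    regime: str
    n: int
    prevalence: float
    brier: float
    auc: float
    auc_ci: tuple[float, float]
    citl: float
    citl_prob_scale: float
    slope: float
    unreliability_chi2: float
    unreliability_df: int
    unreliability_p: float

    def __post_init__(self) -> None:
        lo, hi = self.auc_ci
        if not (lo <= self.auc + 1e-12 and self.auc <= hi + 1e-12):
            raise ValueError("AUC must lie inside its confidence interval")
        if not (0.0 <= self.brier <= 1.0):
            raise ValueError("Brier score must be in [0, 1]")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["auc_ci"] = list(self.auc_ci)
        return d

    def rounded(self, ndigits: int = 2) -> dict:
        d = self.to_dict()
        for k in ("brier", "auc", "citl", "citl_prob_scale", "slope"):
            d[k] = round(d[k], ndigits)
        d["auc_ci"] = [round(v, ndigits) for v in d["auc_ci"]]
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class CalibrationCurve:
    """Smoothed observed-vs-predicted curve with pointwise 95% bands."""

    grid: np.ndarray
    observed: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    group_points: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "grid": np.asarray(self.grid).tolist(),
            "observed": np.asarray(self.observed).tolist(),
            "band_low": np.asarray(self.band_low).tolist(),
            "band_high": np.asarray(self.band_high).tolist(),
            "group_points": [list(p) for p in self.group_points],
        }


def _check_two_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise ValueError("labels contain a single class")


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Concordance probability via the midrank (Mann-Whitney) formula."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    _check_two_classes(y)
    n1 = int((y == 1).sum())
    n0 = len(y) - n1
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def make_bootstrap_indices(labels, B: int, seed: int) -> np.ndarray:
    """Stratified resample index stream, reusable across paired regimes.

    Cases and non-cases are resampled within class, so every resample
    contains both classes.  Returns an integer array of shape (B, n).
    """
    y = np.asarray(labels)
    _check_two_classes(y)
    rng = np.random.default_rng(seed)
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y != 1)
    out = np.empty((B, len(y)), dtype=np.int64)
    for b in range(B):
        out[b, :len(cases)] = rng.choice(cases, size=len(cases))
        out[b, len(cases):] = rng.choice(controls, size=len(controls))
    return out


def bootstrap_auc_ci(scores, labels, B: int = 2000, seed: int = 0,
                     level: float = 0.95,
                     indices: np.ndarray | None = None
                     ) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the AUC.

    ``indices`` may carry a pre-drawn resample stream (from
    :func:`make_bootstrap_indices`) so that several regimes evaluated on the
    same dataset share identical resamples.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if indices is None:
        if B < 200:
            raise ValueError("need at least 200 bootstrap resamples")
        indices = make_bootstrap_indices(y, B, seed)
    aucs = np.array([auc(scores[idx], y[idx]) for idx in indices])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# overall fit and calibration
# ---------------------------------------------------------------------------

def brier(probs, outcomes) -> float:
    """Mean squared difference between predictions and 0/1 outcomes."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probs and outcomes must have equal length")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must be in [0, 1]")
    return float(np.mean((p - y) ** 2))


def calibration_in_the_large(lp, outcomes) -> float:
    """Intercept of ``logit P(y=1) = a + offset(lp)`` fitted by ML."""
    lp = np.asarray(lp, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    _check_two_classes(y)
    X = np.empty((len(y), 0))
    model = fit_penalized(X, y, penalty=0.0, offset=lp, term_names=())
    return float(model.intercept)


def recalibration_fit(lp, outcomes) -> tuple[float, float]:
    """Intercept and slope of ``logit P(y=1) = a + b*lp`` fitted by ML."""
    lp = np.asarray(lp, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    _check_two_classes(y)
    if np.ptp(lp) == 0:
        raise ValueError("linear predictor has zero variance; "
                         "calibration slope is undefined")
    model = fit_penalized(lp[:, None], y, penalty=0.0, term_names=("lp",))
    return float(model.intercept), float(model.coefficients[0])


def calibration_slope(lp, outcomes) -> float:
    """Slope ``b`` of the logistic recalibration of outcomes on ``lp``."""
    return recalibration_fit(lp, outcomes)[1]


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def unreliability_test(lp, outcomes) -> UnreliabilityResult:
    """2-df LR test of perfect calibration (intercept 0, slope 1).

    Compares the free recalibration fit ``logit P = a + b*lp`` against the
    fixed model ``(a, b) = (0, 1)``; the statistic is twice the
    log-likelihood gap, referred to a chi-square with 2 degrees of freedom.
    """
    lp = np.asarray(lp, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    a, b = recalibration_fit(lp, y)
    ll_free = _bernoulli_loglik(a + b * lp, y)
    ll_fixed = _bernoulli_loglik(lp, y)
    chi2 = max(0.0, 2.0 * (ll_free - ll_fixed))
    p = float(stats.chi2.sf(chi2, df=2))
    return UnreliabilityResult(chi2=float(chi2), df=2, p_value=p)


# ---------------------------------------------------------------------------
# flexible calibration curve
# ---------------------------------------------------------------------------

def flexible_calibration_curve(probs, outcomes, span: float = 0.75,
                               grid_size: int = 100, n_groups: int = 10,
                               grid_range: tuple[float, float] | None = None
                               ) -> CalibrationCurve:
    """Local-linear smooth of outcome on predicted probability.

    A loess-style smoother: at each grid point the nearest ``span`` fraction
    of observations is tricube-weighted and a weighted line is fitted; the
    pointwise variance uses the binomial variance of the smoothed value with
    the smoother's equivalent-kernel weights.  The grid spans the observed
    probability range; an explicitly requested ``grid_range`` reaching
    outside it is truncated with a warning.  Decile (mean predicted,
    observed rate) points are attached when ``n_groups`` > 0.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n = len(p)
    if n < 50:
        raise ValueError("need at least 50 observations for the smoother")
    lo, hi = float(p.min()), float(p.max())
    if grid_range is not None:
        want_lo, want_hi = grid_range
        if want_lo < lo or want_hi > hi:
            warnings.warn(
                "calibration grid truncated to the observed probability "
                f"range [{lo:.3f}, {hi:.3f}]", stacklevel=2)
        lo, hi = max(lo, want_lo), min(hi, want_hi)
    grid = np.clip(np.linspace(lo, hi, grid_size), 0.0, 1.0)

    k = max(4, int(np.ceil(span * n)))
    fit = np.empty(grid_size)
    var = np.empty(grid_size)
    order = np.argsort(p)
    ps, ys = p[order], y[order]
    for j, x0 in enumerate(grid):
        d = np.abs(ps - x0)
        h = np.partition(d, k - 1)[k - 1]
        h = max(h, 1e-9)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        use = w > 0
        xw, yw, ww = ps[use] - x0, ys[use], w[use]
        # weighted local line through x0: equivalent kernel l_i
        s0, s1, s2 = ww.sum(), (ww * xw).sum(), (ww * xw**2).sum()
        denom = s0 * s2 - s1**2
        if denom <= 1e-14:
            l = ww / s0
        else:
            l = ww * (s2 - s1 * xw) / denom
        f = float(l @ yw)
        fit[j] = min(1.0, max(0.0, f))
        var[j] = max(fit[j] * (1.0 - fit[j]), 1e-12) * float((l**2).sum())
    half = 1.959963984540054 * np.sqrt(var)
    band_low = np.clip(fit - half, 0.0, 1.0)
    band_high = np.clip(fit + half, 0.0, 1.0)

    group_points = []
    if n_groups > 0:
        edges = np.quantile(p, np.linspace(0, 1, n_groups + 1))
        bins = np.clip(np.searchsorted(edges[1:-1], p, side="right"),
                       0, n_groups - 1)
        for g in range(n_groups):
            mask = bins == g
            if mask.any():
                group_points.append((float(p[mask].mean()),
                                     float(y[mask].mean())))
    return CalibrationCurve(grid=grid, observed=fit, band_low=band_low,
                            band_high=band_high, group_points=group_points)


# ---------------------------------------------------------------------------
# proportions
# ---------------------------------------------------------------------------

def wilson_ci(successes: int, n: int, level: float = 0.95
              ) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= successes <= n):
        raise ValueError("successes must be between 0 and n")
    ci = stats.binomtest(int(successes), int(n)).proportion_ci(
        confidence_level=level, method="wilson")
    return float(ci.low), float(ci.high)


# ---------------------------------------------------------------------------
# full panel
# ---------------------------------------------------------------------------

def compute_report(lp, outcomes, regime: str = "standard", *,
                   B: int = 2000, seed: int = 0,
                   boot_indices: np.ndarray | None = None
                   ) -> PerformanceReport:
    """Compute the full metric panel from a linear predictor and outcomes."""
    lp = np.asarray(lp, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    _check_two_classes(y)
    probs = expit(lp)
    ci = bootstrap_auc_ci(probs, y, B=B, seed=seed, indices=boot_indices)
    unrel = unreliability_test(lp, y)
    return PerformanceReport(
        regime=regime,
        n=len(y),
        prevalence=float(y.mean()),
        brier=brier(probs, y),
        auc=auc(probs, y),
        auc_ci=ci,
        citl=calibration_in_the_large(lp, y),
        citl_prob_scale=float(y.mean() - probs.mean()),
        slope=calibration_slope(lp, y),
        unreliability_chi2=unrel.chi2,
        unreliability_df=unrel.df,
        unreliability_p=unrel.p_value,
    )
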