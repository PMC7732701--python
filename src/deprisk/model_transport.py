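"""Transporting a fitted risk model to a new cohort: the three-regime panel.

* **standard** — the development model's coefficients are frozen and applied
  to the validation cohort as-is.
* **adjusted** — only the intercept is updated (recalibration-in-the-large):
  the ML offset-intercept on the validation data is added to the model
  intercept, leaving all slopes untouched.  By construction the adjusted
  model's calibration-in-the-large on the same data is zero, and its AUC is
  identical to the standard regime (the linear predictor is only shifted).
* **refitted** — every coefficient is re-estimated on the validation cohort
  (unpenalized by default; a penalty can be supplied, in which case the
  in-sample calibration slope will generally differ from 1).

All regimes on a dataset share one bootstrap resample stream so their AUC
confidence intervals are paired.  Age-window sensitivity analyses rerun the
sample selection and all three regimes per window.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .performance_metrics import (CalibrationCurve, PerformanceReport,
                                  compute_report, flexible_calibration_curve,
                                  make_bootstrap_indices)
from .risk_model import (LogisticRiskModel, encode_design, fit_penalized,
                         linear_predictor, predict_prob)
from .survey_coding import select_analysis_sample

__all__ = [
    "ValidationRun",
    "standard_external_validation",
    "adjust_intercept",
    "refit",
    "validate_all_regimes",
    "validation_table",
    "sensitivity_by_age",
]

REGIMES = ("standard", "adjusted", "refitted")


@dataclass
class ValidationRun:
    """One regime's outcome: the model used, its report, and its curve."""

    model_in: LogisticRiskModel
    regime: str
    model_out: LogisticRiskModel
    report: PerformanceReport
    curve: CalibrationCurve

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")


def _run(model_in: LogisticRiskModel, model_out: LogisticRiskModel,
         regime: str, rows, y, *, B: int, seed: int,
         boot_indices, span: float) -> ValidationRun:
    y = np.asarray(y, dtype=float)
    lp = linear_predictor(model_out, rows)
    report = compute_report(lp, y, regime=regime, B=B, seed=seed,
                            boot_indices=boot_indices)
    if len(y) >= 50:
        curve = flexible_calibration_curve(predict_prob(model_out, rows), y,
                                           span=span)
    else:  # too few records for the smoother; metrics still reported
        warnings.warn("fewer than 50 records: calibration curve omitted",
                      stacklevel=2)
        empty = np.empty(0)
        curve = CalibrationCurve(grid=empty, observed=empty, band_low=empty,
                                 band_high=empty)
    return ValidationRun(model_in=model_in, regime=regime,
                         model_out=model_out, report=report, curve=curve)


def standard_external_validation(model: LogisticRiskModel, rows, y, *,
                                 B: int = 2000, seed: int = 0,
                                 boot_indices=None, span: float = 0.75
                                 ) -> ValidationRun:
    """Apply the frozen model to the validation cohort and report."""
    return _run(model, model, "standard", rows, y, B=B, seed=seed,
                boot_indices=boot_indices, span=span)


def adjust_intercept(model: LogisticRiskModel, rows, y, *,
                     B: int = 2000, seed: int = 0,
                     boot_indices=None, span: float = 0.75) -> ValidationRun:
    """Recalibrate in the large: shift the intercept by the ML offset fit."""
    from .performance_metrics import calibration_in_the_large
    y = np.asarray(y, dtype=float)
    lp = linear_predictor(model, rows)
    a = calibration_in_the_large(lp, y)
    adjusted = model.replace(intercept=model.intercept + a,
                             meta={**model.meta,
                                   "intercept_adjustment": float(a)})
    return _run(model, adjusted, "adjusted", rows, y, B=B, seed=seed,
                boot_indices=boot_indices, span=span)


def refit(model: LogisticRiskModel, rows, y, penalty: float = 0.0, *,
          B: int = 2000, seed: int = 0, boot_indices=None,
          span: float = 0.75) -> ValidationRun:
    """Re-estimate all coefficients on the validation cohort (in-sample report)."""
    if isinstance(rows, pd.DataFrame):
        design = rows.loc[:, list(model.terms)]
    else:
        design = pd.DataFrame(np.asarray(rows, dtype=float),
                              columns=list(model.terms))
    refitted = fit_penalized(design, y, penalty=penalty,
                             meta={"refit_of": model.meta.get("label", "model")})
    return _run(model, refitted, "refitted", rows, y, B=B, seed=seed,
                boot_indices=boot_indices, span=span)


def validate_all_regimes(model: LogisticRiskModel, rows, y, *,
                         refit_penalty: float = 0.0, B: int = 2000,
                         seed: int = 0, span: float = 0.75
                         ) -> dict[str, ValidationRun]:
    """Run standard, adjusted and refitted regimes with paired bootstraps."""
    y = np.asarray(y, dtype=float)
    indices = make_bootstrap_indices(y, B, seed)
    return {
        "standard": standard_external_validation(
            model, rows, y, B=B, seed=seed, boot_indices=indices, span=span),
        "adjusted": adjust_intercept(
            model, rows, y, B=B, seed=seed, boot_indices=indices, span=span),
        "refitted": refit(
            model, rows, y, refit_penalty, B=B, seed=seed,
            boot_indices=indices, span=span),
    }


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def validation_table(runs: dict[str, ValidationRun] | Sequence[ValidationRun],
                     ndigits: int = 2) -> pd.DataFrame:
    """Metric-by-regime table (rows: Brier, AUC with CI, CITL, slope)."""
    if isinstance(runs, dict):
        runs = list(runs.values())
    if not runs:
        raise ValueError("need at least one validation run")
    cols = {}
    for run in runs:
        r = run.report.rounded(ndigits)
        citl = r["citl"] + 0.0  # avoid printing negative zero
        cols[run.regime] = {
            "Brier score": f"{r['brier']:.{ndigits}f}",
            "AUC (95% CI)": (f"{r['auc']:.{ndigits}f} "
                             f"({r['auc_ci'][0]:.{ndigits}f}, "
                             f"{r['auc_ci'][1]:.{ndigits}f})"),
            "Calibration-in-the-large": f"{citl:.{ndigits}f}",
            "Calibration slope": f"{r['slope']:.{ndigits}f}",
        }
    return pd.DataFrame(cols)


def save_validation_report(runs: dict[str, ValidationRun],
                           json_path: str | Path | None = None,
                           csv_path: str | Path | None = None,
                           ndigits: int = 2) -> dict:
    """Serialize the per-regime reports (full precision) plus the table."""
    payload = {regime: run.report.to_dict() for regime, run in runs.items()}
    if json_path is not None:
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
    if csv_path is not None:
        validation_table(runs, ndigits).to_csv(csv_path)
    return payload


# ---------------------------------------------------------------------------
# sensitivity analyses
# ---------------------------------------------------------------------------

def sensitivity_by_age(cohort: pd.DataFrame, model: LogisticRiskModel,
                       age_windows: Sequence[tuple[int, int]], *,
                       outcome: str = "depressed_followup",
                       refit_penalty: float = 0.0, B: int = 2000,
                       seed: int = 0, span: float = 0.75
                       ) -> dict[tuple[int, int], dict[str, ValidationRun]]:
    """Re-run selection and all three regimes per inclusive age window.

    Windows that select no one are skipped with a warning; windows with fewer
    than 50 records warn but still run.
    """
    out: dict[tuple[int, int], dict[str, ValidationRun]] = {}
    for lo, hi in age_windows:
        selected, flow = select_analysis_sample(cohort, lo, hi)
        if flow.final == 0:
            warnings.warn(f"age window ({lo}, {hi}) selects no records; "
                          "skipped", stacklevel=2)
            continue
        if flow.final < 50:
            warnings.warn(f"age window ({lo}, {hi}) selects only "
                          f"{flow.final} records", stacklevel=2)
        design = encode_design(selected)
        design = design.loc[:, list(model.terms)]
        y = selected[outcome].to_numpy(dtype=float)
        out[(lo, hi)] = validate_all_regimes(
            model, design, y, refit_penalty=refit_penalty, B=B, seed=seed,
            span=span)
    return out
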