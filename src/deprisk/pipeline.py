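"""End-to-end pipeline: simulate -> code -> fit -> validate -> report/plots.

The full run reproduces the study workflow on synthetic cohorts: a
development cohort is simulated and a penalized logistic model fitted on it
(penalty fixed or chosen by 10-fold cross-validated deviance); a raw
validation survey is simulated, coded and filtered through the selection
flow; the model is then evaluated under the standard, intercept-adjusted and
refitted regimes, producing the metric table, ROC and calibration figures,
and a selection-flow audit.  Every stage logs its record counts and the
seeds and penalty actually used, and the whole run is deterministic under a
fixed configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import yaml

from . import model_transport, risk_model, survey_coding, synthetic_cohort
from .performance_metrics import CalibrationCurve, auc

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_full_pipeline",
    "plot_roc",
    "plot_calibration",
]

log = logging.getLogger("deprisk")


@dataclass
class PipelineConfig:
    """One document controlling the whole run; YAML/JSON loadable."""

    out_dir: str = "deprisk_run"
    simulation_seed: int = 20
    bootstrap_seed: int = 21
    cv_seed: int = 22
    development_n: int = 10_000
    development_prevalence: float = synthetic_cohort.DEVELOPMENT_PREVALENCE
    validation_shrinkage_k: float = synthetic_cohort.VALIDATION_SHRINKAGE
    validation_prevalence: float = synthetic_cohort.VALIDATION_PREVALENCE
    penalty: float | str = "cv"          # number, or "cv" for CV selection
    refit_penalty: float = 0.0
    bootstrap_B: int = 2000
    smoother_span: float = 0.75
    age_window: tuple[int, int] = (14, 16)
    sensitivity_windows: tuple[tuple[int, int], ...] = ((15, 15), (11, 17))
    report_ndigits: int = 2

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        cfg = cls(**data)
        cfg.age_window = tuple(cfg.age_window)
        cfg.sensitivity_windows = tuple(
            tuple(w) for w in cfg.sensitivity_windows)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_window"] = list(self.age_window)
        d["sensitivity_windows"] = [list(w) for w in self.sensitivity_windows]
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    development_model: risk_model.LogisticRiskModel
    runs: dict
    selection_flow: survey_coding.SelectionFlow
    table: object
    sensitivity: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def _roc_points(labels: np.ndarray, scores: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps[distinct] / max(fps[-1], 1)]
    return fpr, tpr


def plot_roc(labels, scores, path: str | Path, title: str = "ROC") -> Path:
    """ROC curve: true positive rate vs false positive rate, chance diagonal."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(labels) == 0:
        raise ValueError("empty inputs for ROC plot")
    fpr, tpr = _roc_points(labels, scores)
    a = auc(scores, labels)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], color="gray", lw=1, label="chance")
    ax.plot(fpr, tpr, color="black", lw=1.5, label=f"AUC = {a:.2f}")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_calibration(curve: CalibrationCurve, path: str | Path,
                     title: str = "Calibration") -> Path:
    """Calibration plot: predictions on x, smoothed observed proportion on y."""
    grid = np.asarray(curve.grid)
    if grid.size == 0:
        raise ValueError("empty calibration curve")
    fig, ax = plt.subplots(figsize=(5, 5))
    lim = max(float(grid.max()), float(np.max(curve.band_high)))
    ax.plot([0, lim], [0, lim], color="lightgray", lw=1.5, label="ideal")
    ax.plot(grid, curve.observed, color="black", lw=1.5, label="flexible")
    ax.plot(grid, curve.band_low, color="black", lw=0.8, ls="--")
    ax.plot(grid, curve.band_high, color="black", lw=0.8, ls="--")
    if curve.group_points:
        px, py = zip(*curve.group_points)
        ax.plot(px, py, "o", ms=4, color="tab:blue", label="deciles")
    ax.set_xlabel("Predicted probability")
    ax.set_ylabel("Observed proportion")
    ax.set_title(title)
    ax.legend(loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_full_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run simulate -> code -> fit -> three regimes -> report and figures."""
    cfg = config or PipelineConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    seeds = np.random.SeedSequence(cfg.simulation_seed).spawn(2)
    dev_seed = int(seeds[0].generate_state(1)[0] % 2**31)
    val_seed = int(seeds[1].generate_state(1)[0] % 2**31)
    log.info("pipeline start: out_dir=%s sim_seed=%d (dev=%d val=%d) "
             "bootstrap_seed=%d", out, cfg.simulation_seed, dev_seed,
             val_seed, cfg.bootstrap_seed)

    # -- development cohort and model fit
    dev = synthetic_cohort.generate_development_cohort(
        synthetic_cohort.development_spec(
            n=cfg.development_n, seed=dev_seed,
            target_prevalence=cfg.development_prevalence))
    dev_design = risk_model.encode_design(dev.data)
    dev_y = dev.data["depressed_followup"].to_numpy(dtype=float)
    log.info("development cohort: n=%d events=%d", len(dev_y),
             int(dev_y.sum()))
    if cfg.penalty == "cv":
        penalty, cv_table = risk_model.select_penalty_cv(
            dev_design, dev_y, seed=cfg.cv_seed)
        log.info("cross-validated penalty: %.4g (cv_seed=%d)", penalty,
                 cfg.cv_seed)
        cv_table.to_csv(out / "cv_penalty.csv", index=False)
        paths["cv_penalty"] = out / "cv_penalty.csv"
    else:
        penalty = float(cfg.penalty)
        log.info("fixed penalty: %.4g", penalty)
    model = risk_model.fit_penalized(dev_design, dev_y, penalty,
                                     meta={"label": "development"})
    risk_model.save_model(model, out / "model.json")
    paths["model"] = out / "model.json"
    survey_coding.write_cohort(dev.data, out / "development_cohort.csv")
    paths["development_cohort"] = out / "development_cohort.csv"

    # -- validation survey: raw records -> coding -> selection
    raw = synthetic_cohort.generate_raw_survey(seed=val_seed)
    survey_coding.write_cohort(raw.raw, out / "validation_raw.csv")
    paths["validation_raw"] = out / "validation_raw.csv"
    coded, audit = survey_coding.code_cohort(raw.raw)
    log.info("coding: %d records in, %d coded, %d dropped for missingness",
             audit.n_input, audit.n_coded, audit.n_missing_excluded)
    selected, flow = survey_coding.select_analysis_sample(
        coded, *cfg.age_window)
    flow.to_json(out / "selection_flow.json")
    paths["selection_flow"] = out / "selection_flow.json"
    log.info("selection flow: %d -> %d in age window -> %d final "
             "(excluded %d baseline-depressed)", flow.followed_up,
             flow.in_age_range, flow.final, flow.baseline_depressed_excluded)
    survey_coding.write_cohort(selected, out / "validation_coded.csv")
    paths["validation_coded"] = out / "validation_coded.csv"

    # -- three regimes
    design = risk_model.encode_design(selected).loc[:, list(model.terms)]
    y = selected["depressed_followup"].to_numpy(dtype=float)
    runs = model_transport.validate_all_regimes(
        model, design, y, refit_penalty=cfg.refit_penalty,
        B=cfg.bootstrap_B, seed=cfg.bootstrap_seed, span=cfg.smoother_span)
    model_transport.save_validation_report(
        runs, out / "report.json", out / "report.csv",
        ndigits=cfg.report_ndigits)
    paths["report_json"] = out / "report.json"
    paths["report_csv"] = out / "report.csv"
    table = model_transport.validation_table(runs, cfg.report_ndigits)
    for regime, run in runs.items():
        risk_model.save_model(run.model_out, out / f"model_{regime}.json")
        scores = risk_model.predict_prob(run.model_out, design)
        paths[f"roc_{regime}"] = plot_roc(
            y, scores, out / f"roc_{regime}.png",
            title=f"ROC - {regime} validation")
        paths[f"calibration_{regime}"] = plot_calibration(
            run.curve, out / f"calibration_{regime}.png",
            title=f"Calibration - {regime} validation")
        log.info("%s regime: AUC=%.3f brier=%.3f citl=%.3f slope=%.3f",
                 regime, run.report.auc, run.report.brier, run.report.citl,
                 run.report.slope)

    # -- age-window sensitivity runs
    sensitivity: dict = {}
    if cfg.sensitivity_windows:
        sens_runs = model_transport.sensitivity_by_age(
            coded, model, cfg.sensitivity_windows,
            refit_penalty=cfg.refit_penalty, B=cfg.bootstrap_B,
            seed=cfg.bootstrap_seed, span=cfg.smoother_span)
        sens_payload = {}
        for window, wruns in sens_runs.items():
            key = f"{window[0]}-{window[1]}"
            sens_payload[key] = {
                "sensitivity_run": True,
                "reports": {reg: r.report.to_dict()
                            for reg, r in wruns.items()},
            }
            log.info("sensitivity window %s: n=%d standard AUC=%.3f", key,
                     wruns["standard"].report.n,
                     wruns["standard"].report.auc)
        (out / "sensitivity.json").write_text(
            json.dumps(sens_payload, indent=2) + "\n")
        paths["sensitivity"] = out / "sensitivity.json"
        sensitivity = sens_runs

    (out / "config.json").write_text(
        json.dumps(cfg.to_dict(), indent=2) + "\n")
    paths["config"] = out / "config.json"
    return PipelineResult(config=cfg, development_model=model, runs=runs,
                          selection_flow=flow, table=table,
                          sensitivity=sensitivity, paths=paths)
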