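"""Synthetic two-cohort generator for the validation pipeline.

Emulates the study conditions end to end without any external data:

* a **development cohort** with low depression prevalence (3.1%) from which
  the risk model is fitted, optionally carrying extra predictors that are
  "unavailable" in the validation setting to exercise predictor-subset
  rebuilds;
* a **validation cohort** with the documented predictor marginals of the
  school sample (male 50.6%, school failure 25.8%, fights 3.9%, drug use
  6.0%, social isolation 4.4%, ran away 2.3%, maltreatment probable 18.4% /
  severe 6.7%) and follow-up prevalence 11.8%, with optional coefficient
  shrinkage and intercept drift to inject transportable miscalibration;
* a **raw survey fixture** of item-level records whose selection flow is
  exact by construction: 3171 followed up -> 2321 inside the 14-16 age
  window -> 393 excluded as baseline-depressed -> 1928 analysed
  (976 male / 952 female).

Outcomes are Bernoulli draws from ``logit^-1(c + k * x.beta)`` where ``c``
is solved (Monte-Carlo expectation + Brent root) so the population mean
probability hits the target prevalence.  Predictors are independent by
default (only marginals are documented); a Gaussian-copula correlation hook
exists for stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .risk_model import DESIGN_TERMS, LogisticRiskModel, encode_design
from .survey_coding import SelectionFlow

__all__ = [
    "DEFAULT_MARGINALS",
    "DEFAULT_COEFFICIENTS",
    "CohortSpec",
    "GeneratedCohort",
    "RawSurveyFlowSpec",
    "RawSurveyResult",
    "development_spec",
    "validation_spec",
    "generate_coded_cohort",
    "generate_development_cohort",
    "generate_validation_cohort",
    "generate_raw_survey",
    "solve_intercept_for_prevalence",
    "inject_miscalibration",
]

#: documented predictor marginals of the validation school sample
DEFAULT_MARGINALS: dict[str, float] = {
    "sex_female": 1.0 - 0.506,          # 50.6% male
    "maltreatment_probable": 0.184,
    "maltreatment_severe": 0.067,
    "school_failure": 0.258,
    "social_isolation": 0.044,
    "fights": 0.039,
    "ran_away": 0.023,
    "drug_use": 0.060,
}

#: generating log-odds coefficients, fixed package defaults (design terms)
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "sex_female": 0.55,
    "maltreatment[probable]": 0.45,
    "maltreatment[severe]": 0.90,
    "school_failure": 0.40,
    "social_isolation": 0.65,
    "fights": 0.55,
    "ran_away": 0.75,
    "drug_use": 0.50,
}

DEVELOPMENT_PREVALENCE = 0.031
VALIDATION_PREVALENCE = 0.118
#: default shrinkage injected into the validation cohort's effective
#: coefficients, producing the over-fitted transport setting (slope < 1)
VALIDATION_SHRINKAGE = 0.64


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated coded cohort."""

    n: int
    predictor_marginals: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS))
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    target_prevalence: float | None = VALIDATION_PREVALENCE
    base_intercept: float | None = None
    shrinkage_k: float = 1.0
    intercept_drift: float = 0.0
    age_distribution: Mapping[int, float] = field(
        default_factory=lambda: {14: 0.32, 15: 0.41, 16: 0.27})
    n_extra_predictors: int = 0
    extra_marginal: float = 0.2
    extra_coefficient: float = 0.3
    correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.shrinkage_k <= 0:
            raise ValueError("shrinkage_k must be positive")
        for name, p in self.predictor_marginals.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"marginal {name}={p} outside (0, 1)")
        if self.target_prevalence is not None \
                and not (0.0 < self.target_prevalence < 1.0):
            raise ValueError("target_prevalence must be in (0, 1)")
        if self.target_prevalence is None and self.base_intercept is None:
            raise ValueError(
                "either target_prevalence or base_intercept is required")


@dataclass
class GeneratedCohort:
    """A coded cohort together with its effective generating model."""

    data: pd.DataFrame
    generating_model: LogisticRiskModel
    spec: CohortSpec


def development_spec(n: int = 10_000, seed: int = 0, **kwargs) -> CohortSpec:
    """Development-cohort defaults: prevalence 3.1%, no miscalibration."""
    kwargs.setdefault("target_prevalence", DEVELOPMENT_PREVALENCE)
    kwargs.setdefault("shrinkage_k", 1.0)
    return CohortSpec(n=n, seed=seed, **kwargs)


def validation_spec(n: int = 1928, seed: int = 0, **kwargs) -> CohortSpec:
    """Validation-cohort defaults: prevalence 11.8%, shrinkage 0.64."""
    kwargs.setdefault("target_prevalence", VALIDATION_PREVALENCE)
    kwargs.setdefault("shrinkage_k", VALIDATION_SHRINKAGE)
    return CohortSpec(n=n, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# predictor and intercept machinery
# ---------------------------------------------------------------------------

def _draw_predictors(n: int, marginals: Mapping[str, float],
                     rng: np.random.Generator,
                     correlation: np.ndarray | None = None) -> pd.DataFrame:
    """Draw the seven coded predictors at the stated marginals.

    With a correlation matrix (7x7, predictor order as below), latent
    Gaussians are thresholded (copula); maltreatment uses one latent with two
    thresholds for its ordered levels.
    """
    names = ["sex_female", "maltreatment", "school_failure",
             "social_isolation", "fights", "ran_away", "drug_use"]
    p_sev = marginals["maltreatment_severe"]
    p_prob = marginals["maltreatment_probable"]
    if correlation is None:
        u = rng.random((n, 7))
    else:
        corr = np.asarray(correlation, dtype=float)
        if corr.shape != (7, 7):
            raise ValueError("correlation must be 7x7 in predictor order "
                             f"{names}")
        z = rng.multivariate_normal(np.zeros(7), corr, size=n,
                                    method="cholesky")
        u = norm.cdf(z)
    out = pd.DataFrame(index=range(n))
    binary = {"sex_female": marginals["sex_female"],
              "school_failure": marginals["school_failure"],
              "social_isolation": marginals["social_isolation"],
              "fights": marginals["fights"],
              "ran_away": marginals["ran_away"],
              "drug_use": marginals["drug_use"]}
    for j, name in enumerate(names):
        if name == "maltreatment":
            col = np.where(u[:, j] < p_sev, "severe",
                           np.where(u[:, j] < p_sev + p_prob,
                                    "probable", "none"))
            out[name] = col
        else:
            out[name] = (u[:, j] < binary[name]).astype(int)
    return out


def solve_intercept_for_prevalence(coefficients: Mapping[str, float],
                                   marginals: Mapping[str, float],
                                   target: float, *, n_mc: int = 200_000,
                                   seed: int = 0, tol: float = 1e-6) -> float:
    """Intercept c with E[logit^-1(c + x.beta)] = target over the predictors.

    The expectation is Monte-Carlo (one fixed draw of ``n_mc`` predictor
    vectors, so the objective is smooth and monotone in c) and the root is
    bracketed on [-30, 30] and solved to ``tol``.
    """
    if not (0.0 < target < 1.0):
        raise ValueError("target prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    X = _mc_design(marginals, n_mc, rng)
    beta = np.array([coefficients.get(t, 0.0) for t in DESIGN_TERMS])
    xb = X @ beta

    def gap(c: float) -> float:
        return float(expit(c + xb).mean()) - target

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"target prevalence {target} unachievable; attainable range is "
            f"({gap(lo) + target:.6f}, {gap(hi) + target:.6f})")
    return float(brentq(gap, lo, hi, xtol=tol))


def _mc_design(marginals: Mapping[str, float], n: int,
               rng: np.random.Generator) -> np.ndarray:
    preds = _draw_predictors(n, marginals, rng)
    return encode_design(preds).to_numpy(dtype=float)


def inject_miscalibration(model: LogisticRiskModel, k: float,
                          drift: float) -> LogisticRiskModel:
    """Scale all slopes by ``k`` and shift the intercept by ``drift``."""
    if k <= 0:
        raise ValueError("k must be positive")
    return model.replace(coefficients=model.coefficients * k,
                         intercept=model.intercept + drift,
                         meta={**model.meta, "injected_shrinkage": k,
                               "injected_drift": drift})


# ---------------------------------------------------------------------------
# coded cohorts
# ---------------------------------------------------------------------------

def generate_coded_cohort(spec: CohortSpec) -> GeneratedCohort:
    """Draw one coded cohort (predictors + follow-up outcome) from ``spec``.

    The outcome model applies ``shrinkage_k`` to the spec coefficients.  When
    ``target_prevalence`` is set, the intercept is solved so the mean outcome
    probability equals it (any ``intercept_drift`` is then absorbed by the
    solve); with an explicit ``base_intercept`` the intercept is
    ``base_intercept + intercept_drift`` and the realized prevalence floats.
    """
    rng = np.random.default_rng(spec.seed)
    preds = _draw_predictors(spec.n, spec.predictor_marginals, rng,
                             spec.correlation)
    design = encode_design(preds)
    terms = list(DESIGN_TERMS)
    coef_map = {t: spec.shrinkage_k * spec.coefficients.get(t, 0.0)
                for t in DESIGN_TERMS}
    if spec.n_extra_predictors:
        for i in range(spec.n_extra_predictors):
            name = f"extra_{i + 1}"
            preds[name] = (rng.random(spec.n) < spec.extra_marginal).astype(int)
            design[name] = preds[name]
            terms.append(name)
            coef_map[name] = spec.shrinkage_k * spec.extra_coefficient

    if spec.target_prevalence is not None:
        intercept = _solve_intercept_full(coef_map, spec)
    else:
        intercept = float(spec.base_intercept) + float(spec.intercept_drift)

    beta = np.array([coef_map[t] for t in terms])
    model = LogisticRiskModel(
        intercept=intercept, terms=tuple(terms), coefficients=beta,
        meta={"generating": True, "seed": spec.seed,
              "shrinkage_k": spec.shrinkage_k,
              "intercept_drift": spec.intercept_drift})
    lp = intercept + design.to_numpy(dtype=float) @ beta
    y = (rng.random(spec.n) < expit(lp)).astype(int)

    ages = np.array(sorted(spec.age_distribution))
    probs = np.array([spec.age_distribution[a] for a in ages], dtype=float)
    data = preds.copy()
    data.insert(0, "id", [f"C{j:06d}" for j in range(spec.n)])
    data.insert(1, "age_baseline",
                rng.choice(ages, size=spec.n, p=probs / probs.sum()))
    data["depressed_baseline"] = 0
    data["depressed_followup"] = y
    return GeneratedCohort(data=data, generating_model=model, spec=spec)


def _solve_intercept_full(coef_map: Mapping[str, float],
                          spec: CohortSpec) -> float:
    """Solve the intercept including any extra predictors."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 917]))
    n_mc = 200_000
    X = _mc_design(spec.predictor_marginals, n_mc, rng)
    xb = X @ np.array([coef_map[t] for t in DESIGN_TERMS])
    for i in range(spec.n_extra_predictors):
        extra = (rng.random(n_mc) < spec.extra_marginal).astype(float)
        xb = xb + coef_map[f"extra_{i + 1}"] * extra

    def gap(c: float) -> float:
        return float(expit(c + xb).mean()) - spec.target_prevalence

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"target prevalence {spec.target_prevalence} unachievable")
    return float(brentq(gap, lo, hi, xtol=1e-6))


def generate_development_cohort(spec: CohortSpec | None = None,
                                seed: int | None = None,
                                **kwargs) -> GeneratedCohort:
    """Development cohort at 3.1% prevalence (optionally extra predictors)."""
    if spec is None:
        spec = development_spec(seed=0 if seed is None else seed, **kwargs)
    elif seed is not None:
        spec = replace(spec, seed=seed)
    return generate_coded_cohort(spec)


def generate_validation_cohort(spec: CohortSpec | None = None,
                               seed: int | None = None,
                               **kwargs) -> GeneratedCohort:
    """Validation cohort at 11.8% prevalence with default shrinkage 0.64."""
    if spec is None:
        spec = validation_spec(seed=0 if seed is None else seed, **kwargs)
    elif seed is not None:
        spec = replace(spec, seed=seed)
    return generate_coded_cohort(spec)


# ---------------------------------------------------------------------------
# raw survey fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawSurveyFlowSpec:
    """Named fixture configuration with exact selection-flow counts."""

    n_followed_up: int = 3171
    n_in_age_range: int = 2321
    n_baseline_depressed: int = 393
    n_final_male: int = 976
    n_final_female: int = 952
    age_min: int = 14
    age_max: int = 16
    target_prevalence: float = VALIDATION_PREVALENCE
    shrinkage_k: float = VALIDATION_SHRINKAGE
    out_of_range_depression_rate: float = 0.17

    def __post_init__(self) -> None:
        final = self.n_in_age_range - self.n_baseline_depressed
        if final != self.n_final_male + self.n_final_female:
            raise ValueError("final sample must equal male + female counts")
        if self.n_in_age_range > self.n_followed_up:
            raise ValueError("in-age count exceeds cohort size")

    @property
    def n_final(self) -> int:
        return self.n_in_age_range - self.n_baseline_depressed

    def expected_flow(self) -> SelectionFlow:
        return SelectionFlow(
            followed_up=self.n_followed_up,
            in_age_range=self.n_in_age_range,
            baseline_depressed_excluded=self.n_baseline_depressed,
            final=self.n_final,
        )


@dataclass
class RawSurveyResult:
    raw: pd.DataFrame
    coded_reference: pd.DataFrame
    expected_flow: SelectionFlow
    generating_model: LogisticRiskModel


def _symptom_matrix(rng: np.random.Generator,
                    depressed: np.ndarray) -> np.ndarray:
    """Draw 9-item symptom vectors consistent with each depression status."""
    n = len(depressed)
    items = np.zeros((n, 9), dtype=int)
    for i in range(n):
        if depressed[i]:
            m = int(rng.integers(5, 10))
            core = int(rng.integers(0, 2))
            items[i, core] = 1
            pool = np.delete(np.arange(9), core)
            items[i, rng.choice(pool, size=m - 1, replace=False)] = 1
        else:
            # mostly sub-threshold counts; occasionally >=5 without a core
            # symptom, which the rule also classifies as not depressed
            if rng.random() < 0.03:
                m = int(rng.integers(5, 8))
                items[i, rng.choice(np.arange(2, 9), size=m, replace=False)] = 1
            else:
                m = int(rng.integers(0, 5))
                if m:
                    items[i, rng.choice(9, size=m, replace=False)] = 1
    return items


def _decode_maltreatment(rng: np.random.Generator,
                         levels: np.ndarray) -> pd.DataFrame:
    """Raw (dv, abuse, lives-with-parent) combos coding back to each level."""
    n = len(levels)
    dv = np.full(n, "no", dtype=object)
    abuse = np.full(n, "no", dtype=object)
    lives = np.full(n, "yes", dtype=object)
    sev = levels == "severe"
    if sev.any():
        pick_dv = rng.random(sev.sum()) < 0.5
        dv[np.flatnonzero(sev)[pick_dv]] = "a_lot"
        abuse[np.flatnonzero(sev)[~pick_dv]] = "a_lot"
        other = rng.choice(["no", "a_little", "a_lot"], size=sev.sum(),
                           p=[0.5, 0.35, 0.15])
        idx = np.flatnonzero(sev)
        abuse[idx[pick_dv]] = other[pick_dv]
        dv[idx[~pick_dv]] = np.where(other[~pick_dv] == "a_lot",
                                     "a_little", other[~pick_dv])
        lives[idx] = rng.choice(["yes", "no"], size=sev.sum(), p=[0.85, 0.15])
    prob = levels == "probable"
    if prob.any():
        idx = np.flatnonzero(prob)
        both_little = rng.random(prob.sum()) < 0.5
        dv[idx[both_little]] = "a_little"
        abuse[idx[both_little]] = "a_little"
        # neglect route: no biological parent, exposures below "a lot"
        neg = idx[~both_little]
        lives[neg] = "no"
        dv[neg] = rng.choice(["no", "a_little"], size=len(neg), p=[0.7, 0.3])
        abuse[neg] = rng.choice(["no", "a_little"], size=len(neg),
                                p=[0.7, 0.3])
        # avoid accidental both-a_little on the neglect route upgrading
        # nothing (still probable), fine either way
    return pd.DataFrame({"domestic_violence": dv, "physical_abuse": abuse,
                         "lives_with_biological_parent": lives})


def _decode_substances(rng: np.random.Generator,
                       drug_use: np.ndarray) -> pd.DataFrame:
    n = len(drug_use)
    alcohol = np.full(n, "none", dtype=object)
    cig = np.full(n, "none", dtype=object)
    mar = np.full(n, "none", dtype=object)
    users = np.flatnonzero(drug_use == 1)
    if len(users):
        alcohol[users] = rng.choice(FREQS, size=len(users), p=[0.25, 0.6, 0.15])
        cig[users] = rng.choice(FREQS, size=len(users), p=[0.7, 0.22, 0.08])
        mar[users] = rng.choice(FREQS, size=len(users), p=[0.85, 0.11, 0.04])
        allnone = users[(alcohol[users] == "none") & (cig[users] == "none")
                        & (mar[users] == "none")]
        alcohol[allnone] = "a_little"
    return pd.DataFrame({"alcohol_freq": alcohol, "cigarette_freq": cig,
                         "marijuana_freq": mar})


FREQS = ["none", "a_little", "a_lot"]


def generate_raw_survey(flow: RawSurveyFlowSpec | None = None,
                        seed: int = 0, *,
                        marginals: Mapping[str, float] | None = None,
                        coefficients: Mapping[str, float] | None = None
                        ) -> RawSurveyResult:
    """Emit item-level records reproducing the fixture selection flow exactly.

    Counts (followed-up, in-age, baseline-depressed, final males/females) are
    assigned deterministically and the row order is then shuffled by ``seed``;
    all other fields are random but reproducible.  Re-coding the raw records
    recovers the returned coded reference table exactly.
    """
    flow = flow or RawSurveyFlowSpec()
    marginals = dict(marginals or DEFAULT_MARGINALS)
    coefficients = dict(coefficients or DEFAULT_COEFFICIENTS)
    rng = np.random.default_rng(seed)
    n = flow.n_followed_up

    in_age = np.zeros(n, dtype=bool)
    in_age[:flow.n_in_age_range] = True
    base_dep = np.zeros(n, dtype=bool)
    base_dep[:flow.n_baseline_depressed] = True  # all inside the age window
    out_of_range = ~in_age
    base_dep[out_of_range] = (rng.random(out_of_range.sum())
                              < flow.out_of_range_depression_rate)

    sex = np.empty(n, dtype=object)
    final = in_age & ~base_dep
    final_idx = np.flatnonzero(final)
    assert len(final_idx) == flow.n_final
    sex[final_idx[:flow.n_final_male]] = "male"
    sex[final_idx[flow.n_final_male:]] = "female"
    rest = ~final
    sex[rest] = rng.choice(["male", "female"], size=rest.sum())

    ages = np.empty(n, dtype=int)
    window = np.arange(flow.age_min, flow.age_max + 1)
    ages[in_age] = rng.choice(window, size=in_age.sum())
    low = np.arange(11, flow.age_min)
    high = np.arange(flow.age_max + 1, 19)
    outside = np.concatenate([low, high])
    weights = np.where(np.isin(outside, [flow.age_min - 1, flow.age_max + 1]),
                       3.0, 1.0)
    ages[out_of_range] = rng.choice(outside, size=out_of_range.sum(),
                                    p=weights / weights.sum())

    preds = _draw_predictors(n, marginals, rng)
    preds["sex_female"] = (sex == "female").astype(int)  # honour exact counts
    design = encode_design(preds)
    beta = np.array([flow.shrinkage_k * coefficients.get(t, 0.0)
                     for t in DESIGN_TERMS])
    intercept = solve_intercept_for_prevalence(
        {t: flow.shrinkage_k * coefficients.get(t, 0.0) for t in DESIGN_TERMS},
        marginals, flow.target_prevalence,
        seed=int(rng.integers(2**31)))
    lp = intercept + design.to_numpy(dtype=float) @ beta
    fup_dep = rng.random(n) < expit(lp)

    base_items = _symptom_matrix(rng, base_dep)
    fup_items = _symptom_matrix(rng, fup_dep.astype(int))

    malt_raw = _decode_maltreatment(rng, preds["maltreatment"].to_numpy())
    subst_raw = _decode_substances(rng, preds["drug_use"].to_numpy())

    friends = np.where(preds["social_isolation"] == 1, 0,
                       1 + rng.poisson(2.5, size=n))
    started = np.where(preds["fights"] == 1, "yes",
                       rng.choice(["yes", "no"], size=n, p=[0.15, 0.85]))
    hurt = np.where(preds["fights"] == 1, "yes", "no")

    raw = pd.DataFrame({
        "age_baseline": ages,
        "sex": sex,
        "school_year": "SS1",
    })
    for i in range(9):
        raw[f"dep_base_{i}"] = base_items[:, i]
    for i in range(9):
        raw[f"dep_fup_{i}"] = fup_items[:, i]
    raw["close_friends"] = friends
    raw["repeated_class"] = np.where(preds["school_failure"] == 1, "yes", "no")
    raw["started_fight"] = started
    raw["hurt_someone"] = hurt
    raw["ran_away_many_days"] = np.where(preds["ran_away"] == 1, "yes", "no")
    raw = pd.concat([raw, subst_raw, malt_raw], axis=1)

    coded = preds.copy()
    coded["age_baseline"] = ages
    coded["depressed_baseline"] = base_dep.astype(int)
    coded["depressed_followup"] = fup_dep.astype(int)

    perm = rng.permutation(n)
    raw = raw.iloc[perm].reset_index(drop=True)
    coded = coded.iloc[perm].reset_index(drop=True)
    ids = [f"S{j:05d}" for j in range(n)]
    raw.insert(0, "id", ids)
    coded.insert(0, "id", ids)
    coded = coded[["id", "age_baseline", "sex_female", "maltreatment",
                   "school_failure", "social_isolation", "fights", "ran_away",
                   "drug_use", "depressed_baseline", "depressed_followup"]]

    model = LogisticRiskModel(
        intercept=intercept, terms=DESIGN_TERMS, coefficients=beta,
        meta={"generating": True, "seed": seed,
              "shrinkage_k": flow.shrinkage_k})
    return RawSurveyResult(raw=raw, coded_reference=coded,
                           expected_flow=flow.expected_flow(),
                           generating_model=model)
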