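"""Survey-item coding: depression status, harmonized predictors, sample selection.

The raw instrument is a self-completed adolescent school survey administered at
two waves.  Each wave carries nine binary DSM-IV major-depression symptom items
(item 0 = depressed mood, item 1 = anhedonia); a respondent is classified as
depressed when five or more items are endorsed and at least one of the two core
symptoms is among them.  The remaining survey items (friendship counts, school
repetition, fighting, running away, substance-use frequency, family-violence
exposure, household composition) are collapsed into the seven harmonized
predictors of the risk model:

====================  =========================================================
predictor             coding rule
====================  =========================================================
sex_female            1 if biological sex is female
maltreatment          ``severe`` if "a lot" on domestic violence or physical
                      abuse; else ``probable`` if "a little" on both, or not
                      living with any biological parent; else ``none``
school_failure        1 if ever repeated a class
social_isolation      1 if zero close friends
fights                1 if both started a fight and hurt someone on purpose
ran_away              1 if ever ran away from home for many days
drug_use              1 if any of alcohol/cigarettes/marijuana used at all
====================  =========================================================

Analysis-sample selection mirrors the study flow: keep respondents inside the
baseline age window, then drop those already depressed at baseline, recording
counts at every stage in a :class:`SelectionFlow` audit.

Records with a missing value in any coding input are excluded from the coded
output (complete-case) and counted in the :class:`CodingAudit`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MALTREATMENT_LEVELS",
    "FREQ_LEVELS",
    "EXPOSURE_LEVELS",
    "SEX_LEVELS",
    "YESNO_LEVELS",
    "SCHOOL_YEARS",
    "PREDICTOR_COLUMNS",
    "RAW_COLUMNS",
    "DepressionStatus",
    "PredictorVector",
    "RawStudentRecord",
    "SelectionFlow",
    "CodingAudit",
    "classify_depression",
    "derive_maltreatment",
    "derive_drug_use",
    "derive_social_isolation",
    "derive_fights",
    "derive_simple_flags",
    "code_record",
    "code_cohort",
    "select_analysis_sample",
    "read_raw_cohort",
    "read_coded_cohort",
    "write_cohort",
]

MALTREATMENT_LEVELS = ("none", "probable", "severe")
FREQ_LEVELS = ("none", "a_little", "a_lot")          # substance-use frequency
EXPOSURE_LEVELS = ("no", "a_little", "a_lot")        # violence/abuse exposure
SEX_LEVELS = ("male", "female")
YESNO_LEVELS = ("yes", "no")
SCHOOL_YEARS = ("SS1", "SS2", "SS3")

N_SYMPTOM_ITEMS = 9
SYMPTOM_THRESHOLD = 5
AGE_RANGE = (11, 21)

#: columns of a coded cohort table
PREDICTOR_COLUMNS = (
    "sex_female",
    "maltreatment",
    "school_failure",
    "social_isolation",
    "fights",
    "ran_away",
    "drug_use",
)

_BASE_ITEMS = tuple(f"dep_base_{i}" for i in range(N_SYMPTOM_ITEMS))
_FUP_ITEMS = tuple(f"dep_fup_{i}" for i in range(N_SYMPTOM_ITEMS))

#: column dictionary for a raw cohort CSV
RAW_COLUMNS = (
    ("id", "opaque respondent identifier"),
    ("age_baseline", "integer age in years at baseline (11-21)"),
    ("sex", "male|female"),
    ("school_year", "SS1|SS2|SS3 at baseline"),
    *[(c, "baseline symptom item, 0/1") for c in _BASE_ITEMS],
    *[(c, "follow-up symptom item, 0/1") for c in _FUP_ITEMS],
    ("close_friends", "non-negative integer count of close friends"),
    ("repeated_class", "yes|no"),
    ("started_fight", "yes|no"),
    ("hurt_someone", "yes|no"),
    ("ran_away_many_days", "yes|no"),
    ("alcohol_freq", "none|a_little|a_lot"),
    ("cigarette_freq", "none|a_little|a_lot"),
    ("marijuana_freq", "none|a_little|a_lot"),
    ("domestic_violence", "no|a_little|a_lot"),
    ("physical_abuse", "no|a_little|a_lot"),
    ("lives_with_biological_parent", "yes|no"),
)


class CodingError(ValueError):
    """Raised when a raw survey value is outside its documented level set."""


def _check_level(name: str, value, levels: Sequence) -> None:
    if value not in levels:
        raise CodingError(f"{name}={value!r} is not one of {tuple(levels)}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepressionStatus:
    """Outcome of the symptom-count depression rule for one wave."""

    positive_item_count: int
    core_symptom_present: bool
    depressed: bool


@dataclass(frozen=True)
class PredictorVector:
    """The seven harmonized predictors for one respondent."""

    sex_female: int
    maltreatment: str
    school_failure: int
    social_isolation: int
    fights: int
    ran_away: int
    drug_use: int

    def __post_init__(self) -> None:
        _check_level("maltreatment", self.maltreatment, MALTREATMENT_LEVELS)
        for name in ("sex_female", "school_failure", "social_isolation",
                     "fights", "ran_away", "drug_use"):
            _check_level(name, getattr(self, name), (0, 1))


@dataclass(frozen=True)
class RawStudentRecord:
    """One respondent's raw item-level answers across both waves."""

    id: str
    age_baseline: int
    sex: str
    school_year: str
    depression_items_baseline: tuple
    depression_items_followup: tuple
    close_friends: int
    repeated_class: str
    started_fight: str
    hurt_someone: str
    ran_away_many_days: str
    alcohol_freq: str
    cigarette_freq: str
    marijuana_freq: str
    domestic_violence: str
    physical_abuse: str
    lives_with_biological_parent: str

    def __post_init__(self) -> None:
        if not (AGE_RANGE[0] <= self.age_baseline <= AGE_RANGE[1]):
            raise CodingError(
                f"age_baseline={self.age_baseline} outside {AGE_RANGE}")
        _check_level("sex", self.sex, SEX_LEVELS)
        _check_level("school_year", self.school_year, SCHOOL_YEARS)
        for wave, items in (("baseline", self.depression_items_baseline),
                            ("followup", self.depression_items_followup)):
            _validate_items(items, f"depression_items_{wave}")
        if self.close_friends < 0:
            raise CodingError(f"close_friends={self.close_friends} is negative")
        for name in ("repeated_class", "started_fight", "hurt_someone",
                     "ran_away_many_days", "lives_with_biological_parent"):
            _check_level(name, getattr(self, name), YESNO_LEVELS)
        for name in ("alcohol_freq", "cigarette_freq", "marijuana_freq"):
            _check_level(name, getattr(self, name), FREQ_LEVELS)
        for name in ("domestic_violence", "physical_abuse"):
            _check_level(name, getattr(self, name), EXPOSURE_LEVELS)


@dataclass
class SelectionFlow:
    """Counts at each stage of the analysis-sample selection."""

    followed_up: int
    in_age_range: int
    baseline_depressed_excluded: int
    final: int

    def __post_init__(self) -> None:
        if self.final != self.in_age_range - self.baseline_depressed_excluded:
            raise ValueError(
                "inconsistent selection flow: final must equal "
                "in_age_range - baseline_depressed_excluded")
        counts = (self.followed_up, self.in_age_range, self.final)
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError("selection-flow counts must be non-increasing")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class CodingAudit:
    """Complete-case accounting for the raw-to-coded conversion."""

    n_input: int = 0
    n_missing_excluded: int = 0
    n_coded: int = 0
    missing_by_column: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# item-level coding rules
# ---------------------------------------------------------------------------

def _validate_items(items, name: str = "items") -> np.ndarray:
    arr = np.asarray(items)
    if arr.shape != (N_SYMPTOM_ITEMS,):
        raise CodingError(
            f"{name} must have exactly {N_SYMPTOM_ITEMS} entries, "
            f"got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        bad = arr[~np.isin(arr, (0, 1))][0]
        raise CodingError(f"{name} contains non-binary entry {bad!r}")
    return arr.astype(int)


def classify_depression(items: Iterable[int]) -> DepressionStatus:
    """Apply the DSM-IV symptom-count rule to one wave's nine items.

    Depression is present iff at least five items are endorsed *and* at least
    one of the two core symptoms (item 0, depressed mood; item 1, anhedonia)
    is endorsed.
    """
    arr = _validate_items(items)
    count = int(arr.sum())
    core = bool(arr[0] or arr[1])
    return DepressionStatus(
        positive_item_count=count,
        core_symptom_present=core,
        depressed=(count >= SYMPTOM_THRESHOLD and core),
    )


def derive_maltreatment(domestic_violence: str, physical_abuse: str,
                        lives_with_parent: str) -> str:
    """Collapse family-adversity items into the ordered maltreatment predictor.

    ``severe`` takes precedence over ``probable`` over ``none``:

    * severe  — "a lot" on either domestic violence or physical abuse;
    * probable — "a little" on *both* exposure items, or not living with any
      biological parent;
    * none — everything else (including "a little" on exactly one exposure
      item while living with a parent, which the rule set leaves unclassified
      and this implementation codes conservatively as ``none``).
    """
    _check_level("domestic_violence", domestic_violence, EXPOSURE_LEVELS)
    _check_level("physical_abuse", physical_abuse, EXPOSURE_LEVELS)
    _check_level("lives_with_parent", lives_with_parent, YESNO_LEVELS)
    if domestic_violence == "a_lot" or physical_abuse == "a_lot":
        return "severe"
    if (domestic_violence == "a_little" and physical_abuse == "a_little") \
            or lives_with_parent == "no":
        return "probable"
    return "none"


def derive_drug_use(alcohol: str, cigarettes: str, marijuana: str) -> int:
    """1 if any substance is used "a little" or "a lot", else 0."""
    _check_level("alcohol_freq", alcohol, FREQ_LEVELS)
    _check_level("cigarette_freq", cigarettes, FREQ_LEVELS)
    _check_level("marijuana_freq", marijuana, FREQ_LEVELS)
    return int(any(v != "none" for v in (alcohol, cigarettes, marijuana)))


def derive_social_isolation(close_friends: int) -> int:
    """1 if the respondent reports zero close friends."""
    if close_friends < 0:
        raise CodingError(f"close_friends={close_friends} is negative")
    return int(close_friends == 0)


def derive_fights(started_fight: str, hurt_someone: str) -> int:
    """1 only when both fight items are endorsed (conjunction)."""
    _check_level("started_fight", started_fight, YESNO_LEVELS)
    _check_level("hurt_someone", hurt_someone, YESNO_LEVELS)
    return int(started_fight == "yes" and hurt_someone == "yes")


def derive_simple_flags(record: RawStudentRecord) -> tuple[int, int, int]:
    """Direct yes/no mappings: (school_failure, ran_away, sex_female)."""
    return (
        int(record.repeated_class == "yes"),
        int(record.ran_away_many_days == "yes"),
        int(record.sex == "female"),
    )


def code_record(record: RawStudentRecord) -> tuple[PredictorVector,
                                                   DepressionStatus,
                                                   DepressionStatus]:
    """Code one raw record: (predictors, baseline status, follow-up status)."""
    school_failure, ran_away, sex_female = derive_simple_flags(record)
    predictors = PredictorVector(
        sex_female=sex_female,
        maltreatment=derive_maltreatment(
            record.domestic_violence, record.physical_abuse,
            record.lives_with_biological_parent),
        school_failure=school_failure,
        social_isolation=derive_social_isolation(record.close_friends),
        fights=derive_fights(record.started_fight, record.hurt_someone),
        ran_away=ran_away,
        drug_use=derive_drug_use(
            record.alcohol_freq, record.cigarette_freq,
            record.marijuana_freq),
    )
    base = classify_depression(record.depression_items_baseline)
    followup = classify_depression(record.depression_items_followup)
    return predictors, base, followup


# ---------------------------------------------------------------------------
# cohort-level coding
# ---------------------------------------------------------------------------

_CODING_INPUTS = [c for c, _ in RAW_COLUMNS if c != "id"]


def code_cohort(raw: pd.DataFrame) -> tuple[pd.DataFrame, CodingAudit]:
    """Convert a raw cohort table into a coded (model-ready) table.

    Rows with any missing coding input are dropped (complete-case) and counted
    in the returned :class:`CodingAudit`.  Invalid (non-missing) values raise
    :class:`CodingError` naming the offending column.
    """
    missing_cols = [c for c, _ in RAW_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise CodingError(f"raw cohort lacks required columns: {missing_cols}")

    audit = CodingAudit(n_input=len(raw))
    complete = raw.dropna(subset=_CODING_INPUTS)
    audit.n_missing_excluded = len(raw) - len(complete)
    audit.missing_by_column = {
        c: int(raw[c].isna().sum()) for c in _CODING_INPUTS
        if raw[c].isna().any()
    }

    def _col(name, levels):
        vals = complete[name]
        bad = ~vals.isin(levels)
        if bad.any():
            raise CodingError(
                f"{name}={vals[bad].iloc[0]!r} is not one of {tuple(levels)}")
        return vals

    base_items = complete[list(_BASE_ITEMS)].to_numpy()
    fup_items = complete[list(_FUP_ITEMS)].to_numpy()
    for name, arr in (("baseline", base_items), ("follow-up", fup_items)):
        if not np.isin(arr, (0, 1)).all():
            raise CodingError(f"non-binary {name} symptom item present")
    ages = complete["age_baseline"].astype(int)
    if ((ages < AGE_RANGE[0]) | (ages > AGE_RANGE[1])).any():
        raise CodingError(f"age_baseline outside {AGE_RANGE}")

    sex = _col("sex", SEX_LEVELS)
    dv = _col("domestic_violence", EXPOSURE_LEVELS)
    abuse = _col("physical_abuse", EXPOSURE_LEVELS)
    lives = _col("lives_with_biological_parent", YESNO_LEVELS)
    friends = complete["close_friends"].astype(int)
    if (friends < 0).any():
        raise CodingError("close_friends contains a negative count")

    severe = (dv == "a_lot") | (abuse == "a_lot")
    probable = ((dv == "a_little") & (abuse == "a_little")) | (lives == "no")
    maltreatment = np.where(severe, "severe",
                            np.where(probable, "probable", "none"))

    drug = (
        _col("alcohol_freq", FREQ_LEVELS).ne("none")
        | _col("cigarette_freq", FREQ_LEVELS).ne("none")
        | _col("marijuana_freq", FREQ_LEVELS).ne("none")
    )
    fights = (_col("started_fight", YESNO_LEVELS) == "yes") \
        & (_col("hurt_someone", YESNO_LEVELS) == "yes")

    def _dep(items):
        count = items.sum(axis=1)
        core = (items[:, 0] == 1) | (items[:, 1] == 1)
        return (count >= SYMPTOM_THRESHOLD) & core

    coded = pd.DataFrame({
        "id": complete["id"].to_numpy(),
        "age_baseline": ages.to_numpy(),
        "sex_female": (sex == "female").astype(int).to_numpy(),
        "maltreatment": maltreatment,
        "school_failure": (_col("repeated_class", YESNO_LEVELS) == "yes")
        .astype(int).to_numpy(),
        "social_isolation": (friends == 0).astype(int).to_numpy(),
        "fights": fights.astype(int).to_numpy(),
        "ran_away": (_col("ran_away_many_days", YESNO_LEVELS) == "yes")
        .astype(int).to_numpy(),
        "drug_use": drug.astype(int).to_numpy(),
        "depressed_baseline": _dep(base_items).astype(int),
        "depressed_followup": _dep(fup_items).astype(int),
    })
    audit.n_coded = len(coded)
    return coded.reset_index(drop=True), audit


def select_analysis_sample(cohort: pd.DataFrame, age_min: int = 14,
                           age_max: int = 16
                           ) -> tuple[pd.DataFrame, SelectionFlow]:
    """Apply the baseline age window then the baseline-depression exclusion.

    Returns the retained rows (original order preserved) and a
    :class:`SelectionFlow` with counts at every stage.  An empty result is a
    warning, not an error.
    """
    for col in ("age_baseline", "depressed_baseline"):
        if col not in cohort.columns:
            raise CodingError(f"cohort lacks required column {col!r}")
    in_age = cohort[(cohort["age_baseline"] >= age_min)
                    & (cohort["age_baseline"] <= age_max)]
    final = in_age[in_age["depressed_baseline"] == 0]
    flow = SelectionFlow(
        followed_up=len(cohort),
        in_age_range=len(in_age),
        baseline_depressed_excluded=len(in_age) - len(final),
        final=len(final),
    )
    if flow.final == 0:
        warnings.warn("analysis sample is empty after selection filters",
                      stacklevel=2)
    return final.reset_index(drop=True), flow


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_raw_cohort(path: str | Path) -> pd.DataFrame:
    """Read a raw cohort CSV (columns per :data:`RAW_COLUMNS`)."""
    return pd.read_csv(path)


def read_coded_cohort(path: str | Path) -> pd.DataFrame:
    """Read a coded cohort CSV (predictors + outcome columns)."""
    df = pd.read_csv(path)
    missing = [c for c in PREDICTOR_COLUMNS if c not in df.columns]
    if missing:
        raise CodingError(f"coded cohort lacks predictor columns: {missing}")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV (no index column)."""
    df.to_csv(path, index=False)
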