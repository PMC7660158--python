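"""Rule-based smoking-phenotype derivation.

Because smoking start/stop ages are recorded in whole years, whether a
woman smoked during the pregnancy of her first child (birth at age ``b``)
can only sometimes be determined from her smoking history. The rules:

Non-smoker in pregnancy if she
  (i)   never smoked;
  (ii)  currently smokes but started at age b+1 or later;
  (iii) formerly smoked but started at age b+1 or later;
  (iv)  formerly smoked but stopped at age b-2 or earlier.

Smoker in pregnancy if she
  (i)   currently smokes and started at age b-1 or earlier;
  (ii)  formerly smoked, started at b-1 or earlier and stopped at b+1
        or later.

Every other configuration (e.g. started at exactly age b, or a former
smoker who stopped at b-1 or b) is indeterminate: the whole-year ages
cannot place the episode relative to the pregnancy.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "SmokingHistory",
    "PregnancySmokingClass",
    "classify_pregnancy_smoking",
    "classify_smoking_before_age",
    "derive_ever_never",
    "classify_cohort_pregnancy_smoking",
]

STATUSES = ("never", "former", "current")


@dataclass(frozen=True)
class SmokingHistory:
    """Smoking status with integer start/stop ages (whole years).

    Invariants: never smokers carry no ages; current smokers have a start
    age and no stop age; former smokers have both, with stop >= start.
    """

    status: str
    age_started: int | None = None
    age_stopped: int | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"status must be one of {STATUSES}, got {self.status!r}")
        if self.status == "never" and (
            self.age_started is not None or self.age_stopped is not None
        ):
            raise ValueError("never smokers cannot have start/stop ages")
        if self.status == "current" and self.age_stopped is not None:
            raise ValueError("current smokers cannot have a stop age")
        if (
            self.status == "former"
            and self.age_started is not None
            and self.age_stopped is not None
            and self.age_stopped < self.age_started
        ):
            raise ValueError("age_stopped must be >= age_started")


class PregnancySmokingLabel(str, Enum):
    SMOKER = "smoker"
    NON_SMOKER = "non_smoker"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class PregnancySmokingClass:
    label: PregnancySmokingLabel
    rule_fired: str  # e.g. "non_smoker_i", "smoker_ii", "indeterminate"


def classify_pregnancy_smoking(
    history: SmokingHistory, age_first_birth: int
) -> PregnancySmokingClass:
    """Classify smoking during the first pregnancy from history and birth age.

    Returns smoker / non_smoker exactly when one of the listed rules
    fires, indeterminate otherwise. Missing start ages in current/former
    smokers are indeterminate (the episode cannot be placed).
    """
    b = age_first_birth
    if not (isinstance(b, (int, np.integer)) and b > 0):
        raise ValueError(f"age at first birth must be a positive integer, got {b!r}")
    s, start, stop = history.status, history.age_started, history.age_stopped

    if s == "never":
        return PregnancySmokingClass(PregnancySmokingLabel.NON_SMOKER, "non_smoker_i")
    if start is None:
        return PregnancySmokingClass(PregnancySmokingLabel.INDETERMINATE, "indeterminate")
    if s == "current":
        if start >= b + 1:
            return PregnancySmokingClass(
                PregnancySmokingLabel.NON_SMOKER, "non_smoker_ii"
            )
        if start <= b - 1:
            return PregnancySmokingClass(PregnancySmokingLabel.SMOKER, "smoker_i")
        return PregnancySmokingClass(PregnancySmokingLabel.INDETERMINATE, "indeterminate")
    # former
    if start >= b + 1:
        return PregnancySmokingClass(PregnancySmokingLabel.NON_SMOKER, "non_smoker_iii")
    if stop is None:
        return PregnancySmokingClass(PregnancySmokingLabel.INDETERMINATE, "indeterminate")
    if stop <= b - 2:
        return PregnancySmokingClass(PregnancySmokingLabel.NON_SMOKER, "non_smoker_iv")
    if start <= b - 1 and stop >= b + 1:
        return PregnancySmokingClass(PregnancySmokingLabel.SMOKER, "smoker_ii")
    return PregnancySmokingClass(PregnancySmokingLabel.INDETERMINATE, "indeterminate")


def classify_smoking_before_age(
    history: SmokingHistory, threshold_age: int
) -> str:
    """Was this person ever a smoker before ``threshold_age``?

    Used for sensitivity re-stratification of outcomes fixed around
    puberty (adult height: age 17 for men, 15 for women; menarche: the
    woman's own age at menarche). Returns ``"ever_before"``,
    ``"never_before"`` or ``"indeterminate"`` (smoker with missing start
    age).
    """
    if not (isinstance(threshold_age, (int, np.integer)) and threshold_age > 0):
        raise ValueError(
            f"threshold_age must be a positive integer, got {threshold_age!r}"
        )
    if history.status == "never":
        return "never_before"
    if history.age_started is None:
        return "indeterminate"
    return "ever_before" if history.age_started < threshold_age else "never_before"


def derive_ever_never(history: SmokingHistory) -> str:
    """Collapse current and former smokers into 'ever'; otherwise 'never'."""
    return "ever" if history.status in ("current", "former") else "never"


# ----------------------------------------------------------------------
# Vectorised cohort-level wrappers


def classify_cohort_pregnancy_smoking(
    cohort: pd.DataFrame,
    status_col: str = "g1_smoking_status",
    started_col: str = "g1_age_started",
    stopped_col: str = "g1_age_stopped",
    birth_age_col: str = "g1_age_first_birth",
) -> pd.Series:
    """Pregnancy-smoking class for every woman with a first birth.

    Returns a string Series aligned to the cohort index with values
    'smoker' / 'non_smoker' / 'indeterminate'; rows without a birth age
    get NA. Vectorised re-statement of :func:`classify_pregnancy_smoking`.
    """
    status = cohort[status_col].to_numpy(dtype=object)
    start = cohort[started_col].to_numpy(dtype=float, na_value=np.nan)
    stop = cohort[stopped_col].to_numpy(dtype=float, na_value=np.nan)
    b = cohort[birth_age_col].to_numpy(dtype=float, na_value=np.nan)

    out = np.full(len(cohort), "indeterminate", dtype=object)
    never = status == "never"
    current = status == "current"
    former = status == "former"
    with np.errstate(invalid="ignore"):
        non_smoker = (
            never
            | ((current | former) & (start >= b + 1))
            | (former & (stop <= b - 2))
        )
        smoker = (current & (start <= b - 1)) | (
            former & (start <= b - 1) & (stop >= b + 1)
        )
    out[non_smoker] = "non_smoker"
    out[smoker] = "smoker"
    result = pd.Series(out, index=cohort.index, dtype="object")
    result[np.isnan(b)] = pd.NA
    return result
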