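"""The 18-predictor covariate set and its single, shared encoding map.

Thirteen baseline predictors are fixed at diagnosis — sex, smoking status,
rurality, material-deprivation quintile and nine comorbidity indicators —
and five are time-dependent: age, and the running counts of prior
COPD-related and non-COPD-related ED visits and hospitalizations.  Every
transition model (parametric and multinomial) uses the same design vector,
built here so reference levels are declared exactly once:

* smoking status: reference *never* (dummies: current, former)
* rurality: reference *urban* (dummies: suburban, rural)
* deprivation: reference quintile 1, most advantaged (dummies: 2-5)
* sex: indicator ``female`` (reference male)
* comorbidities: indicator = presence (reference absence)
* age enters centred at 64 years (the cohort median) to keep linear
  predictors numerically tame; event counters enter as raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SMOKING_LEVELS", "RURALITY_LEVELS", "DEPRIVATION_LEVELS",
    "COMORBIDITIES", "BASELINE_COLUMNS", "COUNTER_COLUMNS",
    "COEFFICIENT_NAMES", "AGE_CENTER",
    "SubjectProfile", "encode_covariates", "encode_frame", "validate_cohort",
]

SMOKING_LEVELS = ("never", "current", "former")          # first = reference
RURALITY_LEVELS = ("urban", "suburban", "rural")
DEPRIVATION_LEVELS = (1, 2, 3, 4, 5)

COMORBIDITIES = (
    "chf", "ihd", "cancer", "diabetes", "asthma",
    "dementia", "depression", "anxiety", "hypertension",
)

COUNTER_COLUMNS = ("n_copd_ed", "n_other_ed", "n_copd_hosp", "n_other_hosp")

BASELINE_COLUMNS = (
    ("age", "smoking", "rurality", "deprivation", "female") + COMORBIDITIES
)

AGE_CENTER = 64.0

COEFFICIENT_NAMES = (
    ("age", "female")
    + tuple(f"smoking_{lv}" for lv in SMOKING_LEVELS[1:])
    + tuple(f"rurality_{lv}" for lv in RURALITY_LEVELS[1:])
    + tuple(f"deprivation_{lv}" for lv in DEPRIVATION_LEVELS[1:])
    + COMORBIDITIES
    + COUNTER_COLUMNS
)

N_COVARIATES = len(COEFFICIENT_NAMES)  # 23


@dataclass
class SubjectProfile:
    """Baseline predictors of one subject; counters start at zero."""

    subject_id: int
    age: float
    female: int
    smoking: str
    rurality: str
    deprivation: int
    comorbidities: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.smoking not in SMOKING_LEVELS:
            raise ValueError(f"smoking must be one of {SMOKING_LEVELS}")
        if self.rurality not in RURALITY_LEVELS:
            raise ValueError(f"rurality must be one of {RURALITY_LEVELS}")
        if self.deprivation not in DEPRIVATION_LEVELS:
            raise ValueError("deprivation must be a quintile 1..5")
        for c in COMORBIDITIES:
            self.comorbidities.setdefault(c, 0)

    def __getitem__(self, key: str):
        """Mapping-style access so a profile can stand in for a cohort row."""
        if key in COMORBIDITIES:
            return self.comorbidities[key]
        return getattr(self, key)

    def __contains__(self, key: str) -> bool:
        try:
            self[key]
        except (AttributeError, KeyError):
            return False
        return True

    @classmethod
    def from_row(cls, row: Mapping) -> "SubjectProfile":
        return cls(
            subject_id=int(row["subject_id"]),
            age=float(row["age"]),
            female=int(row["female"]),
            smoking=str(row["smoking"]),
            rurality=str(row["rurality"]),
            deprivation=int(row["deprivation"]),
            comorbidities={c: int(row[c]) for c in COMORBIDITIES},
        )


def encode_covariates(
    profile: Mapping,
    age: float,
    counters: Mapping[str, int] | Sequence[int] | None = None,
) -> np.ndarray:
    """Design vector (length 23) for one subject at one moment.

    ``age`` is the *current* age in years (time-dependent); baseline fields
    come from ``profile``; ``counters`` are the four prior-event counts
    (zero if omitted).
    """
    if counters is None:
        counts = (0, 0, 0, 0)
    elif isinstance(counters, Mapping):
        counts = tuple(counters.get(c, 0) for c in COUNTER_COLUMNS)
    else:
        counts = tuple(counters)
    if any(c < 0 for c in counts):
        raise ValueError("event counters must be non-negative")
    x = np.empty(N_COVARIATES)
    x[0] = age - AGE_CENTER
    x[1] = profile["female"]
    smoking, rural, dep = profile["smoking"], profile["rurality"], int(profile["deprivation"])
    x[2] = 1.0 if smoking == "current" else 0.0
    x[3] = 1.0 if smoking == "former" else 0.0
    x[4] = 1.0 if rural == "suburban" else 0.0
    x[5] = 1.0 if rural == "rural" else 0.0
    x[6:10] = [1.0 if dep == k else 0.0 for k in (2, 3, 4, 5)]
    for j, c in enumerate(COMORBIDITIES):
        x[10 + j] = profile[c] if c in profile else profile["comorbidities"][c]
    x[19:23] = counts
    return x


def encode_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized encoding of a record table carrying the raw predictor columns.

    Expects ``age_entry`` (current age at sojourn entry) plus the baseline
    and counter columns; returns a frame whose columns are exactly
    ``COEFFICIENT_NAMES`` in order.
    """
    out = pd.DataFrame(index=df.index)
    out["age"] = df["age_entry"].astype(float) - AGE_CENTER
    out["female"] = df["female"].astype(float)
    for lv in SMOKING_LEVELS[1:]:
        out[f"smoking_{lv}"] = (df["smoking"] == lv).astype(float)
    for lv in RURALITY_LEVELS[1:]:
        out[f"rurality_{lv}"] = (df["rurality"] == lv).astype(float)
    for lv in DEPRIVATION_LEVELS[1:]:
        out[f"deprivation_{lv}"] = (df["deprivation"].astype(int) == lv).astype(float)
    for c in COMORBIDITIES:
        out[c] = df[c].astype(float)
    for c in COUNTER_COLUMNS:
        out[c] = df[c].astype(float)
    return out[list(COEFFICIENT_NAMES)]


def validate_cohort(df: pd.DataFrame) -> None:
    """Raise if a cohort table violates the declared predictor domains."""
    required = ("subject_id",) + BASELINE_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if (df["age"] <= 0).any():
        raise ValueError("ages must be positive")
    if not df["smoking"].isin(SMOKING_LEVELS).all():
        raise ValueError("smoking levels outside declared set")
    if not df["rurality"].isin(RURALITY_LEVELS).all():
        raise ValueError("rurality levels outside declared set")
    if not df["deprivation"].isin(DEPRIVATION_LEVELS).all():
        raise ValueError("deprivation outside quintiles 1..5")
    for c in ("female",) + COMORBIDITIES:
        if not df[c].isin((0, 1)).all():
            raise ValueError(f"{c} must be binary 0/1")
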