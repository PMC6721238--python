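"""Data dictionary and model design matrices for the utilization analysis.

Variables follow the Andersen behavioural model of health-care utilization:
needs factors (self-rated health, chronic disease, mobility difficulty,
depression tendency), predisposing factors (age group, marital history,
education, recent exercise), enabling factors (region of residence, log
equivalent income) and an environmental factor (physician density band).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "MODEL_COLUMNS",
    "DESIGN_COLUMNS",
    "INCOME_DESIGN_COLUMNS",
    "build_design",
    "build_income_design",
]

# canonical column -> allowed categories (order fixes dummy construction)
CATEGORIES: dict[str, list] = {
    "outpatient_use": [0, 1],
    "sex": ["female", "male"],
    "age_group": ["65-74", "75+"],
    "married_ever": [0, 1],
    "education": ["informal", "elementary", "junior_high_plus"],
    "self_rated_health": ["poor", "fair", "good"],
    "chronic_disease": [0, 1],
    "mobility_difficulty": [0, 1],
    "exercise_2wk": [0, 1],
    "region": ["eastern_offshore", "central", "northern", "southern"],
    "physician_band": [1, 2, 3],
    "income_band": list(range(1, 11)),
}

# columns every analysis-ready table must carry
MODEL_COLUMNS = list(CATEGORIES) + [
    "cesd_score", "household_adults", "household_children", "weight", "year",
]

# probit regressors, in table order; reference levels: 75+, never married,
# informal education, fair health, no chronic disease, no mobility
# difficulty, CES-D below cutoff, no exercise, central region, band-2
# physician density
DESIGN_COLUMNS = [
    "lpinco",
    "age_65_74",
    "married",
    "edu_elementary",
    "edu_junior_plus",
    "health_good",
    "health_poor",
    "chronic",
    "mobility",
    "depress",
    "exercise",
    "region_east",
    "region_north",
    "region_south",
    "phys_band_1",
    "phys_band_3",
]

# covariates of the banded-income interval regression
INCOME_DESIGN_COLUMNS = [
    "age_65_74",
    "edu_elementary",
    "edu_junior_plus",
    "region_east",
    "region_north",
    "region_south",
]


def _indicators(df: pd.DataFrame, cesd_cutoff: int = 10) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    out["age_65_74"] = (df["age_group"] == "65-74").astype(float)
    out["married"] = df["married_ever"].astype(float)
    out["edu_elementary"] = (df["education"] == "elementary").astype(float)
    out["edu_junior_plus"] = (df["education"] == "junior_high_plus").astype(float)
    out["health_good"] = (df["self_rated_health"] == "good").astype(float)
    out["health_poor"] = (df["self_rated_health"] == "poor").astype(float)
    out["chronic"] = df["chronic_disease"].astype(float)
    out["mobility"] = df["mobility_difficulty"].astype(float)
    out["depress"] = (df["cesd_score"] >= cesd_cutoff).astype(float)
    out["exercise"] = df["exercise_2wk"].astype(float)
    out["region_east"] = (df["region"] == "eastern_offshore").astype(float)
    out["region_north"] = (df["region"] == "northern").astype(float)
    out["region_south"] = (df["region"] == "southern").astype(float)
    out["phys_band_1"] = (df["physician_band"] == 1).astype(float)
    out["phys_band_3"] = (df["physician_band"] == 3).astype(float)
    return out


def build_design(df: pd.DataFrame, lpinco, cesd_cutoff: int = 10) -> pd.DataFrame:
    """Probit design matrix (without intercept) in ``DESIGN_COLUMNS`` order.

    ``lpinco`` is the log of equivalent income (imputed, floored, price
    adjusted) aligned with ``df``.
    """
    X = _indicators(df, cesd_cutoff)
    X.insert(0, "lpinco", np.asarray(lpinco, dtype=float))
    return X[DESIGN_COLUMNS]


def build_income_design(df: pd.DataFrame) -> pd.DataFrame:
    """Interval-regression design (without intercept) for banded income."""
    return _indicators(df)[INCOME_DESIGN_COLUMNS]
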