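"""Maturity-offset prediction equations and derived anthropometric quantities.

Maturity offset is the signed time (years) from a measurement occasion to peak
height velocity, negative before PHV under the convention
``offset = chronological age - APHV``. Five published sex-specific regression
equations predict it from age and body dimensions:

* ``moore1_girls``  — age x stature
* ``moore1_boys``   — age x sitting height
* ``moore2_boys``   — age x stature (alternative when sitting height is absent)
* ``mirwald_boys``  — leg length, sitting height, age and mass-by-stature terms
* ``mirwald_girls`` — as above with an additional age x mass term

Predicted age at PHV is ``age - offset``. Coefficients are stored to full
published precision and never re-estimated here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "EQUATIONS",
    "EQUATIONS_BY_SEX",
    "CALIBRATION_AGE_RANGE",
    "MaturityOffsetPredictor",
    "moore1_girls",
    "moore1_boys",
    "moore2_boys",
    "mirwald_boys",
    "mirwald_girls",
    "predicted_aphv",
    "derived_ratios",
    "mass_stature_ratio",
    "predict_cohort",
]

# Published coefficients, full printed precision. Keys are the regressor
# products each equation uses; "intercept" stands alone.
EQUATIONS: dict[str, dict[str, float]] = {
    "moore1_girls": {"intercept": -7.709133, "age_x_stature": 0.0042232},
    "moore1_boys": {"intercept": -8.128741, "age_x_sitting_height": 0.0070346},
    "moore2_boys": {"intercept": -7.999994, "age_x_stature": 0.0036124},
    "mirwald_boys": {
        "intercept": -9.236,
        "leg_x_sitting_height": 0.0002708,
        "age_x_leg": -0.001663,
        "age_x_sitting_height": 0.007216,
        "mass_stature_ratio": 0.02292,
    },
    "mirwald_girls": {
        "intercept": -9.376,
        "leg_x_sitting_height": 0.0001882,
        "age_x_leg": 0.0022,
        "age_x_sitting_height": 0.005841,
        "age_x_mass": -0.002658,
        "mass_stature_ratio": 0.07693,
    },
}

EQUATIONS_BY_SEX = {
    "M": ("moore1_boys", "moore2_boys", "mirwald_boys"),
    "F": ("moore1_girls", "mirwald_girls"),
}

# ages outside this window are outside the samples the equations were
# calibrated on; predictions are still returned, with a flag
CALIBRATION_AGE_RANGE = (8.0, 18.0)


def _validate_anthro(age, stature=None, sitting_height=None, mass=None):
    age = np.asarray(age, dtype=float)
    out_of_range = (age < 6.0) | (age > 20.0)
    if stature is not None and sitting_height is not None:
        stature = np.asarray(stature, dtype=float)
        sitting_height = np.asarray(sitting_height, dtype=float)
        if np.any(sitting_height <= 0) or np.any(sitting_height >= stature):
            raise ValueError("require 0 < sitting_height < stature")
    if mass is not None and np.any(np.asarray(mass, dtype=float) <= 0):
        raise ValueError("mass must be positive")
    return out_of_range


def derived_ratios(stature, sitting_height):
    """Leg (subischial) length in cm and leg-to-sitting-height ratio in %.

    Leg length is stature minus sitting height.
    """
    _validate_anthro(np.full_like(np.asarray(stature, dtype=float), 12.0),
                     stature, sitting_height)
    stature = np.asarray(stature, dtype=float)
    sitting_height = np.asarray(sitting_height, dtype=float)
    leg = stature - sitting_height
    return leg, 100.0 * leg / sitting_height


def mass_stature_ratio(mass, stature):
    """Mass-by-stature ratio x 100 (kg per cm, scaled), as used by Mirwald."""
    return 100.0 * np.asarray(mass, dtype=float) / np.asarray(stature, dtype=float)


def moore1_girls(age, stature):
    c = EQUATIONS["moore1_girls"]
    return c["intercept"] + c["age_x_stature"] * np.asarray(age, float) * np.asarray(stature, float)


def moore1_boys(age, sitting_height):
    c = EQUATIONS["moore1_boys"]
    return c["intercept"] + c["age_x_sitting_height"] * np.asarray(age, float) * np.asarray(sitting_height, float)


def moore2_boys(age, stature):
    c = EQUATIONS["moore2_boys"]
    return c["intercept"] + c["age_x_stature"] * np.asarray(age, float) * np.asarray(stature, float)


def mirwald_boys(age, stature, sitting_height, mass):
    _validate_anthro(age, stature, sitting_height, mass)
    age = np.asarray(age, float)
    stature = np.asarray(stature, float)
    sitting_height = np.asarray(sitting_height, float)
    mass = np.asarray(mass, float)
    leg = stature - sitting_height
    c = EQUATIONS["mirwald_boys"]
    return (
        c["intercept"]
        + c["leg_x_sitting_height"] * leg * sitting_height
        + c["age_x_leg"] * age * leg
        + c["age_x_sitting_height"] * age * sitting_height
        + c["mass_stature_ratio"] * mass_stature_ratio(mass, stature)
    )


def mirwald_girls(age, stature, sitting_height, mass):
    _validate_anthro(age, stature, sitting_height, mass)
    age = np.asarray(age, float)
    stature = np.asarray(stature, float)
    sitting_height = np.asarray(sitting_height, float)
    mass = np.asarray(mass, float)
    leg = stature - sitting_height
    c = EQUATIONS["mirwald_girls"]
    return (
        c["intercept"]
        + c["leg_x_sitting_height"] * leg * sitting_height
        + c["age_x_leg"] * age * leg
        + c["age_x_sitting_height"] * age * sitting_height
        + c["age_x_mass"] * age * mass
        + c["mass_stature_ratio"] * mass_stature_ratio(mass, stature)
    )


def predicted_aphv(age, offset):
    """Predicted age at PHV: chronological age minus maturity offset."""
    return np.asarray(age, float) - np.asarray(offset, float)


_EQUATION_FUNCS = {
    "moore1_girls": lambda df: moore1_girls(df["age_years"], df["stature_cm"]),
    "moore1_boys": lambda df: moore1_boys(df["age_years"], df["sitting_height_cm"]),
    "moore2_boys": lambda df: moore2_boys(df["age_years"], df["stature_cm"]),
    "mirwald_boys": lambda df: mirwald_boys(
        df["age_years"], df["stature_cm"], df["sitting_height_cm"], df["mass_kg"]
    ),
    "mirwald_girls": lambda df: mirwald_girls(
        df["age_years"], df["stature_cm"], df["sitting_height_cm"], df["mass_kg"]
    ),
}


class MaturityOffsetPredictor(BaseEstimator, TransformerMixin):
    """Stateless transformer applying one published offset equation per visit.

    ``transform`` takes the long-format visit DataFrame and appends
    ``offset_<equation_id>`` and ``aphv_<equation_id>`` columns plus an
    ``age_out_of_calibration`` flag. Dispatch is explicit via ``equation_id``;
    the transformer never infers sex from the data.
    """

    def __init__(self, equation_id: str = "moore1_boys"):
        self.equation_id = equation_id

    def fit(self, X, y=None):
        if self.equation_id not in EQUATIONS:
            raise ValueError(
                f"unknown equation_id {self.equation_id!r}; "
                f"choose from {sorted(EQUATIONS)}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "n_features_in_"):
            self.fit(X)
        out = X.copy()
        offset = np.asarray(_EQUATION_FUNCS[self.equation_id](X), dtype=float)
        lo, hi = CALIBRATION_AGE_RANGE
        age = X["age_years"].to_numpy(dtype=float)
        out[f"offset_{self.equation_id}"] = offset
        out[f"aphv_{self.equation_id}"] = predicted_aphv(age, offset)
        out["age_out_of_calibration"] = (age < lo) | (age > hi)
        return out


def predict_cohort(visits: pd.DataFrame, equations=None) -> pd.DataFrame:
    """Apply every sex-appropriate equation across a visit table.

    Boys get the three boys' equations, girls the two girls' equations;
    columns for the other sex's equations are left NaN so the frame stays
    rectangular.
    """
    out = visits.copy()
    for sex, eq_ids in EQUATIONS_BY_SEX.items():
        mask = out["sex"] == sex
        if not mask.any():
            continue
        sub = out.loc[mask]
        for eq in eq_ids if equations is None else [e for e in equations if e in eq_ids]:
            pred = MaturityOffsetPredictor(equation_id=eq).fit(sub).transform(sub)
            out.loc[mask, f"offset_{eq}"] = pred[f"offset_{eq}"].to_numpy()
            out.loc[mask, f"aphv_{eq}"] = pred[f"aphv_{eq}"].to_numpy()
    lo, hi = CALIBRATION_AGE_RANGE
    age = out["age_years"].to_numpy(dtype=float)
    out["age_out_of_calibration"] = (age < lo) | (age > hi)
    return out
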