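"""Synthetic longitudinal cohorts with known ground-truth age at PHV.

Emulates the structure of a 1960s-style urban growth study: boys measured
annually from 8 to 18 years and girls from 8 to 16 years, with stature,
sitting height and body mass at each visit, occasional missed examinations
(more often in late adolescence) and occasional second visits falling inside
the same age class. Each subject's stature follows a Preece–Baines Model 1
curve whose timing parameter is placed so that the true age at PHV is drawn
from a sex-specific truncated normal; the registry of true parameters and
true APHV makes every downstream stage testable without external data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .pb1 import PB1Params, aphv_shift, pb1_height, THETA_MIN, THETA_MAX

__all__ = [
    "SexConfig",
    "CohortConfig",
    "sample_pb1_params",
    "generate_subject",
    "apply_missingness",
    "generate_cohort",
    "cohort_to_csv",
]

VISIT_COLUMNS = [
    "subject_id",
    "sex",
    "age_years",
    "stature_cm",
    "sitting_height_cm",
    "mass_kg",
]


class ConfigError(ValueError):
    """Raised for configurations violating the generator's invariants."""


@dataclass
class SexConfig:
    """Per-sex targets: measurement schedule and true-APHV distribution."""

    age_start: int
    age_stop: int  # inclusive
    aphv_mean: float
    aphv_sd: float
    aphv_min: float
    aphv_max: float
    h_adult_mean: float
    h_adult_sd: float

    @property
    def schedule(self) -> np.ndarray:
        return np.arange(self.age_start, self.age_stop + 1, dtype=float)


def _default_boys() -> SexConfig:
    return SexConfig(
        age_start=8, age_stop=18,
        aphv_mean=14.06, aphv_sd=1.11, aphv_min=11.45, aphv_max=17.34,
        h_adult_mean=176.0, h_adult_sd=6.5,
    )


def _default_girls() -> SexConfig:
    return SexConfig(
        age_start=8, age_stop=16,
        aphv_mean=11.89, aphv_sd=1.00, aphv_min=9.03, aphv_max=14.82,
        h_adult_mean=164.0, h_adult_sd=6.0,
    )


@dataclass
class CohortConfig:
    """Study-design and noise parameters for one simulated cohort.

    Defaults reproduce the reference study scale: 193 boys (8-18 y) and 199
    girls (8-16 y), annual visits with decimal-age jitter sd 0.15 y (so
    within-age-group sd is about 0.3 y once measurement scheduling is
    included), 0.3 cm stature noise, 5% missed visits weighted toward the
    oldest ages, and 5% duplicated age-class visits.
    """

    n_boys: int = 193
    n_girls: int = 199
    age_jitter_sd: float = 0.15
    height_noise_sd: float = 0.3
    sitting_noise_sd: float = 0.3
    mass_noise_sd: float = 0.5
    missing_visit_rate: float = 0.05
    duplicate_visit_rate: float = 0.05
    seed: int = 0
    boys: SexConfig = field(default_factory=_default_boys)
    girls: SexConfig = field(default_factory=_default_girls)
    # rate-constant and shape priors (invented calibration, see docs/methods.md)
    s0_mean: float = 0.11
    s0_sd: float = 0.015
    s1_mean: float = 1.2
    s1_sd: float = 0.2
    drop_mean: float = 13.0  # h_adult - h_theta, cm
    drop_sd: float = 2.0

    def validate(self) -> "CohortConfig":
        for name in ("missing_visit_rate", "duplicate_visit_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in (
            "age_jitter_sd", "height_noise_sd", "sitting_noise_sd", "mass_noise_sd"
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_boys < 0 or self.n_girls < 0:
            raise ConfigError("cohort sizes must be non-negative")
        for sex_cfg in (self.boys, self.girls):
            if sex_cfg.aphv_sd < 0:
                raise ConfigError("aphv_sd must be >= 0")
            if sex_cfg.aphv_sd > 0 and not (
                sex_cfg.aphv_min <= sex_cfg.aphv_mean - 2 * sex_cfg.aphv_sd + 4 * sex_cfg.aphv_sd
                and sex_cfg.aphv_min <= sex_cfg.aphv_mean
                and sex_cfg.aphv_max >= sex_cfg.aphv_mean
            ):
                raise ConfigError("APHV bounds must contain the mean")
        return self

    def sex_config(self, sex: str) -> SexConfig:
        return self.boys if sex == "M" else self.girls


def _draw_aphv(sex_cfg: SexConfig, rng: np.random.Generator) -> float:
    if sex_cfg.aphv_sd == 0:
        return sex_cfg.aphv_mean
    a = (sex_cfg.aphv_min - sex_cfg.aphv_mean) / sex_cfg.aphv_sd
    b = (sex_cfg.aphv_max - sex_cfg.aphv_mean) / sex_cfg.aphv_sd
    return float(
        truncnorm.rvs(a, b, loc=sex_cfg.aphv_mean, scale=sex_cfg.aphv_sd,
                      random_state=rng)
    )


def sample_pb1_params(
    sex: str, rng: np.random.Generator, config: CohortConfig, max_retries: int = 200
) -> tuple[PB1Params, float]:
    """Draw one subject's true PB1 parameters with APHV on target.

    The target APHV is drawn from the sex-specific truncated normal; because
    the model is translation-equivariant in theta, theta is set exactly to
    ``target - (APHV - theta)(s0, s1)``, so the induced APHV distribution
    matches the configured one by construction. Invalid draws (theta outside
    its domain, non-increasing curve) are rejected and resampled.

    Returns ``(params, true_aphv)``.
    """
    config.validate()
    sex_cfg = config.sex_config(sex)
    for _ in range(max_retries):
        target = _draw_aphv(sex_cfg, rng)
        s0 = rng.normal(config.s0_mean, config.s0_sd)
        s1 = rng.normal(config.s1_mean, config.s1_sd)
        if not (0.02 <= s0 <= 0.3 and s0 + 0.3 <= s1 <= 3.0):
            continue
        h_adult = rng.normal(sex_cfg.h_adult_mean, sex_cfg.h_adult_sd)
        drop = rng.normal(config.drop_mean, config.drop_sd)
        if drop < 6.0 or h_adult <= 120.0:
            continue
        try:
            # rejects rate pairs whose velocity curve has no adolescent peak
            theta = target - aphv_shift(s0, s1)
        except ValueError:
            continue
        if not (THETA_MIN <= theta <= THETA_MAX):
            continue
        params = PB1Params(
            h_adult=h_adult, h_theta=h_adult - drop, s0=s0, s1=s1, theta=theta
        )
        try:
            params.validate()
        except ValueError:
            continue
        return params, target
    raise RuntimeError("could not sample valid PB1 parameters within retry budget")


def _sitting_fraction(t: np.ndarray, aphv: float) -> np.ndarray:
    """Sitting-height/stature ratio: logistic decline 0.535 -> 0.52 across the
    spurt with a transient 0.005 dip centred 0.5 y before APHV (legs spurt
    before the trunk)."""
    base = 0.52 + 0.015 / (1.0 + np.exp((t - aphv) / 1.5))
    dip = 0.005 * np.exp(-0.5 * ((t - (aphv - 0.5)) / 1.0) ** 2)
    return base - dip


def _bmi(t: np.ndarray, subject_intercept: float) -> np.ndarray:
    """Age-linear BMI trend 16 -> 21 kg/m^2 over ages 8-18 plus a subject
    random intercept; only feeds the mass channel used by Mirwald."""
    return 16.0 + 0.5 * (t - 8.0) + subject_intercept


def generate_subject(
    sex: str,
    subject_id: str,
    rng: np.random.Generator,
    config: CohortConfig,
    params: PB1Params | None = None,
    true_aphv: float | None = None,
) -> pd.DataFrame:
    """One subject's scheduled visit records (before missingness/duplication)."""
    config.validate()
    sex_cfg = config.sex_config(sex)
    if params is None:
        params, true_aphv = sample_pb1_params(sex, rng, config)
    bmi_intercept = rng.normal(0.0, 1.5)

    ages = sex_cfg.schedule + rng.normal(0.0, config.age_jitter_sd,
                                         size=sex_cfg.schedule.size)
    ages = np.sort(ages)
    return _measure_at(
        ages, sex, subject_id, params, true_aphv, bmi_intercept, rng, config
    )


def _measure_at(ages, sex, subject_id, params, true_aphv, bmi_intercept, rng,
                config) -> pd.DataFrame:
    true_stature = pb1_height(params, ages)
    stature = true_stature + rng.normal(0.0, config.height_noise_sd, ages.size)
    frac = _sitting_fraction(ages, true_aphv)
    sitting = true_stature * frac + rng.normal(0.0, config.sitting_noise_sd,
                                               ages.size)
    mass = (
        _bmi(ages, bmi_intercept) * (true_stature / 100.0) ** 2
        + rng.normal(0.0, config.mass_noise_sd, ages.size)
    )
    # plausibility guards
    stature = np.clip(stature, 80.0, 230.0)
    sitting = np.clip(sitting, 40.0, stature - 20.0)
    mass = np.clip(mass, 12.0, 150.0)
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "sex": sex,
            "age_years": ages,
            "stature_cm": stature,
            "sitting_height_cm": sitting,
            "mass_kg": mass,
        }
    )


def apply_missingness(
    measurements: pd.DataFrame, rng: np.random.Generator, config: CohortConfig
) -> pd.DataFrame:
    """Drop visits (weighted toward the oldest ages) and insert same-age-class
    duplicates, mimicking missed late-adolescent examinations and repeat
    visits within an age class.

    Drop probabilities are scaled so their mean over the schedule equals
    ``missing_visit_rate``. Duplicates re-measure the subject at a nearby age
    inside the same whole-year age class; their anthropometry is drawn fresh
    from the same true curve plus noise.
    """
    config.validate()
    if measurements.empty:
        return measurements.copy()
    out_parts = []
    for (sid, sex), grp in measurements.groupby(["subject_id", "sex"], sort=False):
        grp = grp.sort_values("age_years").reset_index(drop=True)
        ages = grp["age_years"].to_numpy()
        n = len(grp)
        keep = np.ones(n, dtype=bool)
        if config.missing_visit_rate > 0 and n > 1:
            w = 1.0 + 2.0 * (ages - ages.min()) / max(ages.max() - ages.min(), 1e-9)
            p = np.minimum(config.missing_visit_rate * w / w.mean(), 1.0)
            keep = rng.random(n) >= p
            if not keep.any():
                keep[0] = True
        kept = grp.loc[keep].copy()
        if config.duplicate_visit_rate > 0:
            dup_mask = rng.random(len(kept)) < config.duplicate_visit_rate
            dups = []
            for _, row in kept.loc[dup_mask].iterrows():
                ca = np.floor(row["age_years"] + 0.5)
                new_age = float(
                    np.clip(
                        row["age_years"] + rng.uniform(0.1, 0.35) * rng.choice([-1, 1]),
                        ca - 0.499, ca + 0.489,
                    )
                )
                dup = row.copy()
                dup["age_years"] = new_age
                # re-measured on a nearby occasion: jitter anthropometry
                dup["stature_cm"] += rng.normal(0.0, max(config.height_noise_sd, 0.1))
                dup["sitting_height_cm"] += rng.normal(
                    0.0, max(config.sitting_noise_sd, 0.1)
                )
                dup["mass_kg"] += rng.normal(0.0, max(config.mass_noise_sd, 0.1))
                dups.append(dup)
            if dups:
                kept = pd.concat([kept, pd.DataFrame(dups)], ignore_index=True)
        kept = kept.sort_values("age_years")
        out_parts.append(kept)
    return pd.concat(out_parts, ignore_index=True)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full cohort: returns ``(visits, registry)``.

    ``visits`` is the long-format measurement table; ``registry`` holds one
    row per subject with the true PB1 parameters, true APHV and the maturity
    class implied by the true APHV relative to the cohort's true sex means.
    Deterministic under ``config.seed``; each subject draws from its own
    deterministic substream so cohorts are reproducible and extensible.
    """
    config.validate()
    plan = [("M", config.n_boys), ("F", config.n_girls)]
    visit_parts, reg_rows = [], []
    counter = 0
    for sex, n in plan:
        for i in range(n):
            sid = f"{'B' if sex == 'M' else 'G'}{i + 1:04d}"
            # per-subject deterministic substream keyed by (seed, index)
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, counter]))
            counter += 1
            params, true_aphv = sample_pb1_params(sex, rng, config)
            visits = generate_subject(sex, sid, rng, config, params, true_aphv)
            visits = apply_missingness(visits, rng, config)
            visit_parts.append(visits)
            reg_rows.append(
                {
                    "subject_id": sid,
                    "sex": sex,
                    "true_aphv": true_aphv,
                    "h_adult": params.h_adult,
                    "h_theta": params.h_theta,
                    "s0": params.s0,
                    "s1": params.s1,
                    "theta": params.theta,
                }
            )
    visits = pd.concat(visit_parts, ignore_index=True)
    registry = pd.DataFrame(reg_rows)
    # maturity class under the true APHV, relative to the cohort's true means
    registry["maturity_class"] = ""
    for sex in ("M", "F"):
        mask = registry["sex"] == sex
        if not mask.any():
            continue
        mean_aphv = registry.loc[mask, "true_aphv"].mean()
        aphv = registry.loc[mask, "true_aphv"]
        cls = np.where(
            aphv < mean_aphv - 1.0, "early",
            np.where(aphv > mean_aphv + 1.0, "late", "average"),
        )
        registry.loc[mask, "maturity_class"] = cls
    return visits, registry


def cohort_to_csv(df: pd.DataFrame) -> str:
    """Serialise a table deterministically (fixed float format, LF endings)."""
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.6f", lineterminator="\n")
    return buf.getvalue()
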