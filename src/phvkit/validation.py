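"""Validation battery for maturity-offset predictions against observed APHV.

Implements the evaluation a longitudinal validation study applies once each
subject's observed age at PHV is in hand:

* chronological-age grouping by the midpoint rule (8.0 covers 7.50-8.49 y);
* years-relative-to-PHV bins from -3 to +3 under the same rounding rule;
* early / average / late maturity classes (sex mean observed APHV +/- 1 y);
* removal of duplicate observations within an age class;
* per-bin descriptive summaries of actual offset, predicted offset,
  predicted APHV and the error (predicted - observed APHV);
* percentages of predictions within +/-0.5 y of observed APHV;
* Bland-Altman regressions of difference on mean, with limits of agreement;
* intra-individual spread of predicted APHV across a subject's visits;
* the end-to-end runner tying PB1 fitting, prediction and all summaries
  together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .offsets import EQUATIONS_BY_SEX, predict_cohort
from .pb1 import fit_cohort

__all__ = [
    "MaturityClass",
    "AgreementFit",
    "ValidationReport",
    "ca_group",
    "phv_bin",
    "classify_maturity",
    "dedupe_age_class",
    "summarize_by_bin",
    "pct_within_band",
    "bland_altman",
    "intra_individual_spread",
    "run_validation",
]

PHV_BIN_WINDOW = (-3, 3)


@dataclass(frozen=True)
class MaturityClass:
    """Early/average/late label with the sex-specific band bounds used."""

    category: str
    lower: float
    upper: float


@dataclass(frozen=True)
class AgreementFit:
    """Bland-Altman regression of difference on mean plus limits of agreement."""

    intercept: float
    slope: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class ValidationReport:
    """Everything the end-to-end runner produces for one cohort."""

    fits: pd.DataFrame
    visits: pd.DataFrame  # deduped, with predictions, bins and classes
    ca_tables: dict[str, pd.DataFrame]  # per sex: summaries by CA group
    phv_tables: dict[str, pd.DataFrame]  # per sex: summaries by years-from-PHV bin
    hit_rate_ca: pd.DataFrame
    hit_rate_phv: pd.DataFrame
    ba_ca: pd.DataFrame
    ba_phv: pd.DataFrame
    spread: pd.DataFrame
    sex_mean_aphv: dict[str, float]
    exclusions: dict[str, int] = field(default_factory=dict)


def ca_group(age) -> np.ndarray | int:
    """Chronological-age group: whole year nearest the decimal age.

    The whole year is the midpoint of the group's range, so group 8 covers
    7.50-8.49 y; implemented as floor(age + 0.5), which tiles the line with
    no gaps or overlaps.
    """
    res = np.floor(np.asarray(age, dtype=float) + 0.5).astype(int)
    return int(res) if np.isscalar(age) else res


def phv_bin(age, observed_aphv):
    """Years-relative-to-PHV bin in -3..+3, or None outside the window.

    ``x = age - observed APHV`` is rounded to the nearest whole year by the
    same midpoint rule; bin 0 covers -0.50 to +0.49 and bin +3 ends at +3.49.
    Vector inputs return a float array with NaN for excluded visits.
    """
    x = np.asarray(age, dtype=float) - np.asarray(observed_aphv, dtype=float)
    b = np.floor(x + 0.5)
    lo, hi = PHV_BIN_WINDOW
    inside = (b >= lo) & (b <= hi)
    if np.isscalar(age) or np.ndim(x) == 0:
        return int(b) if inside else None
    return np.where(inside, b, np.nan)


def classify_maturity(
    observed_aphv: float, sex_mean_aphv: float, band: float = 1.0
) -> MaturityClass:
    """Early / average / late relative to the sex mean observed APHV.

    Average means within +/- ``band`` years of the mean, endpoints inclusive.
    """
    lower = sex_mean_aphv - band
    upper = sex_mean_aphv + band
    if observed_aphv < lower:
        cat = "early"
    elif observed_aphv > upper:
        cat = "late"
    else:
        cat = "average"
    return MaturityClass(category=cat, lower=lower, upper=upper)


def dedupe_age_class(visits: pd.DataFrame) -> pd.DataFrame:
    """Keep one observation per (subject, CA group).

    When two visits fall in the same age class, the one nearer the group
    midpoint is retained; exact ties keep the earlier age.
    """
    out = visits.copy()
    grp = ca_group(out["age_years"].to_numpy())
    out["_ca"] = grp
    out["_dist"] = np.abs(out["age_years"].to_numpy() - grp)
    out = out.sort_values(["subject_id", "_ca", "_dist", "age_years"],
                          kind="mergesort")
    out = out.drop_duplicates(subset=["subject_id", "_ca"], keep="first")
    return (
        out.drop(columns=["_ca", "_dist"])
        .sort_values(["subject_id", "age_years"], kind="mergesort")
        .reset_index(drop=True)
    )


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(x))
    s = float(np.std(x, ddof=1)) if x.size >= 2 else math.nan
    return m, s


def summarize_by_bin(
    visits: pd.DataFrame,
    equations: list[str],
    bin_kind: str = "ca",
    group: str | None = None,
    n_bootstrap: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-bin descriptive statistics in long format.

    ``visits`` must carry ``age_years``, ``observed_aphv``, a ``bin_ca`` or
    ``bin_phv`` column, per-equation ``offset_<eq>`` / ``aphv_<eq>`` columns
    and (for ``group``) ``maturity_class``. One output row per (bin,
    equation) with n, actual-offset stats (CA bins only), predicted offset,
    predicted APHV and difference predicted - observed APHV. SDs are NaN for
    singleton bins. With ``n_bootstrap > 0`` a resampling standard error of
    the mean difference is added as ``diff_se`` (no significance testing is
    performed, only uncertainty for the descriptive differences).
    """
    if n_bootstrap and rng is None:
        rng = np.random.default_rng(0)
    bin_col = f"bin_{bin_kind}"
    df = visits
    if group is not None:
        df = df[df["maturity_class"] == group]
    df = df[df[bin_col].notna()]
    rows = []
    for bin_id, sub in df.groupby(bin_col, sort=True):
        age = sub["age_years"].to_numpy(dtype=float)
        obs = sub["observed_aphv"].to_numpy(dtype=float)
        actual_offset = age - obs
        for eq in equations:
            off = sub[f"offset_{eq}"].to_numpy(dtype=float)
            pred = sub[f"aphv_{eq}"].to_numpy(dtype=float)
            ok = np.isfinite(off) & np.isfinite(pred)
            if not ok.any():
                continue
            row = {"bin": int(bin_id), "equation": eq, "n": int(ok.sum())}
            row["age_mean"], row["age_sd"] = _mean_sd(age[ok])
            if bin_kind == "ca":
                row["actual_offset_mean"], row["actual_offset_sd"] = _mean_sd(
                    actual_offset[ok]
                )
            row["offset_mean"], row["offset_sd"] = _mean_sd(off[ok])
            row["pred_aphv_mean"], row["pred_aphv_sd"] = _mean_sd(pred[ok])
            row["obs_aphv_mean"], row["obs_aphv_sd"] = _mean_sd(obs[ok])
            diff = pred[ok] - obs[ok]
            row["diff_mean"], row["diff_sd"] = _mean_sd(diff)
            if n_bootstrap and diff.size >= 2:
                idx = rng.integers(0, diff.size, size=(n_bootstrap, diff.size))
                row["diff_se"] = float(np.std(diff[idx].mean(axis=1), ddof=1))
            rows.append(row)
    return pd.DataFrame(rows)


def pct_within_band(predicted_aphv, observed_aphv, band: float = 0.5) -> float:
    """Percentage of predictions within ``band`` years of observed APHV.

    Boundary inclusive: a difference of exactly +/- ``band`` counts as a hit.
    """
    pred = np.asarray(predicted_aphv, dtype=float)
    obs = np.asarray(observed_aphv, dtype=float)
    if pred.size == 0:
        raise ValueError("pct_within_band requires at least one pair")
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed arrays must match in shape")
    return 100.0 * float(np.mean(np.abs(pred - obs) <= band))


def bland_altman(predicted_aphv, observed_aphv) -> AgreementFit:
    """Agreement between predicted and observed APHV.

    Ordinary least squares of the difference ``d = pred - obs`` on the mean
    ``m = (pred + obs)/2`` quantifies proportional bias; limits of agreement
    are ``mean(d) +/- 1.96 sd(d)`` (sd with n-1 denominator).
    """
    pred = np.asarray(predicted_aphv, dtype=float)
    obs = np.asarray(observed_aphv, dtype=float)
    if pred.size < 3:
        raise ValueError("Bland-Altman regression requires at least 3 pairs")
    d = pred - obs
    m = 0.5 * (pred + obs)
    mbar = m.mean()
    var_m = float(np.sum((m - mbar) ** 2))
    if var_m == 0.0:
        slope = 0.0
    else:
        slope = float(np.sum((m - mbar) * (d - d.mean())) / var_m)
    intercept = float(d.mean() - slope * mbar)
    sd_d = float(np.std(d, ddof=1))
    mean_d = float(d.mean())
    return AgreementFit(
        intercept=intercept,
        slope=slope,
        mean_diff=mean_d,
        sd_diff=sd_d,
        loa_low=mean_d - 1.96 * sd_d,
        loa_high=mean_d + 1.96 * sd_d,
        n=int(pred.size),
    )


def intra_individual_spread(
    visits: pd.DataFrame, equations: list[str]
) -> pd.DataFrame:
    """Min, max and range of predicted APHV across each subject's visits.

    Single-visit subjects get range 0 and ``low_information = True``.
    """
    rows = []
    for sid, sub in visits.groupby("subject_id", sort=True):
        for eq in equations:
            col = f"aphv_{eq}"
            if col not in sub:
                continue
            vals = sub[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            rows.append(
                {
                    "subject_id": sid,
                    "equation": eq,
                    "n_visits": int(vals.size),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "range": float(vals.max() - vals.min()),
                    "low_information": bool(vals.size < 2),
                }
            )
    return pd.DataFrame(rows)


def _ba_by_bin(visits: pd.DataFrame, equations: list[str], bin_col: str) -> pd.DataFrame:
    rows = []
    df = visits[visits[bin_col].notna()]
    for bin_id, sub in df.groupby(bin_col, sort=True):
        obs = sub["observed_aphv"].to_numpy(dtype=float)
        for eq in equations:
            pred = sub[f"aphv_{eq}"].to_numpy(dtype=float)
            ok = np.isfinite(pred)
            if ok.sum() < 3:
                continue
            fitres = bland_altman(pred[ok], obs[ok])
            rows.append(
                {
                    "bin": int(bin_id),
                    "equation": eq,
                    "n": fitres.n,
                    "intercept": fitres.intercept,
                    "slope": fitres.slope,
                    "mean_diff": fitres.mean_diff,
                    "loa_low": fitres.loa_low,
                    "loa_high": fitres.loa_high,
                }
            )
    return pd.DataFrame(rows)


def _hit_rates(visits: pd.DataFrame, equations: list[str], bin_col: str,
               band: float) -> pd.DataFrame:
    rows = []
    df = visits[visits[bin_col].notna()]
    for (bin_id, cls), sub in df.groupby([bin_col, "maturity_class"], sort=True):
        obs = sub["observed_aphv"].to_numpy(dtype=float)
        for eq in equations:
            pred = sub[f"aphv_{eq}"].to_numpy(dtype=float)
            ok = np.isfinite(pred)
            if not ok.any():
                continue
            rows.append(
                {
                    "bin": int(bin_id),
                    "maturity_class": cls,
                    "equation": eq,
                    "n": int(ok.sum()),
                    "pct_within": pct_within_band(pred[ok], obs[ok], band=band),
                }
            )
    return pd.DataFrame(rows)


def run_validation(
    visits: pd.DataFrame,
    band_maturity: float = 1.0,
    band_hit: float = 0.5,
    equations: dict | None = None,
    fit_random_state: int = 0,
    bootstrap_se: bool = False,
    n_bootstrap: int = 200,
) -> ValidationReport:
    """End-to-end validation of the offset equations on a longitudinal cohort.

    Fits PB1 to each subject's serial heights (all visits, including
    duplicates — more data helps the fit), extracts observed APHV, excludes
    subjects whose fit did not converge or whose APHV falls outside their
    measurement span, dedupes visits within age classes, applies each
    sex-appropriate equation, then assembles every summary of the battery.

    ``equations`` optionally replaces the published equations with arbitrary
    callables ``{name: fn(visits_df) -> offset array}`` applied to all
    subjects — useful for oracle checks such as predicted == observed.
    """
    fits = fit_cohort(visits, random_state=fit_random_state)
    usable = fits[fits["converged"] & fits["aphv_in_span"]]
    exclusions = {
        "n_subjects": int(len(fits)),
        "not_converged": int((~fits["converged"]).sum()),
        "aphv_out_of_span": int((fits["converged"] & ~fits["aphv_in_span"]).sum()),
        "analysed": int(len(usable)),
    }

    obs_map = usable.set_index("subject_id")["aphv"]
    v = visits[visits["subject_id"].isin(obs_map.index)].copy()
    v["observed_aphv"] = v["subject_id"].map(obs_map)
    v = dedupe_age_class(v)

    sex_mean_aphv = {
        sex: float(usable.loc[usable["sex"] == sex, "aphv"].mean())
        for sex in ("M", "F")
        if (usable["sex"] == sex).any()
    }
    v["maturity_class"] = [
        classify_maturity(a, sex_mean_aphv[s], band=band_maturity).category
        for a, s in zip(v["observed_aphv"], v["sex"])
    ]
    v["bin_ca"] = ca_group(v["age_years"].to_numpy())
    v["bin_phv"] = phv_bin(v["age_years"].to_numpy(), v["observed_aphv"].to_numpy())

    if equations is None:
        v = predict_cohort(v)
        eq_by_sex = {s: list(EQUATIONS_BY_SEX[s]) for s in ("M", "F")}
    else:
        for name, fn in equations.items():
            v[f"offset_{name}"] = np.asarray(fn(v), dtype=float)
            v[f"aphv_{name}"] = v["age_years"] - v[f"offset_{name}"]
        eq_by_sex = {s: list(equations) for s in ("M", "F")}

    ca_tables, phv_tables = {}, {}
    ba_ca_parts, ba_phv_parts, hit_ca_parts, hit_phv_parts, spread_parts = (
        [], [], [], [], []
    )
    for sex in ("M", "F"):
        sub = v[v["sex"] == sex]
        if sub.empty:
            continue
        eqs = eq_by_sex[sex]
        nboot = n_bootstrap if bootstrap_se else 0
        boot_rng = np.random.default_rng(fit_random_state)
        ca_tables[sex] = summarize_by_bin(
            sub, eqs, bin_kind="ca", n_bootstrap=nboot, rng=boot_rng
        )
        phv_tables[sex] = summarize_by_bin(
            sub, eqs, bin_kind="phv", n_bootstrap=nboot, rng=boot_rng
        )
        for name, parts, bin_col in (
            ("ba_ca", ba_ca_parts, "bin_ca"),
            ("ba_phv", ba_phv_parts, "bin_phv"),
        ):
            t = _ba_by_bin(sub, eqs, bin_col)
            if not t.empty:
                t.insert(0, "sex", sex)
                parts.append(t)
        for parts, bin_col in ((hit_ca_parts, "bin_ca"), (hit_phv_parts, "bin_phv")):
            t = _hit_rates(sub, eqs, bin_col, band=band_hit)
            if not t.empty:
                t.insert(0, "sex", sex)
                parts.append(t)
        sp = intra_individual_spread(sub, eqs)
        if not sp.empty:
            sp.insert(0, "sex", sex)
            spread_parts.append(sp)

    def _cat(parts):
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()

    return ValidationReport(
        fits=fits,
        visits=v,
        ca_tables=ca_tables,
        phv_tables=phv_tables,
        hit_rate_ca=_cat(hit_ca_parts),
        hit_rate_phv=_cat(hit_phv_parts),
        ba_ca=_cat(ba_ca_parts),
        ba_phv=_cat(ba_phv_parts),
        spread=_cat(spread_parts),
        sex_mean_aphv=sex_mean_aphv,
        exclusions=exclusions,
    )
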