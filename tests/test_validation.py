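"""Binning rules, maturity classes, agreement statistics, end-to-end runner."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phvkit.validation import (
    bland_altman,
    ca_group,
    classify_maturity,
    dedupe_age_class,
    intra_individual_spread,
    pct_within_band,
    phv_bin,
    run_validation,
    summarize_by_bin,
)


class TestCaGroup:
    @pytest.mark.parametrize(
        "age, group",
        [(7.50, 8), (8.49, 8), (8.50, 9), (14.0, 14), (17.49, 17), (7.49, 7)],
    )
    def test_midpoint_rule_endpoints(self, age, group):
        assert ca_group(age) == group

    @given(st.floats(6.0, 19.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_tiles_the_line(self, age):
        g = ca_group(age)
        assert g - 0.5 <= age < g + 0.5


class TestPhvBin:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (-1.0, -1), (0.50, 1), (-0.50, 0), (0.49, 0), (-3.50, -3),
            (3.49, 3), (-1.51, -2), (1.49, 1),
        ],
    )
    def test_printed_range_endpoints(self, x, expected):
        assert phv_bin(12.0 + x, 12.0) == expected

    @pytest.mark.parametrize("x", [3.6, -3.51, 4.0, 5.5])
    def test_outside_window_excluded(self, x):
        assert phv_bin(12.0 + x, 12.0) is None

    def test_vectorised_nan_for_excluded(self):
        out = phv_bin(np.array([11.0, 16.0]), np.array([12.0, 12.0]))
        assert out[0] == -1 and np.isnan(out[1])


class TestMaturityClass:
    def test_early_boys(self):
        assert classify_maturity(12.5, 14.06).category == "early"

    def test_late_girls(self):
        assert classify_maturity(13.0, 11.89).category == "late"

    def test_centre_and_inclusive_edges(self):
        assert classify_maturity(14.06, 14.06).category == "average"
        assert classify_maturity(13.06, 14.06).category == "average"
        assert classify_maturity(15.06, 14.06).category == "average"

    @given(
        aphv=st.floats(9.0, 18.0),
        mean=st.floats(11.0, 15.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_partition(self, aphv, mean):
        cls = classify_maturity(aphv, mean)
        assert cls.category in {"early", "average", "late"}
        assert cls.lower == pytest.approx(mean - 1.0)
        assert cls.upper == pytest.approx(mean + 1.0)
        # exactly one class fits
        inside = cls.lower <= aphv <= cls.upper
        assert (cls.category == "average") == inside


class TestDedupe:
    def _visits(self, ages):
        return pd.DataFrame(
            {
                "subject_id": "s1",
                "sex": "M",
                "age_years": ages,
                "stature_cm": np.linspace(150, 160, len(ages)),
            }
        )

    def test_keeps_nearest_to_midpoint(self):
        out = dedupe_age_class(self._visits([13.95, 14.40]))
        assert out["age_years"].tolist() == [13.95]

    def test_no_duplicates_identity(self):
        v = self._visits([13.0, 14.0, 15.0])
        out = dedupe_age_class(v)
        assert out["age_years"].tolist() == [13.0, 14.0, 15.0]

    def test_exact_tie_keeps_earlier(self):
        out = dedupe_age_class(self._visits([13.8, 14.2]))
        assert out["age_years"].tolist() == [13.8]


class TestSummaries:
    def _frame(self):
        return pd.DataFrame(
            {
                "subject_id": ["a", "b", "c"],
                "age_years": [13.9, 14.1, 14.4],
                "observed_aphv": [14.0, 13.5, 15.0],
                "offset_eq": [0.1, 0.5, -0.2],
                "aphv_eq": [13.8, 13.6, 14.6],
                "bin_ca": [14, 14, 14],
                "maturity_class": ["average"] * 3,
            }
        )

    def test_hand_computed_three_visit_fixture(self):
        t = summarize_by_bin(self._frame(), ["eq"], bin_kind="ca")
        assert len(t) == 1
        row = t.iloc[0]
        assert row["n"] == 3
        assert row["offset_mean"] == pytest.approx(np.mean([0.1, 0.5, -0.2]))
        assert row["offset_sd"] == pytest.approx(np.std([0.1, 0.5, -0.2], ddof=1))
        # actual offset = age - observed APHV
        assert row["actual_offset_mean"] == pytest.approx(
            np.mean([-0.1, 0.6, -0.6])
        )
        # linearity of means: mean(pred) - mean(obs) = mean(diff)
        assert row["pred_aphv_mean"] - row["obs_aphv_mean"] == pytest.approx(
            row["diff_mean"]
        )

    def test_bootstrap_se_tracks_analytic_se(self):
        rng = np.random.default_rng(4)
        n = 200
        f = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "age_years": 14.0,
                "observed_aphv": rng.normal(14.0, 1.0, n),
                "offset_eq": 0.0,
                "aphv_eq": rng.normal(14.2, 0.5, n),
                "bin_ca": 14,
                "maturity_class": "average",
            }
        )
        t = summarize_by_bin(f, ["eq"], bin_kind="ca", n_bootstrap=500,
                             rng=np.random.default_rng(5))
        row = t.iloc[0]
        analytic = row["diff_sd"] / np.sqrt(n)
        assert row["diff_se"] == pytest.approx(analytic, rel=0.2)

    def test_singleton_bin_has_no_sd(self):
        f = self._frame().iloc[:1]
        t = summarize_by_bin(f, ["eq"], bin_kind="ca")
        assert t.iloc[0]["n"] == 1
        assert np.isnan(t.iloc[0]["offset_sd"])


class TestPctWithinBand:
    def test_perfect_agreement(self):
        assert pct_within_band([14.0, 12.0], [14.0, 12.0]) == 100.0

    def test_boundary_inclusive_enumeration(self):
        pred = np.array([14.2, 13.4, 14.5])
        obs = np.array([14.0, 14.0, 14.0])
        assert pct_within_band(pred, obs) == pytest.approx(200.0 / 3.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pct_within_band([], [])


class TestBlandAltman:
    def test_constant_difference(self):
        obs = np.array([10.0, 12.0, 14.0])
        fit = bland_altman(obs + 0.3, obs)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.3, abs=1e-12)
        assert fit.loa_low == pytest.approx(0.3) and fit.loa_high == pytest.approx(0.3)

    def test_closed_form_three_point_fixture(self):
        # (m, d) = (10, 0.2), (12, 0.0), (14, -0.2) -> slope -0.1, intercept 1.2
        pred = np.array([10.1, 12.0, 13.9])
        obs = np.array([9.9, 12.0, 14.1])
        fit = bland_altman(pred, obs)
        assert fit.slope == pytest.approx(-0.1, abs=1e-12)
        assert fit.intercept == pytest.approx(1.2, abs=1e-12)
        assert fit.loa_low <= fit.mean_diff <= fit.loa_high

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([14.0, 13.0], [14.0, 13.0])

    def test_slope_zero_under_independent_noise(self):
        # unbiased prediction with small independent error: no proportional
        # bias beyond Monte-Carlo fluctuation
        rng = np.random.default_rng(8)
        obs = rng.normal(14.0, 1.1, 4000)
        pred = obs + rng.normal(0.0, 0.1, 4000)
        assert abs(bland_altman(pred, obs).slope) < 0.02
        # two equally noisy measures of the same truth: slope exactly 0 in
        # expectation
        a = obs + rng.normal(0.0, 0.4, 4000)
        b = obs + rng.normal(0.0, 0.4, 4000)
        assert abs(bland_altman(a, b).slope) < 0.05


class TestSpread:
    def _frame(self, values):
        return pd.DataFrame(
            {
                "subject_id": ["s"] * len(values),
                "aphv_eq": values,
            }
        )

    def test_constant_predictions(self):
        t = intra_individual_spread(self._frame([14.0, 14.0, 14.0]), ["eq"])
        assert t.iloc[0]["range"] == 0.0
        assert not t.iloc[0]["low_information"]

    def test_arithmetic_fixture(self):
        t = intra_individual_spread(self._frame([13.2, 13.9, 14.6]), ["eq"])
        assert t.iloc[0]["range"] == pytest.approx(1.4)

    def test_single_visit_flagged(self):
        t = intra_individual_spread(self._frame([13.2]), ["eq"])
        assert t.iloc[0]["range"] == 0.0
        assert bool(t.iloc[0]["low_information"])


class TestRunValidation:
    def test_null_case_oracle_equations(self, small_cohort):
        # predicted == observed: differences 0, hit rates 100, slopes 0
        _, visits, _ = small_cohort
        rep = run_validation(
            visits,
            equations={"oracle": lambda df: df["age_years"] - df["observed_aphv"]},
        )
        for sex, table in rep.ca_tables.items():
            assert np.allclose(table["diff_mean"], 0.0, atol=1e-9)
        assert np.allclose(rep.hit_rate_ca["pct_within"], 100.0)
        assert np.allclose(rep.hit_rate_phv["pct_within"], 100.0)
        assert np.allclose(rep.ba_ca["slope"], 0.0, atol=1e-9)
        assert np.allclose(rep.ba_phv["slope"], 0.0, atol=1e-9)

    def test_partition_and_uniqueness(self, small_cohort):
        _, visits, _ = small_cohort
        rep = run_validation(visits)
        v = rep.visits
        # every subject in exactly one maturity class
        per_subject = v.groupby("subject_id")["maturity_class"].nunique()
        assert (per_subject == 1).all()
        assert set(v["maturity_class"]) <= {"early", "average", "late"}
        # at most one visit per (subject, CA group) after deduplication
        counts = v.groupby(["subject_id", "bin_ca"]).size()
        assert (counts == 1).all()

    def test_exclusion_bookkeeping(self, small_cohort):
        _, visits, _ = small_cohort
        rep = run_validation(visits)
        ex = rep.exclusions
        assert ex["n_subjects"] == 80
        assert (
            ex["analysed"] + ex["not_converged"] + ex["aphv_out_of_span"]
            == ex["n_subjects"]
        )
        assert rep.visits["subject_id"].nunique() == ex["analysed"]

    def test_variance_compression_single_cohort(self, small_cohort):
        _, visits, _ = small_cohort
        rep = run_validation(visits)
        for sex in ("M", "F"):
            t = rep.ca_tables[sex]
            big = t[t["n"] >= 20]
            assert (big["pred_aphv_sd"] < big["obs_aphv_sd"]).all()
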