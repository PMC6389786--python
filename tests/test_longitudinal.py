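"""Tests of annualisation, transforms and the GEE progression models."""

import numpy as np
import pandas as pd
import pytest

from circlegait.longitudinal import (
    annualize,
    apply_transforms,
    between_subject_sd,
    fit_progression_gee,
    percent_annual_change,
    regress_on_updrs,
)
from circlegait.simulate import CohortParams, generate_cohort


def visits_frame(records):
    return pd.DataFrame(records, columns=["subject_id", "visit", "value"])


class TestAnnualize:
    def test_two_visits_average(self):
        v = visits_frame([("s1", 1, 10.0), ("s1", 2, 12.0)])
        out = annualize(v, ["value"])
        assert out.loc[0, "value"] == 11.0
        assert out.loc[0, "year"] == 0

    def test_single_missed_visit_uses_remaining(self):
        v = visits_frame([("s1", 1, 10.0), ("s1", 2, 12.0), ("s1", 4, 8.0)])
        out = annualize(v, ["value"])
        assert out.loc[out["year"] == 1, "value"].iloc[0] == 8.0

    def test_fully_missed_year_has_no_row(self):
        v = visits_frame([("s1", 1, 10.0), ("s1", 2, 12.0), ("s1", 5, 7.0)])
        out = annualize(v, ["value"])
        assert set(out["year"]) == {0, 2}

    def test_duplicate_visits_abort(self):
        v = visits_frame([("s1", 1, 10.0), ("s1", 1, 11.0)])
        with pytest.raises(ValueError, match="duplicate"):
            annualize(v, ["value"])

    def test_idempotent_on_annual_data(self):
        v = visits_frame([("s1", 1, 10.0), ("s1", 3, 12.0), ("s2", 1, 5.0)])
        once = annualize(v, ["value"])
        again = annualize(once.assign(visit=once["year"] * 2 + 1), ["value"])
        pd.testing.assert_frame_equal(once, again)


def _cohort(seed=0, **over):
    base = dict(
        n_per_group={"HC": 25, "EarlyPD": 25, "MidPD": 0},
        n_years=5,
        baseline_mean={"f1": {"HC": 1.0, "EarlyPD": 1.0, "MidPD": 1.0}},
        annual_slope={"f1": {"HC": 0.0, "EarlyPD": 0.0, "MidPD": 0.0}},
        between_subject_sd={"f1": 1.0},
        residual_sd={"f1": 0.5},
        features=("f1",),
        seed=seed,
    )
    base.update(over)
    return generate_cohort(CohortParams(**base))


class TestTransforms:
    def test_symmetric_feature_is_not_logged(self):
        tab = _cohort(seed=1)
        out, spec = apply_transforms(tab, ["f1"])
        assert spec.log_applied["f1"] is False
        assert spec.log_offset["f1"] == 0.0

    def test_subject_means_standardised(self):
        tab = _cohort(seed=2)
        out, _ = apply_transforms(tab, ["f1"])
        means = out.groupby("subject_id")["f1"].mean()
        assert means.mean() == pytest.approx(0.0, abs=1e-9)
        assert means.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_negative_skewed_feature_gets_offset(self):
        rng = np.random.default_rng(3)
        x = np.maximum(rng.lognormal(0, 1, 200) - 3.0, -2.0)  # right skew, min pinned
        x[np.argmin(x)] = -2.0  # ensure the minimum is exactly -2
        tab = pd.DataFrame({"subject_id": np.repeat(np.arange(50), 4), "f1": x})
        out, spec = apply_transforms(tab, ["f1"])
        assert spec.log_applied["f1"] is True
        assert spec.log_offset["f1"] == pytest.approx(3.0)

    def test_zero_between_subject_variance_skipped(self):
        tab = pd.DataFrame({"subject_id": ["a", "a", "b", "b"], "f1": [1.0, 1.0, 1.0, 1.0]})
        out, spec = apply_transforms(tab, ["f1"])
        assert "f1" in spec.skipped


class TestProgressionGee:
    def test_planted_interaction_recovered(self):
        ests = []
        for seed in range(30):
            tab = _cohort(seed=seed, annual_slope={"f1": {"HC": 0.0, "EarlyPD": 0.10, "MidPD": 0.0}})
            fit = fit_progression_gee(tab.drop(columns=["age", "medication", "updrs_gait"]),
                                      "early", "f1")
            ests.append(fit.params["group_time"])
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.10) < 2 * mc_se + 1e-9

    def test_zero_correlation_matches_independence(self):
        tab = _cohort(seed=3, between_subject_sd={"f1": 0.0},
                      retention_by_year=(1.0,) * 5)
        tab = tab.drop(columns=["age", "medication", "updrs_gait"])
        fe = fit_progression_gee(tab, "early", "f1")
        fi = fit_progression_gee(tab, "early", "f1", exchangeable=False)
        for k in fe.params:
            assert fe.params[k] == pytest.approx(fi.params[k], abs=1e-6)

    def test_pvalues_valid_and_shift_invariant(self):
        tab = _cohort(seed=4)
        fit = fit_progression_gee(tab, "early", "f1")
        assert all(0.0 <= p <= 1.0 for p in fit.pvalues.values())
        shifted = tab.assign(f1=tab["f1"] + 100.0)
        fit2 = fit_progression_gee(shifted, "early", "f1")
        for k in ("group_ind", "time", "group_time"):
            assert fit.robust_se[k] == pytest.approx(fit2.robust_se[k], rel=1e-6)
        scaled = tab.assign(f1=tab["f1"] * 3.0)
        fit3 = fit_progression_gee(scaled, "early", "f1")
        for k in ("group_ind", "time", "group_time"):
            assert fit3.params[k] == pytest.approx(3.0 * fit.params[k], rel=1e-6)

    def test_strong_confounder_retained_noise_dropped(self):
        tab = _cohort(seed=5, confounder_effects={"f1": {"age": 0.2, "medication": 0.0,
                                                         "total_duration": 0.0}})
        fit = fit_progression_gee(tab.drop(columns=["updrs_gait"]), "early", "f1")
        assert "age" in fit.retained_confounders
        assert "medication" not in fit.retained_confounders

    def test_missing_group_aborts(self):
        tab = _cohort(seed=6)
        with pytest.raises(ValueError):
            fit_progression_gee(tab, "mid", "f1")


class TestAnnualChange:
    def test_noise_free_slope_over_baseline(self):
        years = np.arange(5)
        rows = []
        for s in range(8):
            for y in years:
                rows.append({"subject_id": f"s{s}", "group": "EarlyPD", "year": y,
                             "f1": 100.0 * (1 - 0.02 * y)})
        ch = percent_annual_change(pd.DataFrame(rows), "EarlyPD", "f1")
        assert ch.percent_per_year == pytest.approx(-2.0, abs=1e-9)

    def test_flat_trajectory_is_null(self):
        rows = [{"subject_id": f"s{s}", "group": "HC", "year": y, "f1": 5.0}
                for s in range(6) for y in range(5)]
        ch = percent_annual_change(pd.DataFrame(rows), "HC", "f1")
        assert ch.percent_per_year == pytest.approx(0.0, abs=1e-12)
        assert ch.p_value == pytest.approx(1.0)

    def test_zero_baseline_mean_aborts(self):
        rows = [{"subject_id": f"s{s}", "group": "HC", "year": y, "f1": 0.0 + y}
                for s in range(6) for y in range(3)]
        with pytest.raises(ValueError, match="first-year mean"):
            percent_annual_change(pd.DataFrame(rows), "HC", "f1")


class TestUpdrsRegression:
    def test_shared_severity_gives_positive_slope(self):
        hits = 0
        for seed in range(10):
            tab = generate_cohort(CohortParams(
                n_per_group={"HC": 20, "EarlyPD": 20, "MidPD": 20},
                baseline_mean={"f1": {g: 1.0 for g in ("HC", "EarlyPD", "MidPD")}},
                annual_slope={"f1": {g: 0.0 for g in ("HC", "EarlyPD", "MidPD")}},
                between_subject_sd={"f1": 0.3}, residual_sd={"f1": 0.3},
                severity_loading={"f1": 0.5}, features=("f1",), seed=seed))
            zt, _ = apply_transforms(tab, ["f1"])
            fit = regress_on_updrs(zt, "f1")
            est, _, p = fit.term("updrs_gait")
            if est > 0 and p < 0.05:
                hits += 1
        assert hits >= 9

    def test_constant_rating_aborts(self):
        tab = _cohort(seed=7).assign(updrs_gait=1.0)
        with pytest.raises(ValueError):
            regress_on_updrs(tab, "f1")


def test_between_subject_sd_definition():
    df = pd.DataFrame({"s": ["a", "a", "b", "b", "c", "c"], "v": [1.0, 3.0, 4.0, 6.0, 7.0, 9.0]})
    # subject means 2, 5, 8 -> SD 3
    assert between_subject_sd(df["v"], df["s"]) == pytest.approx(3.0)
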