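"""Correlation and median-split statistics linking fatigue to daily risk."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fatiguerisk.association import (
    build_records,
    correlate,
    median_split_test,
    run_association,
)


class TestCorrelate:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = correlate(x, 2.0 * x + 1.0)
        assert res.r == pytest.approx(1.0)
        assert res.n == 10

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert correlate(x, y).r == pytest.approx(correlate(y, x).r)
        assert correlate(3.0 * x + 7.0, y).r == pytest.approx(correlate(x, y).r)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(1)
        res = correlate(rng.normal(size=5000), rng.normal(size=5000))
        assert abs(res.r) < 0.05

    def test_pairwise_complete_filtering(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, np.nan, 10.0])
        res = correlate(x, y)
        assert res.n == 3 and res.r == pytest.approx(1.0)

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError, match="3"):
            correlate([1.0, 2.0], [3.0, 4.0])

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            correlate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestMedianSplit:
    def test_median_arithmetic_and_tie_to_low(self):
        comp = median_split_test([10.0, 20.0, 30.0, 40.0], [1.0, 2.0, 3.0, 4.0])
        assert comp.threshold == 2.5
        assert (comp.n_low, comp.n_high) == (2, 2)
        assert comp.mean_low == 15.0 and comp.mean_high == 35.0

    def test_welch_reduces_to_student_for_equal_variances(self):
        lo, hi = [1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]
        comp = median_split_test(lo + hi, [0.0] * 4 + [1.0] * 4)
        t_student, p_student = stats.ttest_ind(hi, lo, equal_var=True)
        assert comp.t == pytest.approx(t_student)
        assert comp.p == pytest.approx(p_student)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(2)
        split = np.concatenate([np.zeros(200), np.ones(200)])
        values = np.concatenate([rng.normal(0, 1, 200), rng.normal(1, 1, 200)])
        comp = median_split_test(values, split)
        assert comp.p < 0.05
        assert np.isfinite(comp.shapiro_p_high)

    def test_degenerate_split_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split_test([1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 2.0])

    def test_too_small_groups_are_error(self):
        with pytest.raises(ValueError, match="2 records"):
            median_split_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def _tables(n_days=6, vas_values=None, r_values=None, wt=8.0):
    dates = pd.date_range("2019-04-01", periods=n_days).strftime("%Y-%m-%d")
    hrv_rows, vas_rows, daily_rows = [], [], []
    for i, date in enumerate(dates):
        for cond in ("pre_shift", "post_shift"):
            hrv_rows.append(
                {
                    "driver_id": "D1",
                    "date": date,
                    "condition": cond,
                    "n_beats": 110,
                    "accepted": True,
                    "lf_power": 400.0 + 10 * i,
                    "hf_power": 300.0,
                    "lf_hf": (400.0 + 10 * i) / 300.0,
                    "rri_average": 850.0,
                    "lf_score": 50.0 + i + (5 if cond == "post_shift" else 0),
                }
            )
            vas_rows.append(
                {
                    "driver_id": "D1",
                    "date": date,
                    "condition": cond,
                    "vas": vas_values[i] if vas_values else 40.0 + 3 * i,
                }
            )
        daily_rows.append(
            {
                "driver_id": "D1",
                "date": date,
                "R": r_values[i] if r_values else 2 + i,
                "wt_hours": wt if np.isscalar(wt) else wt[i],
                "r_1hr": np.nan,
                "included": True,
                "n_events": 5 + i,
            }
        )
    daily = pd.DataFrame(daily_rows)
    daily["included"] = daily["wt_hours"] >= 3.0
    daily["r_1hr"] = np.where(daily["included"], daily["R"] / daily["wt_hours"], np.nan)
    return pd.DataFrame(hrv_rows), daily, pd.DataFrame(vas_rows)


class TestBuildRecords:
    def test_joined_row_count_and_lags(self):
        hrv_t, daily, vas = _tables()
        rec = build_records(hrv_t, daily, vas)
        assert len(rec) == 6
        # previous-calendar-day post-shift score appears from day 2 onward
        assert rec["lf_score_post_prev"].isna().sum() == 1
        day2 = rec[rec["date"] == "2019-04-02"].iloc[0]
        assert day2["lf_score_post_prev"] == pytest.approx(55.0)

    def test_gap_in_dates_yields_null_lag(self):
        hrv_t, daily, vas = _tables()
        keep = daily["date"] != "2019-04-02"
        rec = build_records(
            hrv_t[hrv_t["date"] != "2019-04-02"], daily[keep], vas[vas["date"] != "2019-04-02"]
        )
        assert np.isnan(rec.loc[rec["date"] == "2019-04-03", "lf_score_post_prev"].iloc[0])

    def test_duplicate_keys_rejected(self):
        hrv_t, daily, vas = _tables()
        with pytest.raises(ValueError, match="duplicate"):
            build_records(hrv_t, pd.concat([daily, daily.iloc[:1]]), vas)

    def test_vas_invariant_driver_flagged(self):
        hrv_t, daily, vas = _tables(vas_values=[50.0] * 6)
        rec = build_records(hrv_t, daily, vas)
        assert rec["exclude_vas_invariant"].all()
        assert not rec["analysis_ok"].any()

    def test_never_warned_driver_flagged(self):
        hrv_t, daily, vas = _tables(r_values=[0] * 6)
        daily = daily.assign(n_events=0)
        rec = build_records(hrv_t, daily, vas)
        assert rec["exclude_never_warned"].all()

    def test_disjoint_dates_give_empty_join(self):
        hrv_t, daily, vas = _tables()
        vas_shift = vas.copy()
        vas_shift["date"] = (
            pd.to_datetime(vas["date"]) + pd.Timedelta(days=365)
        ).dt.strftime("%Y-%m-%d")
        assert len(build_records(hrv_t, daily, vas_shift)) == 0

    def test_short_days_not_analysis_ok(self):
        hrv_t, daily, vas = _tables(wt=[8.0, 2.0, 8.0, 8.0, 2.5, 8.0])
        rec = build_records(hrv_t, daily, vas)
        assert (~rec.loc[rec["wt_hours"] < 3.0, "analysis_ok"]).all()

    def test_rejected_recordings_leave_nulls(self):
        hrv_t, daily, vas = _tables()
        hrv_t.loc[
            (hrv_t["date"] == "2019-04-01") & (hrv_t["condition"] == "pre_shift"),
            "accepted",
        ] = False
        rec = build_records(hrv_t, daily, vas)
        assert np.isnan(rec.loc[rec["date"] == "2019-04-01", "lf_score_pre"].iloc[0])


def test_run_association_reports_all_study_statistics(score_cohort):
    _, data = score_cohort
    hrv_rows = []
    for _, row in data.daily.iterrows():
        for cond, suffix in (("pre_shift", "pre"), ("post_shift", "post")):
            hrv_rows.append(
                {
                    "driver_id": row["driver_id"],
                    "date": row["date"],
                    "condition": cond,
                    "n_beats": 110,
                    "accepted": True,
                    "lf_power": 400.0,
                    "hf_power": 300.0,
                    "lf_hf": row[f"lf_hf_{suffix}"],
                    "rri_average": 850.0,
                    "lf_score": row[f"lf_score_{suffix}"],
                }
            )
    daily = data.daily[["driver_id", "date", "R", "wt_hours", "r_1hr", "included", "n_events"]]
    rec = build_records(pd.DataFrame(hrv_rows), daily, data.vas)
    results = run_association(rec)
    assert set(results["correlations"]) >= {"vas_pre", "lf_score_pre", "lf_score_post_prev"}
    assert results["n_tests"] == len(results["correlations"]) + 1
    comp = results["group_comparison"]
    assert comp["n_high"] + comp["n_low"] <= results["n_records"]
    # only analysis-eligible records enter any statistic
    ok = rec[rec["analysis_ok"]]
    pair = ok[["lf_score_pre", "r_1hr"]].dropna()
    assert results["correlations"]["lf_score_pre"]["n"] == len(pair)
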