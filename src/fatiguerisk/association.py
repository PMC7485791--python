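"""Statistical linkage between fatigue indices and daily collision risk.

Builds per-driver-day analysis records by joining the HRV, daily-risk and
VAS streams (with the study's exclusion rules), then runs:

* Pearson correlations of each fatigue index (VAS, LF deviation score,
  LF/HF — same-day pre/post and previous-day post-shift lags) against the
  daily collision risk index ``R_1hr``;
* Shapiro–Wilk normality screening per group;
* a median split of ``R_1hr`` into high-/low-risk groups compared with
  Welch's unequal-variance t-test at a 5% significance level.

No multiple-testing correction is applied; the result object annotates the
number of tests performed so readers can apply their own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "build_records",
    "correlate",
    "median_split_test",
    "run_association",
    "ANALYSIS_FIELDS",
]

#: fatigue indices correlated against r_1hr, in reporting order
ANALYSIS_FIELDS: Tuple[str, ...] = (
    "vas_pre",
    "vas_post",
    "lf_score_pre",
    "lf_hf_pre",
    "lf_score_post_prev",
    "lf_hf_post_prev",
)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n": self.n}


@dataclass(frozen=True)
class GroupComparison:
    """High- vs low-risk group contrast after a median split."""

    threshold: float
    n_high: int
    n_low: int
    mean_high: float
    mean_low: float
    sd_high: float
    sd_low: float
    t: float
    p: float
    shapiro_p_high: float
    shapiro_p_low: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-based p-value.

    Pairs with a missing value in either series are dropped first
    (pairwise-complete); at least 3 complete pairs and nonzero variance in
    both series are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


def median_split_test(
    values: Sequence[float], split_values: Sequence[float]
) -> GroupComparison:
    """Welch's t-test between groups split at the median of ``split_values``.

    The high group takes records strictly above the median; ties at the
    threshold go to the low group.  Shapiro–Wilk p-values are reported per
    group but never gate the t-test.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(split_values, dtype=float)
    if v.shape != s.shape:
        raise ValueError("values and split_values lengths differ")
    keep = np.isfinite(v) & np.isfinite(s)
    v, s = v[keep], s[keep]
    if s.size and np.ptp(s) == 0:
        raise ValueError("degenerate split: all split values identical")
    thr = float(np.median(s))
    hi, lo = v[s > thr], v[s <= thr]
    if hi.size < 2 or lo.size < 2:
        raise ValueError("need at least 2 records on each side of the split")
    t, p = stats.ttest_ind(hi, lo, equal_var=False)
    return GroupComparison(
        threshold=thr,
        n_high=int(hi.size),
        n_low=int(lo.size),
        mean_high=float(hi.mean()),
        mean_low=float(lo.mean()),
        sd_high=float(hi.std(ddof=1)),
        sd_low=float(lo.std(ddof=1)),
        t=float(t),
        p=float(p),
        shapiro_p_high=float(stats.shapiro(hi).pvalue) if hi.size >= 3 else float("nan"),
        shapiro_p_low=float(stats.shapiro(lo).pvalue) if lo.size >= 3 else float("nan"),
    )


def _pivot_condition(df: pd.DataFrame, value_cols: Sequence[str]) -> pd.DataFrame:
    wide = df.pivot_table(
        index=["driver_id", "date"],
        columns="condition",
        values=list(value_cols),
        aggfunc="first",
    )
    wide.columns = [
        f"{val}_{'pre' if cond == 'pre_shift' else 'post'}"
        for val, cond in wide.columns
    ]
    return wide.reset_index()


def build_records(
    hrv_table: pd.DataFrame,
    daily_table: pd.DataFrame,
    vas_table: pd.DataFrame,
) -> pd.DataFrame:
    """Join the three measurement streams into per-driver-day records.

    ``hrv_table`` is long (driver_id, date, condition, accepted, lf_power,
    hf_power, lf_hf, rri_average, lf_score); only accepted recordings
    contribute.  ``daily_table`` carries R / wt_hours / r_1hr / included
    (and optionally n_events, used for the never-warned exclusion).
    ``vas_table`` is long (driver_id, date, condition, vas).

    Rows are the inner join of the three streams on (driver_id, date).
    Previous-day post-shift lags are taken from the previous *calendar*
    date and left null across gaps.  Two driver-level exclusion flags are
    set: drivers whose VAS never varies, and drivers with no warning
    events in the whole study.  Flagged rows and non-included days survive
    in the returned frame but carry ``analysis_ok=False``.
    """
    for name, tbl, keys in (
        ("hrv", hrv_table, ["driver_id", "date", "condition"]),
        ("daily", daily_table, ["driver_id", "date"]),
        ("vas", vas_table, ["driver_id", "date", "condition"]),
    ):
        if tbl.duplicated(subset=keys).any():
            raise ValueError(f"duplicate {keys} keys in {name} table")

    hrv_ok = hrv_table[hrv_table["accepted"].astype(bool)]
    hrv_wide = _pivot_condition(hrv_ok, ["lf_score", "lf_hf"])
    vas_wide = _pivot_condition(vas_table, ["vas"])

    rec = daily_table.merge(hrv_wide, on=["driver_id", "date"], how="inner").merge(
        vas_wide, on=["driver_id", "date"], how="inner"
    )

    # previous-calendar-day post-shift lags (null across gaps)
    lag_cols = [c for c in ("lf_score_post", "lf_hf_post") if c in rec.columns]
    prev = rec[["driver_id", "date", *lag_cols]].copy()
    prev["date"] = (
        pd.to_datetime(prev["date"]) + pd.Timedelta(days=1)
    ).dt.strftime("%Y-%m-%d")
    prev = prev.rename(columns={c: f"{c}_prev" for c in lag_cols})
    rec = rec.merge(prev, on=["driver_id", "date"], how="left")

    vas_span = vas_table.groupby("driver_id")["vas"].agg(lambda s: s.max() - s.min())
    vas_invariant = set(vas_span.index[vas_span == 0])
    warn_col = "n_events" if "n_events" in daily_table.columns else "R"
    warn_totals = daily_table.groupby("driver_id")[warn_col].sum()
    never_warned = set(warn_totals.index[warn_totals == 0])

    rec["exclude_vas_invariant"] = rec["driver_id"].isin(vas_invariant)
    rec["exclude_never_warned"] = rec["driver_id"].isin(never_warned)
    rec["analysis_ok"] = (
        rec["included"].astype(bool)
        & ~rec["exclude_vas_invariant"]
        & ~rec["exclude_never_warned"]
    )
    return rec


def run_association(records: pd.DataFrame) -> Dict:
    """All study statistics on the analysis-eligible records.

    Returns a JSON-serializable dict: one Pearson correlation of each
    fatigue index against ``r_1hr``, and the median-split Welch comparison
    of previous-day post-shift LF scores between high- and low-risk days.
    """
    ok = records[records["analysis_ok"]] if "analysis_ok" in records.columns else records
    out: Dict = {"correlations": {}, "n_records": int(len(ok))}
    n_tests = 0
    for col in ANALYSIS_FIELDS:
        if col not in ok.columns:
            continue
        pair = ok[[col, "r_1hr"]].dropna()
        if len(pair) < 3 or pair[col].nunique() < 2 or pair["r_1hr"].nunique() < 2:
            continue
        out["correlations"][col] = correlate(pair[col], pair["r_1hr"]).to_dict()
        n_tests += 1
    if "lf_score_post_prev" in ok.columns:
        pair = ok[["lf_score_post_prev", "r_1hr"]].dropna()
        if len(pair) >= 4 and pair["r_1hr"].nunique() > 1:
            out["group_comparison"] = median_split_test(
                pair["lf_score_post_prev"], pair["r_1hr"]
            ).to_dict()
            n_tests += 1
    out["n_tests"] = n_tests
    return out
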