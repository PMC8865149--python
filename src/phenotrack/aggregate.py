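"""Per-visit aggregation: weekly feature vectors, completeness, call logs.

The passive predictor set for each clinician visit is built from the seven
local days strictly preceding the visit date: each of the 14 GPS mobility
features and the accelerometer activity level is averaged separately over
weekdays and weekend days of the window (30 values), and the GPS and
accelerometer missing-minute counts are summed over the whole window
(2 values) — 32 named statistics in a fixed order.

Days with nothing observed contribute nothing to the means (they are not
zeros); only the missing-minute totals encode absence, so sparse windows do
not drag averages toward arbitrary fill values.
"""

from __future__ import annotations

from datetime import date as date_t, timedelta

import numpy as np
import pandas as pd

from .mobility import GPS_FEATURES

#: The 15 daily feature families averaged by day type.
DAILY_FEATURES = GPS_FEATURES + ["activity_level"]

#: Canonical 32-slot weekly feature schema, fixed order.
WEEKLY_FEATURE_COLUMNS = (
    [f"{f}_weekday" for f in DAILY_FEATURES]
    + [f"{f}_weekend" for f in DAILY_FEATURES]
    + ["gps_missing_minutes", "accel_missing_minutes"]
)


def weekly_feature_vector(
    daily: pd.DataFrame,
    visit_date: date_t,
    gps_expected_minutes_per_day: int = 240,
    accel_expected_minutes_per_day: int = 1440,
) -> dict:
    """The 32 passive summary statistics for one visit.

    ``daily`` holds one row per local day with columns ``date``,
    ``is_weekend``, the 14 GPS features, ``activity_level``,
    ``gps_missing_minutes`` and ``accel_missing_minutes``.  The window is
    the 7 days immediately preceding (and excluding) ``visit_date``.  A
    day-type mean is NaN when no day of that type has a value; missing
    minutes for days absent from ``daily`` count as fully missing.
    """
    window = [visit_date - timedelta(days=k) for k in range(7, 0, -1)]
    rows = daily[daily["date"].isin(window)] if len(daily) else daily
    out: dict = {}
    for day_type, wk in (("weekday", False), ("weekend", True)):
        sel = rows[rows["is_weekend"] == wk] if len(rows) else rows
        for f in DAILY_FEATURES:
            vals = sel[f].dropna() if (len(sel) and f in sel) else pd.Series(dtype=float)
            out[f"{f}_{day_type}"] = float(vals.mean()) if len(vals) else np.nan
    present = set(rows["date"]) if len(rows) else set()
    n_absent = sum(1 for d in window if d not in present)
    for col, per_day in (
        ("gps_missing_minutes", gps_expected_minutes_per_day),
        ("accel_missing_minutes", accel_expected_minutes_per_day),
    ):
        observed_sum = float(rows[col].fillna(per_day).sum()) if len(rows) else 0.0
        out[col] = observed_sum + n_absent * per_day
    return {k: out[k] for k in WEEKLY_FEATURE_COLUMNS}


def attach_phq(
    visits: pd.DataFrame, surveys: pd.DataFrame, tz: str = "UTC"
) -> pd.DataFrame:
    """Attach the closest completed self-report survey preceding each visit.

    Eligibility uses the completion timestamp (the score only exists once
    the survey is completed) against the local midnight starting the visit
    day; the latest eligible completion wins.  Visits with no eligible
    survey get a missing predictor.
    """
    done = surveys[surveys["completed"].notna()]
    out = visits.copy()
    phq = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples()):
        visit_ms = pd.Timestamp(row.date, tz=tz).value / 1e6
        mine = done[(done["subject"] == row.subject) & (done["completed"] <= visit_ms)]
        if len(mine):
            phq[i] = float(mine.loc[mine["completed"].idxmax(), "total"])
    out["phq8"] = phq
    return out


def sensor_completeness(
    accel: pd.DataFrame,
    gps: pd.DataFrame,
    window_start_ms: float,
    window_end_ms: float,
    gps_duty_fraction: float = 1.0 / 6.0,
) -> tuple[float, float]:
    """(accelerometer, GPS) completeness proportions for one subject.

    Minutes with at least one sample, divided by the expected minutes: all
    minutes of the window for the accelerometer, and ``gps_duty_fraction``
    of them for the GPS (whose on-cycle covers only that share of time).
    """
    total_min = (window_end_ms - window_start_ms) / 60000.0
    if total_min <= 0:
        raise ValueError("completeness window must be nonempty")

    def observed_minutes(stream: pd.DataFrame) -> int:
        if len(stream) == 0:
            return 0
        t = stream["timestamp"].to_numpy(float)
        t = t[(t >= window_start_ms) & (t < window_end_ms)]
        return len(np.unique((t // 60000.0).astype(np.int64)))

    accel_prop = min(observed_minutes(accel) / total_min, 1.0)
    gps_prop = min(observed_minutes(gps) / (total_min * gps_duty_fraction), 1.0)
    return accel_prop, gps_prop


def survey_completion_rates(
    surveys: pd.DataFrame, deliveries: np.ndarray, subjects: list[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-survey completion rates under the late-completion rule.

    A completion is credited to the latest delivery at or before its
    completion time: completing survey *t* after survey *t+1* went out
    counts for *t+1*, not *t*.  Several completions credited to the same
    delivery count once.  Also returns the per-subject number of weeks with
    at least one credited completion.
    """
    deliveries = np.sort(np.asarray(deliveries, float))
    n_surveys = len(deliveries)
    credited: dict[str, set[int]] = {s: set() for s in subjects}
    done = surveys[surveys["completed"].notna()]
    for row in done.itertuples():
        if row.subject not in credited:
            continue
        idx = int(np.searchsorted(deliveries, row.completed, side="right")) - 1
        if 0 <= idx < n_surveys:
            credited[row.subject].add(idx)
    counts = np.zeros(n_surveys, int)
    for s in subjects:
        for idx in credited[s]:
            counts[idx] += 1
    rates = pd.DataFrame(
        {"survey_index": np.arange(n_surveys), "completion_rate": counts / max(len(subjects), 1)}
    )
    weeks = pd.Series({s: len(credited[s]) for s in subjects}, name="weeks_with_survey")
    return rates, weeks


def comm_log_stats(
    calls: pd.DataFrame,
    demographics: pd.DataFrame,
    window_start_ms: float,
    window_end_ms: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outgoing-call counts and unique dialed numbers over a window.

    Returns one row per subject with call-log data (outgoing count, unique
    numbers, healthy-control status) and a per-group summary with median and
    interquartile range of both statistics.
    """
    subjects = sorted(calls["subject"].unique())
    sel = calls[
        (calls["direction"] == "outgoing")
        & (calls["timestamp"] >= window_start_ms)
        & (calls["timestamp"] < window_end_ms)
    ]
    diag = demographics.set_index("subject")["diagnosis"]
    rows = []
    for s in subjects:
        mine = sel[sel["subject"] == s]
        rows.append(
            dict(subject=s, group="HC" if diag.get(s) == "HC" else "non-HC",
                 outgoing_calls=len(mine),
                 unique_numbers=mine["hashed_number"].nunique())
        )
    per_subject = pd.DataFrame(rows, columns=["subject", "group", "outgoing_calls", "unique_numbers"])
    summaries = []
    for g, gdf in per_subject.groupby("group"):
        for col in ("outgoing_calls", "unique_numbers"):
            q1, q2, q3 = np.percentile(gdf[col], [25, 50, 75]) if len(gdf) else (np.nan,) * 3
            summaries.append(dict(group=g, statistic=col, median=q2, q1=q1, q3=q3, n=len(gdf)))
    return per_subject, pd.DataFrame(summaries, columns=["group", "statistic", "median", "q1", "q3", "n"])


def build_analysis_table(
    visits: pd.DataFrame,
    demographics: pd.DataFrame,
    surveys: pd.DataFrame,
    daily_by_subject: dict[str, pd.DataFrame],
    tz: str = "UTC",
    gps_expected_minutes_per_day: int = 240,
) -> pd.DataFrame:
    """One analysis-ready row per follow-up visit.

    Columns: outcome (clinician total), baseline score, demographics, the
    self-report predictor, and the 32 weekly passive statistics.  Baseline
    visits (index 0) supply the baseline predictor and are not outcome rows.
    """
    visits_phq = attach_phq(visits, surveys, tz=tz)
    baseline = visits.loc[visits["visit_index"] == 0].set_index("subject")["madrs"]
    demo = demographics.set_index("subject")
    rows = []
    for r in visits_phq[visits_phq["visit_index"] >= 1].itertuples():
        daily = daily_by_subject.get(r.subject, pd.DataFrame())
        feats = weekly_feature_vector(
            daily, r.date, gps_expected_minutes_per_day=gps_expected_minutes_per_day
        )
        row = dict(
            subject=r.subject,
            visit_index=r.visit_index,
            madrs=r.madrs,
            baseline_madrs=float(baseline.get(r.subject, np.nan)),
            age=float(demo.loc[r.subject, "age"]),
            sex=demo.loc[r.subject, "sex"],
            diagnosis=demo.loc[r.subject, "diagnosis"],
            phq8=r.phq8,
        )
        row.update(feats)
        rows.append(row)
    return pd.DataFrame(rows)
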