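"""Accelerometer activity scoring.

A minute of a local day is *observed* when enough samples fall in it and
*active* when the standard deviation of the acceleration magnitude
sqrt(x^2 + y^2 + z^2) over the minute exceeds a threshold — at rest the
magnitude sits near 1 g with little variation, while walking or stair use
produces high-variance oscillation.  Daily activity level is the active
fraction of observed minutes, and hourly weekday/weekend curves are ratio
estimators (total active / total observed minutes per hour) so that hours
with more data collection are not overweighted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ActivityConfig


def minute_activity(
    samples: pd.DataFrame,
    tz: str = "UTC",
    config: ActivityConfig | None = None,
) -> pd.DataFrame:
    """Score per-minute activity from a triaxial accelerometer stream.

    ``samples`` has columns ``timestamp`` (UTC ms, sorted), ``x, y, z`` (g).
    Returns one row per observed-or-not minute actually spanned by data,
    with columns ``date`` (local), ``minute`` (0-1439 local minute-of-day),
    ``observed`` and ``active`` (active is pandas NA when unobserved).
    """
    cfg = config or ActivityConfig()
    if len(samples) == 0:
        return pd.DataFrame(columns=["date", "minute", "observed", "active"])
    t = samples["timestamp"].to_numpy(np.int64)
    if np.any(np.diff(t) < 0):
        raise ValueError("accelerometer timestamps must be sorted")
    mag = np.sqrt(
        samples["x"].to_numpy(float) ** 2
        + samples["y"].to_numpy(float) ** 2
        + samples["z"].to_numpy(float) ** 2
    )
    ts = pd.to_datetime(t, unit="ms", utc=True).tz_convert(tz)
    local_date = ts.normalize()
    minute = (ts - local_date).total_seconds() // 60
    df = pd.DataFrame(
        {"date": local_date.date, "minute": minute.astype(int), "mag": mag}
    )
    g = df.groupby(["date", "minute"])["mag"].agg(["count", "std"]).reset_index()
    g["std"] = g["std"].fillna(0.0)
    g["observed"] = g["count"] >= cfg.min_samples
    g["active"] = (g["std"] > cfg.sd_threshold_g).where(g["observed"], other=pd.NA)
    return g[["date", "minute", "observed", "active"]]


def hourly_activity_curve(minutes: pd.DataFrame, weekend: bool | None = None) -> pd.DataFrame:
    """Average hourly activity curve over all days of one day type.

    For hour ``h`` the value is (active observed minutes in hour h across
    days) / (observed minutes in hour h across days): a ratio estimator that
    weights by observation instead of imputing, so duplicating whole days
    leaves the curve unchanged.  Hours with no observed minutes get NaN.

    ``weekend``: True/False restricts to that day type; None uses all days.
    Returns a frame with ``hour``, ``activity``, ``observed_minutes``.
    """
    df = minutes[minutes["observed"] == True]  # noqa: E712 (pandas boolean)
    if weekend is not None and len(df):
        wk = pd.to_datetime(df["date"]).dt.dayofweek >= 5
        df = df[wk == weekend]
    hours = np.arange(24)
    observed = np.zeros(24, int)
    active = np.zeros(24, int)
    if len(df):
        h = (df["minute"] // 60).to_numpy(int)
        a = df["active"].astype(bool).to_numpy()
        observed = np.bincount(h, minlength=24)[:24]
        active = np.bincount(h[a], minlength=24)[:24]
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = np.where(observed > 0, active / np.maximum(observed, 1), np.nan)
    return pd.DataFrame({"hour": hours, "activity": curve, "observed_minutes": observed})


def daily_activity(minutes: pd.DataFrame) -> pd.DataFrame:
    """Daily activity level and missing-minute count per local day.

    Activity level = active / observed minutes (NaN when nothing observed);
    missing minutes = 1440 - observed minutes.
    """
    if len(minutes) == 0:
        return pd.DataFrame(columns=["date", "activity_level", "accel_missing_minutes"])
    obs = minutes[minutes["observed"] == True]  # noqa: E712
    g = obs.groupby("date").agg(
        observed=("observed", "size"), active=("active", lambda s: s.astype(bool).sum())
    )
    all_days = minutes.groupby("date").size().rename("any").to_frame()
    out = all_days.join(g).fillna({"observed": 0, "active": 0})
    with np.errstate(invalid="ignore"):
        out["activity_level"] = np.where(
            out["observed"] > 0, out["active"] / np.maximum(out["observed"], 1), np.nan
        )
    out["accel_missing_minutes"] = (1440 - out["observed"]).astype(int)
    out = out.reset_index()[["date", "activity_level", "accel_missing_minutes"]]
    return out
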