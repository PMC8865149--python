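"""End-to-end orchestration: streams -> daily tables -> analysis table -> RMSE grid."""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import activity, aggregate, mobility
from .config import ActivityConfig, MobilityConfig, SimConfig
from .simulate import DAY_MS, CohortDataset


@dataclass
class FeatureBundle:
    """Daily feature tables and the analysis-ready per-visit table."""

    daily_by_subject: dict[str, pd.DataFrame]
    analysis_table: pd.DataFrame


def subject_daily_features(
    gps: pd.DataFrame,
    accel: pd.DataFrame,
    tz: str,
    sim_config: SimConfig,
    mob_config: MobilityConfig | None = None,
    act_config: ActivityConfig | None = None,
    seed: int = 0,
    method: str = "resampling",
) -> pd.DataFrame:
    """Daily GPS mobility + accelerometer activity table for one subject."""
    mob_config = mob_config or MobilityConfig()
    parts = []
    if len(gps):
        mob = mobility.subject_mobility_days(
            gps, tz=tz, config=mob_config, seed=seed,
            gps_on_s=sim_config.gps_on_s, gps_off_s=sim_config.gps_off_s, method=method,
        )
        if len(mob.days):
            parts.append(mob.days)
    if len(accel):
        minutes = activity.minute_activity(accel, tz=tz, config=act_config)
        parts.append(activity.daily_activity(minutes))
    if not parts:
        return pd.DataFrame()
    daily = parts[0]
    for p in parts[1:]:
        daily = daily.merge(p, on="date", how="outer")
    daily = daily.sort_values("date", ignore_index=True)
    wk = pd.to_datetime(daily["date"]).dt.dayofweek >= 5
    if "is_weekend" in daily:
        daily["is_weekend"] = daily["is_weekend"].fillna(wk).astype(bool)
    else:
        daily["is_weekend"] = wk
    for col, default in (
        ("activity_level", np.nan),
        ("accel_missing_minutes", 1440),
        ("gps_missing_minutes", mobility.expected_on_minutes(
            DAY_MS, sim_config.gps_on_s, sim_config.gps_off_s)),
    ):
        if col not in daily:
            daily[col] = default
        else:
            daily[col] = daily[col].fillna(default)
    return daily


def extract_features(
    dataset: CohortDataset,
    mob_config: MobilityConfig | None = None,
    act_config: ActivityConfig | None = None,
    method: str = "resampling",
) -> FeatureBundle:
    """Run the full passive-feature pipeline over a cohort."""
    cfg = dataset.config
    tz_by_subject = dataset.demographics.set_index("subject")["timezone"]
    daily = {}
    for subject in dataset.demographics["subject"]:
        daily[subject] = subject_daily_features(
            dataset.gps.get(subject, pd.DataFrame()),
            dataset.accel.get(subject, pd.DataFrame()),
            tz=tz_by_subject[subject],
            sim_config=cfg,
            mob_config=mob_config,
            act_config=act_config,
            seed=zlib.crc32(subject.encode()) & 0x7FFFFFFF,
            method=method,
        )
    table = aggregate.build_analysis_table(
        dataset.visits, dataset.demographics, dataset.surveys, daily,
        tz=cfg.timezone,
        gps_expected_minutes_per_day=mobility.expected_on_minutes(
            DAY_MS, cfg.gps_on_s, cfg.gps_off_s
        ),
    )
    return FeatureBundle(daily_by_subject=daily, analysis_table=table)


def completeness_report(dataset: CohortDataset) -> dict:
    """Sensor and survey completeness for a cohort.

    Sensor window per subject: the day after the baseline visit through the
    day before that subject's last follow-up visit (all full study days).
    """
    from .simulate import saturdays

    cfg = dataset.config
    tz = cfg.timezone
    day0_ms = pd.Timestamp(cfg.start_date, tz=tz).value / 1e6
    rows = []
    for subject, sub_visits in dataset.visits.groupby("subject"):
        first = pd.Timestamp(sub_visits["date"].min(), tz=tz).value / 1e6
        last = pd.Timestamp(sub_visits["date"].max(), tz=tz).value / 1e6
        start = first + DAY_MS
        end = last  # start of the last-visit day == end of the prior day
        if end <= start:
            continue
        accel_prop, gps_prop = aggregate.sensor_completeness(
            dataset.accel.get(subject, pd.DataFrame(columns=["timestamp"])),
            dataset.gps.get(subject, pd.DataFrame(columns=["timestamp"])),
            start, end,
            gps_duty_fraction=cfg.gps_on_s / (cfg.gps_on_s + cfg.gps_off_s),
        )
        rows.append(dict(subject=subject, accel=accel_prop, gps=gps_prop))
    sensor = pd.DataFrame(rows, columns=["subject", "accel", "gps"])

    deliveries = np.array(
        [day0_ms + d * DAY_MS + 9 * 3_600_000 for d in saturdays(cfg)]
    )
    subjects = sorted(dataset.demographics["subject"])
    rates, weeks = aggregate.survey_completion_rates(dataset.surveys, deliveries, subjects)
    return {"sensor": sensor, "survey_rates": rates, "weeks_with_survey": weeks}


def cohort_comm_stats(dataset: CohortDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outgoing-call statistics over study weeks 2-7."""
    cfg = dataset.config
    day0_ms = pd.Timestamp(cfg.start_date, tz=cfg.timezone).value / 1e6
    return aggregate.comm_log_stats(
        dataset.calls, dataset.demographics,
        day0_ms + 7 * DAY_MS, day0_ms + 49 * DAY_MS,
    )
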