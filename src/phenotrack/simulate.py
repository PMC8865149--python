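"""Synthetic digital-phenotyping cohorts with known ground truth.

Every downstream stage of the pipeline (GPS mobility features, activity
scoring, aggregation, mixed-model prediction) is exercised against cohorts
generated here, where the latent depression severity, the dense movement
path, the per-minute activity schedule and the generating parameters are all
recorded — so estimator output can be compared against a recoverable truth.

The generative model, per subject:

* latent severity follows a daily AR(1) walk mean-reverting to a
  diagnostic-group baseline (group means/SDs follow the clinical anchors in
  :data:`phenotrack.config.GROUP_BASELINE_MADRS`), clipped to the 0-60
  clinician-scale range;
* each day alternates pauses (at home and at 1-4 recurring away anchors)
  with straight-line flights; higher severity lowers the expected excursion
  rate and away dwell time through configurable coupling coefficients, so
  distance traveled falls and home time rises with severity;
* clinician ratings add rater noise to the latent severity; weekly phone
  self-report totals are an affine function of severity plus noise;
* sensors observe the dense path through duty cycles (GPS 2 min on / 10 min
  off, accelerometer 10 s on / 10 s off, phase-anchored at local midnight)
  and whole-phone outages shared by both sensors.

All randomness flows from one root seed through named substreams, so a
cohort is reproducible and individual subjects/sensors can be regenerated
independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mobility
from .config import GROUP_BASELINE_MADRS, MADRS_MAX, PHQ8_MAX, MobilityConfig, SimConfig
from .mobility import FLIGHT, PAUSE, SEGMENT_COLUMNS, PlanarRef, inverse_projection

DAY_MS = 86_400_000

#: Baseline probability that a minute in each local hour is active, shaped
#: after the empirical pattern of hourly activity curves: near-zero activity
#: overnight, a rise from ~7 a.m., a plateau through the 9 a.m.-1 p.m.
#: window and a decline over the evening.
DIURNAL_PROFILE = np.array(
    [0.02, 0.02, 0.02, 0.02, 0.02, 0.02,
     0.05, 0.12, 0.22, 0.32, 0.32, 0.32,
     0.32, 0.30, 0.25, 0.22, 0.20, 0.20,
     0.22, 0.18, 0.14, 0.10, 0.06, 0.03]
)

#: Planar reference all synthetic coordinates are expressed against.
CITY_REF = PlanarRef(lat0=42.36, lon0=-71.06)


def substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic named RNG substream derived from the root seed."""
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# latent severity
# ---------------------------------------------------------------------------


def simulate_severity(
    group: str, n_days: int, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """AR(1) daily severity path anchored at the group baseline mean."""
    mu, sd = GROUP_BASELINE_MADRS[group]
    s = np.empty(n_days)
    s[0] = rng.normal(mu, sd)
    for d in range(1, n_days):
        s[d] = mu + config.ar1_rho * (s[d - 1] - mu) + rng.normal(0, config.ar1_innovation_sd)
    return np.clip(s, 0.0, MADRS_MAX)


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------


def simulate_day_trajectory(
    home: np.ndarray,
    anchors: np.ndarray,
    severity: float,
    config: SimConfig,
    rng: np.random.Generator,
    day_start_ms: float = 0.0,
) -> pd.DataFrame:
    """One day's continuous ground-truth path as a pause/flight segment table.

    The day starts and ends with a pause at home; a Poisson number of
    excursions visit away anchors via straight-line flights.  With zero
    coupling coefficients the behaviour distribution is severity-invariant
    (identical RNG consumption); negative couplings shrink the excursion
    rate / dwell time exponentially in severity/60.
    """
    if not 0.0 <= severity <= MADRS_MAX:
        raise ValueError(f"severity must be in [0, {MADRS_MAX}], got {severity}")
    s_norm = severity / MADRS_MAX
    rows: list[dict] = []

    def seg(kind, t0, t1, p0, p1):
        rows.append(
            dict(kind=kind, t_start=day_start_ms + t0 * 1000.0,
                 t_end=day_start_ms + t1 * 1000.0,
                 x_start=p0[0], y_start=p0[1], x_end=p1[0], y_end=p1[1],
                 provenance="truth")
        )

    n_trips = 0
    if len(anchors) > 0:
        lam = config.base_trips_per_day * np.exp(config.trip_rate_coupling * s_norm)
        n_trips = int(rng.poisson(lam))
    departures = np.sort(rng.uniform(8 * 3600, 21 * 3600, size=n_trips))
    away_scale_s = config.base_away_minutes * 60.0 * np.exp(
        config.away_duration_coupling * s_norm
    )
    deadline = 86400.0 - 600.0  # home again by 23:50

    cur_t = 0.0
    for dep in departures:
        idx = int(rng.integers(len(anchors)))
        speed = rng.lognormal(np.log(config.travel_speed_ms), 0.3)
        dwell = rng.lognormal(np.log(away_scale_s), 0.5)
        anchor = anchors[idx]
        dist = float(np.hypot(*(anchor - home)))
        travel_s = dist / speed
        if dep <= cur_t or dep + 2 * travel_s + 60.0 > deadline:
            continue
        seg(PAUSE, cur_t, dep, home, home)
        t1 = dep + travel_s
        seg(FLIGHT, dep, t1, home, anchor)
        dwell = min(dwell, deadline - t1 - travel_s)
        t2 = t1 + max(dwell, 60.0)
        seg(PAUSE, t1, t2, anchor, anchor)
        t3 = t2 + travel_s
        seg(FLIGHT, t2, t3, anchor, home)
        cur_t = t3
    seg(PAUSE, cur_t, 86400.0, home, home)
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def sample_path(segments: pd.DataFrame, times_ms: np.ndarray) -> np.ndarray:
    """Positions of the piecewise-linear path at the given times (n, 2)."""
    knots_t = np.empty(2 * len(segments))
    knots_x = np.empty_like(knots_t)
    knots_y = np.empty_like(knots_t)
    knots_t[0::2] = segments["t_start"].to_numpy(float)
    knots_t[1::2] = segments["t_end"].to_numpy(float)
    knots_x[0::2] = segments["x_start"].to_numpy(float)
    knots_x[1::2] = segments["x_end"].to_numpy(float)
    knots_y[0::2] = segments["y_start"].to_numpy(float)
    knots_y[1::2] = segments["y_end"].to_numpy(float)
    t = np.asarray(times_ms, float)
    return np.column_stack([np.interp(t, knots_t, knots_x), np.interp(t, knots_t, knots_y)])


# ---------------------------------------------------------------------------
# duty cycling and outages
# ---------------------------------------------------------------------------


def apply_duty_cycle(
    stream: pd.DataFrame, on_s: float, off_s: float, tz: str = "UTC"
) -> pd.DataFrame:
    """Keep samples falling in on-cycles anchored at local midnight.

    A sample at local second-of-day ``u`` is retained iff
    ``u mod (on + off) < on``.  ``off_s == 0`` is the identity.
    """
    t = stream["timestamp"].to_numpy(np.int64)
    if np.any(np.diff(t) < 0):
        raise ValueError("stream timestamps must be sorted")
    if off_s <= 0:
        return stream.reset_index(drop=True)
    ts = pd.to_datetime(t, unit="ms", utc=True).tz_convert(tz)
    secs = (ts - ts.normalize()).total_seconds().to_numpy()
    keep = np.mod(secs, on_s + off_s) < on_s
    return stream[keep].reset_index(drop=True)


def sample_outages(
    n_days: int, day0_ms: float, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Whole-phone outage intervals: per-day Bernoulli onset, exponential length."""
    rows = []
    for d in range(n_days):
        if rng.random() < config.outage_prob_per_day:
            start = day0_ms + d * DAY_MS + rng.uniform(0, DAY_MS)
            dur = rng.exponential(config.outage_mean_hours * 3_600_000.0)
            rows.append(dict(start_ms=start, end_ms=start + dur))
    return pd.DataFrame(rows, columns=["start_ms", "end_ms"])


def apply_outages(stream: pd.DataFrame, outages: pd.DataFrame) -> pd.DataFrame:
    """Drop samples inside any outage interval (phone off: all sensors)."""
    if len(outages) == 0 or len(stream) == 0:
        return stream.reset_index(drop=True)
    t = stream["timestamp"].to_numpy(float)
    drop = np.zeros(len(t), bool)
    for _, o in outages.iterrows():
        drop |= (t >= o["start_ms"]) & (t < o["end_ms"])
    return stream[~drop].reset_index(drop=True)


# ---------------------------------------------------------------------------
# accelerometer
# ---------------------------------------------------------------------------


def draw_active_minutes(
    severity: float, config: SimConfig, rng: np.random.Generator,
    profile: np.ndarray = DIURNAL_PROFILE,
) -> np.ndarray:
    """Bernoulli per-minute activity mask from the diurnal profile.

    The hourly activity probability is scaled by
    ``exp(activity_coupling * severity/60)`` so more severe days are less
    active.
    """
    p_hour = np.clip(profile * np.exp(config.activity_coupling * severity / MADRS_MAX), 0, 1)
    p_min = np.repeat(p_hour, 60)
    return rng.random(1440) < p_min


def simulate_accel_day(
    active_mask: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    day_start_ms: float = 0.0,
    duty_cycled: bool = True,
) -> pd.DataFrame:
    """Triaxial accelerometer samples for one day given a per-minute schedule.

    Resting samples sit at ~1 g (phone flat) with small noise; active
    minutes add high-variance oscillation on every axis.  With
    ``duty_cycled`` the on/off schedule (phase at local midnight) is applied
    at generation time.
    """
    active_mask = np.asarray(active_mask, bool)
    if len(active_mask) != 1440:
        raise ValueError("active_mask must have 1440 per-minute entries")
    t_s = np.arange(0, 86400, config.accel_sample_interval_s, dtype=float)
    if duty_cycled:
        cycle = config.accel_on_s + config.accel_off_s
        t_s = t_s[np.mod(t_s, cycle) < config.accel_on_s]
    n = len(t_s)
    x = rng.normal(0.0, config.rest_noise_g, n)
    y = rng.normal(0.0, config.rest_noise_g, n)
    z = 1.0 + rng.normal(0.0, config.rest_noise_g, n)
    active = active_mask[(t_s // 60).astype(int)]
    k = int(active.sum())
    if k:
        x[active] += rng.normal(0.0, config.active_noise_g, k)
        y[active] += rng.normal(0.0, config.active_noise_g, k)
        z[active] += rng.normal(0.0, config.active_noise_g, k)
    return pd.DataFrame(
        {"timestamp": (day_start_ms + t_s * 1000.0).astype(np.int64), "x": x, "y": y, "z": z}
    )


# ---------------------------------------------------------------------------
# assessments
# ---------------------------------------------------------------------------


def phq8_items(total: int) -> list[int]:
    """Split a PHQ-8 total into 8 item scores (0-3) by largest remainder."""
    base, rem = divmod(int(total), 8)
    return [min(base + (1 if i < rem else 0), 3) for i in range(8)]


def saturdays(config: SimConfig) -> list[int]:
    """Day indices (relative to baseline) of survey deliveries: Saturdays."""
    return [
        d for d in range(1, config.study_days + 1)
        if (pd.Timestamp(config.start_date) + pd.Timedelta(days=d)).dayofweek == 5
    ]


def simulate_assessments(
    latent: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    last_day: dict[str, int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinician visit table and phone-survey table from latent severity.

    Clinician total = clip(round(severity + rater noise), 0, 60) at visits
    every ``visit_interval_days``; self-report total = clip(round(a*severity
    + b + noise), 0, 24) on Saturday deliveries, with per-survey completion
    probability interpolating linearly between the configured first- and
    last-survey rates, and a configurable fraction of completions arriving
    late by one or more days.
    """
    day0 = pd.Timestamp(config.start_date, tz=config.timezone)
    day0_ms = day0.value / 1e6
    sev = {
        (r.subject, int(r.day)): float(r.severity) for r in latent.itertuples()
    }
    subjects = sorted(latent["subject"].unique())
    visit_days = [i * config.visit_interval_days for i in range(5) if
                  i * config.visit_interval_days <= config.study_days]
    sat = saturdays(config)
    n_surveys = len(sat)

    visit_rows = []
    survey_rows = []
    for subject in subjects:
        cutoff = last_day.get(subject, config.study_days)
        for vi, vd in enumerate(visit_days):
            if vd > cutoff:
                continue
            s = sev[(subject, vd)]
            madrs = int(np.clip(np.round(s + rng.normal(0, config.rater_noise_sd)), 0, MADRS_MAX))
            visit_rows.append(
                dict(subject=subject, visit_index=vi,
                     date=(pd.Timestamp(config.start_date) + pd.Timedelta(days=vd)).date(),
                     madrs=madrs)
            )
        for si, sd in enumerate(sat):
            if sd > cutoff:
                continue
            delivered = day0_ms + sd * DAY_MS + 9 * 3_600_000  # 09:00 local
            frac = si / max(n_surveys - 1, 1)
            p = config.completion_prob_first + frac * (
                config.completion_prob_last - config.completion_prob_first
            )
            completed = np.nan
            total = np.nan
            items = [np.nan] * 8
            if rng.random() < p:
                if rng.random() < config.late_prob:
                    delay_ms = rng.uniform(1.0, config.late_max_days) * DAY_MS
                else:
                    delay_ms = rng.uniform(0.25, 10.0) * 3_600_000
                completed = delivered + delay_ms
                s = sev[(subject, sd)]
                total = int(
                    np.clip(
                        np.round(config.phq_slope * s + config.phq_intercept
                                 + rng.normal(0, config.phq_noise_sd)),
                        0, PHQ8_MAX,
                    )
                )
                items = phq8_items(total)
            row = dict(subject=subject, delivered=delivered, completed=completed,
                       instrument="PHQ8")
            row.update({f"q{i+1}": items[i] for i in range(8)})
            row["total"] = total
            survey_rows.append(row)

    visits = pd.DataFrame(visit_rows, columns=["subject", "visit_index", "date", "madrs"])
    surveys = pd.DataFrame(
        survey_rows,
        columns=["subject", "delivered", "completed", "instrument"]
        + [f"q{i}" for i in range(1, 9)] + ["total"],
    )
    return visits, surveys


# ---------------------------------------------------------------------------
# communication logs
# ---------------------------------------------------------------------------


def simulate_calls(
    subject: str, group: str, n_days: int, day0_ms: float,
    config: SimConfig, rng: np.random.Generator,
) -> pd.DataFrame:
    """Poisson call process with a Zipf-weighted contact pool (Android only)."""
    rate = config.call_rate_hc if group == "HC" else config.call_rate_other
    pool = config.contact_pool_hc if group == "HC" else config.contact_pool_other
    weights = 1.0 / np.arange(1, pool + 1)
    weights /= weights.sum()
    rows = []
    for d in range(n_days):
        for direction, lam in (("outgoing", rate), ("incoming", rate * 0.6), ("missed", 0.3)):
            for _ in range(rng.poisson(lam)):
                t = day0_ms + d * DAY_MS + rng.uniform(8 * 3_600_000, 22 * 3_600_000)
                contact = int(rng.choice(pool, p=weights))
                rows.append(
                    dict(subject=subject, timestamp=int(t), direction=direction,
                         hashed_number=f"{zlib.crc32(f'{subject}:{contact}'.encode()):08x}")
                )
    df = pd.DataFrame(rows, columns=["subject", "timestamp", "direction", "hashed_number"])
    return df.sort_values("timestamp", kind="stable", ignore_index=True)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class CohortDataset:
    """A full synthetic cohort plus its generating truth."""

    config: SimConfig
    demographics: pd.DataFrame
    visits: pd.DataFrame
    surveys: pd.DataFrame
    calls: pd.DataFrame
    gps: dict[str, pd.DataFrame]
    accel: dict[str, pd.DataFrame]
    latent: pd.DataFrame  # subject, day, date, severity
    truth_daily: pd.DataFrame  # subject, date, is_weekend, mobility + activity truth
    outages: pd.DataFrame  # subject, start_ms, end_ms
    true_segments: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)
    homes: dict[str, np.ndarray] = field(default_factory=dict)
    anchors: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        """Cross-table consistency checks."""
        subjects = set(self.demographics["subject"])
        assert set(self.visits["subject"]) <= subjects
        assert set(self.surveys["subject"]) <= subjects
        assert self.visits["madrs"].between(0, MADRS_MAX).all()
        totals = self.surveys["total"].dropna()
        assert totals.between(0, PHQ8_MAX).all()


def simulate_cohort(config: SimConfig) -> CohortDataset:
    """Generate a complete synthetic cohort. Deterministic given the seed."""
    seed = config.seed
    tz = config.timezone
    day0 = pd.Timestamp(config.start_date, tz=tz)
    day0_ms = day0.value / 1e6
    n_sensor_days = config.study_days + 1
    mob_cfg = MobilityConfig()

    # roster
    subjects, groups = [], []
    idx = 0
    for g in sorted(config.n_per_group):
        for _ in range(config.n_per_group[g]):
            subjects.append(f"S{idx:03d}")
            groups.append(g)
            idx += 1
    n = len(subjects)

    rng_demo = substream(seed, "demographics")
    ages = np.clip(np.round(rng_demo.normal(43, 12, n)), 18, 75).astype(int)
    sexes = np.where(rng_demo.random(n) < 0.63, "F", "M")
    oses = np.where(rng_demo.random(n) < config.android_frac, "Android", "iOS")
    demographics = pd.DataFrame(
        {"subject": subjects, "age": ages, "sex": sexes, "diagnosis": groups,
         "timezone": tz, "os": oses}
    )

    rng_drop = substream(seed, "dropout")
    n_drop = int(round(config.dropout_frac * n))
    dropped = set(np.array(subjects)[rng_drop.choice(n, size=n_drop, replace=False)]) if n_drop else set()
    last_day = {
        s: (config.visit_interval_days if s in dropped else config.study_days)
        for s in subjects
    }

    latent_rows = []
    gps_streams: dict[str, pd.DataFrame] = {}
    accel_streams: dict[str, pd.DataFrame] = {}
    true_segments: dict[str, pd.DataFrame] = {}
    homes: dict[str, np.ndarray] = {}
    anchor_map: dict[str, np.ndarray] = {}
    outage_rows = []
    truth_daily_rows = []
    call_frames = []

    for subject, group in zip(subjects, groups):
        rng_lat = substream(seed, subject, "latent")
        rng_mov = substream(seed, subject, "movement")
        rng_gps = substream(seed, subject, "gps_noise")
        rng_acc = substream(seed, subject, "accel")
        rng_out = substream(seed, subject, "outages")
        rng_call = substream(seed, subject, "calls")

        n_days_s = last_day[subject] + 1
        severity = simulate_severity(group, config.study_days + 1, config, rng_lat)
        for d in range(config.study_days + 1):
            latent_rows.append(
                dict(subject=subject, day=d,
                     date=(pd.Timestamp(config.start_date) + pd.Timedelta(days=d)).date(),
                     severity=severity[d])
            )

        home = rng_mov.uniform(-5000, 5000, 2)
        n_anchor = int(rng_mov.integers(config.n_away_anchors_min, config.n_away_anchors_max + 1))
        angles = rng_mov.uniform(0, 2 * np.pi, n_anchor)
        radii = rng_mov.uniform(config.anchor_distance_min_m, config.anchor_distance_max_m, n_anchor)
        anchors = home[None, :] + np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        homes[subject] = home
        anchor_map[subject] = anchors

        day_segments = []
        gps_days = []
        accel_days = []
        active_fracs = []
        gps_interval = config.gps_sample_interval_s
        gps_cycle = config.gps_on_s + config.gps_off_s
        cand_s = np.arange(0, 86400, gps_interval, dtype=float)
        cand_on = cand_s[np.mod(cand_s, gps_cycle) < config.gps_on_s]
        for d in range(n_days_s):
            start_ms = day0_ms + d * DAY_MS
            seg = simulate_day_trajectory(home, anchors, severity[d], config, rng_mov, start_ms)
            day_segments.append(seg)

            t_obs = start_ms + cand_on * 1000.0
            pos = sample_path(seg, t_obs)
            pos = pos + rng_gps.normal(0, config.gps_noise_m, pos.shape)
            lat, lon = inverse_projection(pos[:, 0], pos[:, 1], CITY_REF)
            acc = np.abs(rng_gps.normal(config.gps_accuracy_m, 3.0, len(t_obs)))
            gps_days.append(
                pd.DataFrame({"timestamp": t_obs.astype(np.int64), "latitude": lat,
                              "longitude": lon, "accuracy": acc})
            )

            mask = draw_active_minutes(severity[d], config, rng_acc)
            active_fracs.append(float(mask.mean()))
            accel_days.append(simulate_accel_day(mask, config, rng_acc, start_ms))

        seg_all = pd.concat(day_segments, ignore_index=True)
        true_segments[subject] = seg_all

        # ground-truth daily mobility features from the true trace
        truth = mobility.subject_mobility_days(
            None, tz=tz, config=mob_cfg, seed=zlib.crc32(subject.encode()) & 0x7FFFFFFF,
            precomputed_segments=seg_all,
        )
        tdays = truth.days.copy()
        tdays.insert(0, "subject", subject)
        tdays["activity_level"] = active_fracs[: len(tdays)]
        truth_daily_rows.append(tdays)

        outages = sample_outages(n_days_s, day0_ms, config, rng_out)
        for _, o in outages.iterrows():
            outage_rows.append(dict(subject=subject, start_ms=o["start_ms"], end_ms=o["end_ms"]))

        gps_df = pd.concat(gps_days, ignore_index=True)
        accel_df = pd.concat(accel_days, ignore_index=True)
        gps_streams[subject] = apply_outages(gps_df, outages)
        accel_streams[subject] = apply_outages(accel_df, outages)

        if demographics.loc[demographics["subject"] == subject, "os"].iloc[0] == "Android":
            call_frames.append(
                simulate_calls(subject, group, n_days_s, day0_ms, config, rng_call)
            )

    latent = pd.DataFrame(latent_rows)
    rng_assess = substream(seed, "assessments")
    visits, surveys = simulate_assessments(latent, config, rng_assess, last_day)
    calls = (
        pd.concat(call_frames, ignore_index=True)
        if call_frames
        else pd.DataFrame(columns=["subject", "timestamp", "direction", "hashed_number"])
    )

    dataset = CohortDataset(
        config=config,
        demographics=demographics,
        visits=visits,
        surveys=surveys,
        calls=calls,
        gps=gps_streams,
        accel=accel_streams,
        latent=latent,
        truth_daily=pd.concat(truth_daily_rows, ignore_index=True),
        outages=pd.DataFrame(outage_rows, columns=["subject", "start_ms", "end_ms"]),
        true_segments=true_segments,
        homes=homes,
        anchors=anchor_map,
    )
    dataset.validate()
    return dataset
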