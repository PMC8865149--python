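"""Configuration objects for simulation and feature extraction.

All tunable constants of the pipeline live here so that every threshold a
study could reasonably override (pause radius, duty-cycle schedule,
severity-behaviour couplings, ...) is explicit, validated, and serialisable
to/from plain dictionaries (and hence YAML manifests).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date

import yaml

#: Diagnostic groups and their baseline clinician-rated depression (MADRS)
#: anchors: mean and SD of the baseline score per group.  HC = healthy
#: control, MDD = major depressive disorder, BP = bipolar disorder,
#: SCZ = schizophrenia / schizoaffective disorder.
GROUP_BASELINE_MADRS: dict[str, tuple[float, float]] = {
    "HC": (0.7, 1.2),
    "MDD": (20.0, 12.7),
    "BP": (9.7, 10.6),
    "SCZ": (6.2, 5.4),
}

MADRS_MAX = 60
PHQ8_MAX = 24


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


@dataclass
class SimConfig:
    """Generating parameters of a synthetic digital-phenotyping cohort.

    The defaults emulate the study design this package targets: four
    diagnostic groups followed for 8 weeks, clinician MADRS ratings every
    two weeks (baseline + 4 follow-ups), weekly in-app PHQ-8 surveys
    delivered on Saturdays, GPS duty-cycled 2 min on / 10 min off and the
    accelerometer 10 s on / 10 s off, with block missingness from phone
    outages.
    """

    # cohort design
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 10, "MDD": 10, "BP": 10, "SCZ": 10}
    )
    study_weeks: int = 8
    visit_interval_days: int = 14
    start_date: date = date(2020, 1, 6)  # a Monday; surveys go out Saturdays
    timezone: str = "UTC"
    dropout_frac: float = 3 / 41  # truncated after first follow-up
    android_frac: float = 0.5  # call logs exist for Android subjects only

    # duty cycles (seconds)
    gps_on_s: int = 120
    gps_off_s: int = 600
    accel_on_s: int = 10
    accel_off_s: int = 10

    # sensor sampling resolution of the simulated streams (seconds)
    gps_sample_interval_s: int = 10
    accel_sample_interval_s: int = 5

    # outages: whole-phone gaps shared by both sensors
    outage_prob_per_day: float = 0.15
    outage_mean_hours: float = 6.0

    # latent severity dynamics: AR(1) mean-reverting to the group baseline
    ar1_rho: float = 0.95
    ar1_innovation_sd: float = 1.5

    # severity -> behaviour couplings (applied to severity/60 in [0,1])
    trip_rate_coupling: float = -1.0  # fewer excursions when depressed
    away_duration_coupling: float = -0.5  # shorter excursions when depressed
    activity_coupling: float = -0.7  # less accelerometer activity

    # movement model
    base_trips_per_day: float = 2.5
    base_away_minutes: float = 90.0
    n_away_anchors_min: int = 1
    n_away_anchors_max: int = 4
    anchor_distance_min_m: float = 500.0
    anchor_distance_max_m: float = 5000.0
    travel_speed_ms: float = 8.0
    gps_noise_m: float = 5.0
    gps_accuracy_m: float = 10.0

    # accelerometer model
    rest_noise_g: float = 0.01
    active_noise_g: float = 0.3

    # assessments
    rater_noise_sd: float = 2.0
    phq_slope: float = 0.4
    phq_intercept: float = 0.0
    phq_noise_sd: float = 1.5
    completion_prob_first: float = 0.95
    completion_prob_last: float = 0.80
    late_prob: float = 0.10
    late_max_days: float = 8.0

    # communication logs (outgoing calls per day; contact pool sizes)
    call_rate_hc: float = 1.3
    call_rate_other: float = 2.9
    contact_pool_hc: int = 25
    contact_pool_other: int = 35

    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            _require(n >= 0, "n_per_group", f"group {g!r} size must be >= 0")
            _require(g in GROUP_BASELINE_MADRS, "n_per_group", f"unknown group {g!r}")
        _require(self.study_weeks > 0, "study_weeks", "must be > 0")
        _require(self.visit_interval_days > 0, "visit_interval_days", "must be > 0")
        for name in ("gps_on_s", "gps_off_s", "accel_on_s", "accel_off_s"):
            _require(getattr(self, name) >= 0, name, "must be >= 0")
        _require(self.gps_on_s > 0, "gps_on_s", "must be > 0")
        _require(self.accel_on_s > 0, "accel_on_s", "must be > 0")
        for name in (
            "dropout_frac",
            "android_frac",
            "outage_prob_per_day",
            "completion_prob_first",
            "completion_prob_last",
            "late_prob",
        ):
            _require(0.0 <= getattr(self, name) <= 1.0, name, "must be in [0, 1]")
        for name in (
            "gps_sample_interval_s",
            "accel_sample_interval_s",
            "base_trips_per_day",
            "base_away_minutes",
            "travel_speed_ms",
            "ar1_innovation_sd",
        ):
            _require(getattr(self, name) > 0, name, "must be > 0")
        _require(0.0 <= self.ar1_rho < 1.0, "ar1_rho", "must be in [0, 1)")
        _require(
            self.n_away_anchors_min >= 0
            and self.n_away_anchors_max >= self.n_away_anchors_min,
            "n_away_anchors_max",
            "must be >= n_away_anchors_min >= 0",
        )

    @property
    def study_days(self) -> int:
        return self.study_weeks * 7

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_group.values())

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["start_date"] = self.start_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if isinstance(d.get("start_date"), str):
            d["start_date"] = date.fromisoformat(d["start_date"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class MobilityConfig:
    """Thresholds of the GPS flight/pause feature pipeline.

    Defaults follow the mobility-features literature the pipeline draws on;
    every value can be overridden in the ``gps:`` block of a pipeline YAML.
    """

    pause_radius_m: float = 10.0
    min_pause_s: float = 30.0
    home_radius_m: float = 200.0
    sig_loc_radius_m: float = 200.0
    k_max: int = 10
    routine_threshold_m: float = 500.0
    routine_bin_minutes: int = 30
    accuracy_max_m: float = 250.0  # GPS fixes less accurate than this are dropped
    burst_gap_s: float = 120.0  # larger gaps separate on-cycle bursts
    donor_decay_hours: float = 3.0  # imputation donor weight e-folding time
    same_day_type_bonus: float = 2.0  # weight multiplier for same weekday/weekend
    night_start_hour: int = 21  # home detection window 21:00-06:00 local
    night_end_hour: int = 6

    def __post_init__(self) -> None:
        for name in (
            "pause_radius_m",
            "min_pause_s",
            "home_radius_m",
            "sig_loc_radius_m",
            "routine_threshold_m",
            "burst_gap_s",
            "donor_decay_hours",
        ):
            _require(getattr(self, name) > 0, name, "must be > 0")
        _require(self.k_max >= 1, "k_max", "must be >= 1")
        _require(
            1440 % self.routine_bin_minutes == 0,
            "routine_bin_minutes",
            "must divide 1440",
        )


@dataclass
class ActivityConfig:
    """Accelerometer minute-scoring constants."""

    sd_threshold_g: float = 0.1  # magnitude-SD above this marks a minute active
    min_samples: int = 5  # fewer samples than this leaves a minute unobserved

    def __post_init__(self) -> None:
        _require(self.sd_threshold_g > 0, "sd_threshold_g", "must be > 0")
        _require(self.min_samples >= 1, "min_samples", "must be >= 1")
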