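"""Simulator unit tests: schedules, couplings, duty cycles, assessments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenotrack.config import GROUP_BASELINE_MADRS, ConfigError, SimConfig
from phenotrack.simulate import (
    DAY_MS,
    DIURNAL_PROFILE,
    apply_duty_cycle,
    apply_outages,
    draw_active_minutes,
    phq8_items,
    sample_outages,
    sample_path,
    simulate_accel_day,
    simulate_cohort,
    simulate_day_trajectory,
    simulate_severity,
    substream,
)


def _trajectory_distance(seg: pd.DataFrame) -> float:
    f = seg[seg["kind"] == "flight"]
    return float(np.hypot(f["x_end"] - f["x_start"], f["y_end"] - f["y_start"]).sum())


class TestConfig:
    def test_invalid_fields_name_the_field(self):
        with pytest.raises(ConfigError, match="study_weeks"):
            SimConfig(study_weeks=0)
        with pytest.raises(ConfigError, match="outage_prob_per_day"):
            SimConfig(outage_prob_per_day=1.5)
        with pytest.raises(ConfigError, match="n_per_group"):
            SimConfig(n_per_group={"HC": -1})

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(seed=7, study_weeks=6)
        cfg.to_yaml(tmp_path / "sim.yaml")
        assert SimConfig.from_yaml(tmp_path / "sim.yaml") == cfg


class TestCohortSchedule:
    def test_one_subject_per_group_gives_five_biweekly_visits(self, small_cohort):
        visits = small_cohort.visits
        assert small_cohort.demographics["subject"].nunique() == 4
        for _, sub in visits.groupby("subject"):
            assert list(sub["visit_index"]) == [0, 1, 2, 3, 4]
            gaps = pd.to_datetime(sub["date"]).diff().dropna().dt.days
            assert (gaps == 14).all()

    def test_same_seed_gives_identical_cohorts(self, small_config, small_cohort):
        other = simulate_cohort(small_config)
        pd.testing.assert_frame_equal(other.visits, small_cohort.visits)
        pd.testing.assert_frame_equal(other.surveys, small_cohort.surveys)
        pd.testing.assert_frame_equal(other.truth_daily, small_cohort.truth_daily)
        for s in other.gps:
            pd.testing.assert_frame_equal(other.gps[s], small_cohort.gps[s])

    def test_group_mean_baseline_scores_match_clinical_anchors(self):
        # large per-group sample of latent day-0 severities plus rater noise
        cfg = SimConfig()
        n = 200
        for group, (mu, sd) in GROUP_BASELINE_MADRS.items():
            vals = []
            for i in range(n):
                rng = substream(3, "baseline", group, i)
                sev = simulate_severity(group, 1, cfg, rng)[0]
                vals.append(np.clip(round(sev + rng.normal(0, cfg.rater_noise_sd)), 0, 60))
            se = np.std(vals, ddof=1) / np.sqrt(n)
            # clipping at 0 biases low-mean groups upward; allow that shift
            assert abs(np.mean(vals) - mu) <= 2 * se + 1.0


class TestDayTrajectory:
    def test_zero_coupling_gives_severity_invariant_distance(self):
        cfg = SimConfig(trip_rate_coupling=0.0, away_duration_coupling=0.0)
        home = np.zeros(2)
        anchors = np.array([[1500.0, 0.0]])
        d_low = [
            _trajectory_distance(
                simulate_day_trajectory(home, anchors, 5.0, cfg, substream(0, "d", i))
            )
            for i in range(50)
        ]
        d_high = [
            _trajectory_distance(
                simulate_day_trajectory(home, anchors, 40.0, cfg, substream(0, "d", i))
            )
            for i in range(50)
        ]
        assert d_low == d_high

    def test_negative_coupling_reduces_distance_at_high_severity(self):
        cfg = SimConfig()  # trip_rate_coupling = -1.0
        home = np.zeros(2)
        anchors = np.array([[2000.0, 0.0], [0.0, 1000.0]])
        d_low = np.mean([
            _trajectory_distance(
                simulate_day_trajectory(home, anchors, 5.0, cfg, substream(1, "c", i))
            )
            for i in range(200)
        ])
        d_high = np.mean([
            _trajectory_distance(
                simulate_day_trajectory(home, anchors, 40.0, cfg, substream(1, "c", i))
            )
            for i in range(200)
        ])
        assert d_high < d_low

    def test_no_anchors_keeps_path_at_home_all_day(self):
        cfg = SimConfig()
        home = np.array([10.0, -20.0])
        seg = simulate_day_trajectory(home, np.empty((0, 2)), 10.0, cfg, substream(0, "h"))
        assert (seg["kind"] == "pause").all()
        pos = sample_path(seg, np.arange(0, DAY_MS, 3_600_000))
        assert np.allclose(pos, home)

    def test_rejects_out_of_range_severity(self):
        cfg = SimConfig()
        with pytest.raises(ValueError, match="severity"):
            simulate_day_trajectory(np.zeros(2), np.empty((0, 2)), 70.0, cfg, substream(0, "x"))


class TestDutyCycle:
    def test_gps_schedule_retains_one_sixth_of_uniform_day(self):
        t = np.arange(0, 86400) * 1000
        stream = pd.DataFrame({"timestamp": t})
        kept = apply_duty_cycle(stream, 120, 600)
        assert len(kept) / len(stream) == pytest.approx(1 / 6)

    def test_zero_off_period_is_identity(self):
        stream = pd.DataFrame({"timestamp": np.arange(0, 60000, 1000)})
        kept = apply_duty_cycle(stream, 10, 0)
        pd.testing.assert_frame_equal(kept, stream)

    def test_accel_schedule_keeps_half_with_coverage_every_minute(self):
        t = np.arange(0, 60) * 1000  # one minute at 1 Hz
        kept = apply_duty_cycle(pd.DataFrame({"timestamp": t}), 10, 10)
        assert len(kept) == 30
        assert kept["timestamp"].min() < 60000

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            apply_duty_cycle(pd.DataFrame({"timestamp": [2000, 1000]}), 10, 10)

    @settings(deadline=None, max_examples=25)
    @given(on=st.integers(1, 300), off=st.integers(0, 900))
    def test_retained_fraction_matches_duty_fraction_at_1hz(self, on, off):
        t = np.arange(0, 86400) * 1000
        kept = apply_duty_cycle(pd.DataFrame({"timestamp": t}), on, off)
        # exact up to the truncated final cycle at the end of the day
        assert abs(len(kept) / len(t) - on / (on + off)) <= on / 86400 + 1e-12


class TestOutages:
    def test_zero_probability_is_identity(self):
        cfg = SimConfig(outage_prob_per_day=0.0)
        out = sample_outages(100, 0.0, cfg, substream(0, "o"))
        assert len(out) == 0
        stream = pd.DataFrame({"timestamp": np.arange(10) * 1000})
        pd.testing.assert_frame_equal(apply_outages(stream, out), stream)

    def test_full_day_outage_empties_that_day(self):
        stream = pd.DataFrame({"timestamp": np.arange(0, 2 * DAY_MS, 600_000)})
        outages = pd.DataFrame({"start_ms": [0.0], "end_ms": [float(DAY_MS)]})
        kept = apply_outages(stream, outages)
        assert (kept["timestamp"] >= DAY_MS).all()
        assert len(kept) == (stream["timestamp"] >= DAY_MS).sum()

    def test_outage_day_rate_matches_probability(self):
        cfg = SimConfig(outage_prob_per_day=0.3)
        out = sample_outages(1000, 0.0, cfg, substream(2, "o"))
        rate = len(out) / 1000
        # binomial 99% interval around 0.3 at n=1000
        assert abs(rate - 0.3) < 2.58 * np.sqrt(0.3 * 0.7 / 1000)


class TestAccelDay:
    def test_all_rest_day_has_low_magnitude_sd_every_minute(self):
        cfg = SimConfig()
        df = simulate_accel_day(np.zeros(1440, bool), cfg, substream(0, "a"))
        mag = np.sqrt(df["x"] ** 2 + df["y"] ** 2 + df["z"] ** 2)
        sd = mag.groupby(df["timestamp"] // 60000).std()
        assert (sd < 0.1).all()

    def test_all_active_day_has_unit_hourly_curve(self):
        from phenotrack.activity import hourly_activity_curve, minute_activity

        cfg = SimConfig(accel_sample_interval_s=1)
        df = simulate_accel_day(np.ones(1440, bool), cfg, substream(0, "b"), duty_cycled=False)
        curve = hourly_activity_curve(minute_activity(df))
        assert np.allclose(curve["activity"], 1.0)

    def test_peaked_profile_recovers_peak_hours(self):
        from phenotrack.activity import hourly_activity_curve, minute_activity

        cfg = SimConfig(activity_coupling=0.0)
        profile = np.full(24, 0.02)
        profile[9:14] = 0.9
        frames = []
        for d in range(5):
            mask = draw_active_minutes(0.0, cfg, substream(d, "p"), profile=profile)
            frames.append(simulate_accel_day(mask, cfg, substream(d, "q"), d * DAY_MS))
        curve = hourly_activity_curve(minute_activity(pd.concat(frames, ignore_index=True)))
        assert 9 <= int(curve["activity"].idxmax()) <= 13

    def test_diurnal_profile_peaks_in_late_morning(self):
        assert 9 <= int(np.argmax(DIURNAL_PROFILE)) <= 13


class TestAssessments:
    def test_phq_total_is_affine_in_severity_without_noise(self, small_config):
        cfg = SimConfig.from_dict({**small_config.to_dict(), "phq_noise_sd": 1e-12,
                                   "completion_prob_first": 1.0, "completion_prob_last": 1.0})
        ds = simulate_cohort(cfg)
        done = ds.surveys.dropna(subset=["completed"])
        lat = ds.latent.set_index(["subject", "date"])["severity"]
        day0 = pd.Timestamp(cfg.start_date, tz=cfg.timezone).value / 1e6
        for r in done.itertuples():
            day = int((r.delivered - day0) // DAY_MS)
            sev = lat[(r.subject, (pd.Timestamp(cfg.start_date) + pd.Timedelta(days=day)).date())]
            assert r.total == np.clip(round(0.4 * sev), 0, 24)

    def test_scores_respect_scale_ranges(self, small_cohort):
        assert small_cohort.visits["madrs"].between(0, 60).all()
        done = small_cohort.surveys.dropna(subset=["completed"])
        items = done[[f"q{i}" for i in range(1, 9)]]
        assert items.sum(axis=1).equals(done["total"].astype(items.sum(axis=1).dtype))
        assert ((items >= 0) & (items <= 3)).all().all()

    def test_first_survey_completion_rate_matches_config(self):
        cfg = SimConfig()
        n, completed = 400, 0
        for i in range(n):
            rng = substream(9, "compl", i)
            completed += rng.random() < cfg.completion_prob_first
        assert completed / n == pytest.approx(0.95, abs=3 * np.sqrt(0.95 * 0.05 / n))

    @given(total=st.integers(0, 24))
    def test_item_split_is_valid(self, total):
        items = phq8_items(total)
        assert sum(items) == total
        assert all(0 <= q <= 3 for q in items)


class TestTruthConsistency:
    def test_truth_metrics_match_features_on_dense_noise_free_stream(self):
        """Features recomputed from a dense 1 Hz sampling of the true path
        agree with the simulator-recorded daily truth to <1% relative error."""
        from phenotrack import mobility

        cfg = SimConfig()
        rng = substream(4, "truthcheck")
        home = np.zeros(2)
        anchors = np.array([[2500.0, 500.0], [-800.0, 3000.0]])
        seg = simulate_day_trajectory(home, anchors, 12.0, cfg, rng, 0.0)
        truth = mobility.subject_mobility_days(None, precomputed_segments=seg, seed=1).days
        t = np.arange(0, 86400, 1.0) * 1000.0
        pos = sample_path(seg, t)
        track = pd.DataFrame({"timestamp": t.astype(np.int64), "x": pos[:, 0], "y": pos[:, 1]})
        est = mobility.subject_mobility_days(
            None, precomputed_segments=mobility.segment_flights_pauses(track), seed=1
        ).days
        for f in mobility.GPS_FEATURES:
            tv, ev = truth.iloc[0][f], est.iloc[0][f]
            if np.isnan(tv):
                assert np.isnan(ev)
            elif tv == 0:
                assert abs(ev) < 0.01  # meters-scale residual from 1 Hz sampling
            else:
                assert abs(ev - tv) / abs(tv) < 0.01, f

    def test_negative_coupling_yields_negative_severity_distance_correlation(self, small_cohort):
        merged = small_cohort.truth_daily.merge(
            small_cohort.latent, on=["subject", "date"]
        ).dropna(subset=["distance_m"])
        assert len(merged) >= 150
        r = np.corrcoef(merged["severity"], merged["distance_m"])[0, 1]
        assert r < 0
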