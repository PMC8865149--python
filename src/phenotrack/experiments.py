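"""Reusable validation experiments with known ground truth.

These are the package's own calibration studies: they generate data with
known parameters, run the estimators, and measure recovery.  The test suite
and the acceptance script both call them, so the numbers they report are
always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import mobility
from .config import MobilityConfig, SimConfig
from .models import ModelSpec, fit_lmm, loso_cv
from .simulate import DAY_MS, sample_path, simulate_day_trajectory, simulate_severity, substream

#: The 14 daily GPS features compared in the imputation benchmark.
_BENCH_FEATURES = mobility.GPS_FEATURES


def _remove_blocks(
    t_ms: np.ndarray, day_start: float, frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Drop random 1-3 h contiguous blocks until ~``frac`` of the day is gone."""
    keep = np.ones(len(t_ms), bool)
    target = frac * DAY_MS
    removed = 0.0
    guard = 0
    while removed < target and guard < 100:
        guard += 1
        dur = rng.uniform(1.0, 3.0) * 3_600_000
        start = day_start + rng.uniform(0, DAY_MS - dur)
        block = (t_ms >= start) & (t_ms < start + dur)
        newly = block & keep
        if newly.any():
            removed += newly.sum() / len(t_ms) * DAY_MS
            keep &= ~block
    return keep


def imputation_benchmark(
    n_days: int = 100,
    seed: int = 0,
    missing_lo: float = 0.3,
    missing_hi: float = 0.7,
    sample_interval_s: int = 10,
) -> dict:
    """Resampling vs linear imputation on synthetic days with known truth.

    Simulates one subject's dense movement for ``n_days`` days, observes it
    continuously at ``sample_interval_s``, removes 30-70% of each day's
    observation time in contiguous blocks, imputes the gaps with each
    method, and recomputes the 14 daily GPS features.  Errors are absolute
    deviations from the truth-trace features, normalized per feature by the
    mean magnitude of its true values, then averaged over features and days.

    Returns ``{"mae_resampling", "mae_linear", "ratio", "n_days"}`` where
    ``ratio = mae_linear / mae_resampling`` (> 1 means resampling wins).
    """
    cfg = SimConfig(seed=seed)
    mob_cfg = MobilityConfig()
    rng_mov = substream(seed, "bench", "movement")
    rng_rem = substream(seed, "bench", "removal")
    rng_sev = substream(seed, "bench", "severity")

    home = np.zeros(2)
    angles = rng_mov.uniform(0, 2 * np.pi, 3)
    radii = rng_mov.uniform(cfg.anchor_distance_min_m, cfg.anchor_distance_max_m, 3)
    anchors = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    severity = simulate_severity("BP", n_days, cfg, rng_sev)

    day_segments = []
    tracks = []
    cand = np.arange(0, 86400, sample_interval_s, dtype=float) * 1000.0
    for d in range(n_days):
        start = d * float(DAY_MS)
        seg = simulate_day_trajectory(home, anchors, severity[d], cfg, rng_mov, start)
        day_segments.append(seg)
        t = start + cand
        keep = _remove_blocks(t, start, rng_rem.uniform(missing_lo, missing_hi), rng_rem)
        pos = sample_path(seg, t[keep])
        tracks.append(pd.DataFrame({"timestamp": t[keep].astype(np.int64),
                                    "x": pos[:, 0], "y": pos[:, 1]}))

    truth_all = pd.concat(day_segments, ignore_index=True)
    truth = mobility.subject_mobility_days(
        None, tz="UTC", config=mob_cfg, seed=seed, precomputed_segments=truth_all
    ).days.set_index("date")

    track = pd.concat(tracks, ignore_index=True)
    segments = mobility.segment_flights_pauses(track, mob_cfg)
    results = {}
    for method in ("resampling", "linear"):
        rng_imp = substream(seed, "bench", "impute", method)
        complete = mobility.impute_gaps(segments, method=method, rng=rng_imp,
                                        config=mob_cfg, tz="UTC")
        days = mobility.subject_mobility_days(
            None, tz="UTC", config=mob_cfg, seed=seed, precomputed_segments=complete
        ).days.set_index("date")
        common = truth.index.intersection(days.index)
        errs = []
        for f in _BENCH_FEATURES:
            tv = truth.loc[common, f].to_numpy(float)
            ev = days.loc[common, f].to_numpy(float)
            ok = np.isfinite(tv) & np.isfinite(ev)
            scale = np.nanmean(np.abs(tv[ok])) if ok.any() else 1.0
            scale = scale if scale > 0 else 1.0
            if ok.any():
                errs.append(np.abs(ev[ok] - tv[ok]).mean() / scale)
        results[method] = float(np.mean(errs))
    return {
        "mae_resampling": results["resampling"],
        "mae_linear": results["linear"],
        "ratio": results["linear"] / results["resampling"],
        "n_days": n_days,
    }


# ---------------------------------------------------------------------------
# mixed-model parameter recovery
# ---------------------------------------------------------------------------

#: Generating fixed effects used by the recovery study (self-report +
#: baseline score + demographics structure).
RECOVERY_BETA = {
    "intercept": 2.0,
    "baseline_madrs": 0.6,
    "age": 0.05,
    "sex_M": -1.0,
    "diag_BP": 1.5,
    "diag_MDD": 3.0,
    "diag_SCZ": 0.5,
    "phq8": 0.8,
}
RECOVERY_SIGMA_B = 3.0
RECOVERY_SIGMA_E = 4.0


def _simulate_lmm_table(n_subjects: int, n_visits: int, rng: np.random.Generator) -> pd.DataFrame:
    groups = np.tile(["HC", "MDD", "BP", "SCZ"], n_subjects // 4 + 1)[:n_subjects]
    rows = []
    for i in range(n_subjects):
        b_i = rng.normal(0, RECOVERY_SIGMA_B)
        base = max(rng.normal(10, 8), 0)
        age = rng.normal(43, 12)
        sex = "M" if rng.random() < 0.4 else "F"
        for v in range(1, n_visits + 1):
            phq = max(rng.normal(8, 5), 0)
            x = dict(intercept=1.0, baseline_madrs=base, age=age,
                     sex_M=1.0 if sex == "M" else 0.0,
                     diag_BP=1.0 * (groups[i] == "BP"),
                     diag_MDD=1.0 * (groups[i] == "MDD"),
                     diag_SCZ=1.0 * (groups[i] == "SCZ"),
                     phq8=phq)
            mu = sum(RECOVERY_BETA[k] * x[k] for k in RECOVERY_BETA)
            y = mu + b_i + rng.normal(0, RECOVERY_SIGMA_E)
            rows.append(dict(subject=f"S{i:03d}", visit_index=v, madrs=y,
                             baseline_madrs=base, age=age, sex=sex,
                             diagnosis=groups[i], phq8=phq))
    return pd.DataFrame(rows)


def lmm_recovery(
    n_reps: int = 200, n_subjects: int = 40, n_visits: int = 4, seed: int = 0
) -> dict:
    """Coefficient recovery of the random-intercept model over replicates.

    Each replicate draws a fresh cohort from known coefficients with
    random-intercept SD 3 and residual SD 4, fits by maximum likelihood, and
    records whether each estimate falls within 3 standard errors of its
    generating value.  Also runs one LOSO-CV on the first replicate: with
    the subject intercept unpredictable, the attainable average RMSE is
    governed by sqrt(sigma_b^2 + sigma_e^2).

    Returns per-coefficient coverage, the minimum coverage, the LOSO average
    RMSE and its theoretical scale.
    """
    names = list(RECOVERY_BETA)
    hits = {k: 0 for k in names}
    loso_rmse = np.nan
    for rep in range(n_reps):
        rng = substream(seed, "recovery", rep)
        table = _simulate_lmm_table(n_subjects, n_visits, rng)
        X = pd.DataFrame({k: _design_col(table, k) for k in names})
        fm = fit_lmm(table["madrs"].to_numpy(float), X, table["subject"].to_numpy())
        for k in names:
            if abs(fm.params[k] - RECOVERY_BETA[k]) <= 3 * fm.bse[k]:
                hits[k] += 1
        if rep == 0:
            loso_rmse = loso_cv(table, ModelSpec("A", "full")).average_rmse
    coverage = {k: hits[k] / n_reps for k in names}
    return {
        "coverage": coverage,
        "min_coverage": min(coverage.values()),
        "loso_rmse": float(loso_rmse),
        "rmse_scale": float(np.hypot(RECOVERY_SIGMA_B, RECOVERY_SIGMA_E)),
        "n_reps": n_reps,
    }


def _design_col(table: pd.DataFrame, name: str) -> np.ndarray:
    if name == "intercept":
        return np.ones(len(table))
    if name == "sex_M":
        return (table["sex"] == "M").to_numpy(float)
    if name.startswith("diag_"):
        return (table["diagnosis"] == name[5:]).to_numpy(float)
    return table[name].to_numpy(float)
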