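"""GPS mobility feature extraction.

Converts duty-cycled GPS streams into a flight/pause trace, imputes the
unobserved intervals by resampling observed trace segments, and computes the
14 daily GPS-based mobility statistics (distance traveled, radius of
gyration, home time, significant-location entropy, circadian routines, ...)
plus the count of missing GPS minutes.

Coordinates are handled on a local planar (equirectangular) projection in
meters; timestamps are UTC epoch milliseconds; day and hour semantics follow
a per-subject IANA timezone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import KMeans

from .config import MobilityConfig

EARTH_RADIUS_M = 6_371_000.0

FLIGHT = "flight"
PAUSE = "pause"
GAP = "gap"

SEGMENT_COLUMNS = [
    "kind",
    "t_start",
    "t_end",
    "x_start",
    "y_start",
    "x_end",
    "y_end",
    "provenance",
]

#: Names of the 14 daily GPS-based mobility features, in canonical order.
GPS_FEATURES = [
    "n_significant_locations",
    "home_time_min",
    "distance_m",
    "max_diameter_m",
    "max_home_distance_m",
    "radius_of_gyration_m",
    "mean_flight_length_m",
    "sd_flight_length_m",
    "mean_flight_duration_s",
    "sd_flight_duration_s",
    "prob_pause",
    "sig_location_entropy",
    "circadian_routine",
    "weekend_weekday_routine",
]


def empty_segments() -> pd.DataFrame:
    return pd.DataFrame(columns=SEGMENT_COLUMNS)


def make_segments(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return empty_segments()
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


@dataclass
class PlanarRef:
    """Reference point of an equirectangular projection."""

    lat0: float
    lon0: float

    @property
    def meters_per_deg_lat(self) -> float:
        return EARTH_RADIUS_M * np.pi / 180.0

    @property
    def meters_per_deg_lon(self) -> float:
        return EARTH_RADIUS_M * np.cos(np.radians(self.lat0)) * np.pi / 180.0


def project_to_plane(
    gps: pd.DataFrame, ref: PlanarRef | None = None
) -> tuple[pd.DataFrame, PlanarRef]:
    """Project latitude/longitude to local planar meters.

    Equirectangular projection about the subject's median position: accurate
    to well under a meter over the few-kilometer extents of daily mobility.
    Returns a frame with columns ``timestamp, x, y`` and the reference used
    (so the projection can be inverted).
    """
    if len(gps) == 0:
        raise ValueError("cannot project an empty GPS stream")
    if ref is None:
        ref = PlanarRef(float(gps["latitude"].median()), float(gps["longitude"].median()))
    x = (gps["longitude"].to_numpy(float) - ref.lon0) * ref.meters_per_deg_lon
    y = (gps["latitude"].to_numpy(float) - ref.lat0) * ref.meters_per_deg_lat
    out = pd.DataFrame(
        {"timestamp": gps["timestamp"].to_numpy(np.int64), "x": x, "y": y}
    )
    return out, ref


def inverse_projection(x, y, ref: PlanarRef) -> tuple[np.ndarray, np.ndarray]:
    """Map planar meters back to latitude/longitude degrees."""
    lat = np.asarray(y, float) / ref.meters_per_deg_lat + ref.lat0
    lon = np.asarray(x, float) / ref.meters_per_deg_lon + ref.lon0
    return lat, lon


# ---------------------------------------------------------------------------
# flight / pause segmentation
# ---------------------------------------------------------------------------


def _perp_distances(px, py, ax, ay, bx, by) -> np.ndarray:
    # distance of points p from the infinite line through a and b
    dx, dy = bx - ax, by - ay
    norm = np.hypot(dx, dy)
    if norm == 0:
        return np.hypot(px - ax, py - ay)
    return np.abs(dx * (py - ay) - dy * (px - ax)) / norm


def _simplify_run(t, x, y, tol: float) -> list[int]:
    """Greedy straight-line simplification of a point run.

    Returns vertex indices such that every dropped point lies within ``tol``
    meters of the straight line between its bounding vertices.  A densely
    sampled straight flight therefore collapses to a single flight.
    """
    n = len(t)
    vertices = [0]
    i = 0
    while i < n - 1:
        j = i + 1
        while j + 1 < n:
            d = _perp_distances(x[i + 1 : j + 1], y[i + 1 : j + 1], x[i], y[i], x[j + 1], y[j + 1])
            if d.max() < tol:
                j += 1
            else:
                break
        vertices.append(j)
        i = j
    return vertices


def segment_flights_pauses(
    track: pd.DataFrame, config: MobilityConfig | None = None
) -> pd.DataFrame:
    """Decompose a planar track into pauses, flights and unobserved gaps.

    ``track`` has columns ``timestamp`` (ms, sorted), ``x``, ``y`` (m).
    Within each on-cycle burst (runs separated by more than
    ``burst_gap_s``), consecutive points staying within ``pause_radius_m``
    for at least ``min_pause_s`` collapse to a pause at their centroid;
    remaining motion becomes straight-line flights (simplified so collinear
    sub-steps merge).  Intervals between bursts are emitted as ``gap``
    segments whose endpoints are the bounding observed states.
    """
    cfg = config or MobilityConfig()
    if len(track) == 0:
        return empty_segments()
    t = track["timestamp"].to_numpy(np.int64)
    if np.any(np.diff(t) < 0):
        raise ValueError("track timestamps must be sorted")
    x = track["x"].to_numpy(float)
    y = track["y"].to_numpy(float)

    burst_breaks = np.flatnonzero(np.diff(t) > cfg.burst_gap_s * 1000.0) + 1
    starts = np.concatenate(([0], burst_breaks))
    ends = np.concatenate((burst_breaks, [len(t)]))

    rows: list[dict] = []
    prev_state: tuple[float, float, float] | None = None  # (t_ms, x, y)

    min_pause_ms = cfg.min_pause_s * 1000.0
    for s, e in zip(starts, ends):
        bt, bx, by = t[s:e], x[s:e], y[s:e]
        n = len(bt)
        # classify points into pause events and transit runs
        events: list[tuple] = []  # ("pause", t0, t1, cx, cy) or ("run", idx list)
        i = 0
        run: list[int] = []
        while i < n:
            j = i
            while j + 1 < n and np.hypot(bx[j + 1] - bx[i], by[j + 1] - by[i]) < cfg.pause_radius_m:
                j += 1
            if bt[j] - bt[i] >= min_pause_ms:
                if run:
                    events.append(("run", run))
                    run = []
                cx = float(bx[i : j + 1].mean())
                cy = float(by[i : j + 1].mean())
                events.append(("pause", float(bt[i]), float(bt[j]), cx, cy))
                i = j + 1
            else:
                run.append(i)
                i += 1
        if run:
            events.append(("run", run))

        # stitch events into segments: each maximal transit run is simplified
        # together with its bounding pause states so the connecting motion
        # collapses into the same straight flights
        burst_first_state: tuple | None = None
        cur: tuple | None = None  # current (t, x, y) state
        for k, ev in enumerate(events):
            if ev[0] == "pause":
                _, t0, t1, cx, cy = ev
                if cur is not None and t0 > cur[0]:
                    rows.append(
                        dict(kind=FLIGHT, t_start=cur[0], t_end=t0, x_start=cur[1],
                             y_start=cur[2], x_end=cx, y_end=cy, provenance="observed")
                    )
                rows.append(
                    dict(kind=PAUSE, t_start=t0, t_end=t1, x_start=cx, y_start=cy,
                         x_end=cx, y_end=cy, provenance="observed")
                )
                if burst_first_state is None:
                    burst_first_state = (t0, cx, cy)
                cur = (t1, cx, cy)
            else:
                idx = np.asarray(ev[1])
                rt, rx, ry = bt[idx].astype(float), bx[idx], by[idx]
                if cur is not None:
                    rt = np.concatenate(([cur[0]], rt))
                    rx = np.concatenate(([cur[1]], rx))
                    ry = np.concatenate(([cur[2]], ry))
                if k + 1 < len(events) and events[k + 1][0] == "pause":
                    _, nt0, _, ncx, ncy = events[k + 1]
                    rt = np.concatenate((rt, [nt0]))
                    rx = np.concatenate((rx, [ncx]))
                    ry = np.concatenate((ry, [ncy]))
                verts = _simplify_run(rt, rx, ry, cfg.pause_radius_m)
                for a, b in zip(verts[:-1], verts[1:]):
                    if rt[b] > rt[a]:
                        rows.append(
                            dict(kind=FLIGHT, t_start=rt[a], t_end=rt[b], x_start=rx[a],
                                 y_start=ry[a], x_end=rx[b], y_end=ry[b],
                                 provenance="observed")
                        )
                if burst_first_state is None:
                    burst_first_state = (rt[0], rx[0], ry[0])
                cur = (rt[-1], rx[-1], ry[-1])

        if burst_first_state is None:
            continue
        if prev_state is not None and burst_first_state[0] > prev_state[0]:
            rows.append(
                dict(kind=GAP, t_start=prev_state[0], t_end=burst_first_state[0],
                     x_start=prev_state[1], y_start=prev_state[2],
                     x_end=burst_first_state[1], y_end=burst_first_state[2],
                     provenance="observed")
            )
        if cur is not None:
            prev_state = cur

    seg = make_segments(rows)
    # keep chronological order with gaps interleaved
    return seg.sort_values("t_start", kind="stable", ignore_index=True)


# ---------------------------------------------------------------------------
# gap imputation
# ---------------------------------------------------------------------------


def _is_weekend(t_ms: np.ndarray, tz: str) -> np.ndarray:
    ts = pd.to_datetime(np.asarray(t_ms, np.int64), unit="ms", utc=True).tz_convert(tz)
    return ts.dayofweek.to_numpy() >= 5


def impute_gaps(
    segments: pd.DataFrame,
    method: str = "resampling",
    rng: np.random.Generator | None = None,
    config: MobilityConfig | None = None,
    tz: str = "UTC",
) -> pd.DataFrame:
    """Fill ``gap`` segments so the trace is complete between its endpoints.

    ``linear`` replaces each gap by a single straight flight.  ``resampling``
    draws observed flights and pauses as donors — weighted by temporal
    proximity (exponential decay) and a same-day-type (weekday/weekend)
    bonus — orients donated flights toward the gap's known endpoint and
    rescales the final segment to land exactly on it.  Both methods leave
    the bounding observed positions untouched; imputed segments carry
    ``provenance == "imputed"``.
    """
    cfg = config or MobilityConfig()
    rng = rng or np.random.default_rng(0)
    if method not in ("resampling", "linear"):
        raise ValueError(f"unknown imputation method: {method!r}")
    obs = segments[segments["kind"] != GAP]
    gaps = segments[segments["kind"] == GAP]
    if len(gaps) == 0:
        return segments.reset_index(drop=True)

    donors = obs[(obs["t_end"] > obs["t_start"])]
    use_resampling = method == "resampling"
    if use_resampling and len(donors) == 0:
        warnings.warn("no observed donor segments; falling back to linear imputation")
        use_resampling = False

    if use_resampling:
        d_t0 = donors["t_start"].to_numpy(float)
        d_t1 = donors["t_end"].to_numpy(float)
        d_mid = 0.5 * (d_t0 + d_t1)
        order = np.argsort(d_mid)
        d_mid = d_mid[order]
        d_dur = (d_t1 - d_t0)[order]
        dxy = (donors["x_end"].to_numpy(float) - donors["x_start"].to_numpy(float))[order]
        dyy = (donors["y_end"].to_numpy(float) - donors["y_start"].to_numpy(float))[order]
        d_len = np.hypot(dxy, dyy)
        d_speed = d_len / (d_dur / 1000.0)
        d_is_pause = (donors["kind"].to_numpy() == PAUSE)[order]
        flight_speeds = d_speed[~d_is_pause]
        v_fast = float(np.percentile(flight_speeds, 90)) if len(flight_speeds) else 1.0
        v_fast = max(v_fast, 0.1)
        d_weekend = _is_weekend(d_mid, tz)
        decay_ms = cfg.donor_decay_hours * 3600_000.0
        window_ms = 8.0 * decay_ms
        median_dur = float(np.median(d_dur))

    out_rows: list[pd.DataFrame] = [obs]
    imputed_rows: list[dict] = []

    g_weekend = _is_weekend(gaps["t_start"].to_numpy(float), tz) if len(gaps) else None

    for gi, (_, g) in enumerate(gaps.iterrows()):
        t0, t1 = float(g["t_start"]), float(g["t_end"])
        p0 = np.array([g["x_start"], g["y_start"]], float)
        p1 = np.array([g["x_end"], g["y_end"]], float)
        if t1 <= t0:
            continue
        if not use_resampling:
            imputed_rows.append(
                dict(kind=FLIGHT if np.hypot(*(p1 - p0)) > 0 else PAUSE,
                     t_start=t0, t_end=t1, x_start=p0[0], y_start=p0[1],
                     x_end=p1[0], y_end=p1[1], provenance="imputed")
            )
            continue

        mid = 0.5 * (t0 + t1)
        lo = np.searchsorted(d_mid, mid - window_ms)
        hi = np.searchsorted(d_mid, mid + window_ms)
        if hi <= lo:
            lo, hi = 0, len(d_mid)
        # donor weights: temporal proximity (exponential decay) x day-type
        # bonus.  The pause/flight decision uses duration-weighted shares so
        # the imputed state mix matches the chance of occupying a random
        # instant; the specific donor of that kind is then drawn by count,
        # keeping donated flight lengths/durations representative.
        w = np.exp(-np.abs(d_mid[lo:hi] - mid) / decay_ms)
        w = w * np.where(d_weekend[lo:hi] == g_weekend[gi], cfg.same_day_type_bonus, 1.0)
        pause_sel = d_is_pause[lo:hi]
        time_w = w * d_dur[lo:hi]
        p_pause = time_w[pause_sel].sum() / time_w.sum()
        cum_pause = np.cumsum(w[pause_sel])
        cum_flight = np.cumsum(w[~pause_sel])
        idx_pause = np.flatnonzero(pause_sel) + lo
        idx_flight = np.flatnonzero(~pause_sel) + lo

        def _draw_donor() -> int:
            take_pause = rng.random() < p_pause
            if take_pause and len(idx_pause) == 0:
                take_pause = False
            if not take_pause and len(idx_flight) == 0:
                take_pause = True
            cum, idx = (cum_pause, idx_pause) if take_pause else (cum_flight, idx_flight)
            return int(idx[np.searchsorted(cum, rng.uniform(0, cum[-1]))])

        max_draws = int(np.ceil((t1 - t0) / max(median_dur, 1.0))) + 50
        cur_t, cur_p = t0, p0.copy()
        rows_gap: list[dict] = []
        for _ in range(max_draws):
            if cur_t >= t1:
                break
            k = _draw_donor()
            dur = min(d_dur[k], t1 - cur_t)
            to_end = p1 - cur_p
            dist_to_end = float(np.hypot(*to_end))
            if d_is_pause[k]:
                rows_gap.append(
                    dict(kind=PAUSE, t_start=cur_t, t_end=cur_t + dur,
                         x_start=cur_p[0], y_start=cur_p[1],
                         x_end=cur_p[0], y_end=cur_p[1], provenance="imputed")
                )
                cur_t += dur
            else:
                length = d_len[k]
                remaining_s = (t1 - (cur_t + dur)) / 1000.0
                # donated flights keep their own length with a free heading as
                # long as the endpoint stays reachable at brisk donor speed;
                # otherwise head straight for the gap endpoint
                theta = rng.uniform(0, 2 * np.pi)
                new_p = cur_p + length * np.array([np.cos(theta), np.sin(theta)])
                if np.hypot(*(p1 - new_p)) > remaining_s * v_fast:
                    length = min(length, dist_to_end)
                    if dist_to_end > 0:
                        new_p = cur_p + to_end / dist_to_end * length
                    else:
                        new_p = cur_p.copy()
                rows_gap.append(
                    dict(kind=FLIGHT, t_start=cur_t, t_end=cur_t + dur,
                         x_start=cur_p[0], y_start=cur_p[1],
                         x_end=new_p[0], y_end=new_p[1], provenance="imputed")
                )
                cur_t, cur_p = cur_t + dur, new_p
        if cur_t < t1:  # donors exhausted; close with a flight/pause to the end
            rows_gap.append(
                dict(kind=FLIGHT if np.hypot(*(p1 - cur_p)) > 0 else PAUSE,
                     t_start=cur_t, t_end=t1, x_start=cur_p[0], y_start=cur_p[1],
                     x_end=p1[0], y_end=p1[1], provenance="imputed")
            )
        else:
            # rescale the final segment to land exactly on the gap endpoint
            last = rows_gap[-1]
            if last["x_end"] != p1[0] or last["y_end"] != p1[1]:
                last["x_end"], last["y_end"] = p1[0], p1[1]
                if last["kind"] == PAUSE and (
                    last["x_start"] != p1[0] or last["y_start"] != p1[1]
                ):
                    last["kind"] = FLIGHT
        imputed_rows.extend(rows_gap)

    out_rows.append(make_segments(imputed_rows))
    out = pd.concat([r for r in out_rows if len(r)], ignore_index=True)
    return out.sort_values("t_start", kind="stable", ignore_index=True)


# ---------------------------------------------------------------------------
# significant locations and home
# ---------------------------------------------------------------------------


@dataclass
class SignificantLocationSet:
    """Recurrent places: k-means centroids of pause positions."""

    centroids: np.ndarray  # (k, 2) planar meters
    seed: int = 0

    @property
    def k(self) -> int:
        return len(self.centroids)

    def assign(self, xy: np.ndarray) -> np.ndarray:
        """Index of the nearest centroid for each row of ``xy``."""
        xy = np.atleast_2d(np.asarray(xy, float))
        d = np.linalg.norm(xy[:, None, :] - self.centroids[None, :, :], axis=2)
        return d.argmin(axis=1)


def significant_locations(
    pauses: pd.DataFrame,
    config: MobilityConfig | None = None,
    seed: int = 0,
) -> SignificantLocationSet:
    """Cluster pause centroids into significant locations.

    k-means with pause durations as sample weights; k grows from 1 until
    every pause lies within ``sig_loc_radius_m`` of its centroid or
    ``k_max`` is reached.  Deterministic given ``seed``.
    """
    cfg = config or MobilityConfig()
    if len(pauses) == 0:
        raise ValueError("need at least one pause to find significant locations")
    xy = pauses[["x_start", "y_start"]].to_numpy(float)
    w = (pauses["t_end"] - pauses["t_start"]).to_numpy(float)
    w = np.maximum(w, 1.0)
    for k in range(1, cfg.k_max + 1):
        if k >= len(xy):
            centroids = xy[: len(xy)].copy()
            labels = np.arange(len(xy))
        else:
            km = KMeans(n_clusters=k, n_init=4, random_state=seed).fit(xy, sample_weight=w)
            centroids, labels = km.cluster_centers_, km.labels_
        dist = np.linalg.norm(xy - centroids[labels], axis=1)
        if dist.max() <= cfg.sig_loc_radius_m or k == cfg.k_max or k >= len(xy):
            return SignificantLocationSet(np.atleast_2d(centroids), seed=seed)
    return SignificantLocationSet(np.atleast_2d(centroids), seed=seed)


def _night_overlap_ms(t0: np.ndarray, t1: np.ndarray, tz: str, start_h: int, end_h: int) -> np.ndarray:
    """Milliseconds of each [t0, t1) interval falling in local night hours."""
    t0 = np.asarray(t0, float)
    t1 = np.asarray(t1, float)
    out = np.zeros(len(t0))
    if len(t0) == 0:
        return out
    first = pd.Timestamp(int(t0.min()), unit="ms", tz="UTC").tz_convert(tz)
    last = pd.Timestamp(int(t1.max()), unit="ms", tz="UTC").tz_convert(tz)
    days = pd.date_range(first.normalize() - pd.Timedelta(days=1),
                         last.normalize() + pd.Timedelta(days=1), freq="D", tz=tz)
    for d in days:
        for a, b in (
            (d + pd.Timedelta(hours=start_h), d + pd.Timedelta(hours=24)),
            (d, d + pd.Timedelta(hours=end_h)),
        ):
            a_ms = a.tz_convert("UTC").value / 1e6
            b_ms = b.tz_convert("UTC").value / 1e6
            out += np.clip(np.minimum(t1, b_ms) - np.maximum(t0, a_ms), 0, None)
    return out


def detect_home(
    segments: pd.DataFrame,
    tz: str = "UTC",
    config: MobilityConfig | None = None,
    seed: int = 0,
) -> np.ndarray | None:
    """Locate home as the heaviest nighttime (21:00-06:00 local) pause cluster.

    Returns the centroid as ``[x, y]`` or ``None`` if the subject has no
    nighttime pauses (home-dependent features are then undefined).
    """
    cfg = config or MobilityConfig()
    pauses = segments[segments["kind"] == PAUSE]
    if len(pauses) == 0:
        return None
    overlap = _night_overlap_ms(
        pauses["t_start"].to_numpy(float), pauses["t_end"].to_numpy(float),
        tz, cfg.night_start_hour, cfg.night_end_hour,
    )
    night = pauses[overlap > 0].copy()
    if len(night) == 0:
        return None
    night = night.assign(t_end=night["t_start"] + overlap[overlap > 0])  # weight by night time
    locs = significant_locations(night, cfg, seed=seed)
    labels = locs.assign(night[["x_start", "y_start"]].to_numpy(float))
    weights = np.bincount(labels, weights=overlap[overlap > 0], minlength=locs.k)
    return locs.centroids[int(weights.argmax())]


# ---------------------------------------------------------------------------
# daily features
# ---------------------------------------------------------------------------


def local_day_bounds(segments: pd.DataFrame, tz: str) -> pd.DatetimeIndex:
    """Local midnights spanning the segment range (inclusive of both ends)."""
    t0 = pd.Timestamp(int(segments["t_start"].min()), unit="ms", tz="UTC").tz_convert(tz)
    t1 = pd.Timestamp(int(segments["t_end"].max()) - 1, unit="ms", tz="UTC").tz_convert(tz)
    return pd.date_range(t0.normalize(), t1.normalize() + pd.Timedelta(days=1), freq="D", tz=tz)


def split_segments_by_day(segments: pd.DataFrame, tz: str) -> dict:
    """Clip segments at local midnights; returns ``{date: segment frame}``.

    Flights crossing midnight are split with linear position interpolation.
    """
    if len(segments) == 0:
        return {}
    bounds = local_day_bounds(segments, tz)
    edges = bounds.tz_convert("UTC").asi8 / 1e6  # ms
    t0 = segments["t_start"].to_numpy(float)
    t1 = segments["t_end"].to_numpy(float)
    out: dict = {}
    for di in range(len(edges) - 1):
        a, b = edges[di], edges[di + 1]
        sel = (t1 > a) & (t0 < b)
        if not sel.any():
            continue
        day = segments[sel].copy()
        s0 = day["t_start"].to_numpy(float)
        s1 = day["t_end"].to_numpy(float)
        frac0 = np.clip((a - s0) / (s1 - s0), 0, 1)
        frac1 = np.clip((b - s0) / (s1 - s0), 0, 1)
        for c0, c1 in (("x_start", "x_end"), ("y_start", "y_end")):
            v0 = day[c0].to_numpy(float)
            v1 = day[c1].to_numpy(float)
            day[c0] = v0 + frac0 * (v1 - v0)
            day[c1] = v0 + frac1 * (v1 - v0)
        day["t_start"] = np.maximum(s0, a)
        day["t_end"] = np.minimum(s1, b)
        out[bounds[di].date()] = day.reset_index(drop=True)
    return out


def _segment_home_time_ms(day: pd.DataFrame, home: np.ndarray, radius: float) -> float:
    """Exact time within ``radius`` of home, integrating along flights."""
    dur = (day["t_end"] - day["t_start"]).to_numpy(float)
    a = day[["x_start", "y_start"]].to_numpy(float) - np.asarray(home)[None, :]
    b = day[["x_end", "y_end"]].to_numpy(float) - np.asarray(home)[None, :]
    d = b - a
    A = (d * d).sum(axis=1)
    static = A < 1e-12
    total = float(dur[static & (np.hypot(a[:, 0], a[:, 1]) <= radius)].sum())
    if static.all():
        return total
    # moving segments: fraction of the [0,1] parameter with |a + s d| <= radius
    am, dm, durm = a[~static], d[~static], dur[~static]
    Am = A[~static]
    Bm = 2 * (am * dm).sum(axis=1)
    Cm = (am * am).sum(axis=1) - radius**2
    disc = Bm * Bm - 4 * Am * Cm
    ok = disc > 0
    if ok.any():
        r = np.sqrt(disc[ok])
        s0 = np.maximum((-Bm[ok] - r) / (2 * Am[ok]), 0.0)
        s1 = np.minimum((-Bm[ok] + r) / (2 * Am[ok]), 1.0)
        frac = np.maximum(s1 - s0, 0.0)
        total += float((frac * durm[ok]).sum())
    return total


def _time_weighted_moments(day: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Time-weighted mean position and mean squared radius about it."""
    w = (day["t_end"] - day["t_start"]).to_numpy(float)
    a = day[["x_start", "y_start"]].to_numpy(float)
    b = day[["x_end", "y_end"]].to_numpy(float)
    T = w.sum()
    mean = ((a + b) / 2 * w[:, None]).sum(axis=0) / T
    # ∫|r|² over a linear segment from a to b: (|a|² + a·(b−a) + |b−a|²/3)
    d = b - a
    sq = (a * a).sum(axis=1) + (a * d).sum(axis=1) + (d * d).sum(axis=1) / 3.0
    mean_sq = (sq * w).sum() / T
    var = mean_sq - mean @ mean
    return mean, max(var, 0.0)


def _max_pairwise(points: np.ndarray) -> float:
    pts = np.unique(points, axis=0)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 20:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    return float(d.max())


def daily_mobility_features(
    day: pd.DataFrame,
    home: np.ndarray | None,
    locations: SignificantLocationSet | None,
    config: MobilityConfig | None = None,
) -> dict:
    """The 12 within-day GPS features for one local day's complete segments.

    (Circadian and weekend-weekday routines need the subject's other days
    and are attached by :func:`compute_routines`; missing minutes are counted
    from the raw stream by :func:`gps_minutes`.)  Returns NaN for every
    feature if the day has no segments.
    """
    cfg = config or MobilityConfig()
    feats = {name: np.nan for name in GPS_FEATURES}
    if day is None or len(day) == 0:
        return feats
    flights = day[day["kind"] == FLIGHT]
    pauses = day[day["kind"] == PAUSE]

    lengths = np.hypot(
        flights["x_end"] - flights["x_start"], flights["y_end"] - flights["y_start"]
    ).to_numpy(float)
    durations_s = ((flights["t_end"] - flights["t_start"]) / 1000.0).to_numpy(float)
    feats["distance_m"] = float(lengths.sum())
    if len(flights) > 0:
        feats["mean_flight_length_m"] = float(lengths.mean())
        feats["sd_flight_length_m"] = float(lengths.std(ddof=1)) if len(flights) > 1 else 0.0
        feats["mean_flight_duration_s"] = float(durations_s.mean())
        feats["sd_flight_duration_s"] = float(durations_s.std(ddof=1)) if len(flights) > 1 else 0.0
    else:
        feats["mean_flight_length_m"] = 0.0
        feats["sd_flight_length_m"] = 0.0
        feats["mean_flight_duration_s"] = 0.0
        feats["sd_flight_duration_s"] = 0.0

    endpoints = np.vstack(
        [day[["x_start", "y_start"]].to_numpy(float), day[["x_end", "y_end"]].to_numpy(float)]
    )
    feats["max_diameter_m"] = _max_pairwise(endpoints)

    _, var = _time_weighted_moments(day)
    feats["radius_of_gyration_m"] = float(np.sqrt(var))

    pause_ms = float((pauses["t_end"] - pauses["t_start"]).sum())
    feats["prob_pause"] = pause_ms / (1440 * 60 * 1000.0)

    if home is not None:
        feats["home_time_min"] = _segment_home_time_ms(day, home, cfg.home_radius_m) / 60000.0
        feats["max_home_distance_m"] = float(
            np.linalg.norm(endpoints - np.asarray(home)[None, :], axis=1).max()
        )

    if locations is not None and len(pauses) > 0:
        labels = locations.assign(pauses[["x_start", "y_start"]].to_numpy(float))
        w = (pauses["t_end"] - pauses["t_start"]).to_numpy(float)
        shares = np.bincount(labels, weights=w, minlength=locations.k)
        feats["n_significant_locations"] = float((shares > 0).sum())
        p = shares[shares > 0] / shares.sum()
        feats["sig_location_entropy"] = float(-(p * np.log(p)).sum())
    elif len(pauses) == 0:
        feats["n_significant_locations"] = 0.0
        feats["sig_location_entropy"] = 0.0
    return feats


# ---------------------------------------------------------------------------
# routines (circadian / weekend-weekday similarity)
# ---------------------------------------------------------------------------


def bin_day_positions(day: pd.DataFrame, day_start_ms: float, day_end_ms: float,
                      bin_minutes: int) -> np.ndarray:
    """Time-weighted mean position of the trajectory in each half-hour bin.

    Returns an ``(n_bins, 2)`` array with NaN rows for uncovered bins.
    """
    n_bins = int(round((day_end_ms - day_start_ms) / 60000.0 / bin_minutes))
    n_bins = max(n_bins, 1)
    acc = np.zeros((n_bins, 2))
    wsum = np.zeros(n_bins)
    bin_ms = (day_end_ms - day_start_ms) / n_bins
    t0 = day["t_start"].to_numpy(float)
    t1 = day["t_end"].to_numpy(float)
    a = day[["x_start", "y_start"]].to_numpy(float)
    b = day[["x_end", "y_end"]].to_numpy(float)
    for i in range(len(day)):
        lo = int((t0[i] - day_start_ms) // bin_ms)
        hi = int(np.ceil((t1[i] - day_start_ms) / bin_ms))
        for k in range(max(lo, 0), min(hi, n_bins)):
            ba = day_start_ms + k * bin_ms
            bb = ba + bin_ms
            oa, ob = max(t0[i], ba), min(t1[i], bb)
            if ob <= oa:
                continue
            dur = t1[i] - t0[i]
            if dur <= 0:
                continue
            fa = (oa - t0[i]) / dur
            fb = (ob - t0[i]) / dur
            mid = a[i] + (fa + fb) / 2.0 * (b[i] - a[i])
            acc[k] += mid * (ob - oa)
            wsum[k] += ob - oa
    out = np.full((n_bins, 2), np.nan)
    mask = wsum > 0
    out[mask] = acc[mask] / wsum[mask, None]
    return out


def routine_similarity(bins_a: np.ndarray, bins_b: np.ndarray, threshold_m: float) -> float:
    """Fraction of co-observed bins whose positions lie within threshold."""
    ok = ~(np.isnan(bins_a[:, 0]) | np.isnan(bins_b[:, 0]))
    if not ok.any():
        return np.nan
    d = np.linalg.norm(bins_a[ok] - bins_b[ok], axis=1)
    return float((d <= threshold_m).mean())


def compute_routines(
    bin_stack: np.ndarray, is_weekend: np.ndarray, threshold_m: float
) -> tuple[np.ndarray, np.ndarray]:
    """Circadian and weekend-weekday routine for each day.

    ``bin_stack`` is ``(n_days, n_bins, 2)``.  The circadian routine of a day
    is its mean similarity to all the subject's other days; the
    weekend-weekday routine is its mean similarity to days of the opposite
    type.
    """
    n = len(bin_stack)
    sim = np.full((n, n), np.nan)
    obs = ~np.isnan(bin_stack[:, :, 0])
    for i in range(n):
        diff = bin_stack[i][None, :, :] - bin_stack  # (n, bins, 2)
        dist = np.linalg.norm(diff, axis=2)
        co = obs[i][None, :] & obs
        with np.errstate(invalid="ignore"):
            hits = ((dist <= threshold_m) & co).sum(axis=1).astype(float)
            counts = co.sum(axis=1).astype(float)
        sim[i] = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    circadian = np.full(n, np.nan)
    cross = np.full(n, np.nan)
    for i in range(n):
        others = np.ones(n, bool)
        others[i] = False
        vals = sim[i, others]
        if np.isfinite(vals).any():
            circadian[i] = np.nanmean(vals)
        opp = is_weekend != is_weekend[i]
        vals = sim[i, opp]
        if opp.any() and np.isfinite(vals).any():
            cross[i] = np.nanmean(vals)
    return circadian, cross


# ---------------------------------------------------------------------------
# missing-minute accounting
# ---------------------------------------------------------------------------


def expected_on_minutes(day_ms: float, on_s: float, off_s: float) -> int:
    """Minutes of a day intersecting at least one on-cycle (midnight phase)."""
    cycle = on_s + off_s
    if off_s <= 0:
        return int(round(day_ms / 60000.0))
    minutes = set()
    t = 0.0
    day_s = day_ms / 1000.0
    while t < day_s:
        end = min(t + on_s, day_s)
        minutes.update(range(int(t // 60), int(np.ceil(end / 60.0 - 1e-9))))
        t += cycle
    return len(minutes)


def gps_minutes(
    t_ms: np.ndarray, day_start_ms: float, day_end_ms: float, on_s: float, off_s: float
) -> tuple[int, int]:
    """(observed minutes, missing minutes) of raw GPS for one local day.

    Expected minutes are those intersecting an on-cycle anchored at local
    midnight; a minute is observed if it contains at least one raw sample.
    """
    t = np.asarray(t_ms, float)
    t = t[(t >= day_start_ms) & (t < day_end_ms)]
    expected = expected_on_minutes(day_end_ms - day_start_ms, on_s, off_s)
    observed = len(np.unique(((t - day_start_ms) // 60000.0).astype(int)))
    observed = min(observed, expected)
    return observed, expected - observed


# ---------------------------------------------------------------------------
# per-subject orchestration
# ---------------------------------------------------------------------------


@dataclass
class SubjectMobility:
    """Result bundle of the per-subject GPS pipeline."""

    days: pd.DataFrame  # one row per local day with the 14 features
    home: np.ndarray | None
    locations: SignificantLocationSet | None
    segments: pd.DataFrame = field(repr=False, default=None)


def subject_mobility_days(
    gps: pd.DataFrame,
    tz: str = "UTC",
    config: MobilityConfig | None = None,
    seed: int = 0,
    gps_on_s: float = 120.0,
    gps_off_s: float = 600.0,
    method: str = "resampling",
    ref: PlanarRef | None = None,
    precomputed_segments: pd.DataFrame | None = None,
) -> SubjectMobility:
    """Full GPS pipeline for one subject: project, segment, impute, featurize.

    When ``precomputed_segments`` is given (e.g. a simulator's ground-truth
    trace) the projection/segmentation/imputation stages are skipped and the
    features are computed directly on those segments.
    """
    cfg = config or MobilityConfig()
    rng = np.random.default_rng(seed)

    if precomputed_segments is not None:
        complete = precomputed_segments
        raw_t = np.array([])
    else:
        gps = gps[gps["accuracy"] <= cfg.accuracy_max_m]
        if len(gps) == 0:
            return SubjectMobility(pd.DataFrame(), None, None, empty_segments())
        track, _ = project_to_plane(gps, ref=ref)
        raw_t = track["timestamp"].to_numpy(float)
        segments = segment_flights_pauses(track, cfg)
        complete = impute_gaps(segments, method=method, rng=rng, config=cfg, tz=tz)

    if len(complete) == 0:
        return SubjectMobility(pd.DataFrame(), None, None, complete)

    home = detect_home(complete, tz=tz, config=cfg, seed=seed)
    pauses = complete[complete["kind"] == PAUSE]
    locations = significant_locations(pauses, cfg, seed=seed) if len(pauses) else None

    by_day = split_segments_by_day(complete, tz)
    bounds = local_day_bounds(complete, tz)
    edges = bounds.tz_convert("UTC").asi8 / 1e6

    rows = []
    bin_stacks = []
    dates = []
    for di, d in enumerate(bounds[:-1]):
        date = d.date()
        day = by_day.get(date)
        feats = daily_mobility_features(day, home, locations, cfg)
        if precomputed_segments is not None:
            observed, missing = 0, 0
        else:
            observed, missing = gps_minutes(raw_t, edges[di], edges[di + 1], gps_on_s, gps_off_s)
            if observed == 0:
                feats = {name: np.nan for name in GPS_FEATURES}
        feats["gps_missing_minutes"] = missing
        feats["date"] = date
        feats["is_weekend"] = d.dayofweek >= 5
        rows.append(feats)
        dates.append(date)
        if day is not None and len(day) and not (
            precomputed_segments is None and observed == 0
        ):
            bin_stacks.append(
                bin_day_positions(day, edges[di], edges[di + 1], cfg.routine_bin_minutes)
            )
        else:
            nb = max(int(round((edges[di + 1] - edges[di]) / 60000.0 / cfg.routine_bin_minutes)), 1)
            bin_stacks.append(np.full((nb, 2), np.nan))

    days = pd.DataFrame(rows)
    nb = max(len(b) for b in bin_stacks)
    stack = np.full((len(bin_stacks), nb, 2), np.nan)
    for i, b in enumerate(bin_stacks):
        stack[i, : len(b)] = b
    circ, cross = compute_routines(stack, days["is_weekend"].to_numpy(), cfg.routine_threshold_m)
    days["circadian_routine"] = circ
    days["weekend_weekday_routine"] = cross
    cols = ["date", "is_weekend"] + GPS_FEATURES + ["gps_missing_minutes"]
    return SubjectMobility(days[cols], home, locations, complete)
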