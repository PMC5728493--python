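"""Cluster waggle runs into dances and project them to field coordinates.

Each decoded waggle run is a point in (x, y, t) data space — comb position
in pixels plus time-of-day scaled to quarter units per second. Runs of the
same dance form a tight spatiotemporal clump, so single-linkage clustering
with threshold ``cluster_dist`` groups them; clusters with fewer than
``min_runs_per_dance`` (default 4) runs are not dances. Within a dance,
individual run orientations can be 180-deg flipped by the orientation
decoder; a one-point RANSAC over circular distance finds the consensus mode
and excludes such outliers before circular averaging.

A dance then maps to the field as a polar coordinate: bearing = solar
azimuth at the dance start + mean comb angle (compass convention), distance
= linear conversion of the mean waggle duration with a feeder-calibrated
factor, and profitability = waggle/return duration ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from waggledance.angles import circular_distance, circular_mean, wrap360
from waggledance.config import MappingConfig
from waggledance.solar import solar_azimuth

__all__ = [
    "xyt_embed",
    "cluster_dances",
    "ransac_angles",
    "circular_mean",
    "duration_to_distance",
    "calibrate_factor",
    "profitability",
    "project_dance",
    "build_dances",
    "Dance",
    "FieldVector",
]


@dataclass
class Dance:
    """A cluster of >= min_runs_per_dance waggle runs with robust averages."""

    id: int
    run_indices: list
    inlier_mask: np.ndarray
    mean_duration_ms: float
    mean_return_ms: float | None
    mean_angle_comb_deg: float
    start_time: datetime
    comb_xy: tuple
    weak_mode: bool = False

    @property
    def n_runs(self) -> int:
        return len(self.run_indices)

    @property
    def n_inliers(self) -> int:
        return int(np.sum(self.inlier_mask))


@dataclass
class FieldVector:
    """Field-space reading of a dance: polar coordinate plus map offset."""

    distance_m: float
    bearing_deg: float
    map_xy_m: tuple
    profitability: float | None
    n_runs: int
    low_sun: bool = False


def xyt_embed(positions_px, times_s, cfg: MappingConfig) -> np.ndarray:
    """Embed runs as (x, y, t * time_scale); t in seconds since midnight."""
    pos = np.asarray(positions_px, dtype=np.float64).reshape(-1, 2)
    t = np.asarray(times_s, dtype=np.float64).reshape(-1)
    if len(pos) != len(t):
        raise ValueError("positions and times must have equal length")
    return np.column_stack([pos, t * cfg.time_scale])


def cluster_dances(points: np.ndarray, cfg: MappingConfig) -> list:
    """Single-linkage clusters of XYT points; small clusters are dropped.

    Returns a list of index arrays, one per retained cluster, ordered by
    earliest embedded time.
    """
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) == 0:
        return []
    if len(pts) == 1:
        labels = np.array([1])
    else:
        z = linkage(pts, method="single")
        labels = fcluster(z, t=cfg.cluster_dist, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        if len(idx) >= cfg.min_runs_per_dance:
            clusters.append(idx)
    clusters.sort(key=lambda idx: pts[idx, 2].min())
    return clusters


def _consensus(angles: np.ndarray, center: float, tol_deg: float) -> np.ndarray:
    return circular_distance(angles, center) <= tol_deg


def _circ_var(angles: np.ndarray) -> float:
    rad = np.deg2rad(angles)
    return 1.0 - float(np.hypot(np.sin(rad).mean(), np.cos(rad).mean()))


def ransac_angles(angles, cfg: MappingConfig, rng=None):
    """One-point RANSAC over waggle orientations.

    The model is a single mean direction: each iteration samples one angle
    as candidate center and counts angles within ``ransac_inlier_deg``
    circular distance. The largest consensus set wins (ties: smaller
    circular variance). Returns ``(inlier_mask, robust_mean_deg, weak_mode)``
    with ``weak_mode`` set when the consensus is smaller than
    ``min_runs_per_dance`` — the caller should discard such dances.
    """
    a = wrap360(np.asarray(angles, dtype=float).reshape(-1))
    if len(a) == 0:
        raise ValueError("ransac_angles needs at least one angle")
    if rng is None:
        rng = np.random.default_rng(0)
    best_mask = None
    best_key = None
    for _ in range(cfg.ransac_iters):
        center = a[int(rng.integers(0, len(a)))]
        mask = _consensus(a, center, cfg.ransac_inlier_deg)
        key = (int(mask.sum()), -_circ_var(a[mask]))
        if best_key is None or key > best_key:
            best_key, best_mask = key, mask
    robust_mean = circular_mean(a[best_mask])
    # "no strong mode": the consensus must be a majority and large enough
    n_in = int(best_mask.sum())
    weak = n_in < cfg.min_runs_per_dance or n_in <= len(a) // 2
    return best_mask, robust_mean, weak


def duration_to_distance(d_w_ms: float, f_d: float) -> float:
    """Linear duration-to-distance mapping r = f_d * d_w (zero intercept)."""
    if d_w_ms <= 0:
        raise ValueError("waggle duration must be positive")
    if f_d <= 0:
        raise ValueError("conversion factor must be positive")
    return f_d * d_w_ms


def calibrate_factor(
    angles_deg,
    durations_ms,
    feeder_bearing_comb_deg: float,
    feeder_distance_m: float,
    angle_window_deg: float = 10.0,
):
    """Collective calibration of the duration-to-distance factor.

    Selects all waggle runs whose comb angle lies within +/- the window of
    the known feeder's comb bearing, averages their durations, and returns
    ``(f_d, stats)`` with ``f_d = distance / mean duration`` in m/ms and
    summary statistics (n, mean, sd, coefficient of variation).
    """
    a = np.asarray(angles_deg, dtype=float).reshape(-1)
    d = np.asarray(durations_ms, dtype=float).reshape(-1)
    if len(a) != len(d):
        raise ValueError("angles and durations must have equal length")
    sel = circular_distance(a, feeder_bearing_comb_deg) <= angle_window_deg
    if not np.any(sel):
        raise ValueError(
            f"no waggle runs within +/-{angle_window_deg} deg of the feeder bearing"
        )
    dur = d[sel]
    mean = float(dur.mean())
    sd = float(dur.std(ddof=1)) if len(dur) > 1 else 0.0
    stats = {
        "n": int(sel.sum()),
        "mean_duration_ms": mean,
        "sd_duration_ms": sd,
        "cv": sd / mean if mean > 0 else np.nan,
    }
    return feeder_distance_m / mean, stats


def profitability(d_w_ms: float, d_r_ms: float) -> float:
    """Profitability proxy d_w / d_r; shorter return runs score higher."""
    if d_r_ms <= 0:
        raise ValueError("return-run duration must be positive")
    return d_w_ms / d_r_ms


def build_dances(
    positions_px,
    times: list,
    durations_ms,
    orientations_deg,
    cfg: MappingConfig,
    rng=None,
    run_end_times: list = None,
) -> list:
    """Cluster decoded runs into :class:`Dance` objects.

    ``times`` are absolute datetimes of run starts; ``run_end_times``
    (optional) enable return-run durations as the gaps between consecutive
    inlier runs — gaps spanning an excluded outlier are not used.
    Dances without a strong orientation mode are discarded.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    times = list(times)
    durations_ms = np.asarray(durations_ms, dtype=float)
    orientations_deg = np.asarray(orientations_deg, dtype=float)
    seconds = np.array(
        [t.hour * 3600 + t.minute * 60 + t.second + t.microsecond / 1e6 for t in times]
    )
    points = xyt_embed(positions_px, seconds, cfg)
    clusters = cluster_dances(points, cfg)
    dances = []
    for did, idx in enumerate(clusters):
        idx = idx[np.argsort(seconds[idx])]
        mask, robust_mean, weak = ransac_angles(orientations_deg[idx], cfg, rng)
        if weak:
            continue
        inlier_idx = idx[mask]
        mean_dur = float(durations_ms[inlier_idx].mean())
        mean_ret = None
        if run_end_times is not None:
            gaps = []
            for a, b_ in zip(idx[:-1], idx[1:]):
                if mask[np.nonzero(idx == a)[0][0]] and mask[np.nonzero(idx == b_)[0][0]]:
                    gap = (times[b_] - run_end_times[a]).total_seconds() * 1000.0
                    if gap > 0:
                        gaps.append(gap)
            if gaps:
                mean_ret = float(np.mean(gaps))
        comb_xy = tuple(np.median(np.asarray(positions_px)[inlier_idx], axis=0))
        dances.append(
            Dance(
                id=did,
                run_indices=list(idx),
                inlier_mask=mask,
                mean_duration_ms=mean_dur,
                mean_return_ms=mean_ret,
                mean_angle_comb_deg=robust_mean,
                start_time=times[inlier_idx[0]],
                comb_xy=comb_xy,
            )
        )
    return dances


def project_dance(dance: Dance, cfg: MappingConfig, azimuth_deg: float = None) -> FieldVector:
    """Translate a dance to a field vector.

    bearing = (solar azimuth at the dance's first waggle run + mean comb
    angle) mod 360; distance = f_d * mean waggle duration; map offset =
    (distance sin(bearing), distance cos(bearing)) east/north of the hive.
    A fixed ``azimuth_deg`` overrides the solar computation (useful for
    controlled experiments).
    """
    low_sun = False
    if azimuth_deg is None:
        azimuth_deg, low_sun = solar_azimuth(dance.start_time, cfg.hive_lat, cfg.hive_lon)
    bearing = float(wrap360(azimuth_deg + dance.mean_angle_comb_deg))
    distance = duration_to_distance(dance.mean_duration_ms, cfg.distance_factor)
    rad = np.deg2rad(bearing)
    east, north = distance * np.sin(rad), distance * np.cos(rad)
    prof = None
    if dance.mean_return_ms is not None and dance.mean_return_ms > 0:
        prof = profitability(dance.mean_duration_ms, dance.mean_return_ms)
    return FieldVector(
        distance_m=float(distance),
        bearing_deg=bearing,
        map_xy_m=(float(east), float(north)),
        profitability=prof,
        n_runs=dance.n_runs,
        low_sun=low_sun,
    )
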