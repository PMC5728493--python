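"""Synthetic validation protocols for the full pipeline.

Each experiment here renders ground-truth-annotated synthetic scenes with
:mod:`waggledance.synthetic`, pushes them through the module under test and
measures decoding error against the truth. These are the protocols the test
suite and ``scripts/acceptance.py`` execute; all randomness derives from one
explicit seed.

Problem sizes follow the validation design: 200 waggle runs for the
orientation and duration experiments, ~800 balanced clips for filter
training and 571 dances (4–17 runs each, per-run angular spread 14.37 deg,
durations around 583 ms) for the mapping experiment.
"""

from __future__ import annotations

import numpy as np

from waggledance import attention, filternet, mapping, orientation, synthetic
from waggledance.angles import circular_distance, circular_mean, signed_delta, wrap360
from waggledance.config import (
    AttentionConfig,
    FilterConfig,
    GroundTruthRun,
    MappingConfig,
    OrientationConfig,
    SceneConfig,
)

__all__ = [
    "orientation_error_experiment",
    "duration_error_experiment",
    "filter_training_experiment",
    "mapping_experiment",
]


def _decode_snippets(snips, centers, ori_cfg):
    return orientation.decode_run(None, ori_cfg, positions=centers, snippets=snips)


def orientation_error_experiment(
    n_runs: int = 200,
    seed: int = 0,
    noise_sd: float = 4.0,
    scene_cfg: SceneConfig = None,
    ori_cfg: OrientationConfig = None,
) -> dict:
    """Decode n synthetic waggle runs with uniform random true orientations.

    Each run is rendered as the 50x50 snippet sequence the attention module
    would export (crop following the low-passed trajectory, detection-like
    centroid jitter), decoded, and compared to truth. Returns signed
    circular errors plus their mean and standard deviation in degrees.
    """
    if scene_cfg is None:
        scene_cfg = SceneConfig(noise_sd=noise_sd)
    if ori_cfg is None:
        ori_cfg = OrientationConfig(
            frame_rate=scene_cfg.frame_rate, px_per_mm=scene_cfg.px_per_mm
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    errors = np.empty(n_runs)
    n_flipped = 0
    for i in range(n_runs):
        true_dir = float(rng.uniform(0.0, 360.0))
        n_frames = int(rng.integers(40, 81))
        truth = GroundTruthRun(0, n_frames, (0.0, 0.0), true_dir)
        snips, centers = synthetic.render_run_snippets(
            scene_cfg,
            truth,
            rng=rng,
            size=ori_cfg.image_size,
            jitter_px=1.0,
            phase=float(rng.uniform(0.0, 2.0 * np.pi)),
        )
        res = _decode_snippets(snips, centers, ori_cfg)
        err = float(signed_delta(res.direction_deg, true_dir))
        errors[i] = err
        if abs(err) > 90.0:
            n_flipped += 1
    return {
        "errors_deg": errors,
        "mean_error_deg": float(errors.mean()),
        "sd_error_deg": float(errors.std(ddof=1)),
        "flip_fraction": n_flipped / n_runs,
        "n": n_runs,
    }


def duration_error_experiment(
    n_runs: int = 200,
    seed: int = 0,
    duration_range_ms=(300.0, 900.0),
    scene_cfg: SceneConfig = None,
    att_cfg: AttentionConfig = None,
) -> dict:
    """Duration accuracy of the attention module on single-run scenes.

    Each scene holds one waggle run of known duration drawn uniformly from
    ``duration_range_ms``, with still pre/post roll. The emitted run with
    the largest frame overlap is matched to the truth; the signed duration
    errors (decoded - true) are summarized. Undetected runs are counted as
    misses and excluded from the error statistics.
    """
    if scene_cfg is None:
        scene_cfg = SceneConfig(resolution=(160, 160))
    if att_cfg is None:
        att_cfg = AttentionConfig(sample_rate=scene_cfg.frame_rate)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    w, h = scene_cfg.resolution
    pre_roll = post_roll = 50
    errors = []
    start_errors = []
    end_errors = []
    n_missed = 0
    for i in range(n_runs):
        dur_ms = float(rng.uniform(*duration_range_ms))
        n_frames = max(1, int(round(dur_ms / 1000.0 * scene_cfg.frame_rate)))
        true_dur_ms = n_frames / scene_cfg.frame_rate * 1000.0
        direction = float(rng.uniform(0.0, 360.0))
        travel = n_frames * scene_cfg.forward_speed_px_per_frame
        from waggledance.angles import heading_vector

        fwd = heading_vector(direction)
        start = np.array([w / 2.0, h / 2.0]) - fwd * travel / 2.0
        truth = GroundTruthRun(0, n_frames, tuple(start), direction)
        frames = synthetic.render_run_scene(
            scene_cfg,
            truth,
            pre_roll=pre_roll,
            post_roll=post_roll,
            rng=rng,
            phase=float(rng.uniform(0.0, 2.0 * np.pi)),
        )
        runs = attention.detect_runs(frames, att_cfg, export_snippets=False)
        t0, t1 = pre_roll, pre_roll + n_frames - 1
        best, best_ov = None, 0
        for run in runs:
            ov = min(run.end_frame, t1) - max(run.start_frame, t0) + 1
            if ov > best_ov:
                best, best_ov = run, ov
        if best is None:
            n_missed += 1
            continue
        errors.append(best.duration_ms - true_dur_ms)
        start_errors.append(best.start_frame - t0)
        end_errors.append(best.end_frame - t1)
    errors = np.asarray(errors)
    return {
        "errors_ms": errors,
        "mean_error_ms": float(errors.mean()),
        "abs_mean_error_ms": float(abs(errors.mean())),
        "sd_error_ms": float(errors.std(ddof=1)),
        "start_frame_errors": np.asarray(start_errors),
        "end_frame_errors": np.asarray(end_errors),
        "n_missed": n_missed,
        "n": n_runs,
    }


def make_filter_clips(n_per_class: int, seed: int, scene_cfg: SceneConfig = None):
    """Balanced labeled clip corpus: waggle vs walking/stationary/grooming."""
    if scene_cfg is None:
        scene_cfg = SceneConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    clips = []
    kinds = ("walking", "stationary", "grooming_jitter")
    for i in range(n_per_class):
        n_frames = int(rng.integers(30, 111))
        frames = synthetic.render_waggle_snippet(scene_cfg, n_frames=n_frames, rng=rng)
        clips.append(filternet.LabeledClip(frames=frames, label=1))
        kind = kinds[i % len(kinds)]
        n_neg = int(rng.integers(60, 129))
        frames = synthetic.render_non_waggle_snippet(
            scene_cfg, kind, n_frames=n_neg, rng=rng
        )
        clips.append(filternet.LabeledClip(frames=frames, label=0))
    return clips


def filter_training_experiment(
    n_per_class: int = 400,
    seed: int = 0,
    cfg: FilterConfig = None,
    scene_cfg: SceneConfig = None,
    verbose: bool = False,
) -> dict:
    """Train the filter network on a balanced synthetic corpus.

    Follows the snippet-filter training protocol (random 128-frame
    subsequences, zero padding, flip augmentation, Adam, 20% held-out
    split) and reports the held-out accuracy and precision–recall curve.
    """
    if cfg is None:
        cfg = FilterConfig(seed=seed)
    clips = make_filter_clips(n_per_class, seed, scene_cfg)
    model, metrics = filternet.train(clips, cfg, verbose=verbose)
    metrics["n_clips"] = len(clips)
    metrics["model"] = model
    return metrics


def mapping_experiment(
    n_dances: int = 571,
    seed: int = 0,
    base_comb_angle_deg: float = 120.0,
    azimuth_deg: float = 135.0,
    run_angle_sd_deg: float = 14.37,
    duration_mean_ms: float = 582.79,
    duration_sd_ms: float = 196.10,
    noise_sd: float = 4.0,
    scene_cfg: SceneConfig = None,
    map_cfg: MappingConfig = None,
) -> dict:
    """End-to-end direction precision over many synthetic dances.

    Each dance has 4–17 runs whose comb orientations are drawn around a
    fixed feeder comb angle (per-run spread ``run_angle_sd_deg``) and whose
    durations follow the feeder-calibration distribution. Every run is
    rendered and decoded by the orientation module (so decoding errors and
    180-deg flips are present), dances are re-clustered in XYT space,
    RANSAC-averaged and projected with a fixed solar azimuth. Reports the
    circular distance between the mean mapped bearing and the true feeder
    bearing.
    """
    if scene_cfg is None:
        scene_cfg = SceneConfig(noise_sd=noise_sd)
    if map_cfg is None:
        map_cfg = MappingConfig()
    ori_cfg = OrientationConfig(
        frame_rate=scene_cfg.frame_rate, px_per_mm=scene_cfg.px_per_mm
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    from datetime import datetime, timedelta, timezone

    day0 = datetime(2016, 8, 1, 8, 0, 0, tzinfo=timezone.utc)
    # comb-plausible dance locations, far enough apart for XYT clustering
    grid = [(80.0 + gx * 100.0, 80.0 + gy * 100.0) for gx in range(6) for gy in range(3)]

    positions, times, end_times, durations, decoded = [], [], [], [], []
    true_bearing = wrap360(azimuth_deg + base_comb_angle_deg)
    for j in range(n_dances):
        n_runs = int(rng.integers(4, 18))
        center = np.asarray(grid[j % len(grid)])
        t = day0 + timedelta(seconds=30.0 * j)
        for k in range(n_runs):
            ang = float(wrap360(base_comb_angle_deg + rng.normal(0.0, run_angle_sd_deg)))
            dur_ms = float(np.clip(rng.normal(duration_mean_ms, duration_sd_ms), 300.0, 1100.0))
            n_frames = max(20, int(round(dur_ms / 1000.0 * scene_cfg.frame_rate)))
            truth = GroundTruthRun(0, n_frames, (0.0, 0.0), ang)
            snips, centers = synthetic.render_run_snippets(
                scene_cfg,
                truth,
                rng=rng,
                size=ori_cfg.image_size,
                jitter_px=1.0,
                phase=float(rng.uniform(0.0, 2.0 * np.pi)),
            )
            res = _decode_snippets(snips, centers, ori_cfg)
            decoded.append(res.direction_deg)
            durations.append(n_frames * 10.0)
            positions.append(center + rng.normal(0.0, 3.0, size=2))
            times.append(t)
            end_t = t + timedelta(milliseconds=n_frames * 10.0)
            end_times.append(end_t)
            t = end_t + timedelta(seconds=2.0)

    dances = mapping.build_dances(
        positions,
        times,
        durations,
        decoded,
        map_cfg,
        rng=np.random.default_rng(rng.integers(2**31)),
        run_end_times=end_times,
    )
    vectors = [mapping.project_dance(d, map_cfg, azimuth_deg=azimuth_deg) for d in dances]
    bearings = np.array([v.bearing_deg for v in vectors])
    mean_bearing = circular_mean(bearings)
    return {
        "n_dances_generated": n_dances,
        "n_dances_mapped": len(dances),
        "bearings_deg": bearings,
        "mean_bearing_deg": mean_bearing,
        "true_bearing_deg": float(true_bearing),
        "bearing_error_deg": float(circular_distance(mean_bearing, true_bearing)),
        "mean_distance_m": float(np.mean([v.distance_m for v in vectors])),
    }
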