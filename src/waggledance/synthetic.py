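"""Ground-truth-annotated renderer of dancing and non-dancing bees.

At hive scale a bee is a textureless, homogeneous ellipsoid blob: the
renderer draws a uniform-intensity ellipse with a soft (sigmoid) edge on a
noisy comb background. During a waggle run the blob advances along its body
axis at constant speed while oscillating sinusoidally perpendicular to it at
the waggle frequency; return phases follow semicircular arcs of alternating
handedness, so consecutive runs trace the classic figure eight. Distractor
bees perform slow random walks that never enter the waggle band.

Real dances have richer dynamics (variable tempo, body flexion, occlusion by
followers); the detector downstream only assumes band-limited lateral
periodicity, which is exactly what is rendered. Every rendered waggle phase
is logged as a :class:`~waggledance.config.GroundTruthRun`.

All randomness comes from one explicitly passed ``numpy`` generator (or is
derived from ``SceneConfig.seed``); identical config + seed gives
bit-identical frames.
"""

from __future__ import annotations

import numpy as np

from waggledance.angles import heading_vector, wrap360
from waggledance.config import GroundTruthRun, SceneConfig

__all__ = [
    "render_waggle_run",
    "render_dance",
    "render_non_waggle_snippet",
    "render_waggle_snippet",
    "render_run_snippets",
    "waggle_trajectory",
    "draw_run_orientations",
    "write_scene",
]


# ---------------------------------------------------------------------------
# low-level drawing


def _add_ellipse(frame, center, axis_deg, half_len, half_width, intensity, softness):
    """Additively draw a soft-edged ellipse into ``frame`` (float, in place).

    ``axis_deg`` is the body-axis heading (image-up zero, clockwise). The
    intensity profile is intensity / (1 + exp((rho - 1)/softness)) where rho
    is the elliptical radius, i.e. a uniform blob with a blurred edge.
    """
    h, w = frame.shape
    cx, cy = center
    pad = half_len * (1.0 + 6.0 * softness) + 2.0
    x0, x1 = int(np.floor(cx - pad)), int(np.ceil(cx + pad)) + 1
    y0, y1 = int(np.floor(cy - pad)), int(np.ceil(cy + pad)) + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1, dtype=np.float64) - cx
    ys = np.arange(y0, y1, dtype=np.float64) - cy
    dx, dy = np.meshgrid(xs, ys)
    ax, ay = heading_vector(axis_deg)
    along = dx * ax + dy * ay
    across = dx * ay - dy * ax  # perpendicular component
    rho = np.sqrt((along / half_len) ** 2 + (across / half_width) ** 2)
    frame[y0:y1, x0:x1] += intensity / (1.0 + np.exp((rho - 1.0) / softness))


def _render_frame(cfg: SceneConfig, bees, rng=None) -> np.ndarray:
    """Render one frame. ``bees`` is a list of (center_xy, axis_deg)."""
    w, h = cfg.resolution
    frame = np.full((h, w), cfg.background_level, dtype=np.float64)
    for center, axis_deg in bees:
        _add_ellipse(
            frame,
            center,
            axis_deg,
            cfg.bee_length_px / 2.0,
            cfg.bee_width_px / 2.0,
            cfg.bee_intensity,
            cfg.edge_softness,
        )
    if cfg.noise_sd > 0 and rng is not None:
        frame += rng.normal(0.0, cfg.noise_sd, size=frame.shape)
    return np.clip(frame, 0, 255).astype(np.uint8)


def _quantize(frames_float, noise_sd, rng):
    out = np.asarray(frames_float, dtype=np.float64)
    if noise_sd > 0 and rng is not None:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return np.clip(out, 0, 255).astype(np.uint8)


class _Distractors:
    """Non-dancing bees on a slow random walk (<= 3 px/frame steps)."""

    def __init__(self, cfg: SceneConfig, rng):
        w, h = cfg.resolution
        n = cfg.n_distractors
        margin = cfg.bee_length_px / 2.0 + 2.0
        self.pos = np.column_stack(
            [
                rng.uniform(margin, w - margin, size=n),
                rng.uniform(margin, h - margin, size=n),
            ]
        )
        self.axis = rng.uniform(0.0, 360.0, size=n)
        self.bounds = (margin, w - margin, margin, h - margin)
        self.rng = rng

    def step(self):
        n = len(self.axis)
        if n:
            step = self.rng.uniform(-1.5, 1.5, size=(n, 2))  # |step| <= ~2.1 px
            self.pos = self.pos + step
            x0, x1, y0, y1 = self.bounds
            self.pos[:, 0] = np.clip(self.pos[:, 0], x0, x1)
            self.pos[:, 1] = np.clip(self.pos[:, 1], y0, y1)
            self.axis = wrap360(self.axis + self.rng.uniform(-3.0, 3.0, size=n))
        return [(tuple(p), a) for p, a in zip(self.pos, self.axis)]


# ---------------------------------------------------------------------------
# trajectories


def waggle_trajectory(cfg: SceneConfig, truth: GroundTruthRun, phase: float = 0.0):
    """(n_frames, 2) center positions of a waggle run.

    Forward motion along the body axis plus a perpendicular sinusoid of
    amplitude ``lateral_amplitude_px`` at ``waggle_freq_hz``.
    """
    t = np.arange(truth.n_frames, dtype=np.float64)
    fwd = heading_vector(truth.orientation_deg)
    lat = heading_vector(truth.orientation_deg + 90.0)
    osc = cfg.lateral_amplitude_px * np.sin(
        2.0 * np.pi * cfg.waggle_freq_hz * t / cfg.frame_rate + phase
    )
    start = np.asarray(truth.start_xy, dtype=np.float64)
    return start + np.outer(t * cfg.forward_speed_px_per_frame, fwd) + np.outer(osc, lat)


def _check_bounds(cfg: SceneConfig, traj: np.ndarray, what: str = "trajectory"):
    w, h = cfg.resolution
    margin = cfg.bee_length_px / 2.0 + 1.0
    bad = np.nonzero(
        (traj[:, 0] < margin)
        | (traj[:, 0] > w - margin)
        | (traj[:, 1] < margin)
        | (traj[:, 1] > h - margin)
    )[0]
    if bad.size:
        raise ValueError(
            f"{what} leaves the frame at frame index {int(bad[0])} "
            f"(position {traj[bad[0]]}, frame {w}x{h})"
        )


def draw_run_orientations(rng, base_deg: float, sd_deg: float, n: int) -> np.ndarray:
    """Per-run orientations from a wrapped normal around the dance direction."""
    return wrap360(base_deg + rng.normal(0.0, sd_deg, size=n))


# ---------------------------------------------------------------------------
# public renderers


def render_waggle_run(cfg: SceneConfig, truth: GroundTruthRun, rng=None, phase: float = 0.0):
    """Render a single waggle run as ``truth.n_frames`` grayscale frames.

    Raises ``ValueError`` (naming the offending frame index) if the bee
    would leave the frame. Distractors, if configured, wander in the
    background.
    """
    if truth.label != "waggle":
        raise ValueError("render_waggle_run requires a waggle-labelled truth record")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    traj = waggle_trajectory(cfg, truth, phase=phase)
    _check_bounds(cfg, traj, "waggle-run trajectory")
    distractors = _Distractors(cfg, rng) if cfg.n_distractors else None
    frames = []
    for k in range(truth.n_frames):
        bees = [(tuple(traj[k]), truth.orientation_deg)]
        if distractors is not None:
            bees += distractors.step()
        frames.append(_render_frame(cfg, bees, rng))
    return np.stack(frames)


def render_run_scene(
    cfg: SceneConfig,
    truth: GroundTruthRun,
    pre_roll: int = 50,
    post_roll: int = 50,
    rng=None,
    phase: float = 0.0,
):
    """Render one waggle run embedded in a longer scene.

    The bee sits still at the run's start position for ``pre_roll`` frames
    (letting detector buffers warm up), waggles for ``truth.n_frames``
    frames starting at frame index ``pre_roll``, then sits still at the end
    position for ``post_roll`` frames. ``truth.start_frame`` is ignored;
    the run occupies frames [pre_roll, pre_roll + n_frames).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    traj = waggle_trajectory(cfg, truth, phase=phase)
    _check_bounds(cfg, traj, "waggle-run trajectory")
    positions = np.concatenate(
        [np.tile(traj[0], (pre_roll, 1)), traj, np.tile(traj[-1], (post_roll, 1))]
    )
    distractors = _Distractors(cfg, rng) if cfg.n_distractors else None
    frames = []
    for p in positions:
        bees = [(tuple(p), truth.orientation_deg)]
        if distractors is not None:
            bees += distractors.step()
        frames.append(_render_frame(cfg, bees, rng))
    return np.stack(frames)


def _return_arc(start, end, handedness: int, n_frames: int):
    """Semicircular return path from ``start`` to ``end``.

    The arc bulges left (handedness=+1) or right (-1) of the chord; the bee
    moves at uniform angular speed and its body axis follows the tangent.
    Returns (positions, axis_deg arrays).
    """
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    mid = (start + end) / 2.0
    radius = np.linalg.norm(end - start) / 2.0
    if radius < 1e-9:
        pos = np.tile(start, (n_frames, 1))
        return pos, np.zeros(n_frames)
    a0 = np.arctan2(start[1] - mid[1], start[0] - mid[0])
    sweep = np.pi * handedness
    ang = a0 + sweep * np.linspace(0.0, 1.0, n_frames)
    pos = mid + radius * np.column_stack([np.cos(ang), np.sin(ang)])
    # tangent direction of motion
    tx = -np.sin(ang) * sweep
    ty = np.cos(ang) * sweep
    axis = wrap360(np.rad2deg(np.arctan2(tx, -ty)))
    return pos, axis


def render_dance(
    cfg: SceneConfig,
    n_runs: int,
    base_orientation_deg: float,
    run_angle_sd_deg: float = 14.37,
    run_duration_frames: int = 58,
    return_duration_frames: int = 150,
    seed=None,
    rng=None,
    start_xy=None,
):
    """Render a full figure-eight dance of ``n_runs`` waggle phases.

    Waggle orientations are drawn from a wrapped normal around
    ``base_orientation_deg``; return phases are semicircles of alternating
    handedness (clockwise / counter-clockwise) leading back to the dance
    origin. Returns ``(frames, ground_truth)`` with one
    :class:`GroundTruthRun` per waggle phase.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
    w, h = cfg.resolution
    if start_xy is None:
        start_xy = (w / 2.0, h / 2.0)
    orientations = draw_run_orientations(rng, base_orientation_deg, run_angle_sd_deg, n_runs)

    segments = []  # list of (positions, axes)
    truths = []
    frame_cursor = 0
    pos = np.asarray(start_xy, float)
    distractors = _Distractors(cfg, rng) if cfg.n_distractors else None
    for i in range(n_runs):
        truth = GroundTruthRun(
            start_frame=frame_cursor,
            n_frames=int(run_duration_frames),
            start_xy=tuple(pos),
            orientation_deg=float(orientations[i]),
        )
        traj = waggle_trajectory(cfg, truth)
        _check_bounds(cfg, traj, f"waggle run {i}")
        segments.append((traj, np.full(len(traj), truth.orientation_deg)))
        truths.append(truth)
        frame_cursor += truth.n_frames
        if i < n_runs - 1:
            handedness = 1 if i % 2 == 0 else -1  # alternate CW / CCW loops
            arc, axes = _return_arc(
                traj[-1], start_xy, handedness, int(return_duration_frames)
            )
            _check_bounds(cfg, arc, f"return phase {i}")
            segments.append((arc, axes))
            frame_cursor += len(arc)
            pos = arc[-1]

    frames = []
    for traj, axes in segments:
        for p, a in zip(traj, axes):
            bees = [(tuple(p), float(a))]
            if distractors is not None:
                bees += distractors.step()
            frames.append(_render_frame(cfg, bees, rng))
    return np.stack(frames), truths


def render_non_waggle_snippet(
    cfg: SceneConfig,
    kind: str,
    n_frames: int = 128,
    rng=None,
    size: int = 50,
    walk_speed: float = 1.0,
    pulse_ms: float = 150.0,
):
    """Render a 50x50 px snippet without sustained waggle-band oscillation.

    kinds: ``walking`` (straight translation, no oscillation),
    ``stationary`` (static bee, sensor noise only), ``grooming_jitter``
    (brief oscillation pulses shorter than 200 ms separated by still gaps).
    """
    kinds = ("walking", "stationary", "grooming_jitter")
    if kind not in kinds:
        raise ValueError(f"kind must be one of {kinds}, got {kind!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    center = np.array([size / 2.0, size / 2.0])
    axis = float(rng.uniform(0.0, 360.0))
    fwd = heading_vector(axis)
    t = np.arange(n_frames, dtype=np.float64)

    if kind == "walking":
        # walk through the center so the bee is visible mid-clip
        pos = center + np.outer((t - n_frames / 2.0) * walk_speed, fwd)
    elif kind == "stationary":
        pos = np.tile(center, (n_frames, 1))
    else:  # grooming_jitter: short pulses of lateral shaking
        lat = heading_vector(axis + 90.0)
        pulse_frames = max(1, int(round(pulse_ms / 1000.0 * cfg.frame_rate)))
        envelope = np.zeros(n_frames)
        k = int(rng.integers(0, 20))
        while k < n_frames:
            envelope[k : k + pulse_frames] = 1.0
            k += pulse_frames + int(rng.integers(40, 90))  # >= 400 ms still gap
        osc = (
            0.7
            * cfg.lateral_amplitude_px
            * envelope
            * np.sin(2.0 * np.pi * cfg.waggle_freq_hz * t / cfg.frame_rate)
        )
        pos = center + np.outer(osc, lat)

    frames = []
    for k in range(n_frames):
        frame = np.full((size, size), cfg.background_level, dtype=np.float64)
        _add_ellipse(
            frame,
            tuple(pos[k]),
            axis,
            cfg.bee_length_px / 2.0,
            cfg.bee_width_px / 2.0,
            cfg.bee_intensity,
            cfg.edge_softness,
        )
        frames.append(frame)
    return _quantize(np.stack(frames), cfg.noise_sd, rng)


def render_waggle_snippet(
    cfg: SceneConfig,
    n_frames: int = 58,
    rng=None,
    size: int = 50,
    orientation_deg=None,
    jitter_px: float = 1.0,
):
    """Render a waggle-positive 50x50 snippet as the attention module exports it.

    The crop follows the dancer's smoothed path, so the bee stays centered
    while the 13 Hz lateral throw remains visible; a small random-walk
    jitter of the crop center mimics detection-centroid noise.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if orientation_deg is None:
        orientation_deg = float(rng.uniform(0.0, 360.0))
    truth = GroundTruthRun(
        start_frame=0,
        n_frames=n_frames,
        start_xy=(0.0, 0.0),
        orientation_deg=float(orientation_deg),
    )
    snips, _ = render_run_snippets(cfg, truth, rng=rng, size=size, jitter_px=jitter_px)
    return snips


def _rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean along axis 0 with edge shrinking."""
    if window <= 1:
        return x.copy()
    n = len(x)
    out = np.empty_like(x, dtype=np.float64)
    half = window // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = x[lo:hi].mean(axis=0)
    return out


def render_run_snippets(
    cfg: SceneConfig,
    truth: GroundTruthRun,
    rng=None,
    size: int = 50,
    smooth_frames: int = 8,
    jitter_px: float = 0.0,
    phase: float = 0.0,
):
    """Render a waggle run directly as a snippet sequence plus positions.

    The crop center follows the trajectory low-passed over ~one oscillation
    period (``smooth_frames``), emulating the spectrally lagged detection
    centroids of the attention module: the forward drift is tracked, the
    13 Hz throw stays in the image content. Returns ``(snippets, centers)``
    where ``centers`` are the (float) crop-center positions usable as
    detection positions for direction disambiguation.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    traj = waggle_trajectory(cfg, truth, phase=phase)
    centers = _rolling_mean(traj, smooth_frames)
    if jitter_px > 0:
        centers = centers + np.cumsum(
            rng.normal(0.0, jitter_px / 4.0, size=centers.shape), axis=0
        ).clip(-jitter_px, jitter_px)
    snips = np.empty((truth.n_frames, size, size), dtype=np.float64)
    for k in range(truth.n_frames):
        c = np.round(centers[k])
        frame = np.full((size, size), cfg.background_level, dtype=np.float64)
        local = (
            traj[k, 0] - c[0] + size / 2.0,
            traj[k, 1] - c[1] + size / 2.0,
        )
        _add_ellipse(
            frame,
            local,
            truth.orientation_deg,
            cfg.bee_length_px / 2.0,
            cfg.bee_width_px / 2.0,
            cfg.bee_intensity,
            cfg.edge_softness,
        )
        snips[k] = frame
    return _quantize(snips, cfg.noise_sd, rng), centers


def write_scene(out_dir, frames, truths):
    """Write frames as ``frame_%06d.png`` plus ``ground_truth.json``."""
    import json
    from pathlib import Path

    from waggledance import io as wio

    out = Path(out_dir)
    wio.write_frames(out, frames)
    records = [t.to_dict() for t in truths]
    (out / "ground_truth.json").write_text(json.dumps(records, indent=1))
    return out


def read_ground_truth(path):
    import json
    from pathlib import Path

    records = json.loads((Path(path)).read_text())
    return [GroundTruthRun.from_dict(r) for r in records]
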