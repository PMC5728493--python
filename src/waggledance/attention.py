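"""Waggle-run detection: per-pixel spectral scoring, clustering, assembly.

Layer 0 — every pixel owns a *dot detector*: a ring buffer of its last ``b``
intensity values. The buffer is min–max normalized to [-1, 1] (making the
score invariant to illumination gain and offset) and projected onto sine and
cosine basis functions at each waggle-band frequency; the squared magnitude
of the projection (a periodogram value) is the detector score. A pixel
activates when any band frequency scores above threshold.

Layer 1 — activated pixels are grouped by single-linkage hierarchical
agglomerative clustering with merge threshold ``cluster_dist`` (half a bee
body length); clusters smaller than ``min_cluster_size`` are discarded as
noise and the remaining centroids are potential dancer positions.

Layer 2 — dancer positions are linked over time into waggle-run candidates:
a detection joins the nearest open candidate whose last position lies within
``link_dist``, candidates survive ``max_gap`` frames without detections, and
closed candidates are emitted as waggle runs when they have at least
``min_run_detections`` detections and last at least ``min_run_ms``.

Positions are (x, y) pixel coordinates (x right, y down) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from waggledance.config import AttentionConfig

__all__ = [
    "normalize_window",
    "dd_score",
    "window_scores",
    "activate_detectors",
    "cluster_dancers",
    "RunAssembler",
    "assemble_runs",
    "detect_runs",
    "export_snippet",
    "crop_frame",
    "crop_sequence",
    "DancerDetection",
    "WaggleRun",
]


class WarmUpError(RuntimeError):
    """Raised when a score is requested from a buffer that is not yet full."""


@dataclass
class DancerDetection:
    """Centroid of one cluster of activated dot detectors in one frame."""

    frame: int
    centroid_xy: np.ndarray
    n_detectors: int
    member_pixels: np.ndarray  # (n, 2) int (x, y)


@dataclass
class WaggleRun:
    """A detected waggle event; orientation/confidence filled downstream."""

    id: int
    start_frame: int
    end_frame: int
    duration_ms: float
    detections: list
    comb_xy: tuple
    snippet: np.ndarray | None = None
    snippet_meta: dict | None = None
    snippet_path: str | None = None
    orientation_deg: float | None = None
    axis_deg: float | None = None
    margin: float | None = None
    degenerate: bool = False
    confidence: float | None = None
    rejected: bool = False

    @property
    def positions(self) -> np.ndarray:
        return np.array([d.centroid_xy for d in self.detections])

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections])


# ---------------------------------------------------------------------------
# Layer 0: dot-detector scores


def normalize_window(window) -> np.ndarray:
    """Min–max normalize an intensity window to [-1, 1].

    ``2 (B - min) / (max - min) - 1``; a constant window maps to all zeros
    (a flat pixel can never activate). Works on a 1-D buffer or on a stacked
    (b, ...) window, normalizing each trailing position independently.
    """
    w = np.asarray(window, dtype=np.float64)
    mn = w.min(axis=0)
    mx = w.max(axis=0)
    rng = mx - mn
    safe = np.where(rng == 0, 1.0, rng)
    out = 2.0 * (w - mn) / safe - 1.0
    return np.where(rng == 0, 0.0, out)


def _basis(b: int, freqs, s_r: float):
    """cos/sin basis matrices of shape (b, n_freq) for m = 1..b."""
    m = np.arange(1, b + 1, dtype=np.float64)[:, None]
    r = np.asarray(freqs, dtype=np.float64)[None, :]
    arg = 2.0 * np.pi * r * m / s_r
    return np.cos(arg), np.sin(arg)


def dd_score(b_norm, r: float, s_r: float) -> float:
    """Periodogram score of a normalized window at frequency ``r``.

    The squared magnitude of the projection on the complex exponential at
    ``r``: (sum B(m) cos(2 pi r m / s_r))^2 + (sum B(m) sin(...))^2.
    """
    if r >= s_r / 2.0:
        raise ValueError(f"frequency {r} Hz is not below Nyquist ({s_r / 2} Hz)")
    w = np.asarray(b_norm, dtype=np.float64)
    cos_b, sin_b = _basis(len(w), [r], s_r)
    return float((w @ cos_b[:, 0]) ** 2 + (w @ sin_b[:, 0]) ** 2)


def window_scores(window: np.ndarray, cfg: AttentionConfig) -> np.ndarray:
    """Max waggle-band score per pixel for a full (b, H, W) window.

    Vectorized float32 fast path of :func:`normalize_window` +
    :func:`dd_score`; recomputed in full every frame (an incremental
    sliding update would be an optimization, not a semantic change).
    """
    b, h, w = window.shape
    if b != cfg.window_len:
        raise WarmUpError(f"window has {b} frames, need {cfg.window_len}")
    win = window.astype(np.float32, copy=False).reshape(b, h * w)
    mn = win.min(axis=0)
    rng = win.max(axis=0) - mn
    safe = np.where(rng == 0, 1.0, rng).astype(np.float32)
    norm = 2.0 * (win - mn) / safe - 1.0
    norm[:, rng == 0] = 0.0
    cos_b, sin_b = _basis(b, cfg.waggle_band, cfg.sample_rate)
    c = cos_b.astype(np.float32).T @ norm  # (F, HW)
    s = sin_b.astype(np.float32).T @ norm
    return (c * c + s * s).max(axis=0).reshape(h, w)


def activate_detectors(window: np.ndarray, cfg: AttentionConfig) -> np.ndarray:
    """(n, 2) int array of activated pixel positions (x, y) for one window."""
    scores = window_scores(window, cfg)
    ys, xs = np.nonzero(scores >= cfg.score_threshold)
    return np.column_stack([xs, ys])


# ---------------------------------------------------------------------------
# Layer 1: clustering activated detectors


def cluster_dancers(points, cfg: AttentionConfig, frame: int = 0) -> list:
    """Single-linkage HAC of activated pixels, threshold-cut at cluster_dist.

    Clusters with fewer than ``min_cluster_size`` members are discarded;
    survivors are reported by centroid, sorted lexicographically by
    (x, y) centroid for determinism.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    if len(pts) == 0:
        return []
    if len(pts) == 1:
        labels = np.array([1])
    else:
        z = linkage(pts, method="single")
        labels = fcluster(z, t=cfg.cluster_dist, criterion="distance")
    out = []
    for lab in np.unique(labels):
        members = pts[labels == lab]
        if len(members) < cfg.min_cluster_size:
            continue
        centroid = members.mean(axis=0)
        order = np.lexsort((members[:, 1], members[:, 0]))
        out.append(
            DancerDetection(
                frame=frame,
                centroid_xy=centroid,
                n_detectors=len(members),
                member_pixels=members[order],
            )
        )
    out.sort(key=lambda d: (d.centroid_xy[0], d.centroid_xy[1]))
    return out


# ---------------------------------------------------------------------------
# Layer 2: waggle-run assembly


@dataclass
class _Candidate:
    id: int
    detections: list = field(default_factory=list)

    @property
    def last(self):
        return self.detections[-1]


class RunAssembler:
    """Streaming assembly of per-frame detections into waggle runs.

    A detection joins the nearest open candidate (last position within
    ``link_dist``); ties go to the older candidate; each candidate accepts at
    most one detection per frame. Candidates idle for more than ``max_gap``
    frames are closed and emitted if they satisfy the detection-count and
    minimum-duration filters.
    """

    def __init__(self, cfg: AttentionConfig):
        self.cfg = cfg
        self._open: list[_Candidate] = []
        self.runs: list[WaggleRun] = []
        self._next_id = 0

    def update(self, frame: int, detections):
        cfg = self.cfg
        still_open = []
        for cand in self._open:
            if frame - cand.last.frame > cfg.max_gap:
                self._close(cand)
            else:
                still_open.append(cand)
        self._open = still_open

        taken = set()
        for det in detections:
            best = None
            best_d = np.inf
            for cand in self._open:
                if cand.id in taken:
                    continue
                d = float(np.linalg.norm(det.centroid_xy - cand.last.centroid_xy))
                # strict < keeps ties with the older (earlier-listed) candidate
                if d <= cfg.link_dist and d < best_d:
                    best, best_d = cand, d
            if best is None:
                best = _Candidate(id=self._next_id)
                self._next_id += 1
                self._open.append(best)
            best.detections.append(det)
            taken.add(best.id)

    def finalize(self) -> list:
        for cand in self._open:
            self._close(cand)
        self._open = []
        self.runs.sort(key=lambda r: (r.start_frame, r.id))
        return self.runs

    def _close(self, cand: _Candidate):
        cfg = self.cfg
        dets = cand.detections
        if len(dets) < cfg.min_run_detections:
            return
        # group-delay correction: a score at buffer head n describes the
        # window [n-b+1, n], so the event time is the window center; start
        # and end shift equally (duration = detection span is preserved)
        offset = min(cfg.window_len // 2, dets[0].frame)
        start = dets[0].frame - offset
        end = dets[-1].frame - offset
        duration_ms = (end - start + 1) / cfg.sample_rate * 1000.0
        if duration_ms < cfg.min_run_ms:
            return
        centroids = np.array([d.centroid_xy for d in dets])
        comb_xy = tuple(np.median(centroids, axis=0))
        self.runs.append(
            WaggleRun(
                id=cand.id,
                start_frame=start,
                end_frame=end,
                duration_ms=duration_ms,
                detections=dets,
                comb_xy=comb_xy,
            )
        )


def assemble_runs(detection_stream, cfg: AttentionConfig) -> list:
    """Batch wrapper over :class:`RunAssembler`.

    ``detection_stream`` yields (frame, [DancerDetection, ...]) in frame
    order.
    """
    asm = RunAssembler(cfg)
    for frame, dets in detection_stream:
        asm.update(frame, dets)
    return asm.finalize()


# ---------------------------------------------------------------------------
# full detector


def detect_runs(frames, cfg: AttentionConfig, export_snippets: bool = True) -> list:
    """Run the three attention layers over a frame stack (or iterable).

    Scores are recomputed every frame over the sliding window. Returns the
    detected :class:`WaggleRun` list; snippets are attached in-memory when
    ``export_snippets`` (requires ``frames`` to be an array).
    """
    frames = np.asarray(frames)
    n, h, w = frames.shape
    b = cfg.window_len
    buf = np.empty((b, h, w), dtype=np.float32)
    asm = RunAssembler(cfg)
    for i in range(n):
        buf[i % b] = frames[i]
        if i < b - 1:
            continue
        # chronological view of the ring buffer
        k = (i + 1) % b
        window = np.concatenate([buf[k:], buf[:k]], axis=0) if k else buf
        pts = activate_detectors(window, cfg)
        dets = cluster_dancers(pts, cfg, frame=i)
        asm.update(i, dets)
    runs = asm.finalize()
    if export_snippets:
        for run in runs:
            run.snippet, run.snippet_meta = export_snippet(frames, run, cfg)
    return runs


# ---------------------------------------------------------------------------
# snippet export


def crop_frame(frame: np.ndarray, center_xy, size: int) -> np.ndarray:
    """Size x size crop centered at (x, y), zero-padded at borders."""
    h, w = frame.shape
    cx, cy = int(round(center_xy[0])), int(round(center_xy[1]))
    half = size // 2
    out = np.zeros((size, size), dtype=frame.dtype)
    x0, y0 = cx - half, cy - half
    sx0, sy0 = max(0, x0), max(0, y0)
    sx1, sy1 = min(w, x0 + size), min(h, y0 + size)
    if sx0 < sx1 and sy0 < sy1:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = frame[sy0:sy1, sx0:sx1]
    return out


def crop_sequence(frames: np.ndarray, centers, size: int) -> np.ndarray:
    centers = np.asarray(centers)
    return np.stack([crop_frame(f, c, size) for f, c in zip(frames, centers)])


def export_snippet(frames: np.ndarray, run: WaggleRun, cfg: AttentionConfig):
    """Per-frame snippet crops centered on the detection centroids.

    Returns ``(snippet, meta)``: the (n, size, size) crop stack over the
    run's detection frames and a JSON-serializable metadata record holding
    frame indices, centroids and activated-pixel lists (the centroids are
    needed later for direction disambiguation).
    """
    size = cfg.snippet_size
    snippet = np.stack(
        [crop_frame(frames[d.frame], d.centroid_xy, size) for d in run.detections]
    )
    meta = {
        "run_id": int(run.id),
        "start_frame": int(run.start_frame),
        "end_frame": int(run.end_frame),
        "duration_ms": float(run.duration_ms),
        "comb_xy": [float(v) for v in run.comb_xy],
        "snippet_size": int(size),
        "frames": [int(d.frame) for d in run.detections],
        "centroids": [[float(v) for v in d.centroid_xy] for d in run.detections],
        "member_pixels": [d.member_pixels.tolist() for d in run.detections],
    }
    return snippet, meta
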