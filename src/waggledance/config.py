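"""Configuration dataclasses for every pipeline stage.

All parameters that govern rendering, detection, filtering, decoding and
mapping live here, with the defaults used by the validation experiments.
Configs serialize to/from plain dicts (and hence YAML) via ``to_dict`` /
``from_dict``; the round trip is a fixed point.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from datetime import datetime
from typing import Sequence

import numpy as np

__all__ = [
    "SceneConfig",
    "GroundTruthRun",
    "AttentionConfig",
    "FilterConfig",
    "OrientationConfig",
    "MappingConfig",
    "RecordingMeta",
    "PipelineConfig",
]


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration values."""


def _listify(v):
    if isinstance(v, (tuple, list)):
        return [_listify(x) for x in v]
    if isinstance(v, datetime):
        return v.isoformat()
    return v


def _tuplify(v):
    if isinstance(v, (tuple, list)):
        return tuple(_tuplify(x) for x in v)
    return v


@dataclass
class _DictMixin:
    def to_dict(self) -> dict:
        return {k: _listify(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict):
        cls_fields = {f.name for f in fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in cls_fields:
                raise ConfigError(f"unknown field {k!r} for {cls.__name__}")
            kwargs[k] = _tuplify(v) if isinstance(v, (list, tuple)) else v
        return cls(**kwargs)


@dataclass
class SceneConfig(_DictMixin):
    """Parameters of the synthetic comb scene renderer.

    The defaults emulate the recording conditions the pipeline is designed
    for: ~100 Hz video of an observation-hive comb at 1.7 px/mm, where a
    14 mm bee appears as a textureless bright ellipse about 24 px long, and
    a dancer throws her body laterally at ~13 Hz while creeping forward.

    Parameters
    ----------
    frame_rate : float
        Video frame rate in Hz. Must exceed twice the waggle frequency so
        the oscillation is sampleable.
    resolution : (int, int)
        Frame (width, height) in pixels.
    px_per_mm : float
        Image scale. 1.7 px/mm puts a whole comb side into a small frame.
    bee_length_mm, bee_aspect : float
        Body length and length:width ratio of the rendered ellipse.
    waggle_freq_hz : float
        Lateral oscillation frequency during waggle phases.
    lateral_amplitude_px : float
        Amplitude of the lateral sinusoid, in pixels.
    forward_speed_px_per_frame : float
        Forward creep of the dancer along its body axis during a waggle run.
    noise_sd : float
        Standard deviation of additive Gaussian sensor noise (8-bit scale).
    n_distractors : int
        Number of non-dancing bees performing a slow random walk.
    background_level, bee_intensity : float
        Comb background brightness and the bee's contrast relative to it.
        A negative ``bee_intensity`` renders dark bees on a bright comb.
    edge_softness : float
        Gaussian-like blur of the ellipse edge, as a fraction of the
        elliptical radius.
    seed : int
        Seed for the renderer's random generator when none is passed in.
    """

    frame_rate: float = 100.0
    resolution: tuple = (160, 160)
    px_per_mm: float = 1.7
    bee_length_mm: float = 14.0
    bee_aspect: float = 2.5
    waggle_freq_hz: float = 13.0
    lateral_amplitude_px: float = 6.0
    forward_speed_px_per_frame: float = 0.5
    noise_sd: float = 4.0
    n_distractors: int = 0
    background_level: float = 40.0
    bee_intensity: float = 160.0
    edge_softness: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.frame_rate <= 2.0 * self.waggle_freq_hz:
            raise ConfigError(
                "frame_rate must exceed twice the waggle frequency "
                f"(Nyquist): {self.frame_rate} <= 2 x {self.waggle_freq_hz}"
            )
        for name in ("px_per_mm", "bee_length_mm", "bee_aspect", "waggle_freq_hz"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.lateral_amplitude_px < 0 or self.forward_speed_px_per_frame < 0:
            raise ConfigError("amplitudes and speeds must be non-negative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        w, h = self.resolution
        if w <= 0 or h <= 0:
            raise ConfigError("resolution must be positive")

    @property
    def bee_length_px(self) -> float:
        return self.bee_length_mm * self.px_per_mm

    @property
    def bee_width_px(self) -> float:
        return self.bee_length_px / self.bee_aspect


@dataclass
class GroundTruthRun(_DictMixin):
    """Ground-truth record of one rendered waggle (or non-waggle) phase."""

    start_frame: int
    n_frames: int
    start_xy: tuple
    orientation_deg: float
    label: str = "waggle"

    def __post_init__(self):
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if not (0.0 <= self.orientation_deg < 360.0):
            raise ConfigError("orientation_deg must lie in [0, 360)")
        if self.label not in ("waggle", "non_waggle"):
            raise ConfigError(f"unknown label {self.label!r}")

    @property
    def end_frame(self) -> int:
        return self.start_frame + self.n_frames - 1


@dataclass
class AttentionConfig(_DictMixin):
    """Parameters of the per-pixel spectral detector and run assembly.

    ``window_len`` (b) is the per-pixel ring-buffer length: 32 frames at
    100 Hz covers ~4 waggle cycles. The waggle band is sampled at the seven
    integer frequencies 10..16 Hz. ``cluster_dist`` (d_max1) defaults to
    half a bee body length at 1.7 px/mm; ``link_dist`` (d_max2) likewise,
    since the 13 Hz lateral throw moves the detection centroid by several
    pixels between frames. Candidates survive up to ``max_gap`` (g_max2)
    frames without new detections; closed candidates need at least
    ``min_run_detections`` (c_min2) detections and ``min_run_ms`` duration
    (200 ms ~ three body oscillations) to be emitted as waggle runs.
    """

    window_len: int = 32
    sample_rate: float = 100.0
    waggle_band: tuple = (10.0, 11.0, 12.0, 13.0, 14.0, 15.0, 16.0)
    score_threshold: float = 100.0
    cluster_dist: float = 11.9
    min_cluster_size: int = 4
    link_dist: float = 12.0
    max_gap: int = 10
    min_run_detections: int = 10
    min_run_ms: float = 200.0
    snippet_size: int = 50

    def __post_init__(self):
        if self.window_len < 2:
            raise ConfigError("window_len must be >= 2")
        if any(r >= self.sample_rate / 2.0 for r in self.waggle_band):
            raise ConfigError("all waggle-band frequencies must be < sample_rate/2")
        if self.cluster_dist <= 0 or self.link_dist <= 0:
            raise ConfigError("cluster_dist and link_dist must be positive")
        if self.min_cluster_size < 1 or self.min_run_detections < 1:
            raise ConfigError("minimum cluster/run sizes must be >= 1")
        if self.max_gap < 0:
            raise ConfigError("max_gap must be >= 0")


@dataclass
class FilterConfig(_DictMixin):
    """Architecture and training protocol of the snippet filter network."""

    clip_len: int = 128
    input_size: int = 50
    input_pool: tuple = (2, 2, 2)
    conv_channels: tuple = (8, 16)
    kernel: int = 3
    strides: tuple = ((2, 2, 2), (2, 2, 2))
    dropout_rate: float = 0.1
    threshold: float = 0.5
    optimizer: str = "adam"
    lr: float = 3e-3
    epochs: int = 8
    batch_size: int = 16
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.clip_len < 1:
            raise ConfigError("clip_len must be >= 1")
        if not (0.0 < self.val_fraction < 1.0):
            raise ConfigError("val_fraction must lie in (0, 1)")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.optimizer != "adam":
            raise ConfigError("only the adam optimizer is supported")
        if len(self.conv_channels) != len(self.strides):
            raise ConfigError("conv_channels and strides must have equal length")


@dataclass
class OrientationConfig(_DictMixin):
    """Parameters of the Fourier-domain orientation decoder.

    ``lateral_step_px`` (x) is the dancer's lateral displacement per frame;
    the expected ring radius of the difference-image spectrum is
    k = image_size / (2 x) cycles. The difference-of-Gaussians bandpass
    is centered on that ring with sigmas expressed as fractions of k.
    """

    image_size: int = 50
    frame_rate: float = 100.0
    px_per_mm: float = 1.7
    lateral_step_px: float = 5.0
    dog_center_sigma_ratio: float = 0.5
    dog_surround_sigma_ratio: float = 1.0
    anchor_fraction: float = 0.1
    histogram_bins: int = 36

    def __post_init__(self):
        if self.image_size <= 0:
            raise ConfigError("image_size must be positive")
        if not (0.0 < self.anchor_fraction <= 1.0):
            raise ConfigError("anchor_fraction must lie in (0, 1]")
        if self.lateral_step_px <= 0:
            raise ConfigError("lateral_step_px must be positive")
        if self.histogram_bins < 2:
            raise ConfigError("histogram_bins must be >= 2")

    @property
    def ring_radius(self) -> float:
        """Expected spectral ring radius k = I_size / (2 x), in cycles."""
        return self.image_size / (2.0 * self.lateral_step_px)


#: Feeder-calibrated duration-to-distance factor: a feeder 342 m from the
#: hive was advertised with mean waggle duration 582.79 ms.
DEFAULT_DISTANCE_FACTOR_M_PER_MS = 342.0 / 582.79


@dataclass
class MappingConfig(_DictMixin):
    """Parameters of dance clustering, outlier rejection and projection.

    Time enters the clustering space scaled by ``time_scale`` data-space
    units per second (default 0.25: a quarter unit per second), keeping
    temporal gaps between consecutive runs commensurate with their spatial
    drift on the comb.
    """

    time_scale: float = 0.25
    cluster_dist: float = 60.0
    min_runs_per_dance: int = 4
    ransac_inlier_deg: float = 30.0
    ransac_iters: int = 100
    distance_factor: float = DEFAULT_DISTANCE_FACTOR_M_PER_MS
    hive_lat: float = 52.457
    hive_lon: float = 13.296
    utc_offset: float = 0.0

    def __post_init__(self):
        if self.time_scale <= 0:
            raise ConfigError("time_scale must be positive (time cannot collapse)")
        if self.min_runs_per_dance < 1:
            raise ConfigError("min_runs_per_dance must be >= 1")
        if self.distance_factor <= 0:
            raise ConfigError("distance_factor must be positive")
        if self.ransac_iters < 1:
            raise ConfigError("ransac_iters must be >= 1")


@dataclass
class RecordingMeta(_DictMixin):
    """Per-recording metadata: timing, geography and comb rectification."""

    start_time: str = "2016-08-01T10:00:00+00:00"
    frame_rate: float = 100.0
    px_per_mm: float = 1.7
    hive_lat: float = 52.457
    hive_lon: float = 13.296
    corner_points_image: tuple = ()
    corner_points_mm: tuple = (
        (0.0, 0.0),
        (370.0, 0.0),
        (370.0, 210.0),
        (0.0, 210.0),
    )

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        if self.corner_points_image and len(self.corner_points_image) != 4:
            raise ConfigError("exactly 4 image corner points are required")
        if len(self.corner_points_mm) != 4:
            raise ConfigError("exactly 4 comb reference corners are required")

    @property
    def start_datetime(self) -> datetime:
        return datetime.fromisoformat(self.start_time)

    def frame_time(self, frame_idx: int) -> datetime:
        """Timestamp of a 0-based frame index (start_time + idx/frame_rate)."""
        from datetime import timedelta

        return self.start_datetime + timedelta(seconds=frame_idx / self.frame_rate)


@dataclass
class PipelineConfig(_DictMixin):
    """Bundle of all stage configs plus a master seed."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    orientation: OrientationConfig = field(default_factory=OrientationConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    seed: int = 0

    def __post_init__(self):
        for name, cls in (
            ("scene", SceneConfig),
            ("attention", AttentionConfig),
            ("filter", FilterConfig),
            ("orientation", OrientationConfig),
            ("mapping", MappingConfig),
        ):
            v = getattr(self, name)
            if isinstance(v, dict):
                setattr(self, name, cls.from_dict(v))
        if self.orientation.frame_rate != self.attention.sample_rate:
            raise ConfigError(
                "orientation.frame_rate must equal attention.sample_rate"
            )

    def to_dict(self) -> dict:
        return {
            "scene": self.scene.to_dict(),
            "attention": self.attention.to_dict(),
            "filter": self.filter.to_dict(),
            "orientation": self.orientation.to_dict(),
            "mapping": self.mapping.to_dict(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def spawn_rngs(seed: int, n: int) -> list:
    """Derive ``n`` independent generators from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
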