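"""Decode waggle-run body orientation from snippet sequences.

Subtracting consecutive frames of a laterally oscillating, textureless bee
yields a Gabor-like pattern: a positive lobe beside a negative lobe along
the motion axis. By the Fourier slice theorem its 2-D spectrum concentrates
in a pair of point-symmetric maxima on the line through the origin along the
motion axis, at a radius set by the lobe spacing. Accumulating spectral
*magnitudes* over all difference images gives a location-independent,
phase-insensitive summary of the run; a ring-shaped difference-of-Gaussians
bandpass centered at the expected radius k = I_size / (2 x) (x = lateral
displacement per frame) suppresses noise, and PCA on the filtered spectrum
(magnitudes as weights) yields the motion axis. Adding 90 deg gives the body
axis, which still has a 180 deg ambiguity: the forward drift of the
detection positions resolves it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from waggledance.angles import circular_distance, vector_heading, wrap180, wrap360
from waggledance.config import OrientationConfig

__all__ = [
    "difference_images",
    "accumulate_spectrum",
    "dog_ring",
    "dog_bandpass",
    "pca_axis",
    "disambiguate",
    "decode_run",
    "OrientationResult",
]


@dataclass
class OrientationResult:
    """Decoded body axis and disambiguated heading of one waggle run."""

    axis_deg: float  # body axis in [0, 180)
    direction_deg: float  # heading in [0, 360); direction mod 180 == axis
    disambiguation_margin: float  # |cos| of heading-vs-axis agreement, [0, 1]
    degenerate: bool = False


def difference_images(snippets) -> np.ndarray:
    """Signed consecutive-frame differences, frame[t+1] - frame[t]."""
    s = np.asarray(snippets, dtype=np.float64)
    if len(s) < 2:
        raise ValueError("need at least 2 frames to form difference images")
    return np.diff(s, axis=0)


def accumulate_spectrum(diffs) -> np.ndarray:
    """Sum of centered 2-D Fourier magnitudes over all difference images.

    Each difference image is mean-subtracted before the transform so a
    nonzero DC offset cannot plant a spurious origin peak. Magnitudes (not
    complex values) are summed: the Gabor pattern's phase varies with the
    bee's position frame to frame, so complex accumulation would cancel.
    """
    d = np.asarray(diffs, dtype=np.float64)
    if d.ndim == 2:
        d = d[None]
    if len(d) < 1:
        raise ValueError("need at least one difference image")
    d = d - d.mean(axis=(1, 2), keepdims=True)
    spec = np.abs(np.fft.fftshift(np.fft.fft2(d), axes=(1, 2)))
    return spec.sum(axis=0)


def _freq_grid(size: int):
    """Centered frequency coordinates (u right, v down) of an fftshifted plane."""
    c = size // 2
    u = np.arange(size, dtype=np.float64) - c
    v = np.arange(size, dtype=np.float64) - c
    return np.meshgrid(u, v)


def dog_ring(size: int, k: float, sigma_center: float, sigma_surround: float) -> np.ndarray:
    """Isotropic Mexican-hat ring passband peaking at radius ~k.

    Difference of two origin-centered Gaussians (surround minus center),
    clipped at zero and normalized to unit peak, so energy near radius k
    passes at full gain while low and high frequencies are suppressed.
    """
    uu, vv = _freq_grid(size)
    r2 = uu * uu + vv * vv
    wide = np.exp(-r2 / (2.0 * sigma_surround**2))
    narrow = np.exp(-r2 / (2.0 * sigma_center**2))
    ring = np.clip(wide - narrow, 0.0, None)
    peak = ring.max()
    return ring / peak if peak > 0 else ring


def dog_bandpass(spectrum: np.ndarray, cfg: OrientationConfig) -> np.ndarray:
    """Multiply the accumulated spectrum by the ring bandpass at k = I/(2x)."""
    size = cfg.image_size
    if spectrum.shape != (size, size):
        raise ValueError(f"spectrum must be {size}x{size}, got {spectrum.shape}")
    k = cfg.ring_radius
    if k >= size / 2.0:
        raise ValueError(
            f"ring radius k={k:.2f} cycles lies outside Nyquist ({size / 2}); "
            "increase lateral_step_px or image_size"
        )
    ring = dog_ring(
        size,
        k,
        cfg.dog_center_sigma_ratio * k,
        cfg.dog_surround_sigma_ratio * k,
    )
    return spectrum * ring


_DEGENERATE_EIG_RATIO = 1.05


def pca_axis(filtered_spectrum: np.ndarray):
    """Body axis from PCA of the filtered spectrum as a weighted point cloud.

    Frequency coordinates are weighted by spectral magnitude; the principal
    eigenvector gives the lateral-motion axis, and +90 deg the body axis in
    [0, 180). Returns ``(axis_deg, eigenvalue_ratio)``; a ratio below 1.05
    flags an (almost) isotropic spectrum for which the axis is meaningless.
    """
    w = np.asarray(filtered_spectrum, dtype=np.float64)
    total = w.sum()
    if total <= 0:
        return 0.0, 1.0
    uu, vv = _freq_grid(w.shape[0])
    # second moments about the origin (the spectrum is point symmetric)
    muu = (w * uu * uu).sum() / total
    mvv = (w * vv * vv).sum() / total
    muv = (w * uu * vv).sum() / total
    cov = np.array([[muu, muv], [muv, mvv]])
    evals, evecs = np.linalg.eigh(cov)
    ratio = float(evals[1] / max(evals[0], 1e-12))
    du, dv = evecs[:, 1]  # principal direction (largest eigenvalue)
    lateral = wrap180(vector_heading(du, dv))
    return float(wrap180(lateral + 90.0)), ratio


def disambiguate(axis_deg: float, positions, cfg: OrientationConfig):
    """Pick the heading among {axis, axis+180} using the forward drift.

    The mean of the first ``anchor_fraction`` of detection positions anchors
    the run; the orientations of all (position - anchor) vectors are
    histogrammed (``histogram_bins`` bins over 360 deg), the modal bin(s)
    are circularly averaged into a coarse heading, and the axis alternative
    closer to that heading wins. The margin is |cos| of the angle between
    heading and chosen direction (1 = clean agreement, 0 = orthogonal /
    uninformative). Zero net motion is degenerate: the axis is returned
    unchanged with margin 0.
    """
    pos = np.asarray(positions, dtype=np.float64).reshape(-1, 2)
    if len(pos) == 0:
        raise ValueError("disambiguation needs at least one position")
    n_anchor = max(1, int(np.ceil(cfg.anchor_fraction * len(pos))))
    anchor = pos[:n_anchor].mean(axis=0)
    vec = pos - anchor
    norms = np.linalg.norm(vec, axis=1)
    good = norms > 1e-9
    if not np.any(good):
        return wrap360(axis_deg), 0.0, True
    headings = vector_heading(vec[good, 0], vec[good, 1])
    edges = np.linspace(0.0, 360.0, cfg.histogram_bins + 1)
    counts, _ = np.histogram(headings, bins=edges)
    top = np.nonzero(counts == counts.max())[0]
    centers = (edges[top] + edges[top + 1]) / 2.0
    rad = np.deg2rad(centers)
    coarse = wrap360(np.rad2deg(np.arctan2(np.sin(rad).sum(), np.cos(rad).sum())))
    cand = np.array([wrap360(axis_deg), wrap360(axis_deg + 180.0)])
    chosen = cand[np.argmin(circular_distance(cand, coarse))]
    margin = float(abs(np.cos(np.deg2rad(coarse - chosen))))
    return float(chosen), margin, False


def decode_run(run, cfg: OrientationConfig, positions=None, snippets=None) -> OrientationResult:
    """Full decoding pipeline for one waggle run.

    Operates on the run's snippet sequence and detection positions (taken
    from the run object unless passed explicitly); writes the decoded
    orientation back onto the run and returns the result. Degenerate cases
    (isotropic spectrum, zero forward motion) are still emitted, flagged,
    so the mapping stage can treat them as outliers.
    """
    if snippets is None:
        snippets = run.snippet
    if snippets is None:
        raise ValueError(f"run {getattr(run, 'id', '?')} has no snippet sequence")
    if positions is None:
        positions = run.positions

    diffs = difference_images(snippets)
    spec = accumulate_spectrum(diffs)
    filtered = dog_bandpass(spec, cfg)
    axis_deg, eig_ratio = pca_axis(filtered)
    pca_degenerate = eig_ratio < _DEGENERATE_EIG_RATIO
    direction, margin, motion_degenerate = disambiguate(axis_deg, positions, cfg)
    degenerate = bool(pca_degenerate or motion_degenerate)
    if pca_degenerate:
        margin = 0.0
    result = OrientationResult(
        axis_deg=float(axis_deg),
        direction_deg=float(direction),
        disambiguation_margin=float(margin),
        degenerate=degenerate,
    )
    if run is not None:
        run.orientation_deg = result.direction_deg
        run.axis_deg = result.axis_deg
        run.margin = result.disambiguation_margin
        run.degenerate = result.degenerate
    return result
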