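"""Angle conventions and circular statistics used throughout the package.

Convention (declared once, enforced everywhere): angles on the comb and in
image coordinates are measured from image "up" (the negative row direction),
increasing **clockwise**, in degrees. On a vertical comb "up" corresponds to
the direction of the solar azimuth, so a comb angle of 0 deg means "fly
toward the sun". Field bearings use the compass convention (0 deg = true
north, clockwise positive). Both conventions compose by simple addition.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "wrap360",
    "wrap180",
    "signed_delta",
    "circular_distance",
    "circular_mean",
    "circular_sd",
    "heading_vector",
    "vector_heading",
]


def wrap360(angle_deg):
    """Wrap angles into [0, 360)."""
    return np.mod(angle_deg, 360.0)


def wrap180(angle_deg):
    """Wrap angles into [0, 180) (undirected axis)."""
    return np.mod(angle_deg, 180.0)


def signed_delta(a_deg, b_deg):
    """Smallest signed difference a - b, in (-180, 180]."""
    d = np.mod(np.asarray(a_deg, dtype=float) - b_deg + 180.0, 360.0) - 180.0
    # map -180 -> +180 so the interval is half-open on the left
    return np.where(d == -180.0, 180.0, d)


def circular_distance(a_deg, b_deg):
    """Absolute circular distance between two directions, in [0, 180]."""
    return np.abs(signed_delta(a_deg, b_deg))


def circular_mean(angles_deg, warn_odd: bool = False) -> float:
    """Mean direction atan2(sum sin, sum cos), in [0, 360).

    Raises ``ValueError`` on an empty input or when the resultant vector
    vanishes (perfectly opposed directions), for which the mean direction is
    undefined. With ``warn_odd=True`` a warning is emitted for odd sample
    sizes: consecutive waggle runs alternate around the true direction
    (the divergence angle), so averaging an even number of consecutive runs
    cancels the alternation.
    """
    a = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circular mean of an empty set is undefined")
    if warn_odd and a.size % 2 == 1:
        warnings.warn(
            "circular mean over an odd number of waggle runs does not cancel "
            "the divergence angle",
            stacklevel=2,
        )
    rad = np.deg2rad(a)
    s, c = np.sin(rad).sum(), np.cos(rad).sum()
    if np.hypot(s, c) < 1e-9 * a.size:
        raise ValueError("undefined mean: resultant vector is (numerically) zero")
    return float(wrap360(np.rad2deg(np.arctan2(s, c))))


def circular_sd(angles_deg) -> float:
    """Circular standard deviation sqrt(-2 ln R) in degrees."""
    rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
    r = np.hypot(np.sin(rad).mean(), np.cos(rad).mean())
    r = min(max(r, 1e-12), 1.0)
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r))))


def heading_vector(angle_deg):
    """Unit (dx, dy) in image coordinates (x right, y down) for a heading.

    0 deg points image-up (0, -1); 90 deg points image-right (1, 0).
    """
    rad = np.deg2rad(np.asarray(angle_deg, dtype=float))
    return np.stack([np.sin(rad), -np.cos(rad)], axis=-1)


def vector_heading(dx, dy):
    """Inverse of :func:`heading_vector`: heading in [0, 360) of (dx, dy)."""
    return wrap360(np.rad2deg(np.arctan2(dx, -np.asarray(dy, dtype=float))))
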