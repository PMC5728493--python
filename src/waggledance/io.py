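"""Frame I/O, homography rectification, and table/config serialization."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage.transform import ProjectiveTransform, warp

from waggledance.config import PipelineConfig, RecordingMeta

__all__ = [
    "read_frames",
    "write_frames",
    "to_grayscale",
    "rectify",
    "write_run_table",
    "read_run_table",
    "write_snippet_dir",
    "read_snippet_dir",
    "load_config",
    "save_config",
    "load_meta",
    "save_meta",
    "write_geojson",
]

_LUMA = np.array([0.299, 0.587, 0.114])
_FRAME_EXTS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Fixed-luma (0.299, 0.587, 0.114) grayscale conversion to uint8."""
    if frame.ndim == 2:
        return frame.astype(np.uint8, copy=False)
    rgb = frame[..., :3].astype(np.float64)
    return np.clip(rgb @ _LUMA, 0, 255).round().astype(np.uint8)


def read_frames(source) -> np.ndarray:
    """Read a frame directory (sorted) or a multi-frame file as (N, H, W) uint8."""
    path = Path(source)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTS)
        if not files:
            raise FileNotFoundError(f"no image frames found in {path}")
        frames = [to_grayscale(iio.imread(f)) for f in files]
    elif path.is_file():
        try:
            data = iio.imread(path)
        except Exception as exc:  # codec/plugin missing or unreadable
            raise IOError(f"cannot read video source {path}: {exc}") from exc
        if data.ndim == 2:
            data = data[None]
        frames = [to_grayscale(f) for f in data]
    else:
        raise FileNotFoundError(f"source {path} does not exist")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent frame sizes in {path}: {sorted(shapes)}")
    return np.stack(frames)


def write_frames(out_dir, frames) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(np.asarray(frames, dtype=np.uint8)):
        iio.imwrite(out / f"frame_{i:06d}.png", frame)
    return out


def rectify(frame: np.ndarray, meta: RecordingMeta) -> np.ndarray:
    """Warp the frame so the comb corners map to an upright mm-scaled rectangle.

    The homography maps the four image corner points onto the reference comb
    coordinates scaled by ``px_per_mm``; degenerate correspondences (three
    collinear points) are rejected.
    """
    if not meta.corner_points_image:
        raise ValueError("RecordingMeta.corner_points_image is not set")
    src = np.asarray(meta.corner_points_mm, dtype=np.float64) * meta.px_per_mm
    dst = np.asarray(meta.corner_points_image, dtype=np.float64)
    for pts in (src, dst):
        m = np.column_stack([pts, np.ones(4)])
        for drop in range(4):
            sub = np.delete(m, drop, axis=0)
            if abs(np.linalg.det(sub)) < 1e-9:
                raise ValueError("degenerate corner correspondences (collinear points)")
    tform = ProjectiveTransform.from_estimate(src, dst)
    if not tform:
        raise ValueError("homography estimation failed")
    out_w = int(round(src[:, 0].max()))
    out_h = int(round(src[:, 1].max()))
    warped = warp(
        frame.astype(np.float64),
        tform,
        output_shape=(out_h, out_w),
        order=1,
        preserve_range=True,
    )
    return np.clip(warped, 0, 255).astype(np.uint8)


RUN_TABLE_COLUMNS = [
    "id",
    "start_frame",
    "start_s",
    "x_px",
    "y_px",
    "duration_ms",
    "n_detections",
]


def write_run_table(path, runs, sample_rate: float) -> pd.DataFrame:
    rows = []
    for r in runs:
        row = {
            "id": r.id,
            "start_frame": r.start_frame,
            "start_s": r.start_frame / sample_rate,
            "x_px": r.comb_xy[0],
            "y_px": r.comb_xy[1],
            "duration_ms": r.duration_ms,
            "n_detections": len(r.detections),
        }
        if r.orientation_deg is not None:
            row.update(
                orientation_deg=r.orientation_deg,
                axis_deg=r.axis_deg,
                margin=r.margin,
                degenerate=r.degenerate,
            )
        if r.confidence is not None:
            row.update(confidence=r.confidence, rejected=r.rejected)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_run_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_snippet_dir(out_dir, run, frames_key="snippet") -> Path:
    """One directory per run: wr_<id>/frame_%04d.png + meta.json."""
    out = Path(out_dir) / f"wr_{run.id:05d}"
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(run.snippet):
        iio.imwrite(out / f"frame_{i:04d}.png", frame.astype(np.uint8))
    (out / "meta.json").write_text(json.dumps(run.snippet_meta, indent=1))
    run.snippet_path = str(out)
    return out


def read_snippet_dir(run_dir):
    """Returns (snippet array, meta dict) for one wr_<id> directory."""
    run_dir = Path(run_dir)
    files = sorted(run_dir.glob("frame_*.png"))
    snippet = np.stack([iio.imread(f) for f in files])
    meta = json.loads((run_dir / "meta.json").read_text())
    return snippet, meta


def save_config(path, cfg: PipelineConfig):
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def save_meta(path, meta: RecordingMeta):
    Path(path).write_text(yaml.safe_dump(meta.to_dict(), sort_keys=True))


def load_meta(path) -> RecordingMeta:
    return RecordingMeta.from_dict(yaml.safe_load(Path(path).read_text()))


def write_geojson(path, field_vectors, dances, hive_lat: float, hive_lon: float):
    """Mapped dance points as WGS84 GeoJSON via a local equirectangular frame."""
    m_per_deg_lat = 111320.0
    m_per_deg_lon = 111320.0 * np.cos(np.deg2rad(hive_lat))
    features = []
    for fv, dance in zip(field_vectors, dances):
        east, north = fv.map_xy_m
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [
                        hive_lon + east / m_per_deg_lon,
                        hive_lat + north / m_per_deg_lat,
                    ],
                },
                "properties": {
                    "dance_id": dance.id,
                    "n_runs": fv.n_runs,
                    "distance_m": fv.distance_m,
                    "bearing_deg": fv.bearing_deg,
                    "profitability": fv.profitability,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
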