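"""Top-level pipeline: detect -> (filter) -> decode -> map, with a manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from waggledance import __version__, attention, filternet, io, mapping, orientation
from waggledance.config import PipelineConfig, RecordingMeta

__all__ = ["run_pipeline"]

DANCE_COLUMNS = [
    "dance_id",
    "start_iso",
    "n_runs",
    "n_inliers",
    "mean_duration_ms",
    "mean_return_ms",
    "comb_angle_deg",
    "bearing_deg",
    "distance_m",
    "profitability",
    "east_m",
    "north_m",
]


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(
    cfg: PipelineConfig,
    source,
    meta: RecordingMeta,
    out_dir,
    model=None,
    use_filter: bool = True,
):
    """Execute the full pipeline on a video source.

    Writes per-run snippet directories, the run table CSV (with decoded
    orientations), the dances CSV, a GeoJSON of mapped points and a
    manifest JSON with per-stage counts. A stage failure is recorded in the
    manifest and later stages are skipped. Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stages": {},
    }
    runs = []
    try:
        frames = io.read_frames(source) if not isinstance(source, np.ndarray) else source
        runs = attention.detect_runs(frames, cfg.attention)
        for run in runs:
            io.write_snippet_dir(out / "runs", run)
        manifest["stages"]["detect"] = {"status": "ok", "n_runs": len(runs)}
    except Exception as exc:
        manifest["stages"]["detect"] = {"status": "error", "error": str(exc)}
        _write_manifest(out, manifest)
        return manifest

    if use_filter and model is not None:
        try:
            runs, errors = filternet.filter_runs(runs, model, cfg.filter.threshold)
            manifest["stages"]["filter"] = {
                "status": "ok",
                "n_rejected": sum(r.rejected for r in runs),
                "n_errors": len(errors),
            }
        except Exception as exc:
            manifest["stages"]["filter"] = {"status": "error", "error": str(exc)}
            _write_manifest(out, manifest)
            return manifest
    else:
        manifest["stages"]["filter"] = {"status": "skipped"}

    try:
        for run in runs:
            orientation.decode_run(run, cfg.orientation)
        io.write_run_table(out / "runs.csv", runs, cfg.attention.sample_rate)
        manifest["stages"]["decode"] = {
            "status": "ok",
            "n_decoded": sum(r.orientation_deg is not None for r in runs),
            "n_degenerate": sum(r.degenerate for r in runs),
        }
    except Exception as exc:
        manifest["stages"]["decode"] = {"status": "error", "error": str(exc)}
        _write_manifest(out, manifest)
        return manifest

    try:
        kept = [r for r in runs if not r.rejected]
        times = [meta.frame_time(r.start_frame) for r in kept]
        end_times = [meta.frame_time(r.end_frame) for r in kept]
        dances = mapping.build_dances(
            [r.comb_xy for r in kept],
            times,
            [r.duration_ms for r in kept],
            [r.orientation_deg for r in kept],
            cfg.mapping,
            rng=np.random.default_rng(cfg.seed),
            run_end_times=end_times,
        )
        vectors = [mapping.project_dance(d, cfg.mapping) for d in dances]
        _write_dances_csv(out / "dances.csv", dances, vectors)
        io.write_geojson(out / "dances.geojson", vectors, dances, meta.hive_lat, meta.hive_lon)
        manifest["stages"]["map"] = {"status": "ok", "n_dances": len(dances)}
    except Exception as exc:
        manifest["stages"]["map"] = {"status": "error", "error": str(exc)}

    _write_manifest(out, manifest)
    return manifest


def _write_dances_csv(path, dances, vectors):
    import pandas as pd

    rows = []
    for d, v in zip(dances, vectors):
        rows.append(
            {
                "dance_id": d.id,
                "start_iso": d.start_time.isoformat(),
                "n_runs": d.n_runs,
                "n_inliers": d.n_inliers,
                "mean_duration_ms": d.mean_duration_ms,
                "mean_return_ms": d.mean_return_ms,
                "comb_angle_deg": d.mean_angle_comb_deg,
                "bearing_deg": v.bearing_deg,
                "distance_m": v.distance_m,
                "profitability": v.profitability,
                "east_m": v.map_xy_m[0],
                "north_m": v.map_xy_m[1],
            }
        )
    pd.DataFrame(rows, columns=DANCE_COLUMNS).to_csv(path, index=False)


def _write_manifest(out: Path, manifest: dict):
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
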