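# waggledance

Automatic detection, decoding and field-mapping of honey bee waggle dances
from observation-hive video.

Forager bees advertise profitable food sources with the waggle dance: during
each *waggle run* the dancer throws her body from side to side at ~13 Hz
while creeping forward along a straight line on the vertical comb. The run's
orientation relative to gravity encodes the direction of the resource
relative to the solar azimuth, its duration d_w encodes the distance, and
the ratio d_w/d_r of waggle to *return-run* duration encodes profitability.
A dance is a figure-eight sequence of runs alternating clockwise and
counter-clockwise return loops.

This package turns ~100 Hz grayscale video of a comb surface (≥1.5 px/mm)
into a table of dances mapped to field coordinates. It is aimed at
behavioral ecologists who want to read colony-level foraging maps out of
observation-hive recordings without manual frame-by-frame annotation.

## Method

Four stages run in sequence:

1. **Attention.** Every pixel owns a *dot detector*: its last *b* intensity
   values *B* are min–max normalized to [−1, 1] and scored with a
   periodogram over the waggle band *r* ∈ {10…16} Hz,

       score(B̄, r) = (Σₘ B̄(m) cos(2πrm/s_r))² + (Σₘ B̄(m) sin(2πrm/s_r))²,

   so a pixel activates when its recent history carries lateral-oscillation
   power regardless of illumination gain or offset. Activated pixels are
   grouped by single-linkage agglomerative clustering (threshold = half a
   bee length), cluster centroids are linked over time into waggle runs,
   and 50×50 px snippet sequences are exported per run. Runs shorter than
   200 ms (fewer than three body oscillations) are discarded.
2. **Filter network.** A small 3D convolutional network (two SELU conv
   layers, global average pooling, dropout, sigmoid) scores each snippet
   sequence and flags non-waggle events (walking, grooming pulses). It
   trains on random 128-frame subsequences with horizontal/vertical flip
   augmentation using Adam on binary cross-entropy.
3. **Orientation.** Consecutive-frame differences of a waggling,
   textureless bee form a Gabor-like two-lobe pattern aligned with the
   motion axis. Summed magnitudes of their 2-D Fourier transforms
   concentrate in a point-symmetric pair of maxima at radius
   k = I_size/(2x) (x = lateral displacement per frame, Fourier slice
   theorem); a ring-shaped difference-of-Gaussians bandpass at k plus PCA
   over the filtered spectrum yields the motion axis, +90° the body axis.
   The forward drift of the detections resolves the remaining 180°
   ambiguity.
4. **Mapping.** Runs are clustered into dances in (x, y, t)-space (time in
   quarter units per second, single linkage); clusters need ≥ 4 runs.
   One-point RANSAC over circular distance drops 180°-flipped orientation
   outliers, then per dance: bearing θ = solar azimuth + circular mean
   comb angle, distance r = f_d · d̄_w with a feeder-calibrated factor f_d,
   profitability p = d̄_w/d̄_r. Results are written as CSV and GeoJSON.

A synthetic renderer (`waggledance.synthetic`) draws soft-edged ellipse
bees with exactly this motion model plus sensor noise, distractor bees and
a ground-truth log, so the whole pipeline is testable end to end without
recorded footage.

## Worked example

```python
import numpy as np
from waggledance import synthetic, attention, orientation, mapping
from waggledance.config import (SceneConfig, PipelineConfig, RecordingMeta)
from waggledance.pipeline import run_pipeline

scene = SceneConfig(resolution=(200, 200), noise_sd=4.0, n_distractors=2)
frames, truth = synthetic.render_dance(
    scene, n_runs=5, base_orientation_deg=120.0, run_angle_sd_deg=8.0,
    run_duration_frames=58, return_duration_frames=120, seed=11)

meta = RecordingMeta(start_time="2016-08-01T10:00:00+00:00")
manifest = run_pipeline(PipelineConfig(), frames, meta, "out", use_filter=False)
print(manifest["stages"])
```

prints

```
{'detect': {'status': 'ok', 'n_runs': 5},
 'filter': {'status': 'skipped'},
 'decode': {'status': 'ok', 'n_decoded': 5, 'n_degenerate': 0},
 'map': {'status': 'ok', 'n_dances': 1}}
```

and `out/dances.csv` holds the single detected dance:

```
dance_id,start_iso,n_runs,n_inliers,mean_duration_ms,mean_return_ms,comb_angle_deg,bearing_deg,distance_m,profitability,east_m,north_m
0,2016-08-01T10:00:00.150000+00:00,5,5,562.0,1155.0,124.52,275.12,329.80,0.487,-328.48,29.44
```

All five rendered runs were detected, decoded (comb angle 124.5° vs the
ground-truth circular mean ≈ 125.2°) and clustered into one dance; with the
sun at azimuth ≈ 150.6° the dance points 275.1° (WNW), 330 m from the hive
(562 ms × 0.587 m/ms), with profitability 562/1155 ≈ 0.49.

Short narrative scripts, one per capability, live in `examples/`; the
command line mirrors them (`waggledance simulate | detect | filter |
decode | map | calibrate | pipeline`).

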