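# Methods

This note documents the models, conventions, parameter choices and known
limitations of the package. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Conventions

* Image coordinates: x right, y down; positions are (x, y) pixel pairs.
* Comb angles: degrees from image "up", clockwise positive, in [0, 360);
  on a vertical comb "up" corresponds to flying toward the solar azimuth.
* Field bearings: compass convention, 0° = true north, clockwise. A comb
  angle α observed when the sun stands at azimuth A maps to bearing
  (A + α) mod 360. Magnetic declination is not modelled (true north
  assumed).
* Body *axes* (undirected) live in [0, 180); *directions* in [0, 360) with
  direction mod 180 = axis.
* Frame indices are 0-based; all timestamps derive from
  start_time + frame/frame_rate, never from wall clocks.

## Synthetic scene model

The renderer emulates what a low-resolution hive camera sees: bees are
textureless, homogeneous ellipses (axis ratio 2.5:1, uniform intensity with
a sigmoid edge of relative softness 0.08) on a flat comb background with
additive Gaussian sensor noise. Defaults: 100 Hz, 1.7 px/mm, 14 mm bee
(≈ 24 px long), background 40, bee contrast +160 (bright-on-dark;
configurable sign), noise SD 4 intensity units.

During a waggle run the ellipse center advances along the body axis at
0.5 px/frame (≈ 29 mm/s at scale) and oscillates perpendicular to it as
A·sin(2πft), A = 6 px, f = 13 Hz — so the peak lateral velocity is
≈ 4.9 px/frame, matching the 5–7 px/frame band the orientation bandpass is
tuned for. Return phases are semicircular arcs over the chord from run end
back to the dance origin, with alternating handedness; the figure-eight
geometry beyond alternation and duration is not biologically calibrated
and is exposed as a parameter (`return_duration_frames`) rather than
asserted. Distractor bees random-walk at ≤ ~2 px/frame so they never enter
the waggle band. Non-waggle snippets cover straight walking, stationary
bees, and grooming-like oscillation pulses shorter than 200 ms.

All randomness flows from one explicitly passed `numpy` generator;
identical config + seed yields bit-identical frames.

What the generator does **not** emulate: body flexion and pose texture,
occlusion by dance followers, comb cell structure, illumination flicker,
motion blur, and dancer-specific tempo variation. Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms
under the stated motion model, not performance on real footage; the
real-data error bounds used in the acceptance tests are upper bounds
precisely because real footage is harder.

## Attention module

Per-pixel window length b = 32 frames (0.32 s ≈ 4 waggle cycles): long
enough to resolve the band, short enough to keep detection latency and
temporal smearing low. The waggle band is sampled at the seven integer
frequencies 10–16 Hz. The score is the periodogram value (square the two
basis projections, then sum); the alternative reading that squares each
summand before summing collapses to the window energy at every frequency
and cannot discriminate oscillation from noise — the test suite
demonstrates this and pins the periodogram form against a brute-force DFT
oracle at 1e−9 relative tolerance.

Score threshold t_h = 100 against a theoretical pure-tone score of
(b/2)² = 256 and a noise expectation of ≈ b/3 ≈ 11; chosen so isolated
noise activations are rare and cleaned up by the cluster-size filter
(c_min1 = 4). Clustering is single-linkage HAC cut at d_max1 = 11.9 px
(half a bee length at 1.7 px/mm), implemented as a threshold cut of the
scipy dendrogram and verified against a union-find connected-components
oracle. Run assembly links centroids within d_max2 = 12 px (again about
half a body length — the 13 Hz throw moves the centroid several px between
frames, so a tighter forward-velocity-based radius would drop detections),
allows gaps up to g_max2 = 10 frames, and keeps candidates with ≥ 10
detections and ≥ 200 ms duration.

A sliding-window score at buffer head n describes the interval
[n−b+1, n]; emitted run boundaries are therefore shifted back by the group
delay b/2 (start and end equally, so durations are untouched). With this
convention the synthetic experiments recover run boundaries within a few
frames instead of lagging by half a window.

Snippet export crops 50×50 px per frame, centered on that frame's
detection centroid (zero-padded at borders). Because the detector's
activation mask is itself a temporally smeared version of the bee's path,
these centers are effectively low-passed and the 13 Hz throw stays visible
inside the crop — the synthetic `render_run_snippets` helper reproduces
this by smoothing the ground-truth trajectory over ~one oscillation period
(8 frames) before cropping, plus a 1 px random-walk jitter emulating
centroid noise.

## Filter network

Architecture (all in config): fixed (2,2,2) average pool on the raw
128×50×50 clip, two 3×3×3 SELU convolutions (8 and 16 channels, stride
(2,2,2) each), global average pooling over time and space, dropout 0.1,
and one fully connected sigmoid unit — 3713 parameters. The leading pool
keeps the 13 Hz signal at ~4 samples per cycle while cutting the
convolution cost ~8-fold. The network, backpropagation and Adam are
implemented directly on numpy arrays; gradients are verified against
central finite differences in the tests.

Training protocol: per mini-batch a random 128-frame subsequence is
sampled from each detection (shorter ones zero-padded at the end), flipped
horizontally/vertically with p = 0.5 each, normalized to zero mean / unit
SD per clip; Adam at lr 3e−3, batch 16, 8 epochs, binary cross-entropy,
20% held-out split fixed by the seed. Loss must stay finite and both
classes must be present, else training aborts with a diagnostic. The
module is optional in the pipeline (`use_filter=False` / `--no-filter`):
the attention module is deliberately tuned for sensitivity and the network
is its post-hoc cleaner.

## Orientation module

Difference images are mean-subtracted before the 2-D FFT so a DC offset
cannot plant an origin peak. Magnitudes, not complex values, are summed
over frames: the Gabor-like pattern translates with the bee, so phases
decorrelate across frames and a complex sum cancels (a test quantifies
this). The ring bandpass is a difference of two origin-centered Gaussians
(σ = k and k/2, surround minus center, clipped at 0, unit peak ≈ at
radius k); k = I_size/(2x) with lateral step x = 5 px/frame at the default
scale, giving k = 5 cycles for I_size = 50 — consistent with the renderer's
peak lateral velocity. x is a config field; at other resolutions it should
be set to the expected per-frame lateral displacement in pixels.

PCA treats the filtered spectrum as a weighted point cloud (magnitudes as
weights, no thresholding — thresholding would discard the information that
stabilizes the estimate at low SNR); second moments are taken about the
origin since the spectrum is point-symmetric. An eigenvalue ratio < 1.05
flags a degenerate (isotropic) spectrum. Disambiguation anchors at the
mean of the first 10% of detection positions, histograms the orientations
of all position−anchor vectors into 36 bins of 10°, circularly averages
the modal bin(s) into a coarse heading, and picks the axis alternative
closer to it; the margin |cos Δ| is 1 for clean forward motion and 0 for
an uninformative (orthogonal or absent) drift. Degenerate runs are still
emitted, flagged, so the mapping stage can reject them as outliers — the
180°-flip failure mode is inherent when forward motion vanishes.

## Mapping module

Time enters the clustering space as quarter units per second
(time_scale = 0.25), making the ~2 s gap between consecutive runs of one
dance (≈ 0.5 units) commensurate with their few-px spatial drift;
d_max3 = 60 data-space units then keeps a dance together across its
longest internal gaps while separating dances minutes apart or a comb
width away. Clusters need ≥ 4 runs. RANSAC uses a one-point model (a
single mean direction), 100 iterations, 30° inlier radius — with ≤ 17
runs per dance every candidate center is effectively tried, and a single
180° flip always lands outside the radius; ties between equal consensus
sets resolve to the smaller circular variance. A consensus that is not a
majority (or smaller than the dance minimum) flags "no strong mode" and
the dance is discarded. Return-run durations are the gaps between
consecutive inlier runs only; gaps spanning an excluded outlier are not
used. The solar azimuth is evaluated once per dance, at its first waggle
run, with a self-contained NOAA solar-position implementation (≤ 0.5°;
cross-checked in tests against equinox/noon geometry). The default
duration-to-distance factor 342/582.79 ≈ 0.587 m/ms comes from the
collective feeder calibration (a feeder 342 m from the hive advertised
with mean waggle duration 582.79 ms); `calibrate_factor` recomputes it
from any run table and a known feeder.

Odd run counts only warn (consecutive runs alternate around the true
direction — the divergence angle — so an even count cancels it), because
discarding data would be worse than the small residual bias.

## Validation experiment sizes

The synthetic validation protocols run at the sizes the error bounds refer
to: 200 runs for orientation (uniform random true directions, noise SD 4,
durations 0.4–0.8 s), 200 single-run scenes for duration (300–900 ms,
160×160 px, 0.5 s still pre/post roll), 400 + 400 clips for filter
training, and 571 dances (4–17 runs each, orientation spread 14.37°,
durations ~N(583, 196²) ms clipped to [300, 1100]) for mapping, laid out
over a comb-sized grid and a ~5 h virtual morning. One full acceptance
pass takes a few minutes on one CPU core.

## Known limitations

* The motion model is a pure sinusoid plus constant creep; real dances
  modulate amplitude and tempo and bend their waggle lines.
* Bee identity is not tracked across runs; two dancers waggling
  simultaneously closer than d_max2 could be merged by the assembler.
* The "Restmissweisung" (comb-orientation-dependent residual angular
  error) is not corrected.
* Round dances are out of scope: the waggle oscillation is an unreliable
  feature for them, and sub-200 ms waggle pulses are filtered out by
  design.
* Rectification assumes all four comb corners are visible and the comb is
  planar.
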