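"""Cluster decoded waggle runs into dances and project them to the field.

Six runs (one with a 180-deg flipped orientation, as the decoder sometimes
produces when forward motion is weak) are clustered in (x, y, t) space,
RANSAC removes the flip, and the dance is projected with the solar azimuth
at its start time.
"""

from datetime import datetime, timedelta, timezone

import numpy as np

from waggledance import mapping
from waggledance.config import MappingConfig
from waggledance.solar import solar_azimuth

cfg = MappingConfig()  # hive near Berlin, feeder-calibrated 0.587 m/ms
base = datetime(2016, 8, 1, 10, 0, tzinfo=timezone.utc)
times = [base + timedelta(seconds=2.5 * i) for i in range(6)]
angles = [118.0, 122.0, 301.0, 120.0, 119.0, 121.0]  # run 2 is flipped
dances = mapping.build_dances(
    positions_px=[(100.0 + 3 * i, 50.0) for i in range(6)],
    times=times,
    durations_ms=[580.0] * 6,
    orientations_deg=angles,
    cfg=cfg,
    rng=np.random.default_rng(0),
    run_end_times=[t + timedelta(milliseconds=580) for t in times],
)

d = dances[0]
fv = mapping.project_dance(d, cfg)
az, _ = solar_azimuth(d.start_time, cfg.hive_lat, cfg.hive_lon)
print(f"one dance, {d.n_inliers}/{d.n_runs} runs kept as inliers "
      f"(the 301-deg flip was rejected)")
print(f"mean comb angle : {d.mean_angle_comb_deg:.1f} deg")
print(f"solar azimuth   : {az:.1f} deg at {d.start_time:%H:%M} UTC")
print(f"field bearing   : {fv.bearing_deg:.1f} deg, distance {fv.distance_m:.0f} m")
print(f"map offset      : {fv.map_xy_m[0]:+.0f} m east, {fv.map_xy_m[1]:+.0f} m north")
print(f"profitability   : {fv.profitability:.2f} (waggle/return duration)")
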