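"""Dance clustering, circular statistics, RANSAC, calibration, projection."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waggledance import mapping
from waggledance.angles import circular_distance, circular_mean, wrap360
from waggledance.config import ConfigError, MappingConfig
from waggledance.solar import solar_azimuth, solar_position

CFG = MappingConfig()


class TestXytEmbed:
    def test_quarter_second_time_axis(self):
        pts = mapping.xyt_embed([(10.0, 20.0)], [43200.0], CFG)
        assert pts[0, 2] == pytest.approx(10800.0)

    def test_simultaneous_runs_distance_is_spatial(self):
        pts = mapping.xyt_embed([(0.0, 0.0), (10.0, 0.0)], [100.0, 100.0], CFG)
        assert np.linalg.norm(pts[0] - pts[1]) == pytest.approx(10.0)

    def test_zero_time_scale_rejected_by_config(self):
        with pytest.raises(ConfigError):
            MappingConfig(time_scale=0.0)


class TestClusterDances:
    def test_drifting_sequence_is_one_dance(self):
        # six runs, ~2 s apart, ~15 px drift: the basis for d_max3
        pos = [(100.0 + 15 * i, 50.0) for i in range(6)]
        t = [1000.0 + 2.0 * i for i in range(6)]
        clusters = mapping.cluster_dances(mapping.xyt_embed(pos, t, CFG), CFG)
        assert len(clusters) == 1 and len(clusters[0]) == 6

    def test_three_runs_are_not_a_dance(self):
        pos = [(100.0, 50.0)] * 3
        t = [1000.0, 1002.0, 1004.0]
        assert mapping.cluster_dances(mapping.xyt_embed(pos, t, CFG), CFG) == []

    def test_ten_minutes_apart_splits_at_same_spot(self):
        pos = [(100.0, 50.0)] * 8
        t = [1000.0 + 2 * i for i in range(4)] + [1600.0 + 2 * i for i in range(4)]
        clusters = mapping.cluster_dances(mapping.xyt_embed(pos, t, CFG), CFG)
        assert len(clusters) == 2


def exhaustive_consensus(angles, tol):
    """Oracle: best consensus over every angle as candidate center."""
    best = None
    for c in angles:
        mask = circular_distance(np.asarray(angles), c) <= tol
        rad = np.deg2rad(np.asarray(angles)[mask])
        var = 1.0 - np.hypot(np.sin(rad).mean(), np.cos(rad).mean())
        key = (mask.sum(), -var)
        if best is None or key > best[0]:
            best = (key, mask)
    return best


class TestRansacAngles:
    def test_flipped_outlier_excluded(self):
        angles = [40.0, 42.0, 44.0, 38.0, 222.0]
        mask, mean, weak = mapping.ransac_angles(angles, CFG, np.random.default_rng(0))
        assert list(mask) == [True, True, True, True, False]
        assert mean == pytest.approx(41.0, abs=1e-9)
        assert not weak

    def test_identical_angles_all_inliers(self):
        mask, mean, weak = mapping.ransac_angles(
            [77.0] * 6, CFG, np.random.default_rng(0)
        )
        assert mask.all() and mean == pytest.approx(77.0) and not weak

    def test_even_bimodal_split_flagged_weak(self):
        angles = [0.0] * 4 + [180.0] * 4
        _, _, weak = mapping.ransac_angles(angles, CFG, np.random.default_rng(0))
        assert weak

    @given(
        seed=st.integers(0, 2000),
        n=st.integers(4, 12),
        spread=st.floats(1.0, 25.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_matches_exhaustive_consensus_oracle(self, seed, n, spread):
        rng = np.random.default_rng(seed)
        angles = wrap360(
            np.concatenate(
                [rng.normal(130.0, spread, size=n - 1), [rng.uniform(0, 360)]]
            )
        ).round(2)
        mask, _, _ = mapping.ransac_angles(angles, CFG, np.random.default_rng(1))
        (size, negvar), _ = exhaustive_consensus(angles, CFG.ransac_inlier_deg)
        # with one-point sampling over 100 iters on <=12 angles every center
        # is tried: consensus size must equal the exhaustive optimum
        assert mask.sum() == size


class TestCircularMean:
    def test_wraparound(self):
        assert circular_distance(circular_mean([350.0, 10.0]), 0.0) < 1e-9

    def test_worked_example(self):
        assert circular_mean([10.0, 20.0, 30.0, 40.0]) == pytest.approx(25.0)

    def test_identity(self):
        for a in (0.0, 123.4, 359.9):
            assert circular_mean([a]) == pytest.approx(a)

    def test_opposed_angles_undefined(self):
        with pytest.raises(ValueError):
            circular_mean([0.0, 180.0])

    def test_odd_n_warns(self):
        with pytest.warns(UserWarning):
            circular_mean([10.0, 20.0, 30.0], warn_odd=True)

    @given(
        shift=st.floats(-360.0, 360.0),
        seed=st.integers(0, 1000),
        n=st.integers(2, 10),
    )
    @settings(max_examples=40, deadline=None)
    def test_rotation_equivariance(self, shift, seed, n):
        rng = np.random.default_rng(seed)
        angles = rng.normal(90.0, 20.0, size=n)
        assert circular_distance(
            circular_mean(angles + shift), circular_mean(angles) + shift
        ) < 1e-6


class TestDurationToDistance:
    def test_feeder_calibration_identity(self):
        f_d = 342.0 / 582.79
        assert mapping.duration_to_distance(582.79, f_d) == pytest.approx(342.0)

    def test_linearity(self):
        f_d = CFG.distance_factor
        assert mapping.duration_to_distance(800.0, f_d) == pytest.approx(
            2 * mapping.duration_to_distance(400.0, f_d)
        )

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            mapping.duration_to_distance(0.0, 1.0)


class TestCalibrateFactor:
    def test_single_run_exact(self):
        f_d, stats = mapping.calibrate_factor([100.0], [570.0], 100.0, 342.0)
        assert f_d == pytest.approx(342.0 / 570.0)
        assert stats["n"] == 1

    def test_parameter_recovery_within_5_percent(self):
        rng = np.random.default_rng(8)
        n = 200
        angles = wrap360(rng.normal(225.0, 8.0, size=n))
        true_factor = 342.0 / 582.79
        durations = rng.normal(582.79, 196.10, size=n).clip(150, None)
        f_d, _ = mapping.calibrate_factor(angles, durations, 225.0, 342.0)
        assert f_d == pytest.approx(true_factor, rel=0.05)

    def test_cv_of_feeder_durations(self):
        rng = np.random.default_rng(9)
        durations = rng.normal(582.79, 196.10, size=5000).clip(50, None)
        _, stats = mapping.calibrate_factor(
            np.zeros(5000), durations, 0.0, 342.0
        )
        assert stats["cv"] == pytest.approx(196.10 / 582.79, abs=0.03)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            mapping.calibrate_factor([90.0], [500.0], 270.0, 342.0)


class TestProfitability:
    def test_equal_durations_give_one(self):
        assert mapping.profitability(700.0, 700.0) == pytest.approx(1.0)

    def test_ratio_law(self):
        assert mapping.profitability(600.0, 750.0) == pytest.approx(
            2 * mapping.profitability(600.0, 1500.0)
        )

    def test_worked_example(self):
        assert mapping.profitability(600.0, 1500.0) == pytest.approx(0.4)

    def test_zero_return_rejected(self):
        with pytest.raises(ValueError):
            mapping.profitability(600.0, 0.0)


class TestSolar:
    def test_equator_equinox_sunrise_is_east(self):
        az, elev = solar_position(
            datetime(2016, 3, 20, 6, 6, tzinfo=timezone.utc), 0.0, 0.0
        )
        assert az == pytest.approx(90.0, abs=1.0)
        assert abs(elev) < 2.0

    def test_local_solar_noon_is_south_at_mid_latitude(self):
        # Berlin, 2016-08-01: solar noon ~ 11:13 UTC (longitude + eq. of time)
        az, elev = solar_position(
            datetime(2016, 8, 1, 11, 13, tzinfo=timezone.utc), 52.457, 13.296
        )
        assert az == pytest.approx(180.0, abs=1.0)
        assert elev > 50.0

    def test_azimuth_increases_through_summer_day(self):
        times = [
            datetime(2016, 8, 1, h, 0, tzinfo=timezone.utc) for h in range(6, 19)
        ]
        azs = [solar_position(t, 52.457, 13.296)[0] for t in times]
        assert all(a < b for a, b in zip(azs, azs[1:]))

    def test_polar_night_low_sun_flag(self):
        az, low = solar_azimuth(
            datetime(2016, 12, 21, 12, 0, tzinfo=timezone.utc), 78.2, 15.6
        )
        assert low and 0.0 <= az < 360.0


def _dance(angle, duration_ms=582.79, when=None):
    return mapping.Dance(
        id=0,
        run_indices=[0, 1, 2, 3],
        inlier_mask=np.ones(4, bool),
        mean_duration_ms=duration_ms,
        mean_return_ms=None,
        mean_angle_comb_deg=angle,
        start_time=when or datetime(2016, 8, 1, 10, 0, tzinfo=timezone.utc),
        comb_xy=(0.0, 0.0),
    )


class TestProjectDance:
    def test_upward_dance_points_at_sun(self):
        fv = mapping.project_dance(_dance(0.0), CFG, azimuth_deg=135.0)
        assert fv.bearing_deg == pytest.approx(135.0)

    def test_90_clockwise_at_azimuth_135_gives_225(self):
        fv = mapping.project_dance(_dance(90.0), CFG, azimuth_deg=135.0)
        assert fv.bearing_deg == pytest.approx(225.0)

    def test_southwest_map_offset(self):
        fv = mapping.project_dance(_dance(90.0), CFG, azimuth_deg=135.0)
        assert fv.distance_m == pytest.approx(342.0, rel=1e-6)
        assert fv.map_xy_m[0] == pytest.approx(-241.83, abs=0.1)
        assert fv.map_xy_m[1] == pytest.approx(-241.83, abs=0.1)

    def test_generator_roundtrip(self):
        """Projection inverts the (noise-free) dance generator."""
        rng = np.random.default_rng(11)
        base = datetime(2016, 8, 1, 9, 0, tzinfo=timezone.utc)
        cfg = MappingConfig()
        for bearing, dist in ((30.0, 500.0), (250.0, 1200.0)):
            az, _ = solar_azimuth(base, cfg.hive_lat, cfg.hive_lon)
            comb_angle = wrap360(bearing - az)
            duration = dist / cfg.distance_factor
            fv = mapping.project_dance(_dance(comb_angle, duration, base), cfg)
            assert circular_distance(fv.bearing_deg, bearing) < 1e-6
            assert fv.distance_m == pytest.approx(dist, rel=1e-9)


class TestBuildDances:
    def test_runs_with_flips_become_one_clean_dance(self):
        rng = np.random.default_rng(12)
        base = datetime(2016, 8, 1, 10, 0, tzinfo=timezone.utc)
        times = [base + timedelta(seconds=2.5 * i) for i in range(6)]
        end_times = [t + timedelta(milliseconds=580) for t in times]
        angles = [118.0, 122.0, 301.0, 120.0, 119.0, 121.0]  # one flipped
        dances = mapping.build_dances(
            [(100.0 + 3 * i, 50.0) for i in range(6)],
            times,
            [580.0] * 6,
            angles,
            CFG,
            rng=rng,
            run_end_times=end_times,
        )
        assert len(dances) == 1
        d = dances[0]
        assert d.n_inliers == 5
        assert circular_distance(d.mean_angle_comb_deg, 120.0) < 1.0
        # return durations: gaps between consecutive inlier runs only
        assert d.mean_return_ms == pytest.approx(1920.0, rel=0.01)
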