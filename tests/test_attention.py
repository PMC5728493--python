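"""Dot-detector scoring, clustering and run assembly.

The periodogram score is checked against an independent brute-force DFT
oracle; the clustering against a union-find single-linkage oracle; assembly
against hand-constructed detection streams.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waggledance import attention, synthetic
from waggledance.attention import DancerDetection, RunAssembler
from waggledance.config import AttentionConfig, GroundTruthRun, SceneConfig


def naive_dft_power(series, r, s_r):
    """Brute-force double-loop squared DFT magnitude at frequency r."""
    re = im = 0.0
    for m, v in enumerate(series, start=1):
        re += v * np.cos(2 * np.pi * r * m / s_r)
        im += v * np.sin(2 * np.pi * r * m / s_r)
    return re**2 + im**2


def literal_sum_of_squares(series, r, s_r):
    """The rejected literal reading: square each summand before summing.

    Because cos^2 + sin^2 = 1 it collapses to sum(B^2) — independent of the
    probe frequency and of phase coherence, so it cannot discriminate a
    waggle tone from noise of equal power.
    """
    total = 0.0
    for m, v in enumerate(series, start=1):
        c = v * np.cos(2 * np.pi * r * m / s_r)
        s = v * np.sin(2 * np.pi * r * m / s_r)
        total += c**2 + s**2
    return total


class TestNormalizeWindow:
    def test_extremes_map_to_plus_minus_one(self):
        b = np.array([0, 255] * 8, dtype=float)
        out = attention.normalize_window(b)
        assert np.allclose(out, np.array([-1, 1] * 8, dtype=float))

    def test_constant_window_maps_to_zero(self):
        assert np.allclose(attention.normalize_window(np.full(16, 42.0)), 0.0)

    @given(
        gain=st.floats(0.1, 10.0),
        offset=st.floats(-100.0, 100.0),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, gain, offset, seed):
        b = np.random.default_rng(seed).uniform(0, 255, size=32)
        assert np.allclose(
            attention.normalize_window(gain * b + offset),
            attention.normalize_window(b),
            atol=1e-9,
        )


class TestDDScore:
    def test_pure_cosine_scores_quarter_b_squared(self):
        b, r, s_r = 100, 13.0, 100.0
        m = np.arange(1, b + 1)
        series = np.cos(2 * np.pi * r * m / s_r)
        score = attention.dd_score(series, r, s_r)
        assert score == pytest.approx((b / 2) ** 2, rel=0.05)

    def test_zero_input_zero_score(self):
        for r in (10.0, 13.0, 16.0):
            assert attention.dd_score(np.zeros(32), r, 100.0) == 0.0

    def test_cross_frequency_rejection(self):
        b, s_r = 100, 100.0
        m = np.arange(1, b + 1)
        series = np.cos(2 * np.pi * 13.0 * m / s_r)
        on = attention.dd_score(series, 13.0, s_r)
        off = attention.dd_score(series, 30.0, s_r)
        assert off < 0.01 * on

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            attention.dd_score(np.zeros(32), 60.0, 100.0)

    @given(seed=st.integers(0, 10_000), r=st.sampled_from([10.0, 12.5, 13.0, 16.0]))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_dft_oracle(self, seed, r):
        series = np.random.default_rng(seed).uniform(-1, 1, size=32)
        mine = attention.dd_score(series, r, 100.0)
        oracle = naive_dft_power(series, r, 100.0)
        assert mine == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_literal_reading_cannot_discriminate(self):
        """Squaring each summand loses phase: tone and noise score alike."""
        b, s_r = 32, 100.0
        m = np.arange(1, b + 1)
        tone = np.cos(2 * np.pi * 13.0 * m / s_r)
        rng = np.random.default_rng(0)
        noise = rng.choice([-1.0, 1.0], size=b) / np.sqrt(2.0)  # equal power
        lit_tone = literal_sum_of_squares(tone, 13.0, s_r)
        lit_noise = literal_sum_of_squares(noise, 13.0, s_r)
        # the literal score is just the window energy at any frequency
        assert lit_tone == pytest.approx(np.sum(tone**2), rel=1e-12)
        assert lit_noise == pytest.approx(lit_tone, rel=0.05)
        # while the periodogram reading separates them by >10x
        assert attention.dd_score(tone, 13.0, s_r) > 10 * attention.dd_score(
            noise, 13.0, s_r
        )


class TestActivation:
    def test_waggle_snippet_activates_inside_bee_neighbourhood(
        self, att_cfg, detected_scene
    ):
        frames = detected_scene["frames"]
        cfg = detected_scene["scene_cfg"]
        truth = detected_scene["truth"]
        window = frames[80 : 80 + att_cfg.window_len].astype(np.float32)
        pts = attention.activate_detectors(window, att_cfg)
        assert len(pts) > 0
        traj = synthetic.waggle_trajectory(cfg, truth)
        dists = np.min(
            np.linalg.norm(pts[:, None, :] - traj[None, :, :], axis=2), axis=1
        )
        # isolated noise pixels may activate (the min_cluster_size filter
        # exists for them); the bulk must lie in the dilated bee mask and
        # every *clustered* detection centroid on the path
        assert np.mean(dists <= cfg.bee_length_px) >= 0.9
        dets = attention.cluster_dancers(pts, att_cfg)
        assert len(dets) >= 1
        for d in dets:
            assert np.min(np.linalg.norm(traj - d.centroid_xy, axis=1)) < cfg.bee_length_px

    def test_stationary_bee_never_activates(self, att_cfg):
        cfg = SceneConfig(noise_sd=2.0)
        frames = synthetic.render_non_waggle_snippet(
            cfg, "stationary", n_frames=att_cfg.window_len, rng=np.random.default_rng(1)
        )
        assert len(attention.activate_detectors(frames.astype(np.float32), att_cfg)) == 0

    def test_walking_bee_never_activates(self, att_cfg):
        cfg = SceneConfig(noise_sd=2.0)
        frames = synthetic.render_non_waggle_snippet(
            cfg, "walking", n_frames=att_cfg.window_len,
            rng=np.random.default_rng(2), walk_speed=3.0,
        )
        assert len(attention.activate_detectors(frames.astype(np.float32), att_cfg)) == 0

    def test_zero_threshold_activates_everything(self):
        cfg = AttentionConfig(score_threshold=0.0)
        window = np.random.default_rng(0).uniform(0, 255, size=(32, 10, 10)).astype(np.float32)
        assert len(attention.activate_detectors(window, cfg)) == 100

    def test_illumination_gain_offset_leaves_activations_unchanged(self, att_cfg):
        rng = np.random.default_rng(3)
        m = np.arange(1, att_cfg.window_len + 1)
        window = rng.uniform(0, 60, size=(att_cfg.window_len, 12, 12))
        window[:, 4:7, 4:7] += 100 * np.cos(2 * np.pi * 13 * m / 100.0)[:, None, None]
        a = attention.activate_detectors(window, att_cfg)
        b = attention.activate_detectors(1.7 * window + 21.0, att_cfg)
        assert np.array_equal(a, b) and len(a) > 0


def union_find_single_linkage(points, threshold):
    """Brute-force connected components of the <=threshold graph."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= threshold:
                parent[find(i)] = find(j)
    labels = [find(i) for i in range(n)]
    return {lab: frozenset(np.nonzero(np.array(labels) == lab)[0]) for lab in set(labels)}


class TestClusterDancers:
    def test_two_separated_blobs_two_detections(self, att_cfg):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 5, size=(6, 2))
        b = rng.uniform(0, 5, size=(6, 2)) + 5 * att_cfg.cluster_dist
        dets = attention.cluster_dancers(np.vstack([a, b]), att_cfg)
        assert len(dets) == 2
        for d in dets:
            assert np.allclose(d.centroid_xy, d.member_pixels.mean(axis=0), atol=0.5)

    def test_single_pixel_discarded_as_noise(self, att_cfg):
        assert attention.cluster_dancers(np.array([[10.0, 10.0]]), att_cfg) == []

    def test_empty_input_empty_output(self, att_cfg):
        assert attention.cluster_dancers(np.empty((0, 2)), att_cfg) == []

    @given(seed=st.integers(0, 5000), n=st.integers(2, 20))
    @settings(max_examples=30, deadline=None)
    def test_matches_union_find_oracle_and_order_invariance(self, seed, n):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 60, size=(n, 2)).round(1)
        cfg = AttentionConfig(cluster_dist=10.0, min_cluster_size=1)
        dets = attention.cluster_dancers(pts, cfg)
        oracle = union_find_single_linkage(pts, 10.0)
        mine = {
            frozenset(
                int(np.nonzero((pts == m).all(axis=1))[0][0])
                for m in d.member_pixels
            )
            for d in dets
        }
        assert mine == set(oracle.values())
        perm = rng.permutation(n)
        dets_p = attention.cluster_dancers(pts[perm], cfg)
        cents = sorted(tuple(np.round(d.centroid_xy, 6)) for d in dets)
        cents_p = sorted(tuple(np.round(d.centroid_xy, 6)) for d in dets_p)
        assert cents == cents_p


def _det(frame, x, y):
    return DancerDetection(
        frame=frame,
        centroid_xy=np.array([x, y], dtype=float),
        n_detectors=5,
        member_pixels=np.array([[int(x), int(y)]]),
    )


class TestAssembleRuns:
    def test_single_coherent_track_is_one_run(self, att_cfg):
        stream = [(i, [_det(i, 10 + 3 * i, 20.0)]) for i in range(60)]
        runs = attention.assemble_runs(stream, att_cfg)
        assert len(runs) == 1
        assert len(runs[0].detections) == 60
        assert runs[0].duration_ms == pytest.approx(600.0)

    def test_short_gap_bridged(self, att_cfg):
        frames = [i for i in range(60) if i not in (30, 31)]
        stream = [(i, [_det(i, 10 + 3 * i, 20.0)]) for i in frames]
        runs = attention.assemble_runs(stream, att_cfg)
        assert len(runs) == 1 and len(runs[0].detections) == 58

    def test_long_gap_splits(self):
        cfg = AttentionConfig(max_gap=4, min_run_detections=5, min_run_ms=100.0)
        frames = list(range(25)) + list(range(40, 65))
        stream = [(i, [_det(i, 10.0, 20.0)]) for i in frames]
        runs = attention.assemble_runs(stream, cfg)
        assert len(runs) == 2

    def test_short_pulse_discarded_by_duration_filter(self, att_cfg):
        stream = [(i, [_det(i, 10 + i, 20.0)]) for i in range(12)]  # 120 ms
        assert attention.assemble_runs(stream, att_cfg) == []

    def test_far_detection_seeds_new_candidate(self, att_cfg):
        stream = [(i, [_det(i, 10.0 + i, 20.0), _det(i, 120.0, 120.0)]) for i in range(30)]
        runs = attention.assemble_runs(stream, att_cfg)
        assert len(runs) == 2

    def test_streaming_equals_batch(self, att_cfg):
        rng = np.random.default_rng(4)
        stream = [
            (i, [_det(i, 10 + 0.5 * i + rng.normal(0, 1), 20 + rng.normal(0, 1))])
            for i in range(50)
        ]
        batch = attention.assemble_runs(stream, att_cfg)
        asm = RunAssembler(att_cfg)
        for frame, dets in stream:
            asm.update(frame, dets)
        one_by_one = asm.finalize()
        assert [(r.start_frame, r.end_frame, len(r.detections)) for r in batch] == [
            (r.start_frame, r.end_frame, len(r.detections)) for r in one_by_one
        ]


class TestDetectRuns:
    def test_recovers_the_rendered_run(self, detected_scene, att_cfg):
        runs = detected_scene["runs"]
        truth = detected_scene["truth"]
        assert len(runs) == 1
        run = runs[0]
        assert abs(run.start_frame - truth.start_frame) <= 15
        assert abs(run.end_frame - truth.end_frame) <= 15
        traj = synthetic.waggle_trajectory(detected_scene["scene_cfg"], truth)
        assert np.linalg.norm(np.asarray(run.comb_xy) - traj.mean(axis=0)) < 10

    def test_deterministic(self, detected_scene, att_cfg):
        again = attention.detect_runs(detected_scene["frames"], att_cfg, export_snippets=False)
        runs = detected_scene["runs"]
        assert [(r.start_frame, r.end_frame) for r in again] == [
            (r.start_frame, r.end_frame) for r in runs
        ]


class TestExportSnippet:
    def test_corner_crop_zero_padded(self):
        frame = np.full((100, 100), 50, dtype=np.uint8)
        crop = attention.crop_frame(frame, (0, 0), 50)
        assert crop.shape == (50, 50)
        assert (crop[:25, :25] == 0).all()  # outside the image
        assert (crop[25:, 25:] == 50).all()

    def test_bee_near_snippet_center(self, detected_scene):
        # crops center on the (spectrally low-passed) detection centroids,
        # so the blob oscillates around the crop center with the lateral
        # amplitude — by design, else the waggle signal would be cancelled
        run = detected_scene["runs"][0]
        cfg = detected_scene["scene_cfg"]
        bg = cfg.background_level
        tol = cfg.lateral_amplitude_px + 4.0
        for frame in run.snippet[8:-8]:
            w = np.clip(frame.astype(float) - bg, 0, None)
            ys, xs = np.mgrid[0:50, 0:50]
            c = np.array([(w * xs).sum(), (w * ys).sum()]) / w.sum()
            assert np.linalg.norm(c - [24.5, 24.5]) < tol

    def test_metadata_roundtrip(self, detected_scene, att_cfg, tmp_path):
        from waggledance import io

        run = detected_scene["runs"][0]
        io.write_snippet_dir(tmp_path, run)
        snippet, meta = io.read_snippet_dir(tmp_path / f"wr_{run.id:05d}")
        assert np.array_equal(snippet, run.snippet)
        assert meta == run.snippet_meta
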