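"""Shared fixtures: small rendered scenes reused across test modules."""

import numpy as np
import pytest

from waggledance import attention, synthetic
from waggledance.config import (
    AttentionConfig,
    GroundTruthRun,
    OrientationConfig,
    SceneConfig,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_scene_cfg():
    return SceneConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_scene_cfg():
    return SceneConfig(noise_sd=4.0)


@pytest.fixture(scope="session")
def ori_cfg():
    return OrientationConfig()


@pytest.fixture(scope="session")
def att_cfg():
    return AttentionConfig()


@pytest.fixture(scope="session")
def clean_run_snippets(clean_scene_cfg):
    """Noise-free 50x50 snippet sequence of a run at 123 deg, with centers."""
    truth = GroundTruthRun(0, 58, (0.0, 0.0), 123.0)
    snips, centers = synthetic.render_run_snippets(
        clean_scene_cfg, truth, rng=np.random.default_rng(7)
    )
    return snips, centers, truth


@pytest.fixture(scope="session")
def detected_scene(att_cfg):
    """One noisy waggle-run scene plus the attention module's output on it.

    The run waggles for 60 frames (600 ms) starting at frame 50, heading
    45 deg, with still pre/post roll so buffers can warm up.
    """
    from waggledance.angles import heading_vector

    cfg = SceneConfig(resolution=(160, 160), noise_sd=4.0)
    n_frames, direction = 60, 45.0
    travel = n_frames * cfg.forward_speed_px_per_frame
    start = np.array([80.0, 80.0]) - heading_vector(direction) * travel / 2.0
    truth = GroundTruthRun(50, n_frames, tuple(start), direction)
    frames = synthetic.render_run_scene(
        cfg, truth, pre_roll=50, post_roll=50, rng=np.random.default_rng(99)
    )
    runs = attention.detect_runs(frames, att_cfg, export_snippets=True)
    return {"scene_cfg": cfg, "truth": truth, "frames": frames, "runs": runs}
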