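import numpy as np
import pytest

from orchardtrack import SceneConfig, filter_frames, simulate_scene


def make_scene(**overrides):
    """Synthetic scene with sensible test-scale defaults."""
    base = dict(n_fruits=12, n_frames=150, seed=0)
    base.update(overrides)
    return SceneConfig(**base)


def noiseless_scene(**overrides):
    base = dict(
        feature_noise_sigma=0.0,
        dropout_prob=0.0,
        occlusion_prob=0.0,
        clutter_count=0,
        jitter_px=0.0,
    )
    base.update(overrides)
    return make_scene(**base)


def run_scene(cfg, tracker_cfg=None, apply_filter=True):
    """simulate -> (optionally) filter -> track; returns (result, truth)."""
    from orchardtrack import run_tracker

    frames, feats, truth = simulate_scene(cfg)
    if apply_filter:
        frames, kept = filter_frames(frames)
        feats = [f[i] for f, i in zip(feats, kept)]
    return run_tracker(frames, feats, tracker_cfg), truth


@pytest.fixture
def noiseless_run():
    cfg = noiseless_scene(n_fruits=8, n_frames=120, seed=5)
    result, truth = run_scene(cfg)
    return result, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
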