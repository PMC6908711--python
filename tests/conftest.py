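"""Shared fixtures: one small scene and one reference-waveform set.

Expensive artefacts are session-scoped so the suite generates them once.
"""

import numpy as np
import pytest

from neovitals import (
    SceneConfig,
    generate_reference_waveforms,
    generate_scene,
)
from neovitals.pipeline import collect_frame_features


@pytest.fixture(scope="session")
def small_scene():
    """40 s scene, constant HR 120 / RR 60, fixed seed."""
    cfg = SceneConfig(duration=40.0, hr_schedule=120.0, rr_schedule=60.0, seed=7)
    scene, truth = generate_scene(cfg)
    return cfg, scene, truth


@pytest.fixture(scope="session")
def small_features(small_scene):
    cfg, scene, truth = small_scene
    frames = (scene.frame(i) for i in range(len(scene)))
    return collect_frame_features(frames, truth.skin_masks, cfg.frame_rate)


@pytest.fixture(scope="session")
def ref_waveforms():
    """60 s clean monitor waveforms, HR 150 / RR 50, fixed seed."""
    return generate_reference_waveforms(150.0, 50.0, duration=60.0, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
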