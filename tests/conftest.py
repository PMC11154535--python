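"""Shared fixtures: small ground-truthed scenes reused across test modules.

Scenes are generated programmatically (no stored fixtures); sizes are kept
small so the whole suite runs on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from cagewatch.pipeline import extract_features
from cagewatch.synthetic import SceneConfig, SyntheticScene, profile_from_scene


def make_cfg(**kw) -> SceneConfig:
    """Small-scene config with test-friendly defaults."""
    base = dict(width=320, height=240, semi_major=26, semi_minor=10,
                duration_s=5.0, seed=7)
    base.update(kw)
    return SceneConfig(**base)


@pytest.fixture(scope="session")
def routine_scene():
    """A routine (no-stimulus) scene plus its ground truth and profile."""
    cfg = make_cfg(duration_s=8.0)
    scene = SyntheticScene(cfg)
    return scene, scene.ground_truth(), profile_from_scene(cfg)


@pytest.fixture(scope="session")
def routine_run(routine_scene):
    """Full feature extraction over the routine scene (computed once)."""
    scene, gt, profile = routine_scene
    feats, trace, results = extract_features(iter(scene), profile)
    return scene, gt, profile, feats, trace, results
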