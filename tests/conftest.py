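"""Shared fixtures: synthetic scenes and a small trained detector.

Everything is generated programmatically and seeded, so the suite needs no
stored image data.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import trapgrid as tg
from trapgrid.cli import tiny_profile


TINY_SCENE = tg.SceneConfig(image_size=(256, 256), n_dsm=4, n_dsf=4, n_bc=4,
                            fly_area_mean=5700.0 / 16.0, cluster_prob=0.0,
                            seed=0)


def make_scenes(n: int, master_seed: int, cfg: tg.SceneConfig = TINY_SCENE):
    """Render n scenes with per-scene seeds derived from the master seed."""
    child = np.random.SeedSequence(master_seed).generate_state(n) & 0x7FFFFFFF
    out = []
    for i in range(n):
        scene = tg.render_scene(replace(cfg, seed=int(child[i])))
        scene.annotation.image_id = f"s{master_seed}_{i}"
        out.append(scene)
    return out


@pytest.fixture(scope="session")
def tiny_scene_cfg():
    return TINY_SCENE


@pytest.fixture(scope="session")
def scene_pair():
    """Two deterministic scenes for light-weight tests."""
    return make_scenes(2, master_seed=11)


@pytest.fixture(scope="session")
def trained_tiny():
    """A small detector trained briefly on 12 scenes; good enough to place
    most of its probability mass correctly, used by inference-behaviour
    tests that need a non-random model."""
    prof = tiny_profile(seed=5)
    scenes = make_scenes(12, master_seed=5)
    samples = [(s.image, s.annotation) for s in scenes]
    model = tg.build_model(prof.detector, seed=5)
    cfg = replace(prof.train, epochs_phase1=10, epochs_phase2=2,
                  validate_every=6, seed=5)
    model, history = tg.train(model, samples[:10], samples[10:], cfg,
                              match_cfg=prof.match)
    return model, history, prof
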