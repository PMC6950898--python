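"""Shared fixtures: compact geometries and pre-rendered animals.

Unit tests run on a half-resolution variant of the packaged field (same
physical band layout at 1.3 um/px, 512 px) so each render/segment cycle
stays well under a second; the acceptance suite uses the full-size setup.
"""

from __future__ import annotations

import numpy as np
import pytest

from lamplaq import build_geometry, render_channels
from lamplaq.geometry import GeometrySpec
from lamplaq.presets import fig3_effect_config, fig3_geometry


def small_geometry() -> GeometrySpec:
    g = fig3_geometry()
    g.image_size = (512, 512)
    g.pixel_size = 1.3
    return g


@pytest.fixture(scope="session")
def geo_small():
    return small_geometry()


@pytest.fixture(scope="session")
def map_small(geo_small):
    return build_geometry(geo_small)


@pytest.fixture(scope="session")
def effect_small(geo_small):
    return fig3_effect_config(geo_small)


@pytest.fixture(scope="session")
def rendered_control(map_small, effect_small):
    """One control animal at default noise (session-cached)."""
    img, gt = render_channels(map_small, effect_small, "control", 3.0,
                              np.random.SeedSequence(2024))
    return img, gt


@pytest.fixture(scope="session")
def noiseless_control(map_small, effect_small):
    """Same animal with all noise switched off (exact-recovery oracle)."""
    import copy

    cfg = copy.deepcopy(effect_small)
    cfg.noise.read_sigma = 0.0
    cfg.noise.shot_coeff = 0.0
    img, gt = render_channels(map_small, cfg, "control", 3.0,
                              np.random.SeedSequence(2024))
    return img, gt


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0
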