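"""Shared fixtures: small synthetic outlines and a coarse search grid.

Unit tests run on reduced outline resolutions (64-100 points) and a
coarse alignment grid; the axioms and oracles they check hold at any
resolution, and the full-size defaults are exercised where the value
under test depends on them (e.g. the standard 1000-point resampling).
"""

import numpy as np
import pytest

from heterodont import Outline, ToothParams, make_tooth
from heterodont.align import GridSpec


@pytest.fixture(scope="session")
def coarse_grid():
    return GridSpec(rot_steps=3, shift_steps=3, scale_steps=3, refine=False)


@pytest.fixture(scope="session")
def simple_crown():
    """Single smooth cusp, 100 points."""
    return make_tooth(ToothParams(n_major_cusps=1, cusp_height=0.5), 100)


@pytest.fixture(scope="session")
def cusped_crown():
    """Three-cusped crown, 100 points."""
    return make_tooth(ToothParams(n_major_cusps=3, cusp_height=0.4), 100)


@pytest.fixture(scope="session")
def crown_pool():
    """Varied pool of synthetic crowns for property batteries."""
    rng = np.random.default_rng(42)
    pool = []
    for _ in range(12):
        params = ToothParams(
            n_major_cusps=int(rng.integers(1, 5)),
            cusp_height=float(rng.uniform(0.2, 0.9)),
            asymmetry=float(rng.uniform(-0.6, 0.6)),
            elongation=float(rng.uniform(0.6, 1.8)),
        )
        pool.append(make_tooth(params, 64))
    return pool


@pytest.fixture()
def semicircle():
    """Unit semicircular arc on its diameter baseline, 200 points."""
    theta = np.linspace(np.pi, 0.0, 200)
    return Outline(np.column_stack([np.cos(theta), np.sin(theta)]))
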