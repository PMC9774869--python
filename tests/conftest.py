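"""Shared fixtures.

Small fixtures (random stacks, tiny phantoms) keep unit tests fast; the
full-size study sequences used by the acceptance tests are session-scoped so
the expensive forward projections run once.
"""

from __future__ import annotations

import numpy as np
import pytest

from pastsvd.data_io import ArrayGeometry, RFStack
from pastsvd.experiments import study_sequences
from pastsvd.synthetic import (
    MotionSchedule,
    make_sequence,
    make_vessel_phantom,
)


@pytest.fixture
def small_geometry() -> ArrayGeometry:
    return ArrayGeometry(n_elements=16)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def random_stack(small_geometry, rng) -> RFStack:
    """Unstructured random stack: 16 x 40 x 12."""
    return RFStack(
        samples=rng.standard_normal((16, 40, 12)), geometry=small_geometry
    )


@pytest.fixture
def lowrank_stack(small_geometry, rng) -> RFStack:
    """Exactly rank-3 stack (16 x 64 x 24) with well-separated components."""
    m, n, r = 16 * 64, 24, 3
    U, _ = np.linalg.qr(rng.standard_normal((m, r)))
    V, _ = np.linalg.qr(rng.standard_normal((n, r)))
    s = np.array([100.0, 40.0, 15.0])
    samples = ((U * s) @ V.T).reshape(16, 64, n)
    return RFStack(samples=samples, geometry=small_geometry)


@pytest.fixture(scope="session")
def tiny_phantom():
    """12 mm phantom with 3 vessels between 4 and 8 mm depth."""
    return make_vessel_phantom(
        seed=3, n_vessels=3, extent_mm=12.0, depth_extent_mm=(4.0, 8.0)
    )


@pytest.fixture(scope="session")
def tiny_sequence(tiny_phantom):
    """Clean static 8-frame sequence on a 16-element array (n_z = 256)."""
    geometry = ArrayGeometry(n_elements=16)
    return make_sequence(
        tiny_phantom, geometry, MotionSchedule.static(8), n_t=8, n_z=256
    )


@pytest.fixture(scope="session")
def study_pair():
    """Full-size four-motion-state study pair (clean, noisy at -10 dB)."""
    return study_sequences(phantom_seed=0, noise_seed=1)
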