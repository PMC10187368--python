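"""Shared fixtures: simulated speckle images at several scales.

Everything is generated at session start from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from xstrack.wave_optics import DiffuserSpec, ImagingGeometry, simulate_pair


@pytest.fixture(scope="session")
def geometry() -> ImagingGeometry:
    return ImagingGeometry()


@pytest.fixture(scope="session")
def speckle_128(geometry) -> "SpeckleImage":
    """One simulated 128 x 128 reference speckle image at the default config."""
    ref, _, _ = simulate_pair(
        geometry, DiffuserSpec(seed=101), detector_shape=(128, 128)
    )
    return ref


@pytest.fixture(scope="session")
def speckle_pair_128(geometry):
    """Three independent 128 x 128 references for sweep-style tests."""
    refs = []
    for s in (201, 202, 203):
        ref, _, _ = simulate_pair(geometry, DiffuserSpec(seed=s), detector_shape=(128, 128))
        refs.append(ref)
    return refs


@pytest.fixture(scope="session")
def references_256(geometry):
    """The ten 256 x 256 validation references of the headline protocol."""
    refs = []
    for s in range(10):
        ref, _, _ = simulate_pair(
            geometry, DiffuserSpec(seed=1000 + s), detector_shape=(256, 256)
        )
        refs.append(ref)
    return refs


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
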