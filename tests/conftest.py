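"""Shared small-scale fixtures.

Everything here is deliberately tiny (matrix 24-32, tens of frames) so the
whole suite stays fast; the scaled validation conditions live in
tests/test_acceptance.py.
"""

import numpy as np
import pytest

from radialdce import (
    EncodingSeries,
    PhantomGeometry,
    ScanProtocol,
    build_phantom,
    default_lesions,
    golden_angle_trajectory,
    population_aif,
    sample_kspace,
    simulate_coil_maps,
)


@pytest.fixture(scope="session")
def protocol():
    # 32 pixels at 1.5 mm, 32 frames of 5 s, bolus at 40 s
    return ScanProtocol(matrix=32, n_frames=32, fov=48.0)


@pytest.fixture(scope="session")
def aif(protocol):
    return population_aif(protocol, bolus_arrival=40.0)


@pytest.fixture(scope="session")
def phantom(protocol, aif):
    geom = PhantomGeometry(matrix=32)
    return build_phantom(geom, default_lesions((0.3,)), protocol, aif)


@pytest.fixture(scope="session")
def coils(phantom):
    return simulate_coil_maps(2, phantom.matrix, seed=1,
                              support=phantom.support)


@pytest.fixture(scope="session")
def trajectory(protocol):
    return golden_angle_trajectory(8 * protocol.n_frames,
                                   2 * protocol.matrix, 8)


@pytest.fixture(scope="session")
def encoding(coils, trajectory):
    return EncodingSeries(coils, trajectory)


@pytest.fixture(scope="session")
def kspace(phantom, coils, trajectory, encoding):
    return sample_kspace(phantom, coils, trajectory, encoding)
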