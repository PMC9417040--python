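"""Shared fixtures.

All studies are generated at runtime (the phantom is deterministic given a
seed); session scope keeps the expensive simulations to one instance each.
"""

import numpy as np
import pytest

from cinesort import phantom

#: Small, fast acquisition used by most behavioural tests.
SMALL_CONFIG = phantom.AcquisitionConfig(
    n_couch=3, m_per_couch=5, slices_per_block=4, pixel_grid=(32, 32)
)


@pytest.fixture(scope="session")
def bh_study():
    """Default motion-free breath-hold study (full size)."""
    return phantom.simulate_bh_scan()


@pytest.fixture(scope="session")
def small_bh_study():
    return phantom.simulate_bh_scan(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_cine_study():
    """A small irregular-breathing cine study, seed 1."""
    params = phantom.BreathingParams(seed=1)
    return phantom.simulate_cine_scan(params, SMALL_CONFIG)


@pytest.fixture(scope="session")
def cine_study():
    """Default-geometry cine study, seed 1."""
    params = phantom.BreathingParams(seed=1)
    return phantom.simulate_cine_scan(params, phantom.AcquisitionConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
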