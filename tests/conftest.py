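import numpy as np
import pytest
from hypothesis import settings

import hyperscat as hs

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sphere_model():
    """Polydisperse sphere, R = 3 nm, sigma = 0.08."""
    return hs.precompute(
        hs.ShapeSpec("sphere", (3.0,)), [hs.SizeDistribution(3.0, 0.08)]
    )


@pytest.fixture(scope="session")
def cylinder_model():
    """Polydisperse cylinder R = 2 nm, L = 16 nm, sigma = 0.1 per dimension."""
    return hs.precompute(
        hs.ShapeSpec("cylinder", (2.0, 16.0)),
        [hs.SizeDistribution(2.0, 0.1), hs.SizeDistribution(8.0, 0.1)],
    )


@pytest.fixture(scope="session")
def mono_sphere_model():
    return hs.precompute(
        hs.ShapeSpec("sphere", (3.0,)), [hs.SizeDistribution(3.0, 0.0)]
    )


@pytest.fixture(scope="session")
def fcc_cell():
    return hs.UnitCell.cubic(35.0, "FCC", (0, 0, 1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20230115)
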