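import numpy as np
import pytest

import ionpath as ip


@pytest.fixture(scope="session")
def default_system():
    """Canonical 8-site, 3-ion toy filter."""
    return ip.build_toy_system()


@pytest.fixture(scope="session")
def two_ion_system():
    """Small, low-barrier 2-ion system that equilibrates quickly."""
    return ip.build_toy_system(
        n_sites=4, site_spacing=3.1, n_ions=2, well_depths=1.0, barrier_heights=0.8
    )


@pytest.fixture(scope="session")
def double_well():
    return ip.DoubleWell(barrier=3.0)


@pytest.fixture(scope="session")
def reference_path(default_system):
    return ip.generate_reference_path(default_system)


@pytest.fixture(scope="session")
def filter_fixture():
    return ip.build_filter_fixture()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20121102)
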