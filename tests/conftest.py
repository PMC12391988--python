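import numpy as np
import pytest

import geldiff as g


@pytest.fixture(scope="session")
def medium():
    """Experiment medium: 307 K water."""
    return g.MediumSpec()


@pytest.fixture(scope="session")
def thin_fiber_network():
    """R_f = 1 nm collagen network at the measured volume fraction 0.016."""
    return g.GelNetwork.from_fiber_and_phi(1.0, 0.016)


@pytest.fixture(scope="session")
def thick_fiber_network():
    """R_f = 10 nm variant; mesh radius ≈ 140 nm."""
    return g.GelNetwork.from_fiber_and_phi(10.0, 0.016)


@pytest.fixture(scope="session")
def study_release_params():
    """Release-model truth used throughout: D = 2.5 μm²/s, f_mob = 0.36, l = 1.26 mm."""
    return g.ReleaseModelParams(d_um2_s=2.5, f_mob=0.36, thickness_mm=1.26)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
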