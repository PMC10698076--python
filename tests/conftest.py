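import numpy as np
import pytest

from ctpcal.phantom import PhantomConfig, build_phantom, make_arterial_tdc


@pytest.fixture(scope="session")
def aif():
    return make_arterial_tdc()


@pytest.fixture(scope="session")
def tiny_phantom():
    """One-combo phantom with plenty of realizations (noise statistics)."""
    cfg = PhantomConfig(
        t0_grid=(2.0,), mtt_grid=(8.0,), cbv_grid=(2.0,), n_real=1024
    )
    return build_phantom(cfg, seed=11)


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced-grid phantom for engine/calibration plumbing tests."""
    cfg = PhantomConfig(
        t0_grid=(0.0, 2.0),
        mtt_grid=(4.0, 8.0),
        cbv_grid=(1.0, 3.0),
        n_real=8,
    )
    return build_phantom(cfg, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
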