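import numpy as np
import pytest

from phaselock.periphery import FiberType, PeripheryConfig, make_cf_axis


@pytest.fixture(scope="session")
def small_periphery():
    """A reduced periphery (10 CFs) for fast pipeline tests."""
    return PeripheryConfig(
        cf_axis=make_cf_axis(10, 125.0, 8000.0),
        ihc_cutoff=3000.0,
        total_fibers=6400,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
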