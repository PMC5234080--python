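import numpy as np
import pytest

from photogate import GateBeam, SimConfig, photogate_config, toccsl_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_photogate():
    """Desk-scale gated experiment: 12 um cell, 3 um ROI, 4 s."""
    return photogate_config(
        cell_size=12.0,
        density=5.0,
        D=0.1,
        duration=4.0,
        roi_radius=3.0,
        gate_frequency=1.0,
        dark_delay=0.5,
        seed=7,
    )


@pytest.fixture
def small_toccsl():
    return toccsl_config(
        cell_size=12.0, density=5.0, D=0.1, duration=4.0, roi_radius=3.0, seed=7
    )
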