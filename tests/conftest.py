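import numpy as np
import pytest

from truspa import array_geometry, lens_optics, pa_simulation


@pytest.fixture(scope="session")
def default_lens():
    return lens_optics.LensDesign()


@pytest.fixture(scope="session")
def default_trace(default_lens):
    return lens_optics.trace_lateral(default_lens, 1001)


@pytest.fixture(scope="session")
def default_array():
    return array_geometry.build_convex_array()


@pytest.fixture(scope="session")
def acq_config():
    return pa_simulation.AcquisitionConfig()


@pytest.fixture(scope="session")
def default_pulse(acq_config):
    return array_geometry.synthesize_pulse(
        sampling_rate_mhz=acq_config.sampling_rate_mhz
    )


@pytest.fixture(scope="session")
def wire_phantom():
    return pa_simulation.make_wire_phantom()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260918)
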