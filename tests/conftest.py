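import numpy as np
import pytest

from dscmicro.protocol import AcquisitionProtocol
from dscmicro.synthgen import PhantomSpec, make_phantom, make_aif


@pytest.fixture(scope="session")
def protocol():
    """3 T dual-echo protocol: 80 dynamics at TR 1.5 s, TE 40/96 ms."""
    return AcquisitionProtocol(tr=1.5, te_gre=0.040, te_se=0.096,
                               n_dynamics=80, baseline_frames=10)


@pytest.fixture(scope="session")
def aif(protocol):
    return make_aif(3.5, 15.0, 3.0, 0.8, protocol)


@pytest.fixture(scope="session")
def small_phantom_noiseless():
    """Compact noiseless phantom with all five tissue classes."""
    spec = PhantomSpec(shape=(12, 12, 1), lesion_radius=2.5,
                       snr=np.inf, seed=7)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom_noisy():
    spec = PhantomSpec(shape=(12, 12, 1), lesion_radius=2.5,
                       snr=100.0, seed=11)
    return make_phantom(spec)
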