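import numpy as np
import pytest

from darksense import (REFERENCE_FLUOR, REFERENCE_SCHEME, ApplicationProtocol,
                       SamplingConfig, compute_dff, simulate_patch_sweeps)
from darksense.synth import NoiseModel

NOISELESS = NoiseModel(gaussian_sd_frac=0.0)


@pytest.fixture(scope="session")
def reference_scheme():
    return REFERENCE_SCHEME


@pytest.fixture(scope="session")
def reference_fluor():
    return REFERENCE_FLUOR


@pytest.fixture(scope="session")
def reference_on_off_dff():
    """Noise-free dF/F sweep at 100 uM, 91 Hz: 1 s application + washout."""
    protocol = ApplicationProtocol(concentration=1e-4, pre_s=0.5, app_s=1.0,
                                   post_s=3.0, n_sweeps=1)
    sweep = simulate_patch_sweeps(REFERENCE_SCHEME, REFERENCE_FLUOR, protocol,
                                  SamplingConfig(rate_hz=91.0),
                                  NOISELESS)[0]
    return compute_dff(sweep, (0.0, 0.49))


def make_flat_trace(n=200, rate_hz=91.0, value=0.0):
    from darksense import Trace
    t = np.arange(n) / rate_hz
    return Trace(time_s=t, value=np.full(n, float(value)), rate_hz=rate_hz)
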