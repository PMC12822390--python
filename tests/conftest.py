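import warnings

import numpy as np
import pytest

from brisma.io import Spectrum
from brisma.synthetic import PRESETS, make_reference_set


@pytest.fixture(autouse=True)
def _quiet_model_warnings():
    """Model-diagnostic warnings (clamps, degeneracies) are asserted
    explicitly where relevant; keep the rest out of the test log."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def control_preset():
    return PRESETS["control"]


@pytest.fixture(scope="session")
def control_refs_clean(control_preset):
    """Noiseless reference set matched to the control preset."""
    return make_reference_set(0, preset=control_preset, noise_snr=None)


def two_sided_dho(omega=7.70, gamma=1.0, amplitude=10.0, background=0.0, n=2001, span=15.0):
    """Noiseless symmetric two-sided DHO trace (test helper)."""
    from brisma.brillouin import dho_lineshape

    nu = np.linspace(-span, span, n)
    return Spectrum("brillouin", nu, dho_lineshape(nu, omega, gamma, amplitude, background))
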