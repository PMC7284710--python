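import numpy as np
import pytest
from hypothesis import settings

from dielstab.hn import HNFit

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def freq_grid():
    """10⁻¹–10⁶ Hz at 20 points/decade (the instrument's span)."""
    return np.logspace(-1, 6, 141)


@pytest.fixture
def hn_truth():
    """A typical supercooled-liquid α-relaxation parameter set."""
    return HNFit(delta_eps=5.0, tau_hn=1e-3, a=0.8, b=0.6, eps_inf=3.0,
                 sigma_dc=1e-12)
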