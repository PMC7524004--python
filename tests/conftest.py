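import numpy as np
import pytest

from swdnet import NetworkLayout, CouplingMatrix
from swdnet.layout import Population, Region


@pytest.fixture
def tiny_layout():
    """Three focal PY nodes — smallest layout for integrator checks."""
    return NetworkLayout({(Population.PY, Region.FOCAL): 3})


def make_matrix(C, tau_steps=10, layout=None, pops=None):
    """Build a CouplingMatrix around a raw array for hand-wired test networks."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if layout is None:
        layout = NetworkLayout({(Population.PY, Region.FOCAL): n})
    return CouplingMatrix(C, tau_steps, layout)
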