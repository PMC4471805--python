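import numpy as np
import pytest

from oligomass.cdtherm import MeltingFit, Transition
from oligomass.equilibrium import monomer_trimer, dimer_tetramer_hexamer


@pytest.fixture
def cc_scheme():
    """Monomer↔trimer coiled-coil scheme, 12.5 kDa protomer, midpoint Kd 3 μM."""
    return monomer_trimer(12.5, 6.75)


@pytest.fixture
def hexamer_scheme():
    """Obligate dimer → tetramer → hexamer scheme (46+16 kDa tagged protomer)."""
    return dimer_tetramer_hexamer(46.0, 16.0, 3.0, 3.0)


@pytest.fixture
def temp_grid():
    """Thermal ramp grid: 4–90 °C in 1 °C steps."""
    return np.arange(4.0, 91.0)


def melt_params(*tms, dh=250.0):
    """Two-state melting parameters with realistic θ222 baselines."""
    n = len(tms)
    return MeltingFit(
        tuple(Transition(tm, dh, 1.0 / n) for tm in sorted(tms)),
        baseline_folded=(-20000.0, 25.0),
        baseline_unfolded=(-3000.0, -5.0),
    )


@pytest.fixture
def single_melt_params():
    return melt_params(37.0, dh=200.0)


@pytest.fixture
def double_melt_params():
    return melt_params(50.0, 70.0, dh=250.0)
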