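import numpy as np
import pytest

from dscthermo import (
    EquilibriumTwoStateParams,
    StatTwoStateParams,
    Thermogram,
    ZimmBraggParams,
)
from dscthermo.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def lysozyme_eq_params():
    """Published-style chemical-equilibrium fit parameters for lysozyme."""
    return EquilibriumTwoStateParams(dH0=107.0, t_m=335.0, cp_step=2.27)


@pytest.fixture(scope="session")
def lysozyme_stat_params():
    """Statistical two-state fit parameters for lysozyme heat unfolding."""
    return StatTwoStateParams(dE0=110.0, t_m=335.0, cv=1.05)


@pytest.fixture(scope="session")
def lysozyme_zb_params():
    """Zimm-Bragg parameters for lysozyme (129 residues)."""
    return ZimmBraggParams(h0=0.91, cv_res=0.007, sigma=5e-7, n_res=129, t_m=335.0)


@pytest.fixture(scope="session")
def lysozyme_trace(lysozyme_stat_params):
    """Noise-free synthetic lysozyme heating scan with its ground truth."""
    spec = SyntheticSpec(
        model_name="stat_two_state",
        params=lysozyme_stat_params,
        t_start=300.0,
        t_stop=360.0,
        noise_sd=0.0,
    )
    return generate(spec)


@pytest.fixture
def flat_thermogram():
    t = np.linspace(300.0, 320.0, 101)
    return Thermogram(temperature=t, cp=np.zeros_like(t))
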