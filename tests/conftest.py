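import math

import numpy as np
import pytest

from electrodyne import CPEParams, ExcursionModel, InterfaceCircuit


@pytest.fixture
def truth_circuit() -> InterfaceCircuit:
    """Randles-like ground-truth circuit whose branches are all visible
    in the 0.1 Hz - 100 kHz band (faradaic at low f, double layer at mid,
    series resistance at high f)."""
    return InterfaceCircuit(
        c_dl=CPEParams(q_coeff=1e-7, n_exp=0.9),
        r_ct=1e6,
        c_f=CPEParams(q_coeff=1e-6, n_exp=0.8),
        r_spread=1000.0,
        r_bulk=100.0,
        label="truth",
    )


@pytest.fixture
def init_circuit() -> InterfaceCircuit:
    """Initial guess: truth perturbed by a factor of 2 on every element."""
    return InterfaceCircuit(
        c_dl=CPEParams(q_coeff=2e-7, n_exp=0.8),
        r_ct=2e6,
        c_f=CPEParams(q_coeff=2e-6, n_exp=0.7),
        r_spread=2000.0,
        r_bulk=100.0,
    )


@pytest.fixture
def pure_cpe_circuit() -> InterfaceCircuit:
    """Single CPE with no resistive elements: has the closed-form step
    response V(t) = I*t^n/(Q*Gamma(1+n))."""
    return InterfaceCircuit(
        c_dl=CPEParams(q_coeff=1e-7, n_exp=0.8),
        r_ct=math.inf,
        c_f=None,
        r_spread=0.0,
        r_bulk=0.0,
    )


@pytest.fixture
def truth_excursion_model() -> ExcursionModel:
    """Excursion-law ground truth in (uA, us, kohm) units; gives
    physiological excursions of ~0.1-1.8 V over the factorial test grid."""
    return ExcursionModel(a_scale=0.3, b_coeff=0.002, k2_exp=0.9, k4_exp=0.4, k6_exp=0.7)


@pytest.fixture
def excursion_grids() -> tuple[np.ndarray, np.ndarray, list[float]]:
    """5 x 4 x 3 factorial sweep: a decade+ in current and pulse width."""
    i_grid = np.logspace(1, 3, 5)  # 10..1000 uA
    t_grid = np.logspace(math.log10(50), 3, 4)  # 50..1000 us
    z_values = [10.0, 30.0, 100.0]  # kohm
    return i_grid, t_grid, z_values
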