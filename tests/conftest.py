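import numpy as np
import pytest

from gelcraft.core_model import BeadSpec, ForceField
from gelcraft.io import make_fixture


@pytest.fixture
def bead():
    return BeadSpec()


@pytest.fixture
def forcefield():
    """Published default force field: k_b^n = 1.18479 N/m, l_eq = 0.4615 nm,
    k_b^alpha = 1.15375e-19 N·m/rad, eps = 30 kJ/mol, d_eq = 0.4 nm,
    cutoff = 1.5 nm."""
    return ForceField.from_si(
        bond_stiffness_n_m=1.18479, bond_length_nm=0.4615,
        bending_stiffness_n_m_rad=1.15375e-19, epsilon_kj_mol=30.0,
        d_eq_nm=0.4, cutoff_nm=1.5, d_int_nm=1.5)


@pytest.fixture
def parallel_pair():
    return make_fixture("parallel_pair")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
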