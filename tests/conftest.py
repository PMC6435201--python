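import pytest

from chargediff import BathState, CellState, MembraneParams


@pytest.fixture
def std_bath() -> BathState:
    """Standard physiological bath: 145 Na+, 5 K+, 150 Cl- (mM)."""
    return BathState(Na_o=145.0, K_o=5.0, Cl_o=150.0)


@pytest.fixture
def symmetric_nacl():
    """The symmetric passive NaCl cell: equal Na+ inside/outside, tenfold
    Cl- gradient balanced by 135 mM monovalent impermeant anion, Em = 0."""
    cell = CellState(Na_i=150.0, K_i=0.0, Cl_i=15.0, An_i=135.0, Em=0.0)
    bath = BathState(Na_o=150.0, K_o=0.0, Cl_o=150.0)
    params = MembraneParams(tau=1e9)
    return cell, bath, params
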