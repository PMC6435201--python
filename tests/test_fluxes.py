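"""Flux laws: Nernst/conductive, pump saturation, cotransporter driving."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from chargediff import (
    BathState,
    CellState,
    MembraneParams,
    conductive_fluxes,
    kcc_fluxes,
    nernst_potential,
    nkcc_fluxes,
    pump_activity,
    pump_fluxes,
)

T_BODY = 309.85


class TestNernst:
    @pytest.mark.parametrize(
        "c_out, c_in, valence, expected_mV",
        [
            (150.0, 15.0, +1, 61.48),   # tenfold inward cation gradient
            (150.0, 15.0, -1, -61.48),  # same gradient seen by an anion
            (100.0, 100.0, +1, 0.0),
        ],
    )
    def test_examples(self, c_out, c_in, valence, expected_mV):
        assert nernst_potential(c_out, c_in, valence, T_BODY) * 1e3 == pytest.approx(
            expected_mV, abs=0.005
        )

    @pytest.mark.parametrize("c_out, c_in", [(0.0, 10.0), (10.0, 0.0), (-5.0, 5.0)])
    def test_domain_errors(self, c_out, c_in):
        with pytest.raises(ValueError):
            nernst_potential(c_out, c_in, 1, T_BODY)


class TestConductive:
    def test_zero_at_equilibrium(self, std_bath):
        cell = CellState(Na_i=14.5, K_i=100.0, Cl_i=30.0, An_i=84.5)
        cell.Em = nernst_potential(std_bath.Na_o, cell.Na_i, 1, T_BODY)
        params = MembraneParams(gNa=1e10, gK=0.0, gCl=0.0)
        na, k, cl = conductive_fluxes(cell, std_bath, params)
        assert na == pytest.approx(0.0, abs=1e-6)

    def test_chloride_opening_flux(self):
        """Tenfold Cl- gradient at Em = 0 through gCl = 1e10 carries the
        decade potential's worth of driving force: 6.148e8 ions/s inward."""
        cell = CellState(Na_i=150.0, K_i=0.0, Cl_i=15.0, An_i=135.0, Em=0.0)
        bath = BathState(Na_o=150.0, K_o=0.0, Cl_o=150.0)
        params = MembraneParams(gCl=1e10)
        _, _, cl = conductive_fluxes(cell, bath, params)
        assert cl == pytest.approx(6.148e8, rel=1e-3)
        assert cl > 0  # inward

    def test_closed_channel_carries_nothing(self, std_bath):
        cell = CellState(Na_i=1e-6, K_i=100.0, Cl_i=30.0, An_i=70.0, Em=-0.5)
        params = MembraneParams(gNa=0.0)
        na, _, _ = conductive_fluxes(cell, std_bath, params)
        assert na == 0.0

    def test_chloride_sign_convention(self, std_bath):
        """Depolarisation drives Cl- in; hyperpolarisation drives it out."""
        cell = CellState(Na_i=10.0, K_i=140.0, Cl_i=30.0, An_i=120.0)
        cell.Em = -nernst_potential(std_bath.Cl_o, cell.Cl_i, 1, T_BODY)  # E_Cl
        params = MembraneParams(gCl=1e10)
        assert conductive_fluxes(cell, std_bath, params)[2] == pytest.approx(0, abs=1e-6)
        cell.Em += 0.01
        assert conductive_fluxes(cell, std_bath, params)[2] > 0
        cell.Em -= 0.02
        assert conductive_fluxes(cell, std_bath, params)[2] < 0


class TestPump:
    def test_half_occupation_constant(self):
        """At Na_i = hNa the third-order binding gives Ap = Rp/8."""
        assert pump_activity(8.0, 1.6e9, 8.0) == pytest.approx(2e8, rel=1e-12)

    def test_high_sodium_activity(self):
        """Freshly switched on against 145 mM Na_i, a 24e9/s pump runs at
        about 20.4e9 cycles/s."""
        assert pump_activity(145.0, 2.4e10, 8.0) == pytest.approx(2.04e10, rel=1e-2)

    def test_zero_sodium_limit(self):
        assert pump_activity(0.0, 2.4e10, 8.0) == 0.0

    @given(na=st.floats(0.0, 500.0), rp=st.floats(0.0, 1e12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_by_rate(self, na, rp):
        ap = pump_activity(na, rp, 8.0)
        assert 0.0 <= ap <= rp

    @given(na=st.floats(1e-3, 500.0), dna=st.floats(1e-3, 100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_sodium(self, na, dna):
        assert pump_activity(na + dna, 1e10, 8.0) > pump_activity(na, 1e10, 8.0)

    @pytest.mark.parametrize(
        "ap, x, y, expected",
        [(1e6, 3, 2, (-3e6, 2e6)), (1e6, 3, 0, (-3e6, 0.0)), (0.0, 3, 2, (0.0, 0.0))],
    )
    def test_stoichiometric_fluxes(self, ap, x, y, expected):
        assert pump_fluxes(ap, x, y) == expected


class TestCotransporters:
    def test_nkcc_zero_at_symmetry(self):
        cell = CellState(Na_i=145.0, K_i=5.0, Cl_i=150.0, An_i=0.0)
        bath = BathState(Na_o=145.0, K_o=5.0, Cl_o=150.0)
        assert nkcc_fluxes(cell, bath, 1e8)[0] == 0.0

    def test_nkcc_exhausted_at_limit(self, std_bath):
        """At Cl_i = 83.06 mM (the published NKCC ceiling for this state)
        the concentration-product driving force vanishes."""
        cell = CellState(Na_i=17.9, K_i=132.1, Cl_i=83.06, An_i=66.94)
        a, *_ = nkcc_fluxes(cell, std_bath, 1e8)
        assert abs(a) / 1e8 < 1e-4

    def test_nkcc_driving_force(self, std_bath):
        """Resting-state driving force, frozen from the log-ratio of the
        concentration products: Ankc = 0.89618 * Rnkc at Cl_i = 29.6."""
        cell = CellState(Na_i=17.9, K_i=132.1, Cl_i=29.6, An_i=120.4)
        a, na, k, cl = nkcc_fluxes(cell, std_bath, 2e7)
        assert a == pytest.approx(0.89618 * 2e7, rel=1e-4)
        assert (na, k, cl) == (a, a, 2 * a)

    def test_kcc_zero_at_product_equality(self):
        cell = CellState(Na_i=10.0, K_i=50.0, Cl_i=15.0, An_i=45.0)
        bath = BathState(Na_o=145.0, K_o=5.0, Cl_o=150.0)
        assert kcc_fluxes(cell, bath, 1e8)[0] == 0.0

    def test_kcc_exhausted_at_floor(self, std_bath):
        """Cl_i = 5.68 mM is the KCC floor for K_i = 132.1: zero driving."""
        cell = CellState(Na_i=17.9, K_i=132.1, Cl_i=5.68, An_i=144.32)
        a, *_ = kcc_fluxes(cell, std_bath, 1e8)
        assert abs(a) / 1e8 < 1e-3

    def test_kcc_driving_force(self, std_bath):
        """Akc = -0.71713 * Rkc at the resting state (KCl extrusion)."""
        cell = CellState(Na_i=17.9, K_i=132.1, Cl_i=29.6, An_i=120.4)
        a, k, cl = kcc_fluxes(cell, std_bath, 3e6)
        assert a == pytest.approx(-0.71713 * 3e6, rel=1e-4)
        assert k == cl == a

    @given(rate=st.floats(1e3, 1e12), scale=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linearity_in_rate(self, rate, scale):
        bath = BathState(Na_o=145.0, K_o=5.0, Cl_o=150.0)
        cell = CellState(Na_i=17.9, K_i=132.1, Cl_i=29.6, An_i=120.4)
        a1 = nkcc_fluxes(cell, bath, rate)[0]
        a2 = nkcc_fluxes(cell, bath, rate * scale)[0]
        assert a2 == pytest.approx(a1 * scale, rel=1e-12)
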