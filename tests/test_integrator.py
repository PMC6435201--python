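"""The discrete stepper: accumulation, Em update, volume relaxation,
whole-step composition and the two integration drivers."""

import math

import numpy as np
import pytest

from chargediff import (
    CONSTANTS,
    BathState,
    Buildup,
    BuildupSchedule,
    CellState,
    FluxSet,
    MembraneParams,
    OsmoticCollapseError,
    SimSettings,
    accumulate,
    get_scenario,
    relax_volume,
    run,
    run_scenario,
    run_to_steady_state,
    step,
    update_Em,
)

NO_BUILDUPS = BuildupSchedule()


class TestAccumulate:
    def test_nothing_in_nothing_out(self, symmetric_nacl):
        cell, bath, _ = symmetric_nacl
        new, new_bath, d = accumulate(cell, bath, FluxSet(), NO_BUILDUPS, 1e-3)
        assert (new.Na_i, new.Cl_i, new.An_i) == (cell.Na_i, cell.Cl_i, cell.An_i)
        assert new_bath.Na_o == bath.Na_o
        assert d.dQ == 0.0

    def test_cation_influx_charge_and_concentration(self, symmetric_nacl):
        """6e6 uncompensated cations carry 9.6e-13 C and amount to 13.3 uM
        in the 0.75 pL reference cell."""
        cell, bath, _ = symmetric_nacl
        fx = FluxSet(NaFc=6e6)
        new, _, d = accumulate(cell, bath, fx, NO_BUILDUPS, 1.0)
        assert d.dQ == pytest.approx(9.6e-13, rel=1e-12)
        assert new.Na_i - cell.Na_i == pytest.approx(0.013289, rel=1e-4)

    def test_anion_buildup_brings_sodium(self, symmetric_nacl):
        """bAn = 0.02 mM/s at z = -1.5 adds Na+ at 0.03 mM/s and never
        touches the membrane charge."""
        cell, bath, _ = symmetric_nacl
        bu = BuildupSchedule(bAn=Buildup(0.02, 0.0, 10.0))
        new, _, d = accumulate(cell, bath, FluxSet(), bu, 1.0, z=-1.5)
        assert new.An_i - cell.An_i == pytest.approx(0.02)
        assert new.Na_i - cell.Na_i == pytest.approx(0.03)
        assert d.dQ == 0.0

    def test_nacl_buildup_touches_bath_only(self, symmetric_nacl):
        cell, bath, _ = symmetric_nacl
        bu = BuildupSchedule(bNaCl=Buildup(0.25, 0.0, 60.0))
        new, new_bath, _ = accumulate(cell, bath, FluxSet(), bu, 1.0)
        assert new_bath.Na_o - bath.Na_o == pytest.approx(0.25)
        assert new_bath.Cl_o - bath.Cl_o == pytest.approx(0.25)
        assert new.Na_i == cell.Na_i

    def test_buildup_window_respected(self, symmetric_nacl):
        cell, bath, _ = symmetric_nacl
        bu = BuildupSchedule(bOsi=Buildup(0.05, 5.0, 10.0))
        cell.t = 2.0  # outside the window
        new, _, _ = accumulate(cell, bath, FluxSet(), bu, 1.0)
        assert new.osm_i == cell.osm_i


class TestEmUpdate:
    @pytest.mark.parametrize(
        "em, dq, expected_mV",
        [(0.0, -9.6e-13, -80.0), (0.0, 0.0, 0.0), (0.0, 1.2e-13, 10.0)],
    )
    def test_examples(self, em, dq, expected_mV):
        assert update_Em(em, dq, 1.2e-11) * 1e3 == pytest.approx(expected_mV)

    def test_bad_capacitance(self):
        with pytest.raises(ValueError):
            update_Em(0.0, 1e-13, 0.0)


class TestRelaxVolume:
    def test_osmotic_balance_is_fixed_point(self, std_bath):
        cell = CellState(Na_i=145.0, K_i=5.0, Cl_i=30.0, An_i=120.0)
        new, d = relax_volume(cell, std_bath, tau=1.0, st=1e-3)
        assert d.osV == pytest.approx(1.0)
        assert d.chV == pytest.approx(1.0)
        assert new.vol == cell.vol

    def test_instant_water_equalises_osmolarity(self, std_bath):
        """With tau <= st the full osmotic correction is applied in one
        step and internal osmolarity lands exactly on the bath's."""
        cell = CellState(Na_i=231.8, K_i=0.0, Cl_i=96.8, An_i=135.0)
        bath = BathState(Na_o=150.0, K_o=0.0, Cl_o=150.0)
        new, d = relax_volume(cell, bath, tau=0.0, st=1e-3)
        assert d.chV == pytest.approx(463.6 / 300.0, rel=1e-12)
        assert new.osmolarity == pytest.approx(bath.osmolarity, rel=1e-12)

    def test_water_tight_membrane_freezes_volume(self):
        cell = CellState(Na_i=231.8, K_i=0.0, Cl_i=96.8, An_i=135.0)
        bath = BathState(Na_o=150.0, K_o=0.0, Cl_o=150.0)
        new, d = relax_volume(cell, bath, tau=1e9, st=1e-3)
        assert d.VoR == 0.0 and new.vol == cell.vol

    def test_collapse_raises(self):
        """An osmotically empty cell under instant water is annihilated in
        one step (chV = 0): reported as a fatal error, not silently."""
        cell = CellState(Na_i=0.0, K_i=0.0, Cl_i=0.0, An_i=0.0)
        bath = BathState(Na_o=150.0, K_o=0.0, Cl_o=150.0)
        with pytest.raises(OsmoticCollapseError):
            relax_volume(cell, bath, tau=0.0, st=1.0)


class TestStepComposition:
    def test_equilibrium_is_fixed_point(self):
        """A passive symmetric state with every flux zero does not move."""
        cell = CellState(Na_i=150.0, K_i=0.0, Cl_i=150.0, An_i=0.0, Em=0.0)
        bath = BathState(Na_o=150.0, K_o=0.0, Cl_o=150.0)
        params = MembraneParams(gNa=1e10, gCl=1e10, tau=1.0)
        new, _, _ = step(cell, bath, params, NO_BUILDUPS, 1e-3)
        assert new.Na_i == cell.Na_i and new.Cl_i == cell.Cl_i
        assert new.Em == cell.Em and new.vol == cell.vol

    def test_chloride_leads_the_hyperpolarisation(self, symmetric_nacl):
        """First step of the conductance opening: Cl- influx outruns Na+
        and drives Em negative."""
        cell, bath, params = symmetric_nacl
        params.gNa = params.gCl = 1e10
        new, _, d = step(cell, bath, params, NO_BUILDUPS, 1e-4)
        assert d.dCl > 0 and d.dNa == 0  # Na+ starts at equilibrium
        assert new.Em < 0
        # once hyperpolarised, Na+ is pulled in behind the Cl-
        new2, _, d2 = step(new, bath, params, NO_BUILDUPS, 1e-4)
        assert d2.dNa > 0
        assert new2.Em < new.Em

    def test_kernel_matches_pure_python_step(self):
        """The compiled inner loop and the dataclass step are the same map,
        bit for bit, over hundreds of steps with buildups active."""
        sc = get_scenario("gna_step")
        bu = BuildupSchedule(bOsi=Buildup(0.05, 0.0, 10.0))
        s_py, b_py = sc.cell.copy(), sc.bath.copy()
        for _ in range(300):
            s_py, b_py, _ = step(s_py, b_py, sc.params, bu, 1e-3)
        traj = run(sc.cell.copy(), sc.bath.copy(), sc.params, bu,
                   SimSettings(st=1e-3, t_end=0.3))
        s_k = traj.final_state
        for attr in ("Na_i", "K_i", "Cl_i", "An_i", "osm_i", "Em", "vol"):
            assert getattr(s_py, attr) == getattr(s_k, attr)

    def test_rejection_halves_the_step(self, std_bath):
        """A step that would drive Cl_i negative is retried in halves
        instead of failing."""
        cell = CellState(Na_i=145.0, K_i=5.0, Cl_i=1e-4, An_i=150.0, Em=-0.5)
        params = MembraneParams(gCl=1e10, tau=1e9)
        new, _, _ = step(cell, std_bath, params, NO_BUILDUPS, 1e-2)
        assert new.Cl_i > 0


class TestRunInvariants:
    def test_charge_voltage_ledger(self, symmetric_nacl):
        """Em drift equals the cumulative transferred charge over c."""
        cell, bath, params = symmetric_nacl
        params.gNa = params.gCl = 1e10
        traj = run(cell, bath, params, settings=SimSettings(st=1e-4, t_end=1.0))
        drift = traj.final_state.Em - cell.Em
        assert drift == pytest.approx(traj.q_transferred / params.c, abs=1e-12)

    def test_impermeant_amounts_conserved(self):
        """An_i*vol and osm_i*vol are untouched by fluxes and water."""
        sc = get_scenario("gcl_opening")
        sc.cell.osm_i = 5.0  # give the neutral osmolyte something to conserve
        traj = run_scenario(sc, t_end=5.0)
        an0 = sc.cell.An_i * sc.cell.vol
        osm0 = sc.cell.osm_i * sc.cell.vol
        f = traj.final_state
        assert f.An_i * f.vol == pytest.approx(an0, rel=1e-12)
        assert f.osm_i * f.vol == pytest.approx(osm0, rel=1e-12)

    def test_instant_water_keeps_osmotic_equality_every_step(self):
        sc = get_scenario("double_donnan_na")  # tau = 0: instant water
        sc.settings.record_every = 1
        traj = run_scenario(sc, t_end=0.05)
        osm_i = traj.Na_i + traj.K_i + traj.Cl_i + traj.An_i + traj.osm_i
        osm_o = 82.5 + 82.5 + 135.0
        assert np.allclose(osm_i[1:], osm_o, rtol=1e-12)

    def test_volume_relaxation_matches_closed_form(self):
        """A pure osmotic step (no ion pathways) relaxes exponentially:
        vol(t) = vol1 + (vol2 - vol1)*(1 - exp(-t/tau))."""
        cell = CellState(Na_i=145.0, K_i=5.0, Cl_i=30.0, An_i=120.0, osm_i=30.0)
        bath = BathState(Na_o=145.0, K_o=5.0, Cl_o=150.0)  # 300 vs 330 inside
        params = MembraneParams(tau=60.0)
        traj = run(cell, bath, params,
                   settings=SimSettings(st=1e-3, t_end=120.0, record_every=1000))
        vol1 = cell.vol
        vol2 = vol1 * 330.0 / 300.0  # amounts conserved, osmolarity equalised
        expected = vol1 + (vol2 - vol1) * (1.0 - np.exp(-traj.t / 60.0))
        assert np.allclose(traj.vol, expected, rtol=1e-3)

    def test_time_step_refinement(self):
        """Halving st changes the 20-minute Donnan concentrations by less
        than 0.1%."""
        results = []
        for st_val in (1e-3, 5e-4):
            sc = get_scenario("donnan_novol")
            sc.settings.st = st_val
            traj = run_scenario(sc, t_end=1200.0)
            results.append(traj.final_state.Na_i)
        assert abs(results[0] - results[1]) / results[1] < 1e-3

    def test_zero_horizon_returns_initial_state(self, symmetric_nacl):
        cell, bath, params = symmetric_nacl
        traj = run(cell, bath, params, settings=SimSettings(st=1e-3, t_end=0.0))
        assert len(traj) == 1
        assert traj.Na_i[0] == cell.Na_i


class TestSteadyStateDriver:
    def test_already_balanced_state_converges_immediately(self):
        cell = CellState(Na_i=150.0, K_i=0.0, Cl_i=150.0, An_i=0.0, Em=0.0)
        bath = BathState(Na_o=150.0, K_o=0.0, Cl_o=150.0)
        params = MembraneParams(gNa=1e10, gCl=1e10, tau=1.0)
        rep = run_to_steady_state(cell, bath, params)
        assert rep.converged and rep.elapsed == 0.0

    def test_donnan_with_water_swells_without_bound(self):
        """Pump-free Na+/Cl-/water-permeable cell: no steady state, the
        volume only grows."""
        from chargediff import steady_state

        sc = get_scenario("donnan_water")
        rep = steady_state(sc, SimSettings(st=1e-3, max_steady_time=300.0))
        assert not rep.converged
        assert rep.reason == "unbounded swelling"
        assert rep.state.vol > sc.cell.vol
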