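"""Physical constants and the state/parameter containers of the model.

The simulated object is a single cell (a 10x10x10 um cube with 25% of its
volume occupied by organelles, hence an effective water volume of 7.5e-13 L)
bathed in an effectively infinite extracellular solution.  The cell membrane
carries linear (voltage-insensitive) Na+, K+ and Cl- conductances, an
Na+/K+-ATPase of configurable stoichiometry, electroneutral Na+,K+,2Cl- and
K+,Cl- cotransporters, and a finite water permeability expressed as the time
constant of osmotic volume relaxation.  Intracellular impermeant anions of
mean valence ``z`` and neutral osmolytes on either side complete the system.

Units at this interface are the ones used throughout the package:

* concentrations      mM
* membrane potential  V
* volume              L
* conductances        ions s^-1 V^-1
* pump / cotransporter rates and activities  cycles s^-1
* time                s
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "CONSTANTS",
    "PhysicalConstants",
    "CellState",
    "BathState",
    "MembraneParams",
    "Buildup",
    "BuildupSchedule",
    "SimSettings",
    "FluxSet",
    "StepDiagnostics",
    "validate_state",
    "electroneutrality_residual",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants, at the (rounded) precision used by the model.

    ``R`` gas constant (J mol^-1 K^-1), ``F`` Faraday constant (C mol^-1),
    ``L`` Avogadro number (mol^-1), ``e`` elementary charge (C).

    With these values RT/F at 309.85 K gives 61.48 mV per tenfold
    concentration ratio.  Note that ``e * L`` reproduces ``F`` only to about
    0.17% because each constant is independently rounded; ``F`` is used for
    Nernst potentials and ``e`` for ion-count <-> coulomb conversion.
    """

    R: float = 8.314
    F: float = 96485.0
    L: float = 6.02e23
    e: float = 1.6e-19

    def rt_over_f(self, T: float) -> float:
        """Thermal voltage RT/F in volts at absolute temperature T (K)."""
        return self.R * T / self.F


CONSTANTS = PhysicalConstants()

#: Concentrations below this floor (mM) are treated as numerically zero;
#: a step that would push an intracellular species below it is rejected
#: and retried with a halved time step.
CONC_FLOOR_MM = 1e-9


@dataclass
class CellState:
    """Intracellular state: concentrations (mM), Em (V), water volume (L).

    ``Em`` is a genuine state variable: it is set by the caller at t = 0 and
    afterwards only ever incremented by dQ/c.  It is never recomputed from
    the concentrations -- that is the essence of the charge-difference
    method.  ``atp_total`` accumulates pump cycles (= ATP molecules spent).
    """

    Na_i: float
    K_i: float
    Cl_i: float
    An_i: float
    osm_i: float = 0.0
    Em: float = 0.0
    vol: float = 7.5e-13
    t: float = 0.0
    atp_total: float = 0.0

    def copy(self) -> "CellState":
        return replace(self)

    @property
    def osmolarity(self) -> float:
        """Total intracellular osmolarity in mM (mOsm)."""
        return self.Na_i + self.K_i + self.Cl_i + self.An_i + self.osm_i


@dataclass
class BathState:
    """Extracellular concentrations (mM); constant except under buildups."""

    Na_o: float
    K_o: float
    Cl_o: float
    osm_o: float = 0.0

    def copy(self) -> "BathState":
        return replace(self)

    @property
    def osmolarity(self) -> float:
        return self.Na_o + self.K_o + self.Cl_o + self.osm_o


@dataclass
class MembraneParams:
    """Membrane transport parameters.

    gNa, gK, gCl : linear conductances, ions s^-1 V^-1 (2e10 of total
        conductance equals 3.2 nS, i.e. a 312.5 MOhm input resistance).
    c : membrane capacitance, F (12 pF for the reference cube cell).
    T : absolute temperature, K.
    Rp : Na+/K+-ATPase rate -- the activity ceiling reached as Na_i -> inf,
        cycles s^-1.  hNa is the Na_i (mM) at which activity is Rp/8.
    x, y : Na+ extruded / K+ imported per pump cycle (3:2 physiological).
    Rnkc, Rkc : NKCC and KCC cotransporter rates, cycles s^-1.
    z : mean valence of the impermeant intracellular anion (negative).
    tau : time constant of osmotic volume relaxation, s; tau below the time
        step means instant water, tau > 1e8 s means a water-tight membrane.
    """

    gNa: float = 0.0
    gK: float = 0.0
    gCl: float = 0.0
    c: float = 1.2e-11
    T: float = 309.85
    Rp: float = 0.0
    hNa: float = 8.0
    x: int = 3
    y: int = 2
    Rnkc: float = 0.0
    Rkc: float = 0.0
    z: float = -1.0
    tau: float = 1.0

    def copy(self) -> "MembraneParams":
        return replace(self)

    @property
    def g_total(self) -> float:
        return self.gNa + self.gK + self.gCl

    def input_resistance(self) -> float:
        """Input resistance 1/(g_total * e) in Ohm."""
        g = self.g_total
        if g <= 0:
            raise ValueError("input resistance undefined with zero total conductance")
        return 1.0 / (g * CONSTANTS.e)


@dataclass(frozen=True)
class Buildup:
    """A single exogenous addition: rate (mM/s) inside [t_start, t_stop)."""

    rate: float = 0.0
    t_start: float = 0.0
    t_stop: float = 0.0

    def rate_at(self, t: float) -> float:
        return self.rate if self.t_start <= t < self.t_stop else 0.0


@dataclass
class BuildupSchedule:
    """Time-windowed buildup rates for the four exogenous additions.

    ``bOso``: external neutral osmolyte; ``bNaCl``: external NaCl (raises
    Na_o and Cl_o together); ``bOsi``: internal neutral osmolyte; ``bAn``:
    internal impermeant anion, automatically accompanied by Na+ at a rate
    of -z * bAn for electroneutrality.  Buildups change concentrations but
    never membrane charge.
    """

    bOso: Buildup = field(default_factory=Buildup)
    bNaCl: Buildup = field(default_factory=Buildup)
    bOsi: Buildup = field(default_factory=Buildup)
    bAn: Buildup = field(default_factory=Buildup)

    def is_active(self) -> bool:
        return any(
            b.rate != 0.0 and b.t_stop > b.t_start
            for b in (self.bOso, self.bNaCl, self.bOsi, self.bAn)
        )

    def last_stop(self) -> float:
        return max(b.t_stop for b in (self.bOso, self.bNaCl, self.bOsi, self.bAn))


@dataclass
class SimSettings:
    """Integration settings.

    st : fixed time step, s (0.1 ms for fast transients, up to 1 ms for
        long steady-state runs).
    t_end : simulated horizon for `run`, s.
    record_every : record one sample per this many steps.
    steady_tol : steady-state criterion -- every per-ion net flux, expressed
        as a concentration rate (mM/s), must stay below this value.
    steady_checks : number of consecutive passing checks required.
    check_interval : simulated seconds between steady-state checks.
    max_steady_time : give up (converged=False) beyond this simulated time.
    seed : unused by the deterministic core; reserved for callers.
    """

    st: float = 1e-3
    t_end: float = 1.0
    record_every: int = 1
    steady_tol: float = 1e-9
    steady_checks: int = 10
    check_interval: float = 0.5
    max_steady_time: float = 7200.0
    seed: int = 0


@dataclass(frozen=True)
class FluxSet:
    """Instantaneous transmembrane fluxes, inward positive (ions/s).

    Activities (cycles/s): Ap for the pump, Ankc and Akc for the
    cotransporters.  Stoichiometry ties fluxes to activities:
    NaFp = -x*Ap, KFp = y*Ap; NaFnkc = KFnkc = Ankc, ClFnkc = 2*Ankc;
    KFkc = ClFkc = Akc.
    """

    NaFc: float = 0.0
    KFc: float = 0.0
    ClFc: float = 0.0
    Ap: float = 0.0
    NaFp: float = 0.0
    KFp: float = 0.0
    Ankc: float = 0.0
    NaFnkc: float = 0.0
    KFnkc: float = 0.0
    ClFnkc: float = 0.0
    Akc: float = 0.0
    KFkc: float = 0.0
    ClFkc: float = 0.0

    @property
    def net_Na(self) -> float:
        return self.NaFc + self.NaFp + self.NaFnkc

    @property
    def net_K(self) -> float:
        return self.KFc + self.KFp + self.KFnkc + self.KFkc

    @property
    def net_Cl(self) -> float:
        return self.ClFc + self.ClFnkc + self.ClFkc

    @property
    def charge_flux(self) -> float:
        """Net inward charge flux in elementary charges per second."""
        return self.net_Na + self.net_K - self.net_Cl


@dataclass(frozen=True)
class StepDiagnostics:
    """Per-step bookkeeping: ion-count changes, charge, volume factors."""

    dNa: float = 0.0
    dK: float = 0.0
    dCl: float = 0.0
    dQ: float = 0.0
    osV: float = 1.0
    chV: float = 1.0
    VoR: float = 0.0


def electroneutrality_residual(state: CellState, params: MembraneParams) -> float:
    """Bulk charge imbalance (Na_i + K_i) - (-z*An_i + Cl_i), in mM.

    Macroscopic electroneutrality holds only up to the tiny capacitive
    charge on the membrane; the residual expressed in coulombs
    (residual * vol * L * e * 1e-3) should match Em * c.
    """
    return (state.Na_i + state.K_i) - (-params.z * state.An_i + state.Cl_i)


def validate_state(
    state: CellState,
    bath: BathState,
    params: MembraneParams,
    *,
    charge_tol_mM: float = 0.5,
) -> list[str]:
    """Check type invariants; return a list of violation messages.

    An empty list means the configuration is admissible.  The
    electroneutrality bookkeeping is checked against the capacitive charge
    Em*c with a tolerance of ``charge_tol_mM`` (published initial conditions
    are rounded to 0.1 mM, so sub-mM slack is expected).
    """
    v: list[str] = []
    for name in ("Na_i", "K_i", "Cl_i", "An_i", "osm_i"):
        if getattr(state, name) < 0:
            v.append(f"negative intracellular concentration: {name}")
    if state.vol <= 0:
        v.append("non-positive cell volume")
    for name in ("Na_o", "K_o", "Cl_o", "osm_o"):
        if getattr(bath, name) < 0:
            v.append(f"negative bath concentration: {name}")
    for name in ("gNa", "gK", "gCl", "Rp", "Rnkc", "Rkc"):
        if getattr(params, name) < 0:
            v.append(f"negative transport parameter: {name}")
    if params.hNa <= 0:
        v.append("hNa must be positive")
    if params.c <= 0:
        v.append("capacitance must be positive")
    if params.T <= 0:
        v.append("temperature must be positive")
    if params.x < 0 or params.y < 0 or params.x != int(params.x) or params.y != int(params.y):
        v.append("pump stoichiometry x, y must be non-negative integers")
    if params.z >= 0:
        v.append("mean impermeant-anion valence z must be negative")
    if params.tau < 0:
        v.append("water-permeability time constant tau must be non-negative")
    if not v and state.vol > 0:
        # bulk charge (mM -> coulomb) vs the capacitive charge Em*c
        resid = electroneutrality_residual(state, params)
        cap_mM = state.Em * params.c / (state.vol * CONSTANTS.L * CONSTANTS.e) * 1e3
        if not math.isfinite(resid) or abs(resid - cap_mM) > charge_tol_mM:
            v.append(
                "electroneutrality bookkeeping off by "
                f"{resid - cap_mM:.3g} mM (residual {resid:.3g} mM vs "
                f"capacitive {cap_mM:.3g} mM)"
            )
    return v
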