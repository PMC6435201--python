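"""Analytic equilibrium theory used to cross-validate the simulator.

Closed-form results for the passive states of the model: the Donnan
product rule and its Double Donnan variant (an external impermeant
osmolyte balancing the internal impermeant anion), the chord-conductance
membrane potential with an Na+/K+-pump current term, the energy cost of a
steady state, the thermodynamic Cl- limits of the two cation-Cl-
cotransporters, and the osmolarity-charge asymmetry coefficient k_a that
predicts the equilibrium cation ratio and membrane potential of a
pump-free, cation-permeable cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .integrator import SteadyStateReport
from .state import CONSTANTS, BathState, CellState, MembraneParams

__all__ = [
    "donnan_residual",
    "donnan_equilibrium",
    "AsymmetryReport",
    "asymmetry_coefficient",
    "chord_Em",
    "pump_current",
    "energy_rate",
    "nkcc_limit_Cl",
    "kcc_limit_Cl",
]


def donnan_residual(state: CellState, bath: BathState) -> float:
    """Relative departure from the Donnan product rule.

    Returns Na_i*Cl_i / (Na_o*Cl_o) - 1; zero at Donnan equilibrium.
    """
    for c in (state.Na_i, state.Cl_i, bath.Na_o, bath.Cl_o):
        if c <= 0:
            raise ValueError("Donnan residual requires positive Na+ and Cl-")
    return state.Na_i * state.Cl_i / (bath.Na_o * bath.Cl_o) - 1.0


def donnan_equilibrium(bath: BathState) -> tuple[float, float, float]:
    """Closed-form NaCl Donnan equilibrium with a monovalent internal anion
    and osmotic balance against the bath.

    Solves Na_i*Cl_i = Na_o*Cl_o (product rule), Na_i = Cl_i + An_i
    (electroneutrality, z = -1) and Na_i + Cl_i + An_i = bath osmolarity.
    The two constraints on the anion side pin Na_i at half the external
    osmolarity, so Cl_i = Na_o*Cl_o / Na_i.  Returns (Na_i, Cl_i, An_i)
    in mM.  An_i < 0 means no equilibrium leaves room for the internal
    impermeant anion under these bath conditions.
    """
    na_i = bath.osmolarity / 2.0
    if na_i <= 0:
        raise ValueError("bath osmolarity must be positive")
    cl_i = bath.Na_o * bath.Cl_o / na_i
    an_i = na_i - cl_i
    return na_i, cl_i, an_i


@dataclass(frozen=True)
class AsymmetryReport:
    """Osmolarity-charge asymmetry and its equilibrium predictions.

    ``ka`` is the ratio of all intracellular negative charge to all
    non-cation intracellular osmolytes net of the external neutral
    osmolyte.  ``cation_ratio`` = 2*ka/(ka+1) is the predicted passive
    equilibrium [cat]_i/[cat]_o; ``Em`` the corresponding potential (V),
    negative when the inside cation concentration exceeds the outside;
    ``d_osm`` = osm_i - osm_o (mM).
    """

    ka: float
    cation_ratio: float
    Em: float
    d_osm: float


def asymmetry_coefficient(
    state: CellState, bath: BathState, params: MembraneParams
) -> AsymmetryReport:
    """Compute k_a = (-z*An_i + Cl_i) / (An_i + Cl_i + osm_i - osm_o) and
    the passive-equilibrium cation ratio and Em it predicts.

    ka = 1 (osmolarity-charge symmetry) predicts ratio 1 and Em = 0.  The
    equilibrium Em is the common Nernst potential of the cations,
    (RT/F) * ln([cat]_o/[cat]_i) = -(RT/F) * ln(2*ka/(ka+1)).
    """
    d_osm = state.osm_i - bath.osm_o
    denom = state.An_i + state.Cl_i + d_osm
    if denom <= 0:
        raise ValueError("asymmetry coefficient undefined: non-positive denominator")
    ka = (-params.z * state.An_i + state.Cl_i) / denom
    ratio = 2.0 * ka / (ka + 1.0)
    if ratio <= 0:
        raise ValueError("asymmetry coefficient predicts a non-positive cation ratio")
    em = -CONSTANTS.rt_over_f(params.T) * math.log(ratio)
    return AsymmetryReport(ka=ka, cation_ratio=ratio, Em=em, d_osm=d_osm)


def pump_current(Ap: float, x: int, y: int) -> float:
    """Outward-positive pump charge current (x - y) * Ap * e, in amperes."""
    return (x - y) * Ap * CONSTANTS.e


def chord_Em(
    gNa: float,
    gK: float,
    E_Na: float,
    E_K: float,
    pump_current: float = 0.0,
    R_input: float = 0.0,
) -> float:
    """Chord-conductance membrane potential with a pump term (V).

    (gK*E_K + gNa*E_Na)/(gK + gNa) plus the ohmic contribution of the pump
    current across the input resistance; an outward-positive current
    hyperpolarises, so the pump term enters as -I*R.  With gNa = gK and no
    pump this is the arithmetic mean of the two Nernst potentials.
    """
    g = gNa + gK
    if g <= 0:
        raise ValueError("chord potential undefined with zero cation conductance")
    return (gK * E_K + gNa * E_Na) / g - pump_current * R_input


def energy_rate(report: SteadyStateReport) -> float:
    """ATP expenditure of a converged steady state, molecules per second.

    One pump cycle hydrolyses one ATP, so the rate is simply the pump
    activity at the steady state.  Raises on a non-converged report: an
    energy rate is only meaningful once fluxes balance.
    """
    if not report.converged:
        raise ValueError(
            f"energy rate undefined for non-converged state ({report.reason})"
        )
    return report.atp_per_sec


def nkcc_limit_Cl(bath: BathState, Na_i: float, K_i: float) -> float:
    """Thermodynamic ceiling on Cl_i reachable by the Na+,K+,2Cl-
    cotransporter: the Cl_i at which its log driving force vanishes,
    sqrt(Na_o*K_o*Cl_o^2 / (Na_i*K_i)), in mM."""
    for c in (bath.Na_o, bath.K_o, bath.Cl_o, Na_i, K_i):
        if c <= 0:
            raise ValueError("NKCC limit requires positive concentrations")
    return math.sqrt(bath.Na_o * bath.K_o * bath.Cl_o**2 / (Na_i * K_i))


def kcc_limit_Cl(bath: BathState, K_i: float) -> float:
    """Thermodynamic floor on Cl_i reachable by the K+,Cl- cotransporter:
    K_o*Cl_o / K_i, in mM."""
    for c in (bath.K_o, bath.Cl_o, K_i):
        if c <= 0:
            raise ValueError("KCC limit requires positive concentrations")
    return bath.K_o * bath.Cl_o / K_i
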