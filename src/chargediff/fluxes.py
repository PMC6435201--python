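"""Instantaneous transmembrane fluxes (inward positive).

All fluxes are evaluated from the state at the beginning of a time step
("conditions unchanged within a step"); there is no sub-step splitting.
Passive channel fluxes are linear in the electrochemical driving force
(conductance-based, not Goldman-Hodgkin-Katz), the pump follows a
third-order saturating dependence on intracellular Na+, and the two
cotransporters are linear in the base-10 log of their concentration-product
driving ratios.
"""

from __future__ import annotations

import math

from .state import CONSTANTS, BathState, CellState, FluxSet, MembraneParams

__all__ = [
    "nernst_potential",
    "conductive_fluxes",
    "pump_activity",
    "pump_fluxes",
    "nkcc_fluxes",
    "kcc_fluxes",
    "compute_fluxes",
]


def nernst_potential(c_out: float, c_in: float, valence: int, T: float) -> float:
    """Equilibrium potential (RT/(valence*F)) * ln(c_out/c_in), in volts.

    At 309.85 K this is 61.48 mV for a tenfold inward gradient of a
    monovalent cation.  Concentrations must be strictly positive.
    """
    if c_out <= 0 or c_in <= 0:
        raise ValueError(
            f"Nernst potential undefined for non-positive concentrations "
            f"(c_out={c_out!r}, c_in={c_in!r})"
        )
    if valence == 0:
        raise ValueError("Nernst potential undefined for zero valence")
    return CONSTANTS.rt_over_f(T) / valence * math.log(c_out / c_in)


def conductive_fluxes(
    state: CellState, bath: BathState, params: MembraneParams
) -> tuple[float, float, float]:
    """Channel fluxes (NaFc, KFc, ClFc) in ions/s, inward positive.

    NaFc = gNa * (E_Na - Em) and likewise for K+; for Cl- the membrane
    potential enters with the opposite sign, ClFc = gCl * (Em - E_Cl)
    (equivalently gCl * ((RT/F) ln(Cl_o/Cl_i) + Em) with the cation-sign
    Nernst convention).  A closed channel (g = 0) carries no flux and its
    concentrations are not inspected.
    """
    rt_f = CONSTANTS.rt_over_f(params.T)

    def _cation(g: float, c_out: float, c_in: float) -> float:
        if g == 0.0:
            return 0.0
        if c_out <= 0 or c_in <= 0:
            raise ValueError("open channel with non-positive concentration")
        return g * (rt_f * math.log(c_out / c_in) - state.Em)

    na = _cation(params.gNa, bath.Na_o, state.Na_i)
    k = _cation(params.gK, bath.K_o, state.K_i)
    if params.gCl == 0.0:
        cl = 0.0
    else:
        if bath.Cl_o <= 0 or state.Cl_i <= 0:
            raise ValueError("open Cl- channel with non-positive concentration")
        cl = params.gCl * (rt_f * math.log(bath.Cl_o / state.Cl_i) + state.Em)
    return na, k, cl


def pump_activity(Na_i: float, Rp: float, hNa: float) -> float:
    """Na+/K+-ATPase activity Ap = Rp / (1 + hNa/Na_i)^3, cycles/s.

    Monotone in Na_i, zero at Na_i = 0, approaching the rate Rp as
    Na_i -> infinity; Ap = Rp/8 at Na_i = hNa (third-order Na+ binding).
    One cycle spends one ATP, so Ap is also the ATP consumption rate.
    """
    if Na_i < 0:
        raise ValueError("negative intracellular Na+")
    if hNa <= 0:
        raise ValueError("hNa must be positive")
    if Na_i == 0.0:
        return 0.0
    r = Na_i / (Na_i + hNa)
    return Rp * r * r * r


def pump_fluxes(Ap: float, x: int, y: int) -> tuple[float, float]:
    """Pump fluxes (NaFp, KFp) = (-x*Ap, +y*Ap) in ions/s.

    The pump extrudes x Na+ and imports y K+ per cycle; its charge current,
    outward positive, is (x - y) * Ap * e.
    """
    return -x * Ap, y * Ap


def nkcc_fluxes(
    state: CellState, bath: BathState, Rnkc: float
) -> tuple[float, float, float, float]:
    """Na+,K+,2Cl- cotransporter: (Ankc, NaFnkc, KFnkc, ClFnkc).

    Ankc = Rnkc * log10((Na_o*K_o*Cl_o^2) / (Na_i*K_i*Cl_i^2)); the
    transporter runs forward (inward) while the outside concentration
    product exceeds the inside one and reverses beyond that point.
    """
    if Rnkc == 0.0:
        return 0.0, 0.0, 0.0, 0.0
    for c in (bath.Na_o, bath.K_o, bath.Cl_o, state.Na_i, state.K_i, state.Cl_i):
        if c <= 0:
            raise ValueError("NKCC requires positive Na+, K+ and Cl- on both sides")
    drive = math.log10(
        (bath.Na_o * bath.K_o * bath.Cl_o**2)
        / (state.Na_i * state.K_i * state.Cl_i**2)
    )
    a = Rnkc * drive
    return a, a, a, 2.0 * a


def kcc_fluxes(
    state: CellState, bath: BathState, Rkc: float
) -> tuple[float, float, float]:
    """K+,Cl- cotransporter: (Akc, KFkc, ClFkc).

    Akc = Rkc * log10((K_o*Cl_o) / (K_i*Cl_i)); usually the inside product
    is larger, so Akc is negative and the transporter extrudes KCl.
    """
    if Rkc == 0.0:
        return 0.0, 0.0, 0.0
    for c in (bath.K_o, bath.Cl_o, state.K_i, state.Cl_i):
        if c <= 0:
            raise ValueError("KCC requires positive K+ and Cl- on both sides")
    a = Rkc * math.log10((bath.K_o * bath.Cl_o) / (state.K_i * state.Cl_i))
    return a, a, a


def compute_fluxes(state: CellState, bath: BathState, params: MembraneParams) -> FluxSet:
    """Evaluate every transport pathway at the given state."""
    na_c, k_c, cl_c = conductive_fluxes(state, bath, params)
    ap = pump_activity(state.Na_i, params.Rp, params.hNa)
    na_p, k_p = pump_fluxes(ap, params.x, params.y)
    ankc, na_n, k_n, cl_n = nkcc_fluxes(state, bath, params.Rnkc)
    akc, k_k, cl_k = kcc_fluxes(state, bath, params.Rkc)
    return FluxSet(
        NaFc=na_c, KFc=k_c, ClFc=cl_c,
        Ap=ap, NaFp=na_p, KFp=k_p,
        Ankc=ankc, NaFnkc=na_n, KFnkc=k_n, ClFnkc=cl_n,
        Akc=akc, KFkc=k_k, ClFkc=cl_k,
    )
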