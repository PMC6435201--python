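"""Time stepping: mass/charge accumulation, Em update, volume relaxation.

One discrete step of the charge-difference method is the fixed composition

1. evaluate all fluxes from the beginning-of-step state,
2. accumulate ion amounts, apply buildups, convert to concentrations and
   compute the transferred charge dQ,
3. increment Em by dQ/c and let water relax the osmotic imbalance at the
   rate allowed by the membrane's water permeability,

repeated over and over.  The step order is deliberate and never
sub-iterated: the discrete composition *is* the method, and its fixed
points are the resting/equilibrium states of the cell.  ``step`` spells
the composition out on the dataclass containers; ``run`` and
``run_to_steady_state`` drive the numerically identical compiled kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .fluxes import compute_fluxes
from .state import (
    CONC_FLOOR_MM,
    CONSTANTS,
    BathState,
    BuildupSchedule,
    CellState,
    FluxSet,
    MembraneParams,
    SimSettings,
    StepDiagnostics,
)

__all__ = [
    "IntegrationError",
    "OsmoticCollapseError",
    "StepRejected",
    "Trajectory",
    "SteadyStateReport",
    "accumulate",
    "update_Em",
    "relax_volume",
    "step",
    "run",
    "run_to_steady_state",
    "net_concentration_rates",
]


class IntegrationError(RuntimeError):
    """Fatal integration failure."""


class OsmoticCollapseError(IntegrationError):
    """chV <= 0: the osmotic update annihilated the cell volume.

    This signals a time step grossly too large for the chosen water
    permeability, not a physical outcome.
    """


class StepRejected(IntegrationError):
    """A step would push an intracellular concentration below the floor."""


def accumulate(
    state: CellState,
    bath: BathState,
    fluxes: FluxSet,
    buildups: BuildupSchedule,
    st: float,
    z: float = -1.0,
) -> tuple[CellState, BathState, StepDiagnostics]:
    """Apply one step of ion transfer and exogenous buildups (set 2).

    Ion amounts dNa, dK, dCl (counts) are the summed fluxes times st;
    concentrations change by d/(vol*L) with vol the beginning-of-step
    volume.  Buildups add material on one side of the membrane: external
    NaCl moves the bath only, internal anion buildup brings -z Na+ along
    per anion for electroneutrality.  The transferred charge is
    dQ = (dNa + dK - dCl)*e; buildups never contribute to dQ.

    Returns the interim ("end of step, before water") state and bath plus
    diagnostics.  Volume and Em are untouched here.
    """
    if st <= 0:
        raise ValueError("time step must be positive")
    d_na = fluxes.net_Na * st
    d_k = fluxes.net_K * st
    d_cl = fluxes.net_Cl * st
    d_q = (d_na + d_k - d_cl) * CONSTANTS.e

    t = state.t
    b_oso = buildups.bOso.rate_at(t)
    b_nacl = buildups.bNaCl.rate_at(t)
    b_osi = buildups.bOsi.rate_at(t)
    b_an = buildups.bAn.rate_at(t)

    per_mM = 1e3 / (state.vol * CONSTANTS.L)
    new_state = state.copy()
    new_state.Na_i = state.Na_i + d_na * per_mM + b_an * st * (-z)
    new_state.K_i = state.K_i + d_k * per_mM
    new_state.Cl_i = state.Cl_i + d_cl * per_mM
    new_state.An_i = state.An_i + b_an * st
    new_state.osm_i = state.osm_i + b_osi * st
    new_state.atp_total = state.atp_total + fluxes.Ap * st

    new_bath = bath.copy()
    new_bath.osm_o = bath.osm_o + b_oso * st
    new_bath.Na_o = bath.Na_o + b_nacl * st
    new_bath.Cl_o = bath.Cl_o + b_nacl * st

    diag = StepDiagnostics(dNa=d_na, dK=d_k, dCl=d_cl, dQ=d_q)

    floored = (
        new_state.Na_i < 0
        or new_state.K_i < 0
        or new_state.Cl_i < 0
        or (fluxes.NaFc != 0 and new_state.Na_i < CONC_FLOOR_MM)
        or (fluxes.KFc != 0 and new_state.K_i < CONC_FLOOR_MM)
        or (fluxes.ClFc != 0 and new_state.Cl_i < CONC_FLOOR_MM)
    )
    if floored:
        raise StepRejected(
            f"step of {st} s at t={t} s drives an intracellular "
            "concentration below the floor"
        )
    return new_state, new_bath, diag


def update_Em(Em: float, dQ: float, c: float) -> float:
    """Membrane potential update Em + dQ/c (V)."""
    if c <= 0:
        raise ValueError("capacitance must be positive")
    return Em + dQ / c


def volume_rate_coefficient(tau: float, st: float) -> float:
    """VoR, the inverse water time constant with its two clamps.

    tau below the time step means water moves within one step (VoR = 1/st,
    so the osmotic correction is applied in full); tau beyond 1e8 s means a
    water-impermeable membrane (VoR = 0, volume frozen).
    """
    if tau > _kernel.WATER_TIGHT_TAU:
        return 0.0
    if tau < st:
        return 1.0 / st
    return 1.0 / tau


def relax_volume(
    state: CellState, bath: BathState, tau: float, st: float
) -> tuple[CellState, StepDiagnostics]:
    """Osmotically driven volume change at finite water permeability (set 3).

    osV is the volume factor that would equalise osmolarity instantly;
    the applied factor chV = 1 - (1 - osV)*VoR*st moves a fraction of the
    way there, turning the discrete update into the explicit-Euler form of
    an exponential volume relaxation with time constant tau.  All five
    intracellular concentrations are divided by chV (amounts conserved);
    the bath, assumed infinite, is untouched.
    """
    if st <= 0:
        raise ValueError("time step must be positive")
    os_v = state.osmolarity / bath.osmolarity
    vo_r = volume_rate_coefficient(tau, st)
    ch_v = 1.0 - (1.0 - os_v) * vo_r * st
    if ch_v <= 0:
        raise OsmoticCollapseError(
            f"chV = {ch_v:.3g} <= 0 (osV = {os_v:.3g}, tau = {tau}, st = {st})"
        )
    new_state = state.copy()
    new_state.vol = state.vol * ch_v
    new_state.Na_i = state.Na_i / ch_v
    new_state.K_i = state.K_i / ch_v
    new_state.Cl_i = state.Cl_i / ch_v
    new_state.An_i = state.An_i / ch_v
    new_state.osm_i = state.osm_i / ch_v
    return new_state, StepDiagnostics(osV=os_v, chV=ch_v, VoR=vo_r)


def step(
    state: CellState,
    bath: BathState,
    params: MembraneParams,
    buildups: BuildupSchedule,
    st: float,
    _depth: int = 0,
) -> tuple[CellState, BathState, StepDiagnostics]:
    """One full step: fluxes -> accumulate -> Em -> volume, in that order.

    A rejected update (concentration under the floor) is retried as two
    half steps, recursively, up to 60 halvings.
    """
    fluxes = compute_fluxes(state, bath, params)
    try:
        mid, new_bath, d1 = accumulate(state, bath, fluxes, buildups, st, params.z)
    except StepRejected:
        if _depth >= 60:
            raise
        s1, b1, _ = step(state, bath, params, buildups, st / 2, _depth + 1)
        return step(s1, b1, params, buildups, st / 2, _depth + 1)
    mid.Em = update_Em(state.Em, d1.dQ, params.c)
    final, d3 = relax_volume(mid, new_bath, params.tau, st)
    final.t = state.t + st
    diag = StepDiagnostics(
        dNa=d1.dNa, dK=d1.dK, dCl=d1.dCl, dQ=d1.dQ,
        osV=d3.osV, chV=d3.chV, VoR=d3.VoR,
    )
    return final, new_bath, diag


@dataclass
class Trajectory:
    """Recorded time series of a run; columns are plain numpy arrays.

    ``vol`` is in litres; ``Em`` in volts.  ``Ap``, ``Ankc``, ``Akc`` are
    the instantaneous transporter activities at each sample.  The final
    (possibly un-recorded) state and bath are carried alongside.
    """

    t: np.ndarray
    Na_i: np.ndarray
    K_i: np.ndarray
    Cl_i: np.ndarray
    An_i: np.ndarray
    osm_i: np.ndarray
    Em: np.ndarray
    vol: np.ndarray
    Ap: np.ndarray
    Ankc: np.ndarray
    Akc: np.ndarray
    final_state: CellState = field(repr=False, default=None)  # type: ignore[assignment]
    final_bath: BathState = field(repr=False, default=None)  # type: ignore[assignment]
    q_transferred: float = 0.0

    def __len__(self) -> int:
        return len(self.t)

    def to_dataframe(self, vol_ref: float | None = None) -> pd.DataFrame:
        """Tabulate with the reporting conventions of the package: time in
        seconds, concentrations in mM, Em in mV, volume as percent of
        ``vol_ref`` (default: the first recorded volume)."""
        if vol_ref is None:
            vol_ref = self.vol[0] if len(self.vol) else 1.0
        return pd.DataFrame(
            {
                "t_s": self.t,
                "Na_i_mM": self.Na_i,
                "K_i_mM": self.K_i,
                "Cl_i_mM": self.Cl_i,
                "An_i_mM": self.An_i,
                "osm_i_mM": self.osm_i,
                "Em_mV": self.Em * 1e3,
                "vol_pct": self.vol / vol_ref * 100.0,
                "Ap_per_s": self.Ap,
                "Ankc_per_s": self.Ankc,
                "Akc_per_s": self.Akc,
            }
        )

    @staticmethod
    def concatenate(parts: list["Trajectory"]) -> "Trajectory":
        """Join consecutive segments, dropping each later segment's
        duplicated initial sample."""
        if not parts:
            raise ValueError("nothing to concatenate")
        cols = ["t", "Na_i", "K_i", "Cl_i", "An_i", "osm_i", "Em", "vol",
                "Ap", "Ankc", "Akc"]
        arrays = {c: [getattr(parts[0], c)] for c in cols}
        for seg in parts[1:]:
            for c in cols:
                arrays[c].append(getattr(seg, c)[1:])
        return Trajectory(
            **{c: np.concatenate(arrays[c]) for c in cols},
            final_state=parts[-1].final_state,
            final_bath=parts[-1].final_bath,
            q_transferred=sum(seg.q_transferred for seg in parts),
        )


@dataclass
class SteadyStateReport:
    """Converged-state diagnostics from ``run_to_steady_state``."""

    state: CellState
    bath: BathState
    residuals: dict[str, float]  # per-ion net flux as mM/s
    elapsed: float
    converged: bool
    atp_per_sec: float
    reason: str = ""


_STATUS_ERRORS = {
    _kernel.STATUS_OSMOTIC_COLLAPSE: OsmoticCollapseError,
    _kernel.STATUS_DOMAIN: IntegrationError,
    _kernel.STATUS_STEP_UNDERFLOW: StepRejected,
}


def _unpack(y: np.ndarray, b: np.ndarray) -> tuple[CellState, BathState]:
    state = CellState(
        Na_i=y[_kernel.NA_I], K_i=y[_kernel.K_I], Cl_i=y[_kernel.CL_I],
        An_i=y[_kernel.AN_I], osm_i=y[_kernel.OSM_I], Em=y[_kernel.EM],
        vol=y[_kernel.VOL], t=y[_kernel.T], atp_total=y[_kernel.ATP],
    )
    bath = BathState(Na_o=b[0], K_o=b[1], Cl_o=b[2], osm_o=b[3])
    return state, bath


def _run_kernel(state, bath, params, buildups, st, n_steps, record_every):
    y = _kernel.pack_state(state)
    b = _kernel.pack_bath(bath)
    p = _kernel.pack_params(params)
    bu = _kernel.pack_buildups(buildups)
    n_rec = (n_steps // record_every + 1) if record_every > 0 else 1
    rec = np.empty((n_rec, 11), dtype=np.float64)
    status, written = _kernel.run_kernel(y, b, p, bu, st, n_steps, record_every, rec)
    if status != _kernel.STATUS_OK:
        final, _ = _unpack(y, b)
        raise _STATUS_ERRORS[status](
            f"integration failed with status {status} at t = {final.t:.6g} s"
        )
    rec = rec[:written]
    final_state, final_bath = _unpack(y, b)
    traj = Trajectory(
        t=rec[:, 0].copy(), Na_i=rec[:, 1].copy(), K_i=rec[:, 2].copy(),
        Cl_i=rec[:, 3].copy(), An_i=rec[:, 4].copy(), osm_i=rec[:, 5].copy(),
        Em=rec[:, 6].copy(), vol=rec[:, 7].copy(), Ap=rec[:, 8].copy(),
        Ankc=rec[:, 9].copy(), Akc=rec[:, 10].copy(),
        final_state=final_state, final_bath=final_bath,
        q_transferred=y[_kernel.QCUM],
    )
    return traj


def run(
    state: CellState,
    bath: BathState,
    params: MembraneParams,
    buildups: BuildupSchedule | None = None,
    settings: SimSettings | None = None,
) -> Trajectory:
    """Fixed-step integration from ``state.t`` to ``state.t + t_end``.

    Deterministic given its inputs.  ``t_end = 0`` yields a trajectory
    holding only the initial state.
    """
    settings = settings or SimSettings()
    buildups = buildups or BuildupSchedule()
    if settings.t_end < 0:
        raise ValueError("t_end must be non-negative")
    n_steps = int(round(settings.t_end / settings.st))
    return _run_kernel(
        state, bath, params, buildups, settings.st, n_steps,
        max(1, settings.record_every),
    )


def net_concentration_rates(
    state: CellState, bath: BathState, params: MembraneParams
) -> dict[str, float]:
    """Per-ion net transmembrane flux expressed as d[ion]/dt in mM/s."""
    fluxes = compute_fluxes(state, bath, params)
    per_mM = 1e3 / (state.vol * CONSTANTS.L)
    return {
        "Na": fluxes.net_Na * per_mM,
        "K": fluxes.net_K * per_mM,
        "Cl": fluxes.net_Cl * per_mM,
    }


def run_to_steady_state(
    state: CellState,
    bath: BathState,
    params: MembraneParams,
    settings: SimSettings | None = None,
) -> SteadyStateReport:
    """Integrate until every per-ion net flux rate stays below tolerance.

    Convergence requires |d[ion]/dt| < ``steady_tol`` (mM/s) for
    ``steady_checks`` consecutive checks spaced ``check_interval`` simulated
    seconds apart.  Two failure modes are reported rather than looped on:
    the volume exceeding ten times its initial value (or growing
    monotonically through the whole budget while fluxes stay unbalanced) is
    flagged as unbounded swelling -- the fate of a pump-free cell permeable
    to Na+, Cl- and water -- and exhausting ``max_steady_time`` returns
    ``converged=False``.

    Buildups are intentionally not accepted here: a steady state is only
    well defined once exogenous additions have ceased.
    """
    settings = settings or SimSettings()
    quiet = BuildupSchedule()
    vol0 = state.vol
    chunk_steps = max(1, int(round(settings.check_interval / settings.st)))

    rates = net_concentration_rates(state, bath, params)
    ok_streak = settings.steady_checks if _below(rates, settings.steady_tol) else 0
    elapsed = 0.0
    t_start = state.t
    vols = [state.vol]
    cur_state, cur_bath = state, bath
    while ok_streak < settings.steady_checks:
        if elapsed >= settings.max_steady_time or cur_state.vol > 10.0 * vol0:
            monotone = all(b > a for a, b in zip(vols, vols[1:]))
            swelling = cur_state.vol > 10.0 * vol0 or (
                monotone and len(vols) > 3 and not _below(rates, settings.steady_tol)
            )
            return SteadyStateReport(
                state=cur_state, bath=cur_bath, residuals=rates,
                elapsed=elapsed, converged=False,
                atp_per_sec=compute_fluxes(cur_state, cur_bath, params).Ap,
                reason="unbounded swelling" if swelling else "max time reached",
            )
        traj = _run_kernel(
            cur_state, cur_bath, params, quiet, settings.st, chunk_steps, 0
        )
        cur_state, cur_bath = traj.final_state, traj.final_bath
        elapsed = cur_state.t - t_start
        vols.append(cur_state.vol)
        rates = net_concentration_rates(cur_state, cur_bath, params)
        ok_streak = ok_streak + 1 if _below(rates, settings.steady_tol) else 0

    ap = compute_fluxes(cur_state, cur_bath, params).Ap
    return SteadyStateReport(
        state=cur_state, bath=cur_bath, residuals=rates, elapsed=elapsed,
        converged=True, atp_per_sec=ap,
    )


def _below(rates: dict[str, float], tol: float) -> bool:
    return all(abs(r) < tol for r in rates.values())
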