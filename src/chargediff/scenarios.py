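"""Scenario registry: named, ready-to-run model configurations.

Each scenario bundles an initial cell/bath state, membrane parameters,
buildup schedule, integration settings and a list of timed parameter
changes ("at t = 0 open gCl", "at t = 10 s restore gNa").  The registry
covers the canonical experiments of the charge-difference model: Donnan
and Double Donnan equilibria at various water permeabilities, pump-leak
cation systems with configurable stoichiometry, Cl- conductance openings,
cotransporter sweeps, osmolyte buildups and the osmolarity-charge
asymmetry sweep.  Two concentration conventions recur: "simplified"
(monovalent impermeant anion, no external neutral osmolyte) and
"realistic" (z = -1.5 plus 6 mM external neutral osmolyte).

Steady-state sweep and rate-finding drivers live here too, because the
published steady-state curves are parameter sweeps over these scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import pandas as pd

from .fluxes import nernst_potential, pump_activity
from .integrator import (
    SteadyStateReport,
    Trajectory,
    run,
    run_to_steady_state,
)
from .state import (
    BathState,
    Buildup,
    BuildupSchedule,
    CellState,
    MembraneParams,
    SimSettings,
)

__all__ = [
    "Scenario",
    "TimedChange",
    "SCENARIO_NAMES",
    "get_scenario",
    "list_scenarios",
    "run_scenario",
    "steady_state",
    "sweep_steady_states",
    "find_rate_for_condition",
    "charge_balanced_Em",
    "rate_for_activity",
]


@dataclass(frozen=True)
class TimedChange:
    """Set ``path`` (e.g. ``params.gCl``) to ``value`` at simulated time t."""

    t: float
    path: str
    value: float


@dataclass
class Scenario:
    name: str
    cell: CellState
    bath: BathState
    params: MembraneParams
    buildups: BuildupSchedule = field(default_factory=BuildupSchedule)
    settings: SimSettings = field(default_factory=SimSettings)
    changes: tuple[TimedChange, ...] = ()
    description: str = ""

    def copy(self) -> "Scenario":
        return Scenario(
            name=self.name, cell=self.cell.copy(), bath=self.bath.copy(),
            params=self.params.copy(), buildups=replace(self.buildups),
            settings=replace(self.settings), changes=tuple(self.changes),
            description=self.description,
        )

    def apply_change(self, change: TimedChange) -> None:
        obj_name, _, attr = change.path.partition(".")
        target = {"params": self.params, "cell": self.cell, "bath": self.bath}.get(obj_name)
        if target is None or not hasattr(target, attr):
            raise ValueError(f"unknown parameter path {change.path!r}")
        setattr(target, attr, change.value)


def charge_balanced_Em(
    cell: CellState, bath: BathState, params: MembraneParams
) -> float:
    """Membrane potential at which the net charge flux vanishes for the
    given concentrations (the chord-conductance potential including the
    pump current), in volts.

    Used to initialise Em for scenarios whose published initial conditions
    are steady states: the membrane charges to this potential within
    milliseconds, long before concentrations can move.
    """
    g = params.g_total
    if g <= 0:
        raise ValueError("no open conductance: Em is unconstrained")
    acc = 0.0
    if params.gNa > 0:
        acc += params.gNa * nernst_potential(bath.Na_o, cell.Na_i, 1, params.T)
    if params.gK > 0:
        acc += params.gK * nernst_potential(bath.K_o, cell.K_i, 1, params.T)
    if params.gCl > 0:
        acc += params.gCl * nernst_potential(bath.Cl_o, cell.Cl_i, -1, params.T)
    ap = pump_activity(cell.Na_i, params.Rp, params.hNa)
    acc -= (params.x - params.y) * ap
    return acc / g


def rate_for_activity(activity: float, Na_i: float, hNa: float = 8.0) -> float:
    """Pump rate Rp that yields the given activity at the given Na_i (mM)."""
    if Na_i <= 0:
        raise ValueError("Na_i must be positive")
    return activity * (1.0 + hNa / Na_i) ** 3


_VOL0 = 7.5e-13
_NO_WATER = 1e9  # tau beyond the water-tight threshold


def _open(*pairs: tuple[str, float], t: float = 0.0) -> tuple[TimedChange, ...]:
    return tuple(TimedChange(t, path, value) for path, value in pairs)


def _donnan_novol(tau: float = _NO_WATER) -> Scenario:
    """Symmetric NaCl cell, water-tight membrane; opening equal gNa and gCl
    relaxes it into a textbook Donnan equilibrium at constant volume."""
    return Scenario(
        name="donnan_novol",
        cell=CellState(Na_i=150.0, K_i=0.0, Cl_i=15.0, An_i=135.0, Em=0.0, vol=_VOL0),
        bath=BathState(Na_o=150.0, K_o=0.0, Cl_o=150.0),
        params=MembraneParams(tau=tau),
        settings=SimSettings(st=1e-3, t_end=1200.0, record_every=1000),
        changes=_open(("params.gNa", 1e10), ("params.gCl", 1e10)),
        description="Donnan relaxation with no transmembrane water movement",
    )


def _donnan_water(tau: float = 0.0) -> Scenario:
    """Same opening with free water: no equilibrium exists and the cell
    swells without bound."""
    sc = _donnan_novol(tau=tau)
    sc.name = "donnan_water"
    sc.description = "Donnan conditions with water permeable membrane: unbounded swelling"
    return sc


def _water_perm_sweep(tau: float = 60.0) -> Scenario:
    """Donnan opening at an intermediate water permeability (tau in s)."""
    sc = _donnan_novol(tau=tau)
    sc.name = "water_perm_sweep"
    sc.description = f"Donnan opening with volume time constant {tau} s"
    return sc


def _double_donnan_na(tau: float = 0.0) -> Scenario:
    """135 mM external neutral osmolyte balancing the internal anion;
    NaCl reduced to 82.5 mM outside.  A true Double Donnan equilibrium
    (vol -> 129%, Cl_i -> 45.375 mM) is reached despite free water."""
    return Scenario(
        name="double_donnan_na",
        cell=CellState(Na_i=150.0, K_i=0.0, Cl_i=15.0, An_i=135.0, Em=0.0, vol=_VOL0),
        bath=BathState(Na_o=82.5, K_o=0.0, Cl_o=82.5, osm_o=135.0),
        params=MembraneParams(tau=tau),
        settings=SimSettings(st=1e-3, t_end=2400.0, record_every=1000),
        changes=_open(("params.gNa", 1e10), ("params.gCl", 1e10)),
        description="Double Donnan via external neutral osmolyte",
    )


def _double_donnan_k(tau: float = 0.0) -> Scenario:
    """K+/Cl- Double Donnan with Na+ as the effectively impermeant
    extracellular osmolyte (gNa = 0)."""
    return Scenario(
        name="double_donnan_k",
        cell=CellState(Na_i=145.0, K_i=5.0, Cl_i=15.0, An_i=135.0, Em=0.0, vol=_VOL0),
        bath=BathState(Na_o=145.0, K_o=5.0, Cl_o=150.0),
        params=MembraneParams(tau=tau),
        settings=SimSettings(st=1e-3, t_end=600.0, record_every=1000),
        changes=_open(("params.gK", 1e10), ("params.gCl", 1e10)),
        description="Double Donnan carried by K+ and Cl- with impermeant Na+",
    )


def _cation_cell(z: float = -1.0, osm_o: float = 0.0) -> tuple[CellState, BathState]:
    """Initial equilibrium of the cation-only pump-leak system.

    The plain case (z = -1, no external osmolyte) starts symmetric.  For
    z = -3 or added external osmolyte, the passive equilibrium demands
    proportionally scaled internal concentrations (the osmolarity-charge
    asymmetry at work); the scaled values are derived here rather than
    hard-coded.
    """
    bath = BathState(Na_o=145.0, K_o=5.0, Cl_o=150.0, osm_o=osm_o)
    # internal composition before osmotic scaling: cations as outside,
    # Cl- plus An- carrying 150 mM of negative charge
    cl = 15.0
    an = (150.0 - cl) / (-z)
    raw_osm = 145.0 + 5.0 + cl + an
    scale = bath.osmolarity / raw_osm
    cell = CellState(
        Na_i=145.0 * scale, K_i=5.0 * scale, Cl_i=cl * scale, An_i=an * scale,
        Em=0.0, vol=_VOL0,
    )
    rt_f = 8.314 * 309.85 / 96485.0
    cell.Em = rt_f * math.log(bath.Na_o / cell.Na_i)
    return cell, bath


def _pump_neutral_transient(Rp: float = 2.4e10) -> Scenario:
    """Switch on an electroneutral 3Na:3K pump in the symmetric cation
    cell and watch Na+/K+ swap over a few seconds."""
    cell, bath = _cation_cell()
    return Scenario(
        name="pump_neutral_transient",
        cell=cell,
        bath=bath,
        params=MembraneParams(gNa=1e10, gK=1e10, x=3, y=3, tau=1.0),
        settings=SimSettings(st=5e-4, t_end=8.0, record_every=10),
        changes=_open(("params.Rp", Rp)),
        description="electroneutral pump switch-on transient",
    )


def _pump_sweep(x: int = 3, y: int = 3, z: float = -1.0, osm_o: float = 0.0) -> Scenario:
    """Base for steady-state sweeps over the pump rate (cation-only cell).

    Variants: stoichiometry (x, y), impermeant-anion valence z, external
    neutral osmolyte.
    """
    cell, bath = _cation_cell(z=z, osm_o=osm_o)
    return Scenario(
        name="pump_sweep",
        cell=cell,
        bath=bath,
        params=MembraneParams(gNa=1e10, gK=1e10, x=x, y=y, z=z, tau=1.0),
        settings=SimSettings(st=1e-3, t_end=60.0, record_every=1000),
        description=f"pump-rate sweep base, {x}Na:{y}K stoichiometry, z={z}",
    )


def _gcl_opening(gCl: float = 1e10, Cl_i: float = 15.0, realistic: bool = False) -> Scenario:
    """Open gCl on a pump-leak resting state; Cl_i re-equilibrates to the
    cation-set Em while the volume absorbs the change."""
    if realistic:
        if Cl_i not in (18.0, 52.0):
            raise ValueError("realistic variant published with Cl_i = 18 or 52 mM")
        if Cl_i == 18.0:
            cell = CellState(Na_i=18.5, K_i=161.5, Cl_i=18.0, An_i=108.0, vol=_VOL0)
        else:
            cell = CellState(Na_i=18.4, K_i=154.8, Cl_i=52.0, An_i=80.8, vol=_VOL0)
        bath = BathState(Na_o=145.0, K_o=5.0, Cl_o=150.0, osm_o=6.0)
        z = -1.5
    else:
        if Cl_i not in (15.0, 45.0):
            raise ValueError("simplified variant published with Cl_i = 15 or 45 mM")
        cell = CellState(Na_i=17.9, K_i=132.1, Cl_i=Cl_i, An_i=150.0 - Cl_i, vol=_VOL0)
        bath = BathState(Na_o=145.0, K_o=5.0, Cl_o=150.0)
        z = -1.0
    params = MembraneParams(
        gNa=8e9, gK=1.2e10, x=3, y=2, z=z, tau=1.0,
        Rp=rate_for_activity(2.64e8, cell.Na_i),
    )
    cell.Em = charge_balanced_Em(cell, bath, params)
    return Scenario(
        name="gcl_opening",
        cell=cell,
        bath=bath,
        params=params,
        settings=SimSettings(st=2.5e-4, t_end=600.0, record_every=4000),
        changes=_open(("params.gCl", gCl)),
        description="Cl- conductance opening on a pump-leak resting state",
    )


def _gna_step(pump: str = "electrogenic", gCl: float = 1e10) -> Scenario:
    """Drop gNa fourfold for 10 s, then restore it ("realistic" resting
    cell); volume follows Cl- and is controlled by gCl."""
    bath = BathState(Na_o=145.0, K_o=5.0, Cl_o=150.0, osm_o=6.0)
    if pump == "neutral":
        cell = CellState(Na_i=16.3, K_i=158.3, Cl_i=45.3, An_i=86.2, vol=_VOL0)
        x, y, activity = 3, 3, 2.41e8
    elif pump == "electrogenic":
        cell = CellState(Na_i=18.5, K_i=160.0, Cl_i=25.7, An_i=101.9, vol=_VOL0)
        x, y, activity = 3, 2, 2.72e8
    else:
        raise ValueError("pump must be 'neutral' or 'electrogenic'")
    params = MembraneParams(
        gNa=8e9, gK=1.2e10, gCl=gCl, x=x, y=y, z=-1.5, tau=1.0,
        Rp=rate_for_activity(activity, cell.Na_i),
    )
    cell.Em = charge_balanced_Em(cell, bath, params)
    return Scenario(
        name="gna_step",
        cell=cell,
        bath=bath,
        params=params,
        settings=SimSettings(st=2.5e-4, t_end=20.0, record_every=100),
        changes=(
            TimedChange(0.0, "params.gNa", 2e9),
            TimedChange(10.0, "params.gNa", 8e9),
        ),
        description="temporary fourfold gNa reduction",
    )


def _cotransporter_base(realistic: bool, gCl: float) -> Scenario:
    if realistic:
        cell = CellState(Na_i=18.5, K_i=160.0, Cl_i=25.7, An_i=101.9, vol=_VOL0)
        bath = BathState(Na_o=145.0, K_o=5.0, Cl_o=150.0, osm_o=6.0)
        z = -1.5
    else:
        cell = CellState(Na_i=17.9, K_i=132.1, Cl_i=29.6, An_i=120.4, vol=_VOL0)
        bath = BathState(Na_o=145.0, K_o=5.0, Cl_o=150.0)
        z = -1.0
    params = MembraneParams(
        gNa=8e9, gK=1.2e10, gCl=gCl, x=3, y=2, z=z, tau=1.0,
        Rp=rate_for_activity(2.64e8, cell.Na_i),
    )
    cell.Em = charge_balanced_Em(cell, bath, params)
    return Scenario(
        name="",
        cell=cell,
        bath=bath,
        params=params,
        settings=SimSettings(st=5e-4, t_end=120.0, record_every=1000),
    )


def _nkcc_sweep(gCl: float = 1e8, realistic: bool = False) -> Scenario:
    """Base for sweeping the Na+,K+,2Cl- cotransporter rate."""
    sc = _cotransporter_base(realistic, gCl)
    sc.name = "nkcc_sweep"
    sc.description = "NKCC rate sweep base"
    return sc


def _kcc_sweep(gCl: float = 1e8, realistic: bool = False) -> Scenario:
    """Base for sweeping the K+,Cl- cotransporter rate."""
    sc = _cotransporter_base(realistic, gCl)
    sc.name = "kcc_sweep"
    sc.description = "KCC rate sweep base"
    return sc


def _realistic_rest(gCl: float) -> Scenario:
    cell = CellState(Na_i=18.5, K_i=160.0, Cl_i=25.7, An_i=101.9, vol=_VOL0)
    bath = BathState(Na_o=145.0, K_o=5.0, Cl_o=150.0, osm_o=6.0)
    params = MembraneParams(
        gNa=8e9, gK=1.2e10, gCl=gCl, x=3, y=2, z=-1.5, tau=1.0,
        Rp=rate_for_activity(2.72e8, cell.Na_i),
    )
    cell.Em = charge_balanced_Em(cell, bath, params)
    return Scenario(name="", cell=cell, bath=bath, params=params,
                    settings=SimSettings(st=5e-4, t_end=900.0, record_every=2000))


def _buildup_ext_neutral(gCl: float = 1e10) -> Scenario:
    """External neutral osmolyte ramp, 0.5 mM/s for 1 min (osmotic shock)."""
    sc = _realistic_rest(gCl)
    sc.name = "buildup_ext_neutral"
    sc.buildups = BuildupSchedule(bOso=Buildup(0.5, 0.0, 60.0))
    sc.description = "external neutral osmolyte buildup"
    return sc


def _buildup_ext_nacl(gCl: float = 1e10) -> Scenario:
    """External NaCl ramp, 0.25 mM/s for 1 min."""
    sc = _realistic_rest(gCl)
    sc.name = "buildup_ext_nacl"
    sc.buildups = BuildupSchedule(bNaCl=Buildup(0.25, 0.0, 60.0))
    sc.description = "external NaCl buildup"
    return sc


def _buildup_int_neutral(gCl: float = 1e10) -> Scenario:
    """Internal neutral osmolyte ramp, 0.05 mM/s for 10 min."""
    sc = _realistic_rest(gCl)
    sc.name = "buildup_int_neutral"
    sc.buildups = BuildupSchedule(bOsi=Buildup(0.05, 0.0, 600.0))
    sc.description = "internal neutral osmolyte buildup"
    return sc


def _buildup_int_anion(gCl: float = 1e10) -> Scenario:
    """Internal impermeant anion ramp (0.02 mM/s for 10 min) with the
    automatic -z Na+ accompaniment; the lone lasting effect is swelling."""
    sc = _realistic_rest(gCl)
    sc.name = "buildup_int_anion"
    sc.buildups = BuildupSchedule(bAn=Buildup(0.02, 0.0, 600.0))
    sc.description = "internal charged anion buildup with Na+ accompaniment"
    return sc


def _ka_sweep(osm_i: float = 60.0, osm_o: float = 0.0) -> Scenario:
    """Pump-free cation cell prepared at k_a = 1; vary the neutral
    osmolytes to scan the asymmetry coefficient."""
    cell = CellState(Na_i=145.0, K_i=5.0, Cl_i=30.0, An_i=60.0, osm_i=osm_i,
                     Em=0.0, vol=_VOL0)
    bath = BathState(Na_o=145.0, K_o=5.0, Cl_o=150.0, osm_o=osm_o)
    params = MembraneParams(gNa=1e10, gK=1e10, z=-2.0, tau=1.0)
    return Scenario(
        name="ka_sweep",
        cell=cell,
        bath=bath,
        params=params,
        settings=SimSettings(st=1e-3, t_end=30.0, record_every=1000),
        description="osmolarity-charge asymmetry sweep",
    )


_REGISTRY: dict[str, Callable[..., Scenario]] = {
    "donnan_novol": _donnan_novol,
    "donnan_water": _donnan_water,
    "water_perm_sweep": _water_perm_sweep,
    "double_donnan_na": _double_donnan_na,
    "double_donnan_k": _double_donnan_k,
    "pump_neutral_transient": _pump_neutral_transient,
    "pump_sweep": _pump_sweep,
    "gcl_opening": _gcl_opening,
    "gna_step": _gna_step,
    "nkcc_sweep": _nkcc_sweep,
    "kcc_sweep": _kcc_sweep,
    "buildup_ext_neutral": _buildup_ext_neutral,
    "buildup_ext_nacl": _buildup_ext_nacl,
    "buildup_int_neutral": _buildup_int_neutral,
    "buildup_int_anion": _buildup_int_anion,
    "ka_sweep": _ka_sweep,
}

SCENARIO_NAMES = tuple(sorted(_REGISTRY))


def list_scenarios() -> tuple[str, ...]:
    return SCENARIO_NAMES


def get_scenario(name: str, **variant) -> Scenario:
    """Build a registered scenario; keyword arguments select variants
    (e.g. ``get_scenario("gcl_opening", Cl_i=45.0)``)."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; registered: {', '.join(SCENARIO_NAMES)}"
        ) from None
    return factory(**variant)


def run_scenario(scenario: Scenario, t_end: float | None = None) -> Trajectory:
    """Integrate a scenario, applying its timed changes in order."""
    sc = scenario.copy()
    horizon = sc.settings.t_end if t_end is None else t_end
    changes = sorted(sc.changes, key=lambda ch: ch.t)
    if any(ch.t < 0 for ch in changes):
        raise ValueError("timed changes must not precede t = 0")
    segments: list[Trajectory] = []
    t_now = 0.0
    state, bath = sc.cell, sc.bath
    idx = 0
    boundaries = sorted({ch.t for ch in changes if 0.0 <= ch.t < horizon} | {horizon})
    for t_next in boundaries:
        while idx < len(changes) and changes[idx].t <= t_now:
            sc.apply_change(changes[idx])
            idx += 1
        if t_next > t_now:
            settings = replace(sc.settings, t_end=t_next - t_now)
            state.t = t_now
            seg = run(state, bath, sc.params, sc.buildups, settings)
            segments.append(seg)
            state, bath = seg.final_state, seg.final_bath
            t_now = t_next
    if not segments:  # zero horizon: a trajectory holding the initial state
        settings = replace(sc.settings, t_end=0.0)
        segments.append(run(state, bath, sc.params, sc.buildups, settings))
    return Trajectory.concatenate(segments)


def steady_state(
    scenario: Scenario, settings: SimSettings | None = None
) -> SteadyStateReport:
    """Apply all timed changes at once and integrate to the steady state.

    For scenarios whose changes all occur at t = 0 this is the resting
    state the published sweeps tabulate.  Scenarios with active buildups
    or changes at t > 0 must be driven with ``run_scenario`` instead.
    """
    sc = scenario.copy()
    if sc.buildups.is_active():
        raise ValueError("steady state undefined while buildups are active")
    for ch in sorted(sc.changes, key=lambda c: c.t):
        sc.apply_change(ch)
    return run_to_steady_state(sc.cell, sc.bath, sc.params, settings or sc.settings)


def sweep_steady_states(
    base: Scenario,
    param_path: str,
    values: Sequence[float],
    settings: SimSettings | None = None,
) -> pd.DataFrame:
    """One steady state per swept value of ``param_path``.

    Returns a table carrying both the swept rate and the realised
    transporter activities (the published curves plot activity, which
    differs from the rate by the concentration-dependent driving factor),
    together with the steady concentrations, Em (mV) and volume (percent
    of the scenario's initial volume).  Non-convergent points are flagged,
    not fatal.
    """
    rows = []
    for v in values:
        sc = base.copy()
        sc.changes = sc.changes + (TimedChange(0.0, param_path, v),)
        try:
            rep = steady_state(sc, settings)
            st = rep.state
            rows.append({
                "value": v, "converged": rep.converged,
                "Na_i_mM": st.Na_i, "K_i_mM": st.K_i, "Cl_i_mM": st.Cl_i,
                "An_i_mM": st.An_i, "osm_i_mM": st.osm_i,
                "Em_mV": st.Em * 1e3,
                "vol_pct": st.vol / base.cell.vol * 100.0,
                "Ap_per_s": rep.atp_per_sec,
                "reason": rep.reason,
            })
        except Exception as exc:  # pragma: no cover - defensive
            rows.append({"value": v, "converged": False, "reason": str(exc)})
    return pd.DataFrame(rows)


def find_rate_for_condition(
    base: Scenario,
    predicate: Callable[[SteadyStateReport], float],
    bracket: tuple[float, float],
    param_path: str = "params.Rp",
    settings: SimSettings | None = None,
    rtol: float = 1e-12,
    max_iter: int = 80,
) -> tuple[float, SteadyStateReport]:
    """Bisect a transporter rate until the steady-state predicate vanishes.

    ``predicate`` maps a steady-state report to a signed residual assumed
    monotone in the rate over the bracket (checked at the endpoints).
    Returns the rate and the steady state there.  Used, e.g., to find the
    pump rate at which Na_i and K_i meet, or reach prescribed values.
    """

    def eval_at(rate: float) -> tuple[float, SteadyStateReport]:
        sc = base.copy()
        sc.changes = sc.changes + (TimedChange(0.0, param_path, rate),)
        rep = steady_state(sc, settings)
        return predicate(rep), rep

    lo, hi = bracket
    if not (lo < hi):
        raise ValueError("bracket must satisfy lo < hi")
    f_lo, rep_lo = eval_at(lo)
    if f_lo == 0.0:
        return lo, rep_lo
    f_hi, rep_hi = eval_at(hi)
    if f_hi == 0.0:
        return hi, rep_hi
    if f_lo * f_hi > 0:
        raise ValueError(
            f"bracket does not straddle the condition: residuals "
            f"{f_lo:.3g} and {f_hi:.3g} share a sign"
        )
    rep_mid = rep_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid, rep_mid = eval_at(mid)
        if f_mid == 0.0 or (hi - lo) <= rtol * max(abs(lo), abs(hi)):
            return mid, rep_mid
        if f_mid * f_lo < 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi), rep_mid
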