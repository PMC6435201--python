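"""Configuration files, trajectory serialization and run summaries.

Configs are YAML or JSON mappings with a small documented schema::

    scenario: donnan_novol        # registry name (required)
    variant: {tau: "1 min"}       # keyword arguments of the scenario factory
    overrides:                    # direct parameter edits, applied at t = 0
        params.gCl: 1.0e10
        cell.Cl_i: 45.0
    st: "0.1 ms"                  # time step (number in s, or a unit string)
    t_end: "20 min"
    record_every: 1000

Times accept plain numbers (seconds) or strings with units ms/s/min/h.
Trajectories are written as RFC-4180 CSV with full-precision floats, so a
round trip through ``write_trajectory``/``read_trajectory`` is lossless.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .equilibrium import asymmetry_coefficient, donnan_residual
from .integrator import Trajectory
from .scenarios import Scenario, TimedChange, get_scenario

__all__ = [
    "RunConfig",
    "load_config",
    "build_scenario",
    "write_trajectory",
    "read_trajectory",
    "run_summary",
    "parse_time",
    "eng",
]

_TIME_UNITS = {"ms": 1e-3, "s": 1.0, "sec": 1.0, "min": 60.0, "h": 3600.0, "hr": 3600.0}


def parse_time(value) -> float:
    """Parse a time in seconds from a number or a string like '1 min'."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        parts = value.strip().split()
        if len(parts) == 1:
            # allow "60s" / "0.1ms" without a space
            for unit in sorted(_TIME_UNITS, key=len, reverse=True):
                if parts[0].endswith(unit):
                    num = parts[0][: -len(unit)]
                    return float(num) * _TIME_UNITS[unit]
            return float(parts[0])
        if len(parts) == 2 and parts[1] in _TIME_UNITS:
            return float(parts[0]) * _TIME_UNITS[parts[1]]
    raise ValueError(f"cannot parse time quantity {value!r}")


def eng(x: float, digits: int = 4) -> str:
    """Engineering notation with K/M/G suffixes (e.g. 3.314e8 -> '331.4M')."""
    if x == 0 or not math.isfinite(x):
        return str(x)
    sign = "-" if x < 0 else ""
    a = abs(x)
    for suffix, scale in (("G", 1e9), ("M", 1e6), ("K", 1e3)):
        if a >= scale:
            return f"{sign}{a / scale:.{digits}g}{suffix}"
    return f"{sign}{a:.{digits}g}"


_CONFIG_KEYS = {"scenario", "variant", "overrides", "st", "t_end", "record_every"}


@dataclass
class RunConfig:
    """A validated run request: scenario + variant + overrides + timing."""

    scenario: str
    variant: dict = field(default_factory=dict)
    overrides: dict = field(default_factory=dict)
    st: float | None = None
    t_end: float | None = None
    record_every: int | None = None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "scenario" not in raw:
        raise ValueError("config must name a 'scenario'")
    cfg = RunConfig(
        scenario=str(raw["scenario"]),
        variant=dict(raw.get("variant") or {}),
        overrides=dict(raw.get("overrides") or {}),
        st=parse_time(raw["st"]) if "st" in raw else None,
        t_end=parse_time(raw["t_end"]) if "t_end" in raw else None,
        record_every=int(raw["record_every"]) if "record_every" in raw else None,
    )
    # time-like variant entries ("1 min") are parsed here too
    for key in ("tau",):
        if key in cfg.variant and isinstance(cfg.variant[key], str):
            cfg.variant[key] = parse_time(cfg.variant[key])
    build_scenario(cfg)  # fail fast: must resolve to a valid scenario
    return cfg


def build_scenario(cfg: RunConfig) -> Scenario:
    """Materialise the scenario a config describes."""
    sc = get_scenario(cfg.scenario, **cfg.variant)
    for path, value in cfg.overrides.items():
        if isinstance(value, str):
            value = parse_time(value)
        sc.apply_change(TimedChange(0.0, path, float(value)))
    if cfg.st is not None:
        sc.settings.st = cfg.st
    if cfg.t_end is not None:
        sc.settings.t_end = cfg.t_end
    if cfg.record_every is not None:
        sc.settings.record_every = cfg.record_every
    return sc


_COLUMNS = [
    "t_s", "Na_i_mM", "K_i_mM", "Cl_i_mM", "An_i_mM", "osm_i_mM",
    "Em_mV", "vol_pct", "Ap_per_s", "Ankc_per_s", "Akc_per_s",
]


def write_trajectory(traj: Trajectory, path: str | Path, vol_ref: float | None = None) -> Path:
    """Write a trajectory as CSV (volume in percent of ``vol_ref``).

    Floats are written with shortest round-trip repr, so reading the file
    back reproduces the values exactly.
    """
    path = Path(path)
    df = traj.to_dataframe(vol_ref=vol_ref)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_COLUMNS)
        for row in df.itertuples(index=False):
            w.writerow([repr(float(v)) for v in row])
    return path


def read_trajectory(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps write -> read lossless to the last bit
    return pd.read_csv(path, float_precision="round_trip")


def run_summary(traj: Trajectory, scenario: Scenario) -> dict:
    """Structured end-of-run diagnostics.

    Alongside the final state, every analytic cross-check that applies is
    reported: the Donnan product residual, the asymmetry coefficient and
    its Em prediction, and the ATP rate.  Checks that are undefined for
    the configuration (e.g. Donnan residual with a closed Na+ channel)
    come out as None.
    """
    st = traj.final_state
    bath = traj.final_bath
    out = {
        "scenario": scenario.name,
        "t_s": st.t,
        "final": {
            "Na_i_mM": st.Na_i, "K_i_mM": st.K_i, "Cl_i_mM": st.Cl_i,
            "An_i_mM": st.An_i, "osm_i_mM": st.osm_i,
            "Em_mV": st.Em * 1e3,
            "vol_pct": st.vol / scenario.cell.vol * 100.0,
            "atp_total": st.atp_total,
        },
        "bath": {
            "Na_o_mM": bath.Na_o, "K_o_mM": bath.K_o,
            "Cl_o_mM": bath.Cl_o, "osm_o_mM": bath.osm_o,
        },
    }
    try:
        out["donnan_residual"] = donnan_residual(st, bath)
    except ValueError:
        out["donnan_residual"] = None
    try:
        rep = asymmetry_coefficient(st, bath, scenario.params)
        out["ka"] = rep.ka
        out["ka_predicted_Em_mV"] = rep.Em * 1e3
    except ValueError:
        out["ka"] = None
        out["ka_predicted_Em_mV"] = None
    out["Ap_per_s"] = float(traj.Ap[-1]) if len(traj) else None
    return out


def write_summary(summary: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return path
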