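"""JIT-compiled inner loop of the charge-difference integrator.

The kernel mirrors, number for number, the per-step composition implemented
readably in :mod:`chargediff.integrator` (fluxes -> mass/charge accumulation
-> Em update -> osmotic volume relaxation); the test suite asserts the two
paths agree to floating-point accuracy.  It exists only because simulated
horizons of tens of minutes at sub-millisecond steps are routine here.

State vector layout (index constants below):
``y = [Na_i, K_i, Cl_i, An_i, osm_i, Em, vol, t, atp_total, q_cum]`` with
concentrations in mM, Em in V, vol in L; ``q_cum`` is the cumulative
transferred charge in coulombs.  ``b = [Na_o, K_o, Cl_o, osm_o]`` (mM).
``p = [gNa, gK, gCl, c, T, Rp, hNa, x, y, Rnkc, Rkc, z, tau]``.
``bu`` is a 4x3 array of (rate mM/s, t_start, t_stop) rows in the order
bOso, bNaCl, bOsi, bAn.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# y indices
NA_I, K_I, CL_I, AN_I, OSM_I, EM, VOL, T, ATP, QCUM = range(10)
# b indices
NA_O, K_O, CL_O, OSM_O = range(4)
# p indices
GNA, GK, GCL, CAP, TEMP, RP, HNA, PX, PY, RNKC, RKC, Z, TAU = range(13)

R_GAS = 8.314
FARADAY = 96485.0
AVOGADRO = 6.02e23
E_CHARGE = 1.6e-19
CONC_FLOOR = 1e-9  # mM
WATER_TIGHT_TAU = 1e8  # s

STATUS_OK = 0
STATUS_OSMOTIC_COLLAPSE = 1  # chV <= 0: st far too large for this tau
STATUS_DOMAIN = 2  # open pathway with non-positive concentration
STATUS_STEP_UNDERFLOW = 3  # rejection halving exhausted


@njit(cache=False)
def _substep(y, b, p, bu, h):  # pragma: no cover - exercised via wrappers
    """Attempt one step of size h; commit and return status, or leave y, b
    untouched and return a rejection/fatal code.

    Returns (status, rejected, Ap, Ankc, Akc).
    """
    rtf = R_GAS * p[TEMP] / FARADAY
    em = y[EM]

    # --- set 1: fluxes from beginning-of-step state -----------------------
    na_fc = 0.0
    if p[GNA] > 0.0:
        if b[NA_O] <= 0.0 or y[NA_I] <= 0.0:
            return STATUS_DOMAIN, False, 0.0, 0.0, 0.0
        na_fc = p[GNA] * (rtf * math.log(b[NA_O] / y[NA_I]) - em)
    k_fc = 0.0
    if p[GK] > 0.0:
        if b[K_O] <= 0.0 or y[K_I] <= 0.0:
            return STATUS_DOMAIN, False, 0.0, 0.0, 0.0
        k_fc = p[GK] * (rtf * math.log(b[K_O] / y[K_I]) - em)
    cl_fc = 0.0
    if p[GCL] > 0.0:
        if b[CL_O] <= 0.0 or y[CL_I] <= 0.0:
            return STATUS_DOMAIN, False, 0.0, 0.0, 0.0
        cl_fc = p[GCL] * (rtf * math.log(b[CL_O] / y[CL_I]) + em)

    ap = 0.0
    if p[RP] > 0.0 and y[NA_I] > 0.0:
        r = y[NA_I] / (y[NA_I] + p[HNA])
        ap = p[RP] * r * r * r
    na_fp = -p[PX] * ap
    k_fp = p[PY] * ap

    ankc = 0.0
    if p[RNKC] > 0.0:
        if (
            b[NA_O] <= 0.0 or b[K_O] <= 0.0 or b[CL_O] <= 0.0
            or y[NA_I] <= 0.0 or y[K_I] <= 0.0 or y[CL_I] <= 0.0
        ):
            return STATUS_DOMAIN, False, 0.0, 0.0, 0.0
        ankc = p[RNKC] * math.log10(
            (b[NA_O] * b[K_O] * b[CL_O] * b[CL_O])
            / (y[NA_I] * y[K_I] * y[CL_I] * y[CL_I])
        )
    akc = 0.0
    if p[RKC] > 0.0:
        if b[K_O] <= 0.0 or b[CL_O] <= 0.0 or y[K_I] <= 0.0 or y[CL_I] <= 0.0:
            return STATUS_DOMAIN, False, 0.0, 0.0, 0.0
        akc = p[RKC] * math.log10((b[K_O] * b[CL_O]) / (y[K_I] * y[CL_I]))

    # --- set 2: amounts, concentrations, buildups, charge -----------------
    d_na = (na_fc + na_fp + ankc) * h
    d_k = (k_fc + k_fp + ankc + akc) * h
    d_cl = (cl_fc + 2.0 * ankc + akc) * h

    t_now = y[T]
    b_oso = bu[0, 0] if (bu[0, 1] <= t_now) and (t_now < bu[0, 2]) else 0.0
    b_nacl = bu[1, 0] if (bu[1, 1] <= t_now) and (t_now < bu[1, 2]) else 0.0
    b_osi = bu[2, 0] if (bu[2, 1] <= t_now) and (t_now < bu[2, 2]) else 0.0
    b_an = bu[3, 0] if (bu[3, 1] <= t_now) and (t_now < bu[3, 2]) else 0.0

    per_mM = 1e3 / (y[VOL] * AVOGADRO)  # ion count -> mM in current volume
    na_e = y[NA_I] + d_na * per_mM + b_an * h * (-p[Z])
    k_e = y[K_I] + d_k * per_mM
    cl_e = y[CL_I] + d_cl * per_mM
    an_e = y[AN_I] + b_an * h
    osm_e = y[OSM_I] + b_osi * h

    if (p[GNA] > 0.0 and na_e < CONC_FLOOR) or \
       (p[GK] > 0.0 and k_e < CONC_FLOOR) or \
       (p[GCL] > 0.0 and cl_e < CONC_FLOOR) or \
       na_e < 0.0 or k_e < 0.0 or cl_e < 0.0:
        return STATUS_OK, True, 0.0, 0.0, 0.0

    d_q = (d_na + d_k - d_cl) * E_CHARGE

    na_o_e = b[NA_O] + b_nacl * h
    cl_o_e = b[CL_O] + b_nacl * h
    osm_o_e = b[OSM_O] + b_oso * h

    # --- set 3: Em from charge, volume from osmotic imbalance -------------
    em_f = em + d_q / p[CAP]

    os_v = (na_e + k_e + cl_e + an_e + osm_e) / (na_o_e + b[K_O] + cl_o_e + osm_o_e)
    if p[TAU] > WATER_TIGHT_TAU:
        vo_r = 0.0
    elif p[TAU] < h:
        vo_r = 1.0 / h
    else:
        vo_r = 1.0 / p[TAU]
    ch_v = 1.0 - (1.0 - os_v) * vo_r * h
    if ch_v <= 0.0:
        return STATUS_OSMOTIC_COLLAPSE, False, 0.0, 0.0, 0.0

    y[NA_I] = na_e / ch_v
    y[K_I] = k_e / ch_v
    y[CL_I] = cl_e / ch_v
    y[AN_I] = an_e / ch_v
    y[OSM_I] = osm_e / ch_v
    y[VOL] = y[VOL] * ch_v
    y[EM] = em_f
    y[T] = t_now + h
    y[ATP] += ap * h
    y[QCUM] += d_q
    b[NA_O] = na_o_e
    b[CL_O] = cl_o_e
    b[OSM_O] = osm_o_e
    return STATUS_OK, False, ap, ankc, akc


@njit(cache=False)
def run_kernel(y, b, p, bu, st, n_steps, record_every, rec):
    """Advance n_steps fixed steps of size st, recording into ``rec``.

    ``rec`` is a (n_records, 11) array filled with rows
    (t, Na_i, K_i, Cl_i, An_i, osm_i, Em, vol, Ap, Ankc, Akc); row 0 is the
    initial state and one row is written every ``record_every`` steps.
    A step whose update would drive an intracellular concentration below the
    floor is retried with halved sub-steps (the within-step rejection rule).
    Returns (status, n_records_written).
    """
    r = 0
    nrec = rec.shape[0]

    def _record(idx, ap, ankc, akc):
        rec[idx, 0] = y[T]
        rec[idx, 1] = y[NA_I]
        rec[idx, 2] = y[K_I]
        rec[idx, 3] = y[CL_I]
        rec[idx, 4] = y[AN_I]
        rec[idx, 5] = y[OSM_I]
        rec[idx, 6] = y[EM]
        rec[idx, 7] = y[VOL]
        rec[idx, 8] = ap
        rec[idx, 9] = ankc
        rec[idx, 10] = akc

    ap = ankc = akc = 0.0
    if nrec > 0:
        # instantaneous activities at the initial state
        if p[RP] > 0.0 and y[NA_I] > 0.0:
            f = y[NA_I] / (y[NA_I] + p[HNA])
            ap = p[RP] * f * f * f
        if p[RNKC] > 0.0 and y[NA_I] > 0.0 and y[K_I] > 0.0 and y[CL_I] > 0.0:
            ankc = p[RNKC] * math.log10(
                (b[NA_O] * b[K_O] * b[CL_O] * b[CL_O])
                / (y[NA_I] * y[K_I] * y[CL_I] * y[CL_I])
            )
        if p[RKC] > 0.0 and y[K_I] > 0.0 and y[CL_I] > 0.0:
            akc = p[RKC] * math.log10((b[K_O] * b[CL_O]) / (y[K_I] * y[CL_I]))
        _record(0, ap, ankc, akc)
        r = 1

    for i in range(n_steps):
        remaining = st
        h = st
        tries = 0
        while remaining > 1e-12 * st:
            status, rejected, ap, ankc, akc = _substep(y, b, p, bu, h)
            if status != STATUS_OK:
                return status, r
            if rejected:
                h *= 0.5
                tries += 1
                if tries > 60:
                    return STATUS_STEP_UNDERFLOW, r
            else:
                remaining -= h
                if h > remaining:
                    h = remaining
        if record_every > 0 and (i + 1) % record_every == 0 and r < nrec:
            _record(r, ap, ankc, akc)
            r += 1
    return STATUS_OK, r


def pack_state(state) -> np.ndarray:
    return np.array(
        [state.Na_i, state.K_i, state.Cl_i, state.An_i, state.osm_i,
         state.Em, state.vol, state.t, state.atp_total, 0.0],
        dtype=np.float64,
    )


def pack_bath(bath) -> np.ndarray:
    return np.array([bath.Na_o, bath.K_o, bath.Cl_o, bath.osm_o], dtype=np.float64)


def pack_params(params) -> np.ndarray:
    return np.array(
        [params.gNa, params.gK, params.gCl, params.c, params.T,
         params.Rp, params.hNa, float(params.x), float(params.y),
         params.Rnkc, params.Rkc, params.z, params.tau],
        dtype=np.float64,
    )


def pack_buildups(schedule) -> np.ndarray:
    rows = []
    for bld in (schedule.bOso, schedule.bNaCl, schedule.bOsi, schedule.bAn):
        rows.append([bld.rate, bld.t_start, bld.t_stop])
    return np.array(rows, dtype=np.float64)
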