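"""Fixed-step fourth-order Runge-Kutta integration of the full model.

The integrator advances the five model states plus one auxiliary state,
the cumulative external volume ``V_ext = integral of (I_bleed + I_refill)``,
accumulated with the same RK4 stages so that blood-volume conservation
``V_A + V_V - V_ext = const`` holds to rounding error along the whole
trajectory and can be asserted directly.

The inner loop is a numba-compiled kernel operating on a packed parameter
vector; it implements exactly the same algebra as :func:`hemoshock.core.rhs`
(the readable reference field), and the test suite checks the two against
each other.  The bleed rate and its pressure guard are evaluated at every
RK4 substage time, not frozen per step, for consistency of the one-step
method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .errors import ParameterError, SimulationError
from .observations import Observations
from .parameters import ModelParameters, SimulationGrid
from .protocol import BleedProtocol, bleed_rate
from . import core
from .steady_state import SteadyState, initialize

__all__ = [
    "Trajectory", "simulate", "observe", "shock_index",
    "modified_shock_index", "msi_abnormal", "write_trajectory",
    "read_trajectory", "conservation_defect",
]

# ---------------------------------------------------------------------------
# packed parameter vector layout for the compiled kernel

_PV_FIELDS = (
    "k_VED0", "P_0LV", "k_ELV", "R_valve", "C_A", "C_V", "V_Aun",
    "nu_cut", "S_sat", "P_Aset",
    "nu_HR_min", "nu_HR_max", "C_PRSW_min", "C_PRSW_max",
    "R_TPR_min", "R_TPR_max", "V_Vun_Min", "V_Vun_Max",
    "k_Vcap", "P_CVP0_ref", "closed_loop", "S_0", "nu_HR0_max",
    # bleed protocol block
    "b_start", "b_end", "b_F", "b_shape", "b_lam", "b_guard",
)
_IX = {name: i for i, name in enumerate(_PV_FIELDS)}

_SHAPE_NONE, _SHAPE_CONST, _SHAPE_EXP = 0.0, 1.0, 2.0


def _pack(params: ModelParameters, protocol: Optional[BleedProtocol]) -> np.ndarray:
    pv = np.zeros(len(_PV_FIELDS))
    for name in _PV_FIELDS[:10]:
        pv[_IX[name]] = getattr(params, name)
    for name in _PV_FIELDS[10:19]:
        pv[_IX[name]] = getattr(params, name)
    pv[_IX["P_CVP0_ref"]] = params.P_CVP0 if params.P_CVP0 is not None else np.nan
    pv[_IX["closed_loop"]] = 1.0 if params.closed_loop else 0.0
    pv[_IX["S_0"]] = params.S_0
    pv[_IX["nu_HR0_max"]] = params.nu_HR0_max
    if protocol is None:
        pv[_IX["b_shape"]] = _SHAPE_NONE
        pv[_IX["b_guard"]] = np.nan
    else:
        pv[_IX["b_start"]] = protocol.t_bleedstart
        pv[_IX["b_end"]] = protocol.t_bleedend
        pv[_IX["b_F"]] = protocol.F_withdrawal
        pv[_IX["b_shape"]] = (_SHAPE_CONST if protocol.shape == "constant"
                              else _SHAPE_EXP)
        pv[_IX["b_lam"]] = (protocol.decay_rate
                            if protocol.shape == "exponential_decay" else 0.0)
        pv[_IX["b_guard"]] = (protocol.map_guard
                              if protocol.map_guard is not None else np.nan)
    return pv


@njit(cache=False)
def _deriv(t, y, pv, bleed_active):
    """Kernel twin of :func:`hemoshock.core.rhs` plus the V_ext quadrature.

    Returns NaNs (which abort the integration) where the reference
    implementation would raise: degenerate heart rate, non-positive
    diastole, ventricular volume below the zero-filling volume, or a
    non-positive argument to the filling-law logarithm.
    """
    bad = np.full(6, np.nan)
    V_ES, V_ED, V_A, V_V, S_E = y[0], y[1], y[2], y[3], y[4]

    s = min(max(S_E, 0.0), 1.0)
    nu_HR = s * (pv[11] - pv[10]) + pv[10]
    R_TPR = s * (pv[15] - pv[14]) + pv[14]
    C_PRSW = s * (pv[13] - pv[12]) + pv[12]
    V_Vun = (1.0 - s) * (pv[17] - pv[16]) + pv[16]

    P_A = (V_A - pv[6]) / pv[4]
    P_CVP = (V_V - V_Vun) / pv[5]

    if nu_HR < 1e-6:
        return bad
    t_diast = 1.0 / nu_HR - 0.8 / pv[22]
    if t_diast <= 0.0:
        return bad

    k0, P0, kE, Rv = pv[0], pv[1], pv[2], pv[3]
    if V_ED < k0 * (1.0 - 1e-12) or V_ES < k0 * (1.0 - 1e-12):
        return bad

    # end-systolic beat target (PRSW contraction law, floored at k_VED0)
    P_ED = P0 * math.expm1(kE * (V_ED - k0))
    if P_A > P_ED:
        ve = V_ED - C_PRSW * (V_ED - k0) / (P_A - P_ED)
        v_es_target = min(max(ve, k0), V_ED)
    else:
        v_es_target = k0

    # end-diastolic beat target (closed-form passive filling)
    P_ES = P0 * math.expm1(kE * (V_ES - k0))
    if P_CVP > P_ES:
        w_es = math.exp(-kE * (V_ES - k0))
        denom = P_CVP + P0
        w_eq = P0 / denom
        decay = math.exp(-kE * denom / Rv * t_diast)
        w = w_eq + (w_es - w_eq) * decay
        if w <= 0.0:
            return bad
        v_ed_target = k0 - math.log(w) / kE
    else:
        v_ed_target = V_ES

    sv = V_ED - V_ES
    if sv < -1e-12:
        return bad
    I_CO = max(sv, 0.0) * nu_HR
    I_C = (P_A - P_CVP) / R_TPR
    I_refill = 0.0 if pv[18] == 0.0 else pv[18] * (pv[19] - P_CVP)

    I_bleed = 0.0
    if bleed_active:
        if pv[26] == 1.0:
            I_bleed = -pv[25] / (pv[24] - pv[23])
        else:
            lam = pv[27]
            norm = -math.expm1(-lam * (pv[24] - pv[23]))
            I_bleed = -pv[25] * lam / norm * math.exp(-lam * (t - pv[23]))
        if not math.isnan(pv[28]) and P_A < pv[28]:
            I_bleed = 0.0

    if pv[20] == 1.0:
        k = math.log(99.0) / pv[8]
        S = 1.0 / (1.0 + math.exp(k * (P_A - pv[9])))
    else:
        S = pv[21]

    dV_A = I_CO - I_C
    out = np.empty(6)
    out[0] = (v_es_target - V_ES) * nu_HR
    out[1] = (v_ed_target - V_ED) * nu_HR
    out[2] = dV_A
    out[3] = -dV_A + I_bleed + I_refill
    out[4] = 2.0 * math.pi * pv[7] * (S - S_E)
    out[5] = I_bleed + I_refill
    return out


@njit(cache=False)
def _integrate(y0, t0, dt, n_steps, pv):
    out = np.empty((n_steps + 1, 6))
    out[0] = y0
    y = y0.copy()
    for i in range(n_steps):
        t = t0 + i * dt
        # bleed-window membership is decided once per step (by the step
        # midpoint) so no RK4 stage straddles the on/off discontinuity;
        # the rate profile itself is evaluated at each substage time
        mid = t + 0.5 * dt
        active = pv[26] != 0.0 and pv[23] <= mid <= pv[24]
        k1 = _deriv(t, y, pv, active)
        k2 = _deriv(t + 0.5 * dt, y + 0.5 * dt * k1, pv, active)
        k3 = _deriv(t + 0.5 * dt, y + 0.5 * dt * k2, pv, active)
        k4 = _deriv(t + dt, y + dt * k3, pv, active)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[i + 1] = y
        ok = True
        for j in range(6):
            if not np.isfinite(y[j]):
                ok = False
        if y[2] <= 0.0 or y[3] <= 0.0:
            ok = False
        if not ok:
            return out, i + 1
    return out, -1


# ---------------------------------------------------------------------------

#: trajectory column -> unit, in output order
COLUMN_UNITS = {
    "t": "min",
    "P_A": "mmHg", "P_CVP": "mmHg", "P_ED": "mmHg", "P_ES": "mmHg",
    "nu_HR": "1/min", "R_TPR": "mmHg*min/L", "C_PRSW": "mmHg",
    "V_Vun": "L", "S": "-", "S_E": "-",
    "I_C": "L/min", "I_CO": "L/min", "I_bleed": "L/min", "I_refill": "L/min",
    "V_A": "L", "V_V": "L", "V_ES": "L", "V_ED": "L", "V_S": "L",
    "V_tilde_ES": "L", "V_tilde_ED": "L",
    "t_Syst": "min", "t_Diast": "min", "V_ext": "L",
}


@dataclass
class Trajectory:
    """Dense simulation output: time grid, states and derived signals.

    ``frame`` holds one row per stored time with the state variables and
    every derived signal (pressures, effectors, flows, beat targets and
    cycle timings) recomputed algebraically from the states.
    """

    t: np.ndarray
    states: np.ndarray          # (N, 5): V_ES, V_ED, V_A, V_V, S_E
    external: np.ndarray        # (N,) cumulative integral of I_bleed + I_refill
    frame: pd.DataFrame
    steady: SteadyState
    params: ModelParameters     # with P_CVP0 resolved
    protocol: Optional[BleedProtocol]
    grid: SimulationGrid

    def at(self, time: float) -> pd.Series:
        """Derived signals linearly interpolated at a single time."""
        row = {}
        for col in self.frame.columns:
            row[col] = float(np.interp(time, self.t, self.frame[col].to_numpy()))
        return pd.Series(row)


def _derived_frame(t, states, external, params, protocol):
    V_ES, V_ED, V_A, V_V, S_E = states.T
    nu_HR, R_TPR, C_PRSW, V_Vun = core.effector_values(S_E, params)
    P_A = core.compartment_pressure(V_A, params.V_Aun, params.C_A)
    P_CVP = core.compartment_pressure(V_V, V_Vun, params.C_V)
    t_syst, t_diast = core.cycle_timing(nu_HR, params.nu_HR0_max)
    P_ED = core.passive_lv_pressure(V_ED, params)
    P_ES = core.passive_lv_pressure(V_ES, params)
    v_es_target = core.end_systolic_target(V_ED, P_A, C_PRSW, params)
    v_ed_target = core.end_diastolic_target(V_ES, P_CVP, t_diast, params)
    I_CO = core.cardiac_output(V_ED, V_ES, nu_HR)
    I_C = core.capillary_flow(P_A, P_CVP, R_TPR)
    I_refill = np.broadcast_to(
        np.asarray(core.transcapillary_refill(P_CVP, params)), t.shape)
    I_bleed = (bleed_rate(t, protocol, P_A) if protocol is not None
               else np.zeros_like(t))
    S = np.broadcast_to(np.asarray(core.sympathetic_activity(P_A, params)), t.shape)
    return pd.DataFrame({
        "t": t, "P_A": P_A, "P_CVP": P_CVP, "P_ED": P_ED, "P_ES": P_ES,
        "nu_HR": nu_HR, "R_TPR": R_TPR, "C_PRSW": C_PRSW, "V_Vun": V_Vun,
        "S": S, "S_E": S_E,
        "I_C": I_C, "I_CO": I_CO, "I_bleed": I_bleed, "I_refill": I_refill,
        "V_A": V_A, "V_V": V_V, "V_ES": V_ES, "V_ED": V_ED,
        "V_S": V_ED - V_ES,
        "V_tilde_ES": v_es_target, "V_tilde_ED": v_ed_target,
        "t_Syst": np.full_like(t, t_syst), "t_Diast": t_diast,
        "V_ext": external,
    })


def simulate(params: ModelParameters,
             protocol: Optional[BleedProtocol] = None,
             grid: SimulationGrid = SimulationGrid(),
             thin: int = 1) -> Trajectory:
    """Integrate the model from its ripple-free steady state.

    Classic fixed-step RK4 with step ``grid.t_delta``, fully deterministic.
    ``thin`` stores every ``thin``-th step (it must divide the step count);
    the integration itself always runs at ``t_delta``.  Raises
    :class:`SimulationError` with the offending time and state if the
    integration produces a non-finite or negative-volume state.
    """
    if thin < 1 or grid.n_steps % thin != 0:
        raise ParameterError(
            f"thin = {thin} must be a positive divisor of the "
            f"step count {grid.n_steps}")
    ss = initialize(params)
    if params.P_CVP0 is None:
        params = params.replace(P_CVP0=ss.P_CVP0)
    pv = _pack(params, protocol)
    y0 = np.append(ss.state_vector(), 0.0)
    out, bad = _integrate(y0, grid.t0, grid.t_delta, grid.n_steps, pv)
    if bad >= 0:
        t_bad = grid.t0 + bad * grid.t_delta
        raise SimulationError(
            f"integration aborted at t = {t_bad:.6g} min with state "
            f"{out[bad]}: non-finite or unphysical values",
            t=t_bad, state=out[bad])
    keep = out[::thin]
    t = grid.times()[::thin]
    frame = _derived_frame(t, keep[:, :5], keep[:, 5], params, protocol)
    return Trajectory(t=t, states=keep[:, :5], external=keep[:, 5],
                      frame=frame, steady=ss, params=params,
                      protocol=protocol, grid=grid)


def observe(traj: Trajectory, times, include_cvp: bool = False) -> Observations:
    """Sample P_A, nu_HR, I_CO (optionally P_CVP) at measurement times.

    Linear interpolation on the stored grid; times outside the simulated
    range are rejected.  Records before the bleed window are flagged as
    baseline when the trajectory has a protocol.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size and (times.min() < traj.t[0] - 1e-9
                       or times.max() > traj.t[-1] + 1e-9):
        raise ParameterError(
            f"observation times must lie within [{traj.t[0]}, {traj.t[-1]}] min")
    data = {"t": times}
    for col in ("P_A", "nu_HR", "I_CO") + (("P_CVP",) if include_cvp else ()):
        data[col] = np.interp(times, traj.t, traj.frame[col].to_numpy())
    frame = pd.DataFrame(data)
    if traj.protocol is not None:
        frame["baseline"] = times < traj.protocol.t_bleedstart
    else:
        frame["baseline"] = False
    return Observations(frame)


def shock_index(nu_HR, SBP):
    """Classic shock index HR/SBP (dimensionless)."""
    if np.any(np.asarray(SBP) <= 0):
        raise ParameterError(f"SBP must be positive, got {SBP}")
    return np.asarray(nu_HR, dtype=float) / SBP


def modified_shock_index(nu_HR, MAP):
    """Modified shock index HR/MAP, the triage marker for hypovolemic shock."""
    if np.any(np.asarray(MAP) <= 0):
        raise ParameterError(f"MAP must be positive, got {MAP}")
    return np.asarray(nu_HR, dtype=float) / MAP


def msi_abnormal(msi):
    """Flag MSI values outside the (0.7, 1.3) band that predicts mortality."""
    m = np.asarray(msi, dtype=float)
    return (m > 1.3) | (m < 0.7)


def conservation_defect(traj: Trajectory) -> np.ndarray:
    """Blood-volume budget residual ``V_A + V_V - V_ext - (V_A0 + V_V0)``.

    Identically zero for an exact integration; bounded by rounding error
    for the RK4 scheme because the veins receive exactly the negated
    arterial derivative plus the external terms.
    """
    total0 = traj.steady.V_A0 + traj.steady.V_V0
    return (traj.states[:, 2] + traj.states[:, 3]) - traj.external - total0


def write_trajectory(traj: Trajectory, path, columns=None, float_format=None):
    """Write a trajectory as CSV with a leading units comment line."""
    cols = list(columns) if columns is not None else list(COLUMN_UNITS)
    unknown = [c for c in cols if c not in traj.frame.columns]
    if unknown:
        raise ParameterError(f"unknown trajectory column(s) {unknown}")
    units = ",".join(f"{c}={COLUMN_UNITS.get(c, '?')}" for c in cols)
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        traj.frame[cols].to_csv(fh, index=False, float_format=float_format)


def read_trajectory(path) -> pd.DataFrame:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")
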