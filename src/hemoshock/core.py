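"""Algebraic relations and the coupled right-hand side of the 5-ODE model.

The state vector is ``y = (V_ES, V_ED, V_A, V_V, S_E)``:

* ``V_ES``, ``V_ED`` — end-systolic / end-diastolic ventricular volumes (L),
  each relaxing toward a beat target at the heart-rate timescale;
* ``V_A``, ``V_V`` — arterial / venous Windkessel volumes (L);
* ``S_E`` — the low-pass-filtered sympathetic drive in (0, 1).

All functions accept scalars or numpy arrays (broadcasting element-wise);
:func:`rhs` is the readable reference implementation of the derivative
field used by tests and small computations, while the production
integrator in :mod:`hemoshock.simulator` uses a compiled kernel that is
checked against it.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ParameterError, SimulationError
from .parameters import ModelParameters
from .protocol import BleedProtocol, bleed_rate

__all__ = [
    "sympathetic_activity", "effector_values", "compartment_pressure",
    "passive_lv_pressure", "cycle_timing", "end_systolic_target",
    "end_diastolic_target", "capillary_flow", "cardiac_output",
    "transcapillary_refill", "filling_equilibrium_volume", "rhs",
]

#: Heart rates below this (1/min) are rejected rather than producing an
#: unbounded diastolic interval.
NU_HR_FLOOR = 1e-6


def sympathetic_activity(P_A, params: ModelParameters):
    """Baroreflex sensor output S in (0, 1) for arterial pressure ``P_A``.

    Logistic in the pressure deviation from the set point, decreasing in
    ``P_A`` (falling pressure raises sympathetic drive), with S = 1/2 at
    the set point and 99% saturation at a deviation of ``S_sat`` either
    way.  In open loop (``S_F`` not the closed-loop flag) the sensor is
    bypassed and the constant drive ``S_0`` is returned.
    """
    if not params.closed_loop:
        return params.S_0 * np.ones_like(np.asarray(P_A, dtype=float))[()] \
            if np.ndim(P_A) else params.S_0
    k = math.log(99.0) / params.S_sat
    return 1.0 / (1.0 + np.exp(k * (np.asarray(P_A, dtype=float) - params.P_Aset)))[()]


def effector_values(S_E, params: ModelParameters):
    """Linear effector maps ``(nu_HR, R_TPR, C_PRSW, V_Vun)`` of the drive.

    Heart rate, peripheral resistance and contractility increase with
    sympathetic drive; the venous unstressed volume decreases (venous
    capacitance vessels contract under sympathetic activation, mobilizing
    blood into the stressed pool).
    """
    s = np.asarray(S_E, dtype=float)
    if np.any((s < 0.0) | (s > 1.0)):
        raise ParameterError(f"S_E must lie in [0, 1], got {S_E}")
    nu_HR = s * (params.nu_HR_max - params.nu_HR_min) + params.nu_HR_min
    R_TPR = s * (params.R_TPR_max - params.R_TPR_min) + params.R_TPR_min
    C_PRSW = s * (params.C_PRSW_max - params.C_PRSW_min) + params.C_PRSW_min
    V_Vun = (1.0 - s) * (params.V_Vun_Max - params.V_Vun_Min) + params.V_Vun_Min
    return nu_HR[()], R_TPR[()], C_PRSW[()], V_Vun[()]


def compartment_pressure(V, V_un, C):
    """Windkessel pressure ``(V - V_un)/C`` of a linear compliance (mmHg)."""
    if not C > 0:
        raise ParameterError(f"compliance must be positive, got {C}")
    return (np.asarray(V, dtype=float) - V_un) / C


def passive_lv_pressure(V, params: ModelParameters):
    """Passive ventricular pressure ``P_0LV * (exp(k_ELV*(V - k_VED0)) - 1)``.

    Defined for ``V >= k_VED0`` (zero pressure at the zero-filling volume,
    strictly increasing and convex above it); the negative-pressure branch
    is outside this model's operating range and is rejected.
    """
    v = np.asarray(V, dtype=float)
    if np.any(v < params.k_VED0 * (1.0 - 1e-12)):
        raise ParameterError(
            f"passive filling law requires V >= k_VED0 = {params.k_VED0}, got {V}")
    return params.P_0LV * np.expm1(params.k_ELV * (v - params.k_VED0))[()]


def cycle_timing(nu_HR, nu_HR0_max):
    """Systolic and diastolic durations ``(t_Syst, t_Diast)`` in minutes.

    Systole occupies a fixed fraction of the shortest possible cycle,
    ``t_Syst = 0.8 / nu_HR0_max``; diastole is the remainder of the
    current cycle, ``1/nu_HR - t_Syst``, and must stay positive.
    """
    nu = np.asarray(nu_HR, dtype=float)
    if np.any(nu < NU_HR_FLOOR):
        raise ParameterError(f"heart rate below {NU_HR_FLOOR}/min: {nu_HR}")
    t_syst = 0.8 / nu_HR0_max
    t_diast = 1.0 / nu - t_syst
    if np.any(t_diast <= 0.0):
        raise ParameterError(
            f"non-positive diastolic duration at nu_HR = {nu_HR} "
            f"(nu_HR0_max = {nu_HR0_max})")
    return t_syst, t_diast[()]


def end_systolic_target(V_ED, P_A, C_PRSW, params: ModelParameters):
    """Beat target for end-systolic volume from the PRSW contraction law.

    Stroke work is linear in the recruited preload ``V_ED - k_VED0`` with
    slope ``C_PRSW``; ejecting against the arterial-minus-end-diastolic
    pressure difference gives the stroke volume and hence the target.
    When the ventricle cannot open the outflow valve (``P_A <= P_ED``) or
    the PRSW term exceeds the available volume, the target is floored at
    ``k_VED0``; it never exceeds ``V_ED``.
    """
    v_ed = np.asarray(V_ED, dtype=float)
    p_ed = passive_lv_pressure(v_ed, params)
    p_a = np.asarray(P_A, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ejected = C_PRSW * (v_ed - params.k_VED0) / (p_a - p_ed)
        target = np.clip(v_ed - ejected, params.k_VED0, v_ed)
    return np.where(p_a > p_ed, target, params.k_VED0)[()]


def filling_equilibrium_volume(P_CVP, params: ModelParameters):
    """Ventricular volume at which passive pressure balances ``P_CVP``."""
    arg = np.asarray(P_CVP, dtype=float) / params.P_0LV + 1.0
    if np.any(arg <= 0.0):
        raise ParameterError(
            f"no filling equilibrium for P_CVP = {P_CVP} (P_0LV = {params.P_0LV})")
    return params.k_VED0 + np.log(arg) / params.k_ELV


def end_diastolic_target(V_ES, P_CVP, t_Diast, params: ModelParameters):
    """Beat target for end-diastolic volume: passive filling for ``t_Diast``.

    Closed-form solution of the filling law
    ``dV/dt = (P_CVP - P_LV(V)) / R_valve`` started from ``V_ES`` and
    evaluated at ``t_Diast``.  Substituting ``w = exp(-k_ELV*(V - k_VED0))``
    linearizes the ODE, giving

        w(t) = w_eq + (w_ES - w_eq) * exp(-k_ELV*(P_CVP + P_0LV)/R_valve * t)

    with ``w_eq = P_0LV/(P_CVP + P_0LV)``; the target is
    ``k_VED0 - log(w)/k_ELV``.  Filling only occurs when the mitral valve
    is open (``P_CVP > P_ES``); otherwise the volume stays at ``V_ES``.
    The target increases with ``t_Diast`` and ``P_CVP`` and is bounded by
    the filling-equilibrium volume.
    """
    v_es = np.asarray(V_ES, dtype=float)
    p_cvp = np.asarray(P_CVP, dtype=float)
    t_d = np.asarray(t_Diast, dtype=float)
    if np.any(t_d <= 0.0):
        raise ParameterError(f"t_Diast must be positive, got {t_Diast}")
    p_es = passive_lv_pressure(v_es, params)

    w_es = np.exp(-params.k_ELV * (v_es - params.k_VED0))
    denom = p_cvp + params.P_0LV
    # Valve-open branch requires P_CVP > P_ES >= 0, hence denom > 0 there;
    # clamp the closed branch to avoid spurious divide warnings.
    safe = np.where(denom > 0.0, denom, 1.0)
    w_eq = params.P_0LV / safe
    decay = np.exp(-params.k_ELV * safe / params.R_valve * t_d)
    w = w_eq + (w_es - w_eq) * decay
    open_valve = p_cvp > p_es
    if np.any(open_valve & (w <= 0.0)):
        raise ParameterError(
            "passive filling law produced a non-positive exponential argument "
            f"(V_ES = {V_ES}, P_CVP = {P_CVP}, t_Diast = {t_Diast}); "
            "the parameter regime is invalid")
    filled = params.k_VED0 - np.log(np.where(w > 0.0, w, 1.0)) / params.k_ELV
    return np.where(open_valve, filled, v_es)[()]


def capillary_flow(P_A, P_CVP, R_TPR):
    """Arterio-venous capillary flow ``(P_A - P_CVP)/R_TPR`` (L/min)."""
    if not np.all(np.asarray(R_TPR) > 0):
        raise ParameterError(f"R_TPR must be positive, got {R_TPR}")
    return (np.asarray(P_A, dtype=float) - P_CVP) / R_TPR


def cardiac_output(V_ED, V_ES, nu_HR):
    """Cardiac output: stroke volume times heart rate (L/min)."""
    sv = np.asarray(V_ED, dtype=float) - V_ES
    if np.any(sv < -1e-12):
        raise ParameterError(f"V_ED must be >= V_ES, got V_ED={V_ED}, V_ES={V_ES}")
    return np.maximum(sv, 0.0) * nu_HR


def transcapillary_refill(P_CVP, params: ModelParameters):
    """Interstitial-to-venous refill flow ``k_Vcap * (P_CVP0 - P_CVP)``.

    Positive when central venous pressure has fallen below its resting
    reference (interstitial fluid enters the vascular space).  The
    reference ``P_CVP0`` is the steady-state venous pressure fixed at
    initialization.  ``k_Vcap = 0`` disables refill entirely.
    """
    if params.k_Vcap == 0.0:
        return np.zeros_like(np.asarray(P_CVP, dtype=float))[()]
    if params.P_CVP0 is None:
        raise ParameterError(
            "transcapillary refill requires the interstitial reference P_CVP0; "
            "run steady-state initialization first")
    return params.k_Vcap * (params.P_CVP0 - np.asarray(P_CVP, dtype=float))[()]


def rhs(t, y, params: ModelParameters, protocol: BleedProtocol | None = None,
        bleed_active=None):
    """Derivative field of the five-state model at time ``t`` (min).

    ``y = (V_ES, V_ED, V_A, V_V, S_E)``.  Both ventricular volumes relax
    toward their beat targets at rate ``nu_HR``; arterial volume gains
    cardiac output and loses capillary flow; venous volume balances the
    arterial change plus the external terms (bleeding, refill); the
    filtered drive follows the sensor through a first-order low-pass with
    cut-off ``nu_cut``.  With no protocol the external bleed term is zero.
    ``bleed_active`` optionally forces bleed-window membership (see
    :func:`hemoshock.protocol.bleed_rate`).  By construction
    ``d(V_A + V_V)/dt = I_bleed + I_refill``.
    """
    y = np.asarray(y, dtype=float)
    V_ES, V_ED, V_A, V_V, S_E = y
    try:
        nu_HR, R_TPR, C_PRSW, V_Vun = effector_values(S_E, params)
        P_A = compartment_pressure(V_A, params.V_Aun, params.C_A)
        P_CVP = compartment_pressure(V_V, V_Vun, params.C_V)
        _, t_diast = cycle_timing(nu_HR, params.nu_HR0_max)

        v_es_target = end_systolic_target(V_ED, P_A, C_PRSW, params)
        v_ed_target = end_diastolic_target(V_ES, P_CVP, t_diast, params)

        I_CO = cardiac_output(V_ED, V_ES, nu_HR)
        I_C = capillary_flow(P_A, P_CVP, R_TPR)
        I_refill = float(transcapillary_refill(P_CVP, params))
        I_bleed = (bleed_rate(t, protocol, P_A, within_window=bleed_active)
                   if protocol is not None else 0.0)
        S = sympathetic_activity(P_A, params)
    except ParameterError as exc:
        raise SimulationError(
            f"derivative evaluation failed at t = {t} min: {exc}",
            t=t, state=y) from exc

    dV_A = I_CO - I_C
    return np.array([
        (v_es_target - V_ES) * nu_HR,
        (v_ed_target - V_ED) * nu_HR,
        dV_A,
        -dV_A + I_bleed + I_refill,
        2.0 * math.pi * params.nu_cut * (S - S_E),
    ])
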