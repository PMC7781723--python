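"""Inverse problem: least-squares calibration and parameter sensitivity.

The cost is the normalized sum of squared relative residuals over the
observed channels,

    J(theta) = sum_t [ ((P_A,exp - P_A,sim)/P_A,exp)^2
                     + ((nu_exp - nu_sim)/nu_exp)^2
                     + ((I_exp - I_sim)/I_exp)^2 ],

minimized with the derivative-free Nelder-Mead simplex over a named
subset of the sixteen free parameters (full 16-parameter fits are badly
under-determined on sparse data, so fitting a frozen-complement subset is
the intended mode).  ``J_nobase`` is the same sum restricted to records
after the start of bleeding, since baseline scatter inflates the cost
without informing the dynamics.

Sensitivity of a parameter xi is the one-at-a-time forward-difference
relative change of the per-channel normalized mean-squared error under a
+10% perturbation,

    S_xi ~= (E(1.1 xi) - E(xi)) / 0.1,

computed separately for I_CO, P_A and nu_HR and summed for the total;
parameters are reported ranked by total.  E is taken as the mean squared
relative residual per channel (J restricted to one channel divided by N);
any fixed normalization rescales all sensitivities uniformly and leaves
the ranking unchanged.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import HemoshockError, ObservationError, ParameterError
from .observations import CHANNELS, Observations
from .parameters import ModelParameters, SimulationGrid
from .protocol import BleedProtocol
from .simulator import observe, simulate

__all__ = [
    "FIT_PARAMETERS", "CalibrationResult", "cost", "calibrate",
    "sensitivity", "sensitivity_report", "write_calibration_result",
    "write_sensitivity_report",
]

logger = logging.getLogger(__name__)

#: The sixteen calibratable parameters (everything except the heart-law
#: constants, the subject's blood volume and the protocol timings).
FIT_PARAMETERS = (
    "R_valve", "C_A", "C_V", "V_Aun", "nu_cut", "S_sat", "P_Aset",
    "nu_HR_min", "nu_HR_max", "C_PRSW_min", "C_PRSW_max",
    "R_TPR_min", "R_TPR_max", "V_Vun_Min", "V_Vun_Max", "k_Vcap",
)

#: Finite cost returned when a candidate parameter set cannot be simulated,
#: so the simplex can move away from it.
FAILED_COST = 1e9


def _check_theta(theta: Dict[str, float]) -> None:
    unknown = set(theta) - set(FIT_PARAMETERS)
    if unknown:
        raise ParameterError(
            f"unknown fit parameter(s) {sorted(unknown)}; "
            f"valid names: {FIT_PARAMETERS}")


def _merged(theta: Dict[str, float], params: ModelParameters) -> ModelParameters:
    return params.replace(**theta)


def _residual_matrix(theta, params, protocol, grid, obs: Observations):
    """(N, 3) relative residuals in channel order P_A, nu_HR, I_CO."""
    merged = _merged(theta, params)
    traj = simulate(merged, protocol, grid)
    sim = observe(traj, obs.t)
    res = np.empty((len(obs), len(CHANNELS)))
    for j, ch in enumerate(CHANNELS):
        exp = obs.channel(ch)
        res[:, j] = (exp - sim.channel(ch)) / exp
    return res


def cost(theta: Dict[str, float],
         params: ModelParameters,
         protocol: Optional[BleedProtocol],
         grid: SimulationGrid,
         obs: Observations):
    """Evaluate the calibration cost; returns ``(J, J_nobase)``.

    ``theta`` maps fit-parameter names to candidate values merged into
    ``params`` for the simulation.  All measured values must be strictly
    positive (they normalize the residuals).
    """
    _check_theta(theta)
    if len(obs) == 0:
        raise ObservationError("cost requires at least one observation record")
    res = _residual_matrix(theta, params, protocol, grid, obs)
    sq = res ** 2
    J = float(sq.sum())
    J_nobase = float(sq[~obs.baseline].sum())
    return J, J_nobase


@dataclass
class CalibrationResult:
    """Outcome of a Nelder-Mead calibration run."""

    theta: Dict[str, float]
    J: float
    J_nobase: float
    iterations: int
    n_evaluations: int
    converged: bool
    underdetermined: bool
    theta_init: Dict[str, float] = field(default_factory=dict)
    options: Dict[str, float] = field(default_factory=dict)


def calibrate(obs: Observations,
              params: ModelParameters,
              protocol: Optional[BleedProtocol],
              grid: SimulationGrid,
              theta_init: Dict[str, float],
              options: Optional[Dict] = None) -> CalibrationResult:
    """Nelder-Mead minimization of the cost over the ``theta_init`` subset.

    Strictly positive initial values are searched in log space (keeping
    them positive without constraints); zero-valued entries are searched
    linearly.  Candidate sets violating the parameter invariants or
    breaking the simulation receive a large finite penalty.  Deterministic
    for fixed inputs; non-convergence is reported through the ``converged``
    flag with the best point found still returned.
    """
    _check_theta(theta_init)
    if not theta_init:
        raise ParameterError("theta_init must name at least one fit parameter")
    try:
        _merged(theta_init, params)
    except ParameterError as exc:
        raise ParameterError(f"theta_init violates parameter constraints: {exc}")
    opts = {"xatol": 1e-6, "fatol": 1e-6, "maxiter": 2000, "adaptive": True,
            "initial_step": 0.1}
    opts.update(options or {})

    # search in log-relative coordinates for strictly positive parameters
    # (keeping them positive without constraints) and in shifted linear
    # coordinates otherwise; x = 0 decodes exactly to theta_init
    names = list(theta_init)
    log_mask = np.array([theta_init[n] > 0 for n in names])
    ref = np.array([theta_init[n] for n in names])
    x0 = np.zeros(len(names))

    def decode(x):
        return {n: float(r * math.exp(v) if m else r + v)
                for n, v, m, r in zip(names, x, log_mask, ref)}

    n_fail = 0

    def objective(x):
        nonlocal n_fail
        theta = decode(x)
        try:
            J, _ = cost(theta, params, protocol, grid, obs)
        except HemoshockError as exc:
            n_fail += 1
            logger.warning("penalized candidate %s: %s", theta, exc)
            return FAILED_COST
        return J

    # explicit initial simplex: each vertex perturbs one coordinate by
    # initial_step (~10% relative for log-transformed parameters)
    simplex = np.zeros((len(names) + 1, len(names)))
    simplex[1:] = np.eye(len(names)) * opts["initial_step"]
    result = minimize(objective, x0, method="Nelder-Mead",
                      options={"xatol": opts["xatol"], "fatol": opts["fatol"],
                               "maxiter": opts["maxiter"],
                               "adaptive": opts["adaptive"],
                               "initial_simplex": simplex})
    theta_hat = decode(result.x)
    try:
        J, J_nobase = cost(theta_hat, params, protocol, grid, obs)
    except HemoshockError:
        # best point itself unsimulatable (can only happen if everything failed)
        J, J_nobase = FAILED_COST, FAILED_COST
    # best-evaluated-point semantics: the start is itself a candidate, and
    # the simplex vertex returned for it can drift by rounding
    try:
        J_init, J_nobase_init = cost(theta_init, params, protocol, grid, obs)
        if J_init <= J:
            theta_hat = {n: float(v) for n, v in theta_init.items()}
            J, J_nobase = J_init, J_nobase_init
    except HemoshockError:
        pass
    underdetermined = 3 * len(obs) < len(names) or len(obs) < 3
    if underdetermined:
        warnings.warn(
            f"{len(obs)} observation record(s) for {len(names)} fitted "
            "parameter(s): the fit is under-determined", stacklevel=2)
    return CalibrationResult(
        theta=theta_hat, J=J, J_nobase=J_nobase,
        iterations=int(result.nit), n_evaluations=int(result.nfev),
        converged=bool(result.success), underdetermined=underdetermined,
        theta_init=dict(theta_init), options=opts)


def _channel_mse(theta, params, protocol, grid, obs) -> Dict[str, float]:
    res = _residual_matrix(theta, params, protocol, grid, obs)
    return {ch: float(np.mean(res[:, j] ** 2)) for j, ch in enumerate(CHANNELS)}


def sensitivity(name: str,
                theta: Dict[str, float],
                params: ModelParameters,
                protocol: Optional[BleedProtocol],
                grid: SimulationGrid,
                obs: Observations,
                step: float = 0.1) -> Dict[str, float]:
    """One-at-a-time sensitivity of parameter ``name`` around ``theta``.

    Returns per-channel entries (keys ``P_A``, ``nu_HR``, ``I_CO``) and
    their sum under ``total``.  A zero-valued parameter admits no relative
    perturbation; its sensitivity is reported as zero with a warning.
    """
    if name not in FIT_PARAMETERS:
        raise ParameterError(f"unknown fit parameter {name!r}")
    base_theta = dict(theta)
    xi = base_theta.get(name, getattr(params, name))
    if xi == 0:
        warnings.warn(
            f"parameter {name} is zero: a relative perturbation is degenerate, "
            "reporting zero sensitivity", stacklevel=2)
        return {**{ch: 0.0 for ch in CHANNELS}, "total": 0.0}
    e0 = _channel_mse(base_theta, params, protocol, grid, obs)
    e1 = _channel_mse({**base_theta, name: xi * (1.0 + step)},
                      params, protocol, grid, obs)
    out = {ch: (e1[ch] - e0[ch]) / step for ch in CHANNELS}
    out["total"] = sum(out[ch] for ch in CHANNELS)
    return out


def sensitivity_report(params: ModelParameters,
                       protocol: Optional[BleedProtocol],
                       grid: SimulationGrid,
                       obs: Observations,
                       theta: Optional[Dict[str, float]] = None,
                       names: Sequence[str] = FIT_PARAMETERS,
                       step: float = 0.1) -> pd.DataFrame:
    """Ranked one-at-a-time sensitivities for all (or selected) parameters.

    Columns: ``rank, parameter, I_CO, P_A, nu_HR, total``, sorted by
    descending total (most to least influential).
    """
    theta = dict(theta or {})
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-valued parameters report 0
        for name in names:
            s = sensitivity(name, theta, params, protocol, grid, obs, step=step)
            rows.append({"parameter": name, "I_CO": s["I_CO"], "P_A": s["P_A"],
                         "nu_HR": s["nu_HR"], "total": s["total"]})
    frame = pd.DataFrame(rows).sort_values(
        "total", ascending=False, kind="mergesort").reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame[["rank", "parameter", "I_CO", "P_A", "nu_HR", "total"]]


def write_calibration_result(result: CalibrationResult, path) -> None:
    """Write a two-column (name, value) table of the fitted parameters."""
    rows = [("parameter", "value")]
    rows += [(k, repr(v)) for k, v in result.theta.items()]
    rows += [("J", repr(result.J)), ("J_nobase", repr(result.J_nobase)),
             ("iterations", str(result.iterations)),
             ("n_evaluations", str(result.n_evaluations)),
             ("converged", str(int(result.converged))),
             ("underdetermined", str(int(result.underdetermined)))]
    with open(path, "w") as fh:
        for k, v in rows:
            fh.write(f"{k},{v}\n")


def write_sensitivity_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, index=False)
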