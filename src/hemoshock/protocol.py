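"""Controlled-hemorrhage protocols: the external withdrawal rate I_bleed(t).

The experiment being emulated withdraws a prescribed fraction of the
blood volume (about a third) over a 30-60 min window, fast at first and
tapering off, while pausing whenever mean arterial pressure falls below a
safety threshold.  Withdrawal is represented as a continuous, negative
venous in-flow; its time integral over the window equals the total
withdrawn volume whenever the pressure guard never triggers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ParameterError

SHAPES = ("constant", "exponential_decay")


@dataclass(frozen=True)
class BleedProtocol:
    """Hemorrhage window, total volume, rate shape and optional MAP guard.

    ``shape = "exponential_decay"`` (the default) gives a withdrawal rate
    proportional to ``exp(-lambda*(t - t_bleedstart))`` with
    ``lambda = ln 2 / decay_halflife``, normalized so the window integral
    equals ``F_withdrawal``; the half-life defaults to a third of the
    window, making the initial rate several times the mean.  ``shape =
    "constant"`` spreads the volume uniformly.  If ``map_guard`` is set,
    withdrawal is suspended (rate 0) whenever the current mean arterial
    pressure is below the guard.
    """

    t_bleedstart: float                    # min
    t_bleedend: float                      # min
    F_withdrawal: float                    # L, total volume to withdraw
    shape: str = "exponential_decay"
    decay_halflife: Optional[float] = None  # min; default window/3
    map_guard: Optional[float] = None       # mmHg; None disables the guard

    def __post_init__(self):
        if not self.t_bleedstart < self.t_bleedend:
            raise ParameterError(
                f"require t_bleedstart < t_bleedend, got "
                f"{self.t_bleedstart} >= {self.t_bleedend}")
        if self.F_withdrawal < 0:
            raise ParameterError(
                f"F_withdrawal must be >= 0, got {self.F_withdrawal}")
        if self.shape not in SHAPES:
            raise ParameterError(
                f"unknown bleed shape {self.shape!r}; choose from {SHAPES}")
        if self.shape == "exponential_decay" and self.decay_halflife is None:
            object.__setattr__(self, "decay_halflife", self.window / 3.0)
        if self.decay_halflife is not None and not self.decay_halflife > 0:
            raise ParameterError(
                f"decay_halflife must be positive, got {self.decay_halflife}")
        if self.map_guard is not None and not self.map_guard > 0:
            raise ParameterError(
                f"map_guard must be positive, got {self.map_guard}")

    @property
    def window(self) -> float:
        """Length of the bleed window in minutes."""
        return self.t_bleedend - self.t_bleedstart

    @property
    def decay_rate(self) -> float:
        """Exponential rate constant lambda (1/min) for the decaying shape."""
        if self.shape != "exponential_decay":
            raise ParameterError("decay_rate is defined only for exponential_decay")
        return math.log(2.0) / self.decay_halflife


def bleed_rate(t, protocol: BleedProtocol, current_MAP=None,
               within_window=None):
    """Withdrawal rate I_bleed(t) in L/min (negative inside the window).

    Zero outside ``[t_bleedstart, t_bleedend]`` and whenever the guard is
    set and ``current_MAP`` is below it.  Accepts scalar or array ``t``
    (with ``current_MAP`` broadcasting against it).

    ``within_window`` overrides the pointwise window test (the rate
    profile is still evaluated at ``t``).  The integrator uses this to
    decide window membership once per step, so that no Runge-Kutta stage
    of a single step straddles the switch-on/off discontinuity.
    """
    t = np.asarray(t, dtype=float)
    if within_window is None:
        inside = (t >= protocol.t_bleedstart) & (t <= protocol.t_bleedend)
    else:
        inside = within_window
    if protocol.shape == "constant":
        magnitude = protocol.F_withdrawal / protocol.window
        rate = np.where(inside, -magnitude, 0.0)
    else:
        lam = protocol.decay_rate
        norm = -math.expm1(-lam * protocol.window)  # 1 - e^{-lam*T}
        peak = protocol.F_withdrawal * lam / norm
        with np.errstate(over="ignore"):
            rate = np.where(
                inside, -peak * np.exp(-lam * (t - protocol.t_bleedstart)), 0.0)
    if protocol.map_guard is not None and current_MAP is not None:
        rate = np.where(np.asarray(current_MAP) < protocol.map_guard, 0.0, rate)
    return rate[()]
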