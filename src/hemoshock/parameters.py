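"""Model parameters and simulation grid.

All quantities use the model's native units: volumes in L, pressures in
mmHg, time in min, flows in L/min, rates (heart rate, cut-off frequency)
in 1/min, compliances in L/mmHg, resistances in mmHg·min/L.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

from .errors import ParameterError

#: Flag value selecting closed-loop baroreflex operation.
CLOSED_LOOP = -1


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the single-ventricle hemorrhagic-shock model.

    The heart is described by the preload-recruitable-stroke-work (PRSW)
    contraction law and a passive exponential pressure-volume filling law
    (constants ``k_VED0``, ``P_0LV``, ``k_ELV`` from Glower's canine
    measurements); arteries and veins are linear Windkessel compartments;
    the baroreflex is a logistic pressure sensor driving four linearly
    interpolated effectors through a first-order low-pass filter; and
    transcapillary refill returns interstitial fluid to the veins at a rate
    proportional to the central-venous pressure deficit. Setting
    ``k_Vcap = 0`` recovers the original refill-free (Zenker) model.
    """

    # Heart: passive filling law and valve resistance
    k_VED0: float          # L, ventricular volume at zero filling pressure
    P_0LV: float           # mmHg, scale of the passive pressure-volume law
    k_ELV: float           # 1/L, stiffness of the passive pressure-volume law
    R_valve: float         # mmHg·min/L, resistance opposing ventricular filling

    # Windkessel compartments
    C_A: float             # L/mmHg, arterial compliance
    C_V: float             # L/mmHg, venous compliance
    V_Aun: float           # L, arterial unstressed volume
    V_total: float         # L, total (vascular) blood volume

    # Baroreflex sensor and low-pass filter
    nu_cut: float          # 1/min, low-pass cut-off frequency
    S_sat: float           # mmHg, deviation from set point giving 99% saturation
    P_Aset: float          # mmHg, arterial pressure set point

    # Effector bounds (linear maps of the filtered sympathetic drive)
    nu_HR_min: float       # 1/min
    nu_HR_max: float       # 1/min
    C_PRSW_min: float      # mmHg
    C_PRSW_max: float      # mmHg
    R_TPR_min: float       # mmHg·min/L
    R_TPR_max: float       # mmHg·min/L
    V_Vun_Min: float       # L, venous unstressed volume at full sympathetic drive
    V_Vun_Max: float       # L, venous unstressed volume at zero sympathetic drive

    # Transcapillary refill
    k_Vcap: float          # L/min/mmHg, refill conductance (0 disables refill)
    P_CVP0: Optional[float] = None  # mmHg, interstitial reference pressure;
    #                                 set to the steady-state CVP at initialization

    # Loop control
    S_F: int = CLOSED_LOOP  # -1 closed loop, any other value opens the reflex
    S_0: float = 0.5        # dimensionless, fixed sympathetic drive in open loop

    # Timing reference; defaults to nu_HR_max when omitted
    nu_HR0_max: Optional[float] = None  # 1/min, sets the fixed systole duration

    def __post_init__(self):
        if self.nu_HR0_max is None:
            object.__setattr__(self, "nu_HR0_max", self.nu_HR_max)
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ParameterError` on any violated physical constraint."""
        positive = {
            "k_VED0": self.k_VED0, "P_0LV": self.P_0LV, "k_ELV": self.k_ELV,
            "R_valve": self.R_valve, "C_A": self.C_A, "C_V": self.C_V,
            "V_Aun": self.V_Aun, "V_total": self.V_total, "nu_cut": self.nu_cut,
            "S_sat": self.S_sat, "P_Aset": self.P_Aset,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ParameterError(f"{name} must be strictly positive, got {value}")
        if self.k_Vcap < 0:
            raise ParameterError(f"k_Vcap must be >= 0, got {self.k_Vcap}")
        if not self.nu_HR_min < self.nu_HR_max:
            raise ParameterError(
                f"require nu_HR_min < nu_HR_max, got {self.nu_HR_min} >= {self.nu_HR_max}")
        if not self.nu_HR_max * 0.8 < self.nu_HR0_max:
            # positive diastole at every reachable rate: 1/nu > 0.8/nu0_max
            raise ParameterError(
                f"require nu_HR_max < 1.25*nu_HR0_max so diastole stays "
                f"positive, got {self.nu_HR_max} vs {self.nu_HR0_max}")
        for lo_name, lo, hi_name, hi in [
            ("C_PRSW_min", self.C_PRSW_min, "C_PRSW_max", self.C_PRSW_max),
            ("R_TPR_min", self.R_TPR_min, "R_TPR_max", self.R_TPR_max),
            ("V_Vun_Min", self.V_Vun_Min, "V_Vun_Max", self.V_Vun_Max),
        ]:
            if not lo < hi:
                raise ParameterError(f"require {lo_name} < {hi_name}, got {lo} >= {hi}")
        if not (self.nu_HR_min >= 0 and self.C_PRSW_min > 0 and self.R_TPR_min > 0
                and self.V_Vun_Min > 0):
            raise ParameterError("effector lower bounds must be non-negative "
                                 "(strictly positive except nu_HR_min)")
        if not 0.0 <= self.S_0 <= 1.0:
            raise ParameterError(f"S_0 must lie in [0, 1], got {self.S_0}")

    @property
    def closed_loop(self) -> bool:
        return self.S_F == CLOSED_LOOP

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform time grid for fixed-step integration (minutes)."""

    t0: float = 0.0
    t_end: float = 500.0
    t_delta: float = 0.01

    def __post_init__(self):
        if not self.t0 < self.t_end:
            raise ParameterError(f"require t0 < t_end, got {self.t0} >= {self.t_end}")
        if not self.t_delta > 0:
            raise ParameterError(f"t_delta must be positive, got {self.t_delta}")
        n = (self.t_end - self.t0) / self.t_delta
        if abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise ParameterError(
                f"(t_end - t0)/t_delta must be an integer step count, got {n}")

    @property
    def n_steps(self) -> int:
        return int(round((self.t_end - self.t0) / self.t_delta))

    def times(self):
        import numpy as np
        return self.t0 + self.t_delta * np.arange(self.n_steps + 1)
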