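"""Sparse observation records of (time, MAP, heart rate, cardiac output).

These are the measurements the calibration cost consumes: mean arterial
pressure ``P_A`` (mmHg), heart rate ``nu_HR`` (1/min) and cardiac output
``I_CO`` (L/min) sampled at irregular times over a baseline / bleed /
post-bleed experiment.  Records taken before the bleed window carry a
``baseline`` flag so the cost can also be reported with the baseline
excluded.  The on-disk format is a delimited text table with a header
``time_min, map_mmHg, hr_per_min, co_L_min[, baseline]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ObservationError

#: CSV column names (with units baked into the names).
CSV_COLUMNS = {
    "time_min": "t",
    "map_mmHg": "P_A",
    "hr_per_min": "nu_HR",
    "co_L_min": "I_CO",
}
CHANNELS = ("P_A", "nu_HR", "I_CO")


@dataclass
class Observations:
    """Observation table with columns ``t, P_A, nu_HR, I_CO, baseline``."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["t", "P_A", "nu_HR", "I_CO", "baseline"]))

    def __post_init__(self):
        required = {"t", *CHANNELS}
        missing = required - set(self.frame.columns)
        if missing:
            raise ObservationError(f"observations missing columns: {sorted(missing)}")
        if "baseline" not in self.frame.columns:
            self.frame = self.frame.assign(baseline=False)
        self.frame = self.frame.reset_index(drop=True)
        if len(self.frame):
            t = self.frame["t"].to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                raise ObservationError("observation times must be sorted")
            vals = self.frame[list(CHANNELS)].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
                raise ObservationError(
                    "measured P_A, nu_HR, I_CO must be finite and strictly "
                    "positive (they normalize the calibration residuals)")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def t(self) -> np.ndarray:
        return self.frame["t"].to_numpy(dtype=float)

    @property
    def baseline(self) -> np.ndarray:
        return self.frame["baseline"].to_numpy(dtype=bool)

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise ObservationError(f"unknown channel {name!r}; choose from {CHANNELS}")
        return self.frame[name].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        out = pd.DataFrame({
            "time_min": self.frame["t"],
            "map_mmHg": self.frame["P_A"],
            "hr_per_min": self.frame["nu_HR"],
            "co_L_min": self.frame["I_CO"],
            "baseline": self.frame["baseline"].astype(int),
        })
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Observations":
        try:
            # round_trip parser: values survive write/read bit-exactly
            raw = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:
            raise ObservationError(f"cannot read observations from {path}: {exc}")
        missing = [c for c in CSV_COLUMNS if c not in raw.columns]
        if missing:
            raise ObservationError(
                f"{path}: missing required column(s) {missing}; expected "
                f"{list(CSV_COLUMNS)}")
        frame = raw.rename(columns=CSV_COLUMNS)
        for col in CSV_COLUMNS.values():
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.isna()
            if bad.any():
                # +2: header line plus 1-based numbering
                lines = [int(i) + 2 for i in frame.index[bad]]
                raise ObservationError(
                    f"{path}: non-numeric or missing {col} value(s) on "
                    f"line(s) {lines}")
            frame[col] = coerced
        if "baseline" in frame.columns:
            frame["baseline"] = frame["baseline"].astype(bool)
        return cls(frame[["t", "P_A", "nu_HR", "I_CO"]
                         + (["baseline"] if "baseline" in frame.columns else [])])
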