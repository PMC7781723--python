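"""Synthetic observation generator emulating the controlled-bleed experiment.

Produces sparse, noisy measurements of mean arterial pressure, heart rate
and cardiac output from a known ground-truth parameter set, on a sampling
schedule shaped like the animal experiments: occasional baseline samples,
dense sampling through the 30-60 min bleed, and regular follow-up over the
remainder of a ~500 min observation window.  Noise is multiplicative
Gaussian per channel (``X_obs = X_true * (1 + cv*z)``), the natural
counterpart of a relative-residual calibration cost.  Generation is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .errors import ParameterError
from .observations import CHANNELS, Observations
from .parameters import ModelParameters, SimulationGrid
from .protocol import BleedProtocol
from .simulator import Trajectory, observe, simulate

__all__ = ["NoiseModel", "default_schedule", "generate"]

#: Redraws allowed before a non-positive sample is treated as an error.
MAX_REDRAWS = 100


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative measurement noise: per-channel CV and a seed.

    ``cv`` is either one coefficient of variation applied to all three
    channels or a mapping ``{"P_A": ..., "nu_HR": ..., "I_CO": ...}``.
    """

    cv: Union[float, dict] = 0.05
    seed: int = 0

    def __post_init__(self):
        cvs = self.channel_cv()
        if any(v < 0 for v in cvs.values()):
            raise ParameterError(f"noise cv must be >= 0, got {self.cv}")

    def channel_cv(self) -> dict:
        if isinstance(self.cv, dict):
            unknown = set(self.cv) - set(CHANNELS)
            if unknown:
                raise ParameterError(f"unknown noise channel(s) {sorted(unknown)}")
            return {ch: float(self.cv.get(ch, 0.0)) for ch in CHANNELS}
        return {ch: float(self.cv) for ch in CHANNELS}


def default_schedule(protocol: BleedProtocol,
                     grid: SimulationGrid,
                     baseline_every: float = 10.0,
                     bleed_every: float = 2.0,
                     post_every: float = 15.0) -> np.ndarray:
    """Deterministic sampling times for a baseline/bleed/post-bleed run.

    Every ``baseline_every`` min from t0 up to the bleed start, every
    ``bleed_every`` min through the bleed window, then every ``post_every``
    min until the end of the grid (duplicates removed, sorted).
    """
    if protocol.t_bleedstart < grid.t0 or protocol.t_bleedend > grid.t_end:
        raise ParameterError("bleed window must lie within the simulation grid")
    eps = 1e-9
    baseline = np.arange(grid.t0, protocol.t_bleedstart - eps, baseline_every)
    bleed = np.arange(protocol.t_bleedstart, protocol.t_bleedend + eps,
                      bleed_every)
    post = np.arange(protocol.t_bleedend, grid.t_end + eps, post_every)
    times = np.unique(np.concatenate([baseline, bleed, post]))
    return times[(times >= grid.t0) & (times <= grid.t_end)]


def _apply_noise(clean: Observations, noise: NoiseModel,
                 t_bleedstart: Optional[float]) -> Observations:
    rng = np.random.default_rng(noise.seed)
    cvs = noise.channel_cv()
    frame = clean.frame.copy()
    n = len(frame)
    for ch in CHANNELS:
        cv = cvs[ch]
        truth = frame[ch].to_numpy(dtype=float)
        samples = truth * (1.0 + cv * rng.standard_normal(n))
        for _ in range(MAX_REDRAWS):
            bad = samples <= 0.0
            if not bad.any():
                break
            warnings.warn(
                f"redrawing {int(bad.sum())} non-positive {ch} sample(s); "
                "noise cv may be unrealistically large", stacklevel=2)
            samples[bad] = truth[bad] * (
                1.0 + cv * rng.standard_normal(int(bad.sum())))
        else:
            raise ParameterError(
                f"could not draw positive {ch} samples after {MAX_REDRAWS} "
                f"redraws (cv = {cv})")
        frame[ch] = samples
    if t_bleedstart is not None:
        frame["baseline"] = frame["t"].to_numpy() < t_bleedstart
    return Observations(frame)


def generate(params: ModelParameters,
             protocol: BleedProtocol,
             grid: SimulationGrid,
             schedule=None,
             noise: NoiseModel = NoiseModel(),
             trajectory: Optional[Trajectory] = None) -> Observations:
    """Simulate ground truth and sample noisy observations from it.

    ``schedule`` defaults to :func:`default_schedule`.  A pre-computed
    ``trajectory`` (for the same parameters/protocol/grid) may be supplied
    to avoid re-simulating when drawing several noise replicates.
    """
    if schedule is None:
        schedule = default_schedule(protocol, grid)
    traj = trajectory if trajectory is not None else simulate(
        params, protocol, grid)
    clean = observe(traj, schedule)
    return _apply_noise(clean, noise, protocol.t_bleedstart)
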