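"""Run configurations: strict YAML parsing, writing, and packaged subjects.

A run configuration has three mandatory blocks — ``parameters`` (the model
constants, keyed by their standard symbol names), ``protocol`` (the
hemorrhage window and shape) and ``grid`` (the integration window and
step) — plus optional ``calibration`` and ``synthetic`` blocks.  Unknown
keys anywhere are rejected so typos cannot silently fall back to
defaults.  Four calibrated swine configurations ship with the package as
``subject1`` ... ``subject4``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from .errors import ConfigurationError, ParameterError
from .parameters import ModelParameters, SimulationGrid
from .protocol import BleedProtocol

__all__ = ["RunConfig", "load_config", "parse_config", "dump_config",
           "load_subject", "SUBJECTS"]

logger = logging.getLogger(__name__)

SUBJECTS = (1, 2, 3, 4)

_BLOCKS = ("parameters", "protocol", "grid", "calibration", "synthetic")
_CALIBRATION_KEYS = {"fit", "theta_init", "options"}
_SYNTHETIC_KEYS = {"cv", "seed", "schedule", "times"}
_SCHEDULE_KEYS = {"baseline_every", "bleed_every", "post_every"}


@dataclass(frozen=True)
class RunConfig:
    """Parsed configuration: typed blocks plus raw optional sections."""

    parameters: ModelParameters
    protocol: Optional[BleedProtocol]
    grid: SimulationGrid
    calibration: Optional[dict] = None
    synthetic: Optional[dict] = None
    source: Optional[str] = None   # path the config was read from, if any

    def content_hash(self) -> str:
        """SHA-256 over the resolved configuration, for provenance logs."""
        payload = yaml.safe_dump(_to_mapping(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _check_keys(block: str, mapping: dict, allowed) -> None:
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in {block!r} block: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}")


def _build(block: str, cls, mapping: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(block, mapping, fields)
    try:
        return cls(**mapping)
    except (ParameterError, TypeError) as exc:
        raise ConfigurationError(f"invalid {block!r} block: {exc}")


def parse_config(data: dict, source: Optional[str] = None) -> RunConfig:
    """Validate a raw mapping into a :class:`RunConfig`."""
    if not isinstance(data, dict):
        raise ConfigurationError("configuration root must be a mapping")
    _check_keys("<root>", data, _BLOCKS)
    if "parameters" not in data or "grid" not in data:
        raise ConfigurationError(
            "configuration requires 'parameters' and 'grid' blocks")
    params = _build("parameters", ModelParameters, dict(data["parameters"]))
    grid = _build("grid", SimulationGrid, dict(data["grid"]))
    protocol = None
    if data.get("protocol") is not None:
        protocol = _build("protocol", BleedProtocol, dict(data["protocol"]))
    calibration = data.get("calibration")
    if calibration is not None:
        _check_keys("calibration", calibration, _CALIBRATION_KEYS)
    synthetic = data.get("synthetic")
    if synthetic is not None:
        _check_keys("synthetic", synthetic, _SYNTHETIC_KEYS)
        sched = synthetic.get("schedule")
        if sched is not None:
            _check_keys("synthetic.schedule", sched, _SCHEDULE_KEYS)
    return RunConfig(parameters=params, protocol=protocol, grid=grid,
                     calibration=calibration, synthetic=synthetic,
                     source=source)


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    cfg = parse_config(data, source=str(path))
    logger.info("loaded configuration %s (sha256 %s)", path, cfg.content_hash())
    logger.debug("resolved parameters: %s", cfg.parameters.as_dict())
    return cfg


def _to_mapping(cfg: RunConfig) -> dict:
    params = {k: v for k, v in cfg.parameters.as_dict().items() if v is not None}
    out = {"parameters": params,
           "grid": dataclasses.asdict(cfg.grid)}
    if cfg.protocol is not None:
        out["protocol"] = {k: v for k, v in
                           dataclasses.asdict(cfg.protocol).items()
                           if v is not None}
    if cfg.calibration is not None:
        out["calibration"] = cfg.calibration
    if cfg.synthetic is not None:
        out["synthetic"] = cfg.synthetic
    return out


def dump_config(cfg: RunConfig, path) -> None:
    """Write a configuration back to YAML (values round-trip exactly)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_mapping(cfg), fh, sort_keys=False)


def load_subject(n: int) -> RunConfig:
    """Load one of the packaged calibrated swine configurations (1-4)."""
    if n not in SUBJECTS:
        raise ConfigurationError(f"subject must be one of {SUBJECTS}, got {n}")
    ref = resources.files("hemoshock").joinpath(f"configs/subject{n}.yaml")
    data = yaml.safe_load(ref.read_text())
    return parse_config(data, source=f"hemoshock:configs/subject{n}.yaml")
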