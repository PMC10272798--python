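"""Run configuration: defaults, file loading, strict validation.

A :class:`RunConfig` aggregates every parameter group of the simulator with
the reference operating point as defaults.  Configurations load from YAML or
JSON and overlay as ``defaults <- file <- explicit overrides``; unknown keys
are rejected by name so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .circulation import CircuitParams, CuffProtocol, SystemicInput
from .mechanics import A_MIN_CM2, R_MAX, ArmGeometry, BloodProperties, TubeLawParams

__all__ = ["Numerics", "Clamps", "RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class Numerics:
    """Integrator settings."""

    dt_s: float = 5e-4
    pre_roll_s: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.dt_s <= 1e-3:
            raise ValueError("dt_s must be in (0, 1 ms]")
        if self.pre_roll_s < 0:
            raise ValueError("pre_roll_s must be non-negative")


@dataclass(frozen=True)
class Clamps:
    """Numerical floors/caps of the vessel mechanics."""

    a_min_cm2: float = A_MIN_CM2
    r_max: float = R_MAX

    def __post_init__(self) -> None:
        if self.a_min_cm2 <= 0 or self.r_max <= 0:
            raise ValueError("clamps must be positive")


#: config section name -> (dataclass, YAML key -> constructor kwarg)
_SCHEMA: dict[str, tuple[type, dict[str, str]]] = {
    "tube_law": (TubeLawParams, {"a": "a", "c": "c", "d": "d"}),
    "blood": (
        BloodProperties,
        {
            "viscosity_mmHg_s": "viscosity_mmHg_s",
            "density_kg_m3": "density_kg_m3",
        },
    ),
    "geometry": (
        ArmGeometry,
        {"arm_length_m": "arm_length_m", "cuff_length_m": "cuff_length_m"},
    ),
    "systemic": (
        SystemicInput,
        {"sbp": "sbp", "pp": "pp", "hr": "hr", "p_ven_sys": "p_ven_sys"},
    ),
    "protocol": (
        CuffProtocol,
        {
            "rate_mmHg_s": "rate_mmHg_s",
            "start_s": "start_s",
            "max_pressure_mmHg": "max_pressure_mmHg",
            "hold_s": "hold_s",
        },
    ),
    "circuit": (
        CircuitParams,
        {
            "r_systemic": "r_systemic",
            "c_art": "c_art",
            "c_ven": "c_ven",
            "r_ven_open": "r_ven_open",
            "collapse_threshold_mmHg": "collapse_threshold_mmHg",
            "collapse_width_mmHg": "collapse_width_mmHg",
        },
    ),
    "numerics": (Numerics, {"dt_s": "dt_s", "pre_roll_s": "pre_roll_s"}),
    "clamps": (Clamps, {"a_min_cm2": "a_min_cm2", "r_max": "r_max"}),
}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved simulator configuration (reference values by default)."""

    tube_law: TubeLawParams = field(default_factory=TubeLawParams)
    blood: BloodProperties = field(default_factory=BloodProperties)
    geometry: ArmGeometry = field(default_factory=ArmGeometry)
    systemic: SystemicInput = field(default_factory=SystemicInput)
    protocol: CuffProtocol = field(default_factory=CuffProtocol)
    circuit: CircuitParams = field(default_factory=CircuitParams)
    numerics: Numerics = field(default_factory=Numerics)
    clamps: Clamps = field(default_factory=Clamps)
    seed: int = 0

    def to_dict(self) -> dict:
        out: dict = {"seed": self.seed}
        for section, (_, keys) in _SCHEMA.items():
            obj = getattr(self, section)
            out[section] = {k: getattr(obj, attr) for k, attr in keys.items()}
        return out


def _build_section(section: str, overrides: dict) -> object:
    cls, keys = _SCHEMA[section]
    kwargs = {}
    for key, value in overrides.items():
        if key not in keys:
            raise ValueError(
                f"unknown key {key!r} in config section {section!r}; "
                f"valid keys: {sorted(keys)}"
            )
        kwargs[keys[key]] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Resolve a configuration from defaults, an optional file, and overrides.

    ``path`` may be YAML or JSON (an empty file yields pure defaults);
    ``overrides`` is a nested dict of the same shape applied last.  Unknown
    sections or keys raise ``ValueError`` naming the offender.
    """
    merged: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else {}
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        merged = loaded
    for section, content in (overrides or {}).items():
        if isinstance(content, dict):
            merged.setdefault(section, {}).update(content)
        else:
            merged[section] = content

    kwargs: dict = {}
    for section, content in merged.items():
        if section == "seed":
            kwargs["seed"] = int(content)
            continue
        if section not in _SCHEMA:
            raise ValueError(
                f"unknown config section {section!r}; valid sections: "
                f"{sorted(_SCHEMA) + ['seed']}"
            )
        if not isinstance(content, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        kwargs[section] = _build_section(section, content)
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the resolved configuration."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
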