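"""Configuration loading, validation and seeded RNG management.

A run configuration is a JSON object with optional parameter blocks::

    {
      "hh": { ... HHParams fields ... },
      "fdf": { ... FDFParams fields ... },
      "template": { ... TraceTemplate fields ... },
      "stack": { ... ImageStackSpec fields ... },
      "seed": 0,
      "log_level": "INFO"
    }

Unknown keys are rejected (typo safety) and all violations across the file
are reported together. Module invariants are enforced by the dataclasses
themselves at construction.

Seed management: a single root seed fans out to per-module streams through
a fixed counter-based derivation (`numpy.random.SeedSequence(root,
spawn_key=(module_index,))`), so adding one stage never perturbs another
stage's stream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .fdf_biofilm import FDFParams
from .hh_membrane import GateSigmoid, HHParams
from .synthetic_data import ImageStackSpec, TraceTemplate

__all__ = ["RunConfig", "load_config", "save_config", "module_seed",
           "ConfigError"]

# fixed module indices of the seed fan-out; append-only
_MODULE_STREAMS = {
    "hh": 0,
    "fdf": 1,
    "synth_traces": 2,
    "synth_track": 3,
    "synth_stack": 4,
    "critical_radius": 5,
}


def module_seed(root_seed: int, module: str, counter: int = 0) -> int:
    """Derive a per-module 31-bit seed from the root seed.

    ``counter`` distinguishes repeated uses within one module (e.g.
    ensemble members).
    """
    if module not in _MODULE_STREAMS:
        raise ValueError(
            f"unknown module stream {module!r}; known: "
            f"{sorted(_MODULE_STREAMS)}"
        )
    ss = np.random.SeedSequence(
        entropy=root_seed, spawn_key=(_MODULE_STREAMS[module], counter)
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


class ConfigError(ValueError):
    """Aggregated configuration violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            "invalid configuration:\n  - " + "\n  - ".join(violations)
        )


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    hh: HHParams = field(default_factory=HHParams)
    fdf: FDFParams = field(default_factory=FDFParams)
    template: TraceTemplate = field(default_factory=TraceTemplate)
    stack: ImageStackSpec = field(default_factory=ImageStackSpec)
    seed: int = 0
    log_level: str = "INFO"


_BLOCKS = {
    "hh": HHParams,
    "fdf": FDFParams,
    "template": TraceTemplate,
    "stack": ImageStackSpec,
}
_SIGMOID_FIELDS = {"h_window_low", "h_window_high", "n_gate"}


def _build_block(cls, data: dict, context: str, violations: list[str]):
    known = {f.name for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in known:
            violations.append(f"{context}: unknown key '{key}'")
            continue
        if key in _SIGMOID_FIELDS and isinstance(value, dict):
            extra = set(value) - {"v_half", "slope"}
            if extra:
                violations.append(
                    f"{context}.{key}: unknown sigmoid keys {sorted(extra)}"
                )
                continue
            try:
                value = GateSigmoid(**value)
            except (TypeError, ValueError) as exc:
                violations.append(f"{context}.{key}: {exc}")
                continue
        if key == "shape" and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        violations.append(f"{context}: {exc}")
        return None


def load_config(path: str | Path) -> RunConfig:
    """Load and fully validate a JSON run configuration.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ConfigError
        Listing every violation found (unknown keys, invalid values,
        broken module invariants).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file {path} does not exist")
    raw = json.loads(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a JSON object"])
    violations: list[str] = []
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _BLOCKS:
            if not isinstance(value, dict):
                violations.append(f"{key}: must be an object")
                continue
            block = _build_block(_BLOCKS[key], value, key, violations)
            if block is not None:
                kwargs[key] = block
        elif key == "seed":
            if not isinstance(value, int):
                violations.append("seed: must be an integer")
            else:
                kwargs["seed"] = value
        elif key == "log_level":
            if value not in ("DEBUG", "INFO", "WARNING", "ERROR"):
                violations.append(f"log_level: invalid level {value!r}")
            else:
                kwargs["log_level"] = value
        else:
            violations.append(f"unknown top-level key '{key}'")
    if violations:
        raise ConfigError(violations)
    return RunConfig(**kwargs)


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration as JSON; save-then-load is the identity."""
    payload = {
        "hh": _to_jsonable(config.hh),
        "fdf": _to_jsonable(config.fdf),
        "template": _to_jsonable(config.template),
        "stack": _to_jsonable(config.stack),
        "seed": config.seed,
        "log_level": config.log_level,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
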