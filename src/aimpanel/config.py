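"""Flat key/value run configuration with CLI override semantics.

Config files are flat YAML mappings mirroring CLI flag names (underscores
for dashes).  Unknown keys are rejected; values given on the command line
override file values; the fully resolved configuration is echoed to the log
together with its hash, so a run is reproducible from its log alone.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Any, Callable, Mapping

import yaml

from .datamodel import DataError

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "Schema", "load_config", "resolve_config", "file_checksum"]


class ConfigError(DataError):
    pass


class Schema:
    """Declarative key set for one subcommand."""

    def __init__(self, keys: Mapping[str, tuple[Callable[[str], Any], bool, Any]]):
        # key -> (caster, required, default)
        self.keys = dict(keys)

    def validate(self, cfg: dict[str, Any]) -> dict[str, Any]:
        unknown = sorted(set(cfg) - set(self.keys))
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
        out: dict[str, Any] = {}
        for key, (caster, required, default) in self.keys.items():
            if key in cfg and cfg[key] is not None:
                try:
                    out[key] = caster(cfg[key])
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"config key {key!r}: {exc}") from None
            elif required:
                raise ConfigError(f"missing required config key: {key!r}")
            else:
                out[key] = default
        return out


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a flat YAML mapping; nested structures are rejected."""
    with open(path, "rt", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a flat key: value mapping")
    for key, value in data.items():
        if isinstance(value, (dict, list)):
            raise ConfigError(f"{path}: key {key!r} is nested; config must be flat")
    return {str(k): v for k, v in data.items()}


def resolve_config(
    schema: Schema,
    file_values: Mapping[str, Any] | None,
    cli_values: Mapping[str, Any],
) -> dict[str, Any]:
    """Merge file values with CLI overrides and validate against the schema."""
    merged: dict[str, Any] = dict(file_values or {})
    for key, value in cli_values.items():
        if value is not None:
            merged[key] = value
    resolved = schema.validate(merged)
    digest = hashlib.sha256(
        repr(sorted(resolved.items())).encode("utf-8")
    ).hexdigest()[:12]
    logger.info("resolved config (hash %s): %s", digest, resolved)
    return resolved


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


# ---- shared value parsers ----

def positive_int(v: Any) -> int:
    i = int(v)
    if i <= 0:
        raise ValueError(f"must be positive, got {i}")
    return i


def nonneg_int(v: Any) -> int:
    i = int(v)
    if i < 0:
        raise ValueError(f"must be >= 0, got {i}")
    return i


def unit_float(v: Any) -> float:
    f = float(v)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"must lie in [0, 1], got {f}")
    return f


def float_list(v: Any) -> list[float]:
    if isinstance(v, (list, tuple)):
        return [float(x) for x in v]
    return [float(x) for x in str(v).split(",") if x.strip()]


def int_list(v: Any) -> list[int]:
    if isinstance(v, (list, tuple)):
        return [int(x) for x in v]
    return [int(x) for x in str(v).split(",") if x.strip()]
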