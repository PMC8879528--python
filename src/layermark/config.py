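"""Run configuration: defaults, file loading, and validation.

Defaults are the reference process settings: 0.2 mm layer height, two
separating layers, 0.8 mm top/bottom margins, 0.4 mm extrusion width,
1200 dpi scans.  Config files are YAML or JSON with the section names
``geometry``, ``params``, ``synth``, and ``code``; unknown keys are
rejected with their full path so typos cannot silently fall back to a
default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import TabletGeometry, WatermarkParams
from .synth import SynthParams

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content (message carries the path)."""


@dataclass
class CodeLayout:
    """Requested code matrix size and physical placement choices."""

    rows: int = 3
    cols: int = 3
    face: str = "-y"
    row_order: str = "top"
    seam_x: float = 0.0


@dataclass
class RunConfig:
    geometry: TabletGeometry = field(
        default_factory=lambda: TabletGeometry(12.0, 4.0, 4.0, 2.0)
    )
    params: WatermarkParams = field(default_factory=WatermarkParams)
    synth: SynthParams = field(default_factory=SynthParams)
    code: CodeLayout = field(default_factory=CodeLayout)
    seed: int = 0
    verbosity: int = 0


_SECTIONS = {
    "geometry": TabletGeometry,
    "params": WatermarkParams,
    "synth": SynthParams,
    "code": CodeLayout,
}


def _build(cls, data: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys under '{path}': {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{path}' section: {exc}") from exc


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON config file and apply flat overrides.

    Override keys use dotted paths (``params.layer_height``); precedence is
    overrides > file > defaults.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")

    for key, value in (overrides or {}).items():
        section, _, name = key.partition(".")
        if not name:
            data[section] = value
        else:
            data.setdefault(section, {})[name] = value

    top_known = set(_SECTIONS) | {"seed", "verbosity"}
    unknown = set(data) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data[name]
            if not isinstance(section, dict):
                raise ConfigError(f"'{name}' must be a mapping")
            kwargs[name] = _build(cls, section, name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "verbosity" in data:
        kwargs["verbosity"] = int(data["verbosity"])
    return RunConfig(**kwargs)
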