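"""Configuration loading and run manifests.

A config file is a flat YAML mapping whose keys are DesignParams /
AnalysisParams field names; unknown keys are hard errors so typos never
silently fall back to defaults.  Every successful CLI run writes a JSON
manifest capturing the exact parameters, input digests and outputs
needed to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .io_model import AnalysisParams, DesignParams

__all__ = ["load_config", "RunManifest", "TOOL_VERSION"]

TOOL_VERSION = "0.1.0"


def _coerce(key: str, value: Any, target_type: type) -> Any:
    if target_type is float and isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if target_type is int:
        if isinstance(value, bool) or not isinstance(value, int):
            raise ValueError(f"config key {key!r}: expected integer, got {value!r}")
        return value
    if target_type is str and isinstance(value, str):
        return value
    if isinstance(value, target_type) and not isinstance(value, bool):
        return value
    raise ValueError(
        f"config key {key!r}: expected {target_type.__name__}, got {value!r}"
    )


def load_config(path: str | Path | None) -> tuple[DesignParams, AnalysisParams]:
    """Load parameter overrides from a YAML key-value file.

    Absent keys take the documented defaults; unknown keys and type
    mismatches are hard errors naming the key.
    """
    if path is None:
        return DesignParams(), AnalysisParams()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must be a flat key-value mapping")
    design_fields = {f.name: f.type for f in dataclasses.fields(DesignParams)}
    analysis_fields = {f.name: f.type for f in dataclasses.fields(AnalysisParams)}
    design_kwargs: dict[str, Any] = {}
    analysis_kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in design_fields:
            default = getattr(DesignParams(), key)
            design_kwargs[key] = _coerce(key, value, type(default))
        elif key in analysis_fields:
            default = getattr(AnalysisParams(), key)
            analysis_kwargs[key] = _coerce(key, value, type(default))
        else:
            raise ValueError(f"unknown config key {key!r}")
    return DesignParams(**design_kwargs), AnalysisParams(**analysis_kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written on every successful run."""

    command: str
    parameters: dict[str, Any] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    seed: int | None = None
    tool_version: str = TOOL_VERSION

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.input_digests[str(p)] = _sha256(p)

    def write(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w", newline="\n") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
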