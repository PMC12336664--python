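"""Run configuration, result serialization and manifests.

Interface conventions: concentrations are serialized in nM and times in
minutes; internally everything runs in seconds.  Censored lag times are
written as ``(lag_min = duration, censored = true)`` pairs, never as magic
numbers.  A result directory carries a manifest with SHA-256 checksums so
that rerunning an identical configuration can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "write_results"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Top-level pipeline configuration with defaults for every field."""

    model: str = "flow"  # compartment | flow | scenarios
    tf_density: float = 9.0
    fviii_level: float = 0.01
    duration_min: float = 40.0
    concizumab: bool = True
    dose: float = 21.5
    tfpib_present: bool = True
    plasma_target: float = 4.0
    rtol: float = 1e-8
    atol: float = 1e-12
    seed: int = 0
    log_level: str = "INFO"
    outdir: str = "results"
    rate_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in ("compartment", "flow", "scenarios"):
            raise ConfigError(f"unknown model {self.model!r}")
        if self.tf_density < 0 or self.duration_min <= 0:
            raise ConfigError("tf_density must be >= 0 and duration_min > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rate_overrides"] = dict(d["rate_overrides"])
        return d


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected by name; an empty file yields all defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame] | None = None,
    timecourses: Mapping[str, pd.DataFrame] | None = None,
    summaries: Mapping[str, Mapping] | None = None,
    outdir="results",
) -> dict:
    """Write CSV tables/time courses and JSON summaries plus a manifest.

    Returns the manifest (also written as ``manifest.json``): a sorted list
    of artifacts with SHA-256 checksums.  Identical inputs produce
    identical checksums.
    """
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    written: list[Path] = []
    for name, df in (tables or {}).items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    for name, df in (timecourses or {}).items():
        p = out / f"{name}_timecourse.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    for name, payload in (summaries or {}).items():
        p = out / f"{name}.json"
        p.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
        written.append(p)
    manifest = {
        "artifacts": [
            {"file": p.name, "sha256": _sha256(p)} for p in sorted(written)
        ]
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
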