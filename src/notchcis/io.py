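"""Run configuration, result writing and provenance manifests.

Every pipeline stage reads a validated :class:`RunConfig` (YAML with
defaults filled in) and writes plain CSV tables plus a JSON manifest
recording the package version, master seed and a hash of the effective
configuration, so any output file is traceable to the run that made it.
Floats are written with 12 significant digits, which makes re-runs of an
identical configuration byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .scan import ScanConfig
from .synth import TraceSimConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config",
           "write_results", "setup_logging"]

log = logging.getLogger("notchcis")

_COMMANDS = ("scan", "trans", "traces", "synth")


class ConfigError(ValueError):
    """Raised on malformed configuration, naming the offending keys."""


@dataclass(frozen=True)
class RunConfig:
    """Top-level pipeline configuration."""

    command: str = "scan"
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    scan: ScanConfig = field(default_factory=ScanConfig)
    tracesim: TraceSimConfig = field(default_factory=TraceSimConfig)
    max_sets: int = 100          # cap on parameter sets in trans analyses
    smoothing_window: int = 3    # trace pipeline smoothing

    def __post_init__(self) -> None:
        if self.command not in _COMMANDS:
            raise ConfigError(f"unknown command {self.command!r}; "
                              f"expected one of {_COMMANDS}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


def _build(cls: type, block: Mapping[str, Any], context: str) -> Any:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(block) - names)
    if unknown:
        raise ConfigError(f"unknown keys in {context}: {unknown}")
    coerced = dict(block)
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = _as_tuple(coerced[f.name])
    return cls(**coerced)


def _as_tuple(value: Any) -> Any:
    if isinstance(value, list):
        return tuple(_as_tuple(v) for v in value)
    return value


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    An empty file yields all defaults; unknown keys raise
    :class:`ConfigError` naming them.  ``save_config`` followed by
    ``load_config`` is the identity.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config root must be a mapping")
    top = dict(raw)
    scan_cfg = _build(ScanConfig, top.pop("scan", {}), "scan")
    sim_cfg = _build(TraceSimConfig, top.pop("tracesim", {}), "tracesim")
    rc = _build(RunConfig, top, "top level")
    return dataclasses.replace(rc, scan=scan_cfg, tracesim=sim_cfg)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig | Mapping[str, Any]) -> str:
    d = config.to_dict() if isinstance(config, RunConfig) else dict(config)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  seed: int, config: RunConfig | Mapping[str, Any] | None = None,
                  ) -> dict[str, Any]:
    """Write tables as CSV plus a provenance manifest; returns the manifest.

    Each table lands at ``<out_dir>/<name>.csv`` with a mandatory header
    and 12-significant-digit floats.  The manifest records version, seed,
    config hash and per-table row counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {}
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.12g")
        counts[name] = int(len(df))
        log.info("wrote %s (%d rows)", p, len(df))
    manifest = {
        "version": __version__,
        "seed": int(seed),
        "config_hash": config_hash(config) if config is not None else None,
        "tables": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
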