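"""Run configuration, manifests, and reproducibility plumbing.

A run is fully described by a strict YAML config (unknown keys are rejected by
name) plus one master seed.  Every command writes a manifest containing the
fully resolved configuration, the seed, the package version, hashes of any
input files, and timestamps — enough to re-execute the run exactly.  All
randomness flows from the master seed through named substreams (placement,
exploration, replay), so components can be re-seeded independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, fields
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .agent import QNetConfig, TrainConfig
from .phantom import PhantomConfig
from .simulator import ProbeModel, RewardConfig, StepSizes

__all__ = ["RunConfig", "load_config", "RunManifest", "write_manifest"]

_SECTIONS = {
    "phantom": PhantomConfig,
    "probe": ProbeModel,
    "reward": RewardConfig,
    "steps": StepSizes,
    "train": TrainConfig,
    "net": QNetConfig,
}


class RunConfig:
    """Resolved configuration for all modules, defaults = study values."""

    def __init__(self, **sections):
        for name, cls in _SECTIONS.items():
            given = sections.pop(name, {})
            if isinstance(given, dict):
                self._check_keys(name, cls, given)
                given = self._coerce(cls, given)
                setattr(self, name, cls(**given))
            else:
                setattr(self, name, given)
        self.seed = int(sections.pop("seed", 0))
        if sections:
            raise ValueError(f"unknown config section(s): {sorted(sections)}")

    @staticmethod
    def _check_keys(section: str, cls, given: dict) -> None:
        valid = {f.name for f in fields(cls)}
        unknown = set(given) - valid
        if unknown:
            raise ValueError(
                f"unknown key(s) in section '{section}': {sorted(unknown)}"
            )

    @staticmethod
    def _coerce(cls, given: dict) -> dict:
        # YAML lists -> tuples where the dataclass expects tuples
        out = dict(given)
        for f in fields(cls):
            if f.name in out and isinstance(out[f.name], list):
                out[f.name] = tuple(out[f.name])
        return out

    def to_dict(self) -> dict:
        d = {name: asdict(getattr(self, name)) for name in _SECTIONS}
        d["seed"] = self.seed
        return d


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a strict YAML config; empty or missing file resolves all defaults."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config root must be a mapping")
    for k, v in (overrides or {}).items():
        data.setdefault(k, {})
        if isinstance(v, dict):
            data[k] = {**data[k], **v}
        else:
            data[k] = v
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("ribscan")
    except PackageNotFoundError:
        return "unknown"


class RunManifest(dict):
    """Dict with the fields every run records."""


def write_manifest(
    config: RunConfig,
    out_path: str | Path,
    input_files: list[str | Path] | None = None,
    extra: dict | None = None,
) -> RunManifest:
    """Write the reproducibility manifest next to a run's outputs."""
    manifest = RunManifest(
        config=config.to_dict(),
        master_seed=config.seed,
        version=_package_version(),
        input_hashes={
            str(p): _sha256(Path(p)) for p in (input_files or []) if Path(p).exists()
        },
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    if extra:
        manifest.update(extra)
    Path(out_path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
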