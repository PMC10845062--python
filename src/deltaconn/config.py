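"""Declarative run configuration (YAML) with flag overrides and manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run.

    A serialized copy (plus its hash) is stored with every run so outputs
    are reproducible from the manifest alone.
    """

    seed: int = 0
    q: float = 0.05
    outdir: str = "results"
    mode: str = "longitudinal"  # "longitudinal" | "group"
    cohort_dir: str | None = None  # directory produced by simulate/assemble
    target_rois: list[str] = field(default_factory=lambda: ["subthalamic_nucleus_RH"])
    ratio_denominator_rois: list[str] = field(
        default_factory=lambda: ["thalamus_middle", "thalamus_inferior"]
    )
    percentiles: list[int] = field(default_factory=lambda: list(range(50, 100, 5)))
    standardize: bool = True
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"q must be in (0, 1), got {self.q}")
        if self.mode not in ("longitudinal", "group"):
            raise ValueError(f"mode must be longitudinal or group, got {self.mode!r}")

    def validate_paths(self) -> None:
        if self.cohort_dir is not None and not Path(self.cohort_dir).exists():
            raise FileNotFoundError(f"cohort_dir does not exist: {self.cohort_dir}")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_run_config(path=None, **overrides) -> RunConfig:
    """Read a YAML config; keyword overrides (CLI flags) win over file keys."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(outdir, config: RunConfig, stages: list[dict], inputs: dict) -> Path:
    """JSON run manifest: config echo + hash, versions, stage timings, inputs."""
    import numpy
    import pandas
    import scipy

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": {
            "deltaconn": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        "input_hashes": inputs,
        "stages": stages,
    }
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
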