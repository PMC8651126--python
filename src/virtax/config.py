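"""Run configuration and manifest writing.

All thresholds default to the published demarcation values; every value is
serialized into the run manifest so any reported number is recomputable
from inputs + config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    min_identity_pct: float = 30.0
    max_evalue: float = 1e-25
    easyfig_evalue: float = 1e-3
    min_protein_aa: int = 15
    family_cut: float = 0.8
    genus_min_shared: float = 60.0
    provirus_evalue: float = 1e-5
    provirus_min_hits: int = 10
    provirus_max_gap: int = 15_000
    att_min_len: int = 12
    att_max_mismatch: int = 1
    att_window: int = 2_000
    motif: str = "GATC"
    markov_order: int = 1
    adhesin_linkage_identity: float = 45.0
    hs_denominator: str = "union"
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    outdir: str = "virtax_out"

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, config: RunConfig,
                   input_paths: list[str | Path], stage: str) -> Path:
    """Machine-readable run manifest: hashed inputs, echoed config,
    versions, timestamp."""
    import virtax

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "virtax_version": virtax.__version__,
        "python": platform.python_version(),
        "config": dataclasses.asdict(config),
        "inputs": {str(p): _sha256(Path(p)) for p in input_paths if Path(p).is_file()},
    }
    path = outdir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
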