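"""Run configuration: a single YAML-serializable record of every switch.

Every output artifact embeds the configuration hash and seed so a run can
be reproduced bit-for-bit from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # paths
    cohort_csv: str | None = None
    tensor_dir: str | None = None
    roi_yaml: str | None = None
    out_dir: str = "glymph_out"
    # analysis switches
    covariate_model: int = 2  # 1: age/sex/TIV; 2: + APOE e4
    n_boot: int = 5000
    seed: int = 0
    standardize_mediation: bool = True
    wmh_floor_ml: float | None = None
    lenient_qc: bool = False
    # simulation
    n: int = 93
    n_reference: int = 40
    # logging
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.covariate_model not in (1, 2):
            raise ValueError("covariate_model must be 1 or 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def manifest(self, extra: dict | None = None) -> dict:
        out = {"config": self.to_dict(), "config_hash": self.config_hash(), "seed": self.seed}
        if extra:
            out.update(extra)
        return out

    def write_manifest(self, out_dir, name: str = "manifest.json", extra: dict | None = None) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / name
        path.write_text(json.dumps(self.manifest(extra), indent=2, sort_keys=True, default=str))
        return path
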