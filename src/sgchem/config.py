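"""Pipeline configuration: plain-text (YAML) with strict key checking."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end run.

    Tolerances: census m/z 0.02 Da, chemotyping EIC 0.05 Da, network
    retention-time window 0.1 min.  Thresholds: node association fraction
    0.75; chemotype presence threshold (None = automatic baseline rule).
    """

    seed: int = 0
    # synthetic design
    n_genotypes_s: int = 3
    n_genotypes_u: int = 4
    replicates: int = 1
    intensity_sigma: float = 0.4
    decoy_peaks: int = 5
    n_noise_features: int = 20
    # tolerances / thresholds
    census_mz_tol: float = 0.02
    chemotype_mz_tol: float = 0.05
    mdn_mz_tol: float = 0.02
    rt_window: float = 0.1
    association_threshold: float = 0.75
    presence_threshold: float | None = None
    losses: tuple = ("hexose", "deoxyhexose", "pentose", "malonylhexoside",
                     "hydroxylation", "saturation", "acetylation")
    tic_exclude_mz: tuple = (329.32,)
    # statistics
    n_perm_asca: int = 1000
    n_perm_screen: int = 199
    n_perm_permanova: int = 999
    # qPCR
    cq1: float = 37.0
    qpcr_mode: str = "soft"
    reference_genes: tuple = ("EXP", "SAND")

    def __post_init__(self):
        for name in ("census_mz_tol", "chemotype_mz_tol", "mdn_mz_tol",
                     "rt_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        for key in ("losses", "tic_exclude_mz", "reference_genes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
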