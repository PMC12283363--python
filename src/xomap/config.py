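"""Run configuration: one structured object, one top-level seed.

A :class:`RunConfig` either points at an input VCF or carries a simulation
block describing one or more offspring groups (label, sex, genotype, sample
size, transmitted CO mean, interference shape).  All thresholds are echoed
into output metadata, and every random stage derives its substream from the
single top-level seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["GroupConfig", "RunConfig"]


@dataclass
class GroupConfig:
    """One offspring group (a cross direction x genotype)."""

    label: str
    sex: str = "male"
    genotype: str = "WT"
    n_samples: int = 100
    transmitted_mean: float = 4.8
    nu: int = 1
    obligate_co: bool = False


@dataclass
class RunConfig:
    # input: either a VCF path or a simulation block
    vcf: str | None = None
    groups: list = field(default_factory=list)
    n_markers_per_chrom: int = 2000
    # observation model (simulation only)
    depth_mean: float = 1.2
    p_missing: float = 0.0
    e_het_to_hom: float = 0.01
    e_hom_to_het: float = 0.01
    e_hom_ler: float = 0.02
    read_based_het_calls: bool = False
    # QC thresholds
    maf_range: tuple = (0.2, 0.3)
    min_dp: int = 4
    max_dp: int = 100
    mean_dp_range: tuple = (1.0, 1.5)
    dp_scope: str = "genotype"
    max_missing: float = 0.75
    percentile_lo: float = 0.05
    percentile_hi: float = 0.95
    # smoothing / calling
    window: int = 20
    step: int = 1
    min_run_markers: int = 1
    # landscapes / interference
    bin_size: int = 1_000_000
    n_perm: int = 500
    d_max_mb: int = 15
    loess_span: float = 0.75
    loess_degree: int = 2
    # bookkeeping
    seed: int = 1
    outdir: str = "xomap_out"

    def __post_init__(self):
        self.groups = [g if isinstance(g, GroupConfig) else GroupConfig(**g) for g in self.groups]
        self.maf_range = tuple(self.maf_range)
        self.mean_dp_range = tuple(self.mean_dp_range)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["mean_dp_range"] = list(self.mean_dp_range)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
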