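"""Pipeline configuration: every numeric threshold the analysis uses.

Defaults are the reference behavior of the sugarcane water-depletion
study this pipeline reproduces: 18-28 nt reads, >=3 distinct bases,
<=3 mismatches to mature miRNAs, >=18-nt ungapped siRNA alignment,
>50 reads per library for siRNA candidates, Fisher alpha 0.05, and the
six duplex rules with total <=4.0 weighted mismatches, <=2.5 in
positions 1-12, and a duplex/perfect MFE ratio >=0.74.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml


@dataclass
class PipelineConfig:
    # preprocessing
    l_min: int = 18
    l_max: int = 28
    complexity_min_bases: int = 3
    adapter_min_overlap: int = 6
    # miRNA profiling
    max_mirna_mismatches: int = 3
    # siRNA discovery
    min_sirna_alignment: int = 18
    min_sirna_reads: int = 50  # strict: present iff raw count > this
    merge_end_tolerance: int = 2
    # differential expression
    alpha: float = 0.05
    pseudocount: int = 1
    # target prediction rule caps
    mismatch_cap_total: float = 4.0
    max_adjacent_mismatches: int = 2
    mismatch_cap_5prime: float = 2.5
    mfe_ratio_min: float = 0.74
    mismatch_penalty_kcal: float = 1.0
    # clustering
    cluster_merge_gap: int = 100
    # reproducibility
    rng_seed: int = 0

    def __post_init__(self):
        for name in (
            "l_min",
            "l_max",
            "complexity_min_bases",
            "adapter_min_overlap",
            "max_mirna_mismatches",
            "min_sirna_alignment",
            "min_sirna_reads",
            "mismatch_cap_total",
            "mismatch_cap_5prime",
            "cluster_merge_gap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.mfe_ratio_min <= 1.0):
            raise ValueError("mfe_ratio_min must be in (0, 1]")
        if self.l_min > self.l_max:
            raise ValueError("l_min > l_max")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("thresholds", data))

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
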