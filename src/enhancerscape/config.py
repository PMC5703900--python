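"""Pipeline configuration: every tunable with its default.

Defaults are the procedure's published operating points: 25-bp bins,
200-bp read extension, Poisson p < 1e-9 with >=5-fold over input,
>=200-bp constituent enhancers, 12.5-kb stitching, +-1-kb promoter
windows, 0.1-FPKM expression floor, coding-score cutoff 4, 2-fold
enrichment sets, HE threshold 1, 1000-bp phastCons promoters, -500/+100
phyloP TSS windows, 3400 bp +- 20% intergenic fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Mapping

from .synthetic import SyntheticConfig


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    bin_size: int = 25
    extension: int = 200
    p_threshold: float = 1e-9
    min_fold: float = 5.0
    local_lambda: bool = False
    min_ce_length: int = 200
    stitch_distance: int = 12_500
    promoter_halfwidth: int = 1000
    min_transcript_length: int = 200
    min_exons: int = 2
    max_coding_score: float = 4.0
    min_fpkm: float = 0.1
    fold_change: float = 2.0
    pseudocount: float = 0.01
    he_threshold: float = 1.0
    phastcons_promoter: int = 1000
    phylop_upstream: int = 500
    phylop_downstream: int = 100
    intergenic_size_mean: int = 3400
    intergenic_size_jitter: float = 0.2
    n_intergenic: int = 500

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "synthetic" in d and isinstance(d["synthetic"], Mapping):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        from .io import read_yaml

        return cls.from_dict(read_yaml(path) or {})

    def to_yaml(self, path) -> None:
        from .io import write_yaml

        write_yaml(self.to_dict(), path)
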