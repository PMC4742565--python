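"""Pipeline configuration: every threshold and seed in one declarative object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .ohnologs import OhnologThresholds
from .qcnorm import QcThresholds
from .synthdata import GeneratorParams


@dataclass(frozen=True)
class PipelineConfig:
    """All module settings with their documented defaults.

    ``qc_min_genes`` defaults to the synthetic scale (150 expressed
    genes, ~500-gene world); genome-scale runs should set 1,000.
    """

    qc_min_reads: int = 50_000
    qc_min_genes: int = 150
    expressed_cutoff: float = 1.0
    gene_filter_min_tpm: float = 1.0
    gene_filter_min_cells: int = 3
    ica_k: int = 4
    ica_seed: int = 3984
    n_clusters: int = 6
    tsne_perplexity: float = 75.0
    tsne_seed: int = 254
    gplvm_n_genes: int = 500
    gplvm_restarts: int = 3
    gplvm_seed: int = 0
    marker_n_trees: int = 1000
    marker_seed: int = 0
    dynamic_threshold: float = 5.0
    dynamic_restarts: int = 2
    trend_groups: int = 3
    trend_seed: int = 0
    compare_alpha: float = 0.05
    ohnolog_not_expressed: int = 300
    ohnolog_xor: int = 15
    ohnolog_single: int = 60
    generator: GeneratorParams = field(default_factory=GeneratorParams)

    @property
    def qc_thresholds(self) -> QcThresholds:
        return QcThresholds(
            min_reads=self.qc_min_reads,
            min_genes=self.qc_min_genes,
            expressed_cutoff=self.expressed_cutoff,
        )

    @property
    def ohnolog_thresholds(self) -> OhnologThresholds:
        return OhnologThresholds(
            not_expressed_cells=self.ohnolog_not_expressed,
            xor_both_min_diff=self.ohnolog_xor,
            single_difference=self.ohnolog_single,
            expression_cutoff=self.expressed_cutoff,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"]["state_proportions"] = list(
            d["generator"]["state_proportions"]
        )
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "generator" in data and isinstance(data["generator"], dict):
            gen = dict(data["generator"])
            if "state_proportions" in gen:
                gen["state_proportions"] = tuple(gen["state_proportions"])
            data["generator"] = GeneratorParams(**gen)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
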