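"""Pipeline configuration: one flat record of every tunable parameter.

Defaults reflect the study design the package targets: a 40-subject cohort,
165 timepoints, 36 regions in six modules, 4-group reproducibility splits,
and 1000 grouping randomizations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import PlantedPartitionSpec


@dataclass
class PipelineConfig:
    # cohort / generator
    n_subjects: int = 40
    n_timepoints: int = 165
    n_nodes: int = 36
    module_sizes: tuple[int, ...] = (5, 4, 8, 8, 3, 8)
    within_corr: float = 0.6
    between_corr: float = 0.05
    anti_pairs: tuple[tuple[int, int], ...] = ((1, 6), (2, 6))
    anti_corr: float = -0.2
    subject_sd: float = 0.05
    ar_coeff: float = 0.0
    # connectivity
    shrinkage: bool = False
    # modularity
    n_restarts: int = 100
    modularity_convention: str = "asymmetric"
    gamma: float = 1.0
    # centrality
    centrality_scaling: str = "node"
    # reproducibility
    n_groups: int = 4
    n_randomizations: int = 1000
    null_method: str = "permute"
    mi_normalization: str = "sum"
    voi_normalization: str = "logN"
    # randomness
    seed: int = 1

    def __post_init__(self) -> None:
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        self.anti_pairs = tuple((int(a), int(b)) for a, b in self.anti_pairs)
        self.planted_spec()  # validates generator parameters
        if self.n_groups < 2:
            raise ValueError("n_groups must be at least 2")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be at least 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be at least 1")

    def planted_spec(self) -> PlantedPartitionSpec:
        return PlantedPartitionSpec(
            n_nodes=self.n_nodes,
            module_sizes=self.module_sizes,
            within_corr=self.within_corr,
            between_corr=self.between_corr,
            anti_pairs=self.anti_pairs,
            anti_corr=self.anti_corr,
            n_timepoints=self.n_timepoints,
            n_subjects=self.n_subjects,
            subject_sd=self.subject_sd,
            ar_coeff=self.ar_coeff,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["module_sizes"] = list(d["module_sizes"])
        d["anti_pairs"] = [list(p) for p in d["anti_pairs"]]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
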