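"""Pipeline configuration: every tunable threshold in one strict,
YAML-round-trippable structure."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

ALL_STAGES = (
    "simulate",
    "qc",
    "reposition",
    "structure",
    "blues",
    "gwas",
    "qtl",
    "select",
)


@dataclass
class SimulateConfig:
    n_populations: int = 54
    n_bc1f1_streams: int = 12
    n_bc1f2_per_stream: int = 8
    selfing_generations: int = 4
    target_size: int = 60
    n_chromosomes: int = 21
    markers_per_chromosome: int = 100
    chrom_length_bp: int = 600_000_000
    chrom_length_cM: float = 150.0
    polymorphic_fraction: float = 0.5
    n_tetraploid: int = 15
    n_diploid: int = 47
    missing_rate: float = 0.02
    error_rate: float = 0.001
    check_fraction: float = 0.24
    n_breeders: int = 5


@dataclass
class QcConfig:
    het_max: float = 0.10
    missing_max: float = 0.10
    min_minor_hom: int = 15
    duplicate_r_abs: float = 0.99
    duplicate_k_sd: float = 6.0
    nonparental_threshold: float = 0.05
    impute_trees: int = 200
    impute_max_iter: int = 10


@dataclass
class RepositionConfig:
    r2_bin: float = 0.5
    iterations: int = 2
    correlation_min_r2: float = 0.2


@dataclass
class StructureConfig:
    skim_r: float = 0.8
    n_axes: int = 10


@dataclass
class BluesConfig:
    elimination_alpha: float = 0.10


@dataclass
class GwasConfig:
    min_minor_hom: int = 15
    kinship_skim_r: float = 0.80
    alpha: float = 0.05


@dataclass
class QtlConfig:
    critical_r2: float = 0.2
    merge_multiplier: float = 3.0
    lab: str = "sim"


@dataclass
class SelectConfig:
    carrier_min_dose: int = 2


@dataclass
class PipelineConfig:
    seed: int = 0
    out: str = "runs/out"
    stages: tuple[str, ...] = ALL_STAGES
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    reposition: RepositionConfig = field(default_factory=RepositionConfig)
    structure: StructureConfig = field(default_factory=StructureConfig)
    blues: BluesConfig = field(default_factory=BluesConfig)
    gwas: GwasConfig = field(default_factory=GwasConfig)
    qtl: QtlConfig = field(default_factory=QtlConfig)
    select: SelectConfig = field(default_factory=SelectConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = self.to_dict()
        d["stages"] = list(d["stages"])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        sections = {
            "simulate": SimulateConfig,
            "qc": QcConfig,
            "reposition": RepositionConfig,
            "structure": StructureConfig,
            "blues": BluesConfig,
            "gwas": GwasConfig,
            "qtl": QtlConfig,
            "select": SelectConfig,
        }
        for key, sub_cls in sections.items():
            if key in data:
                sub = data.pop(key)
                allowed = {f.name for f in dataclasses.fields(sub_cls)}
                unknown = set(sub) - allowed
                if unknown:
                    raise ValueError(
                        f"unknown keys in {key!r}: {sorted(unknown)}"
                    )
                kwargs[key] = sub_cls(**sub)
        if "stages" in data:
            kwargs["stages"] = tuple(data.pop("stages"))
        allowed_top = {"seed", "out"}
        unknown = set(data) - allowed_top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
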