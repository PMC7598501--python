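"""Pipeline configuration: one structured document drives every stage.

All stage parameters default to the study-like conditions of the synthetic
repeatome; a config round-trips through YAML unchanged.  A single global
seed deterministically derives per-stage seeds (see
:func:`censkim.util.derive_seed`) so stages can be re-run in isolation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .simulate import GenomeSpec, RepeatFamilySpec, default_families


@dataclass
class GenomeConfig:
    length: int = 2_040_000
    n_chromosomes: int = 1
    centromere_fraction: float = 0.435
    pericentromere_spill: float = 0.20
    families: list[dict] | None = None  # None -> default beetle-like families

    def family_specs(self) -> tuple[RepeatFamilySpec, ...]:
        if self.families is None:
            return default_families()
        specs = []
        for f in self.families:
            f = dict(f)
            if f.get("array_length_bp") is not None:
                f["array_length_bp"] = tuple(f["array_length_bp"])
            specs.append(RepeatFamilySpec(**f))
        return tuple(specs)

    def genome_spec(self, seed: int) -> GenomeSpec:
        return GenomeSpec(
            genome_length=self.length,
            families=self.family_specs(),
            n_chromosomes=self.n_chromosomes,
            centromere_fraction=self.centromere_fraction,
            seed=seed,
            pericentromere_spill=self.pericentromere_spill,
        )


@dataclass
class WgsConfig:
    coverage: float = 0.2
    read_length: int = 151
    paired: bool = True
    quality: int = 30
    error_rate: float = 0.0
    # simulate slightly above target coverage, then randomly subsample down
    oversample_factor: float = 1.25


@dataclass
class PreprocessConfig:
    quality_cutoff: int = 10
    pass_fraction: float = 0.95
    trim_length: int = 151
    adapter_prefix: int = 0
    adapter_suffix: int = 0


@dataclass
class ClusterConfig:
    min_identity: float = 0.90
    min_overlap_fraction: float = 0.55


@dataclass
class ChipConfig:
    n_reads: int = 20_000  # per library (ChIP and input each)
    family_weights: dict[str, float] = field(default_factory=lambda: {"major_sat": 4.0, "sat73": 4.0})
    background_weight: float = 1.0
    occupied_fraction: float = 0.5


@dataclass
class MapperCliConfig:
    bit_score_threshold: float = 90.0
    top_n_clusters: int = 1000
    max_candidates: int | None = 64
    precedence: str = "high_abundance"


@dataclass
class PipelineConfig:
    outdir: str = "censkim_run"
    seed: int = 1
    log_level: str = "INFO"
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    wgs: WgsConfig = field(default_factory=WgsConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    chip: ChipConfig = field(default_factory=ChipConfig)
    mapper: MapperCliConfig = field(default_factory=MapperCliConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sections = {
            "genome": GenomeConfig,
            "wgs": WgsConfig,
            "preprocess": PreprocessConfig,
            "cluster": ClusterConfig,
            "chip": ChipConfig,
            "mapper": MapperCliConfig,
        }
        kwargs = {}
        for key, value in data.items():
            if key in sections and isinstance(value, dict):
                kwargs[key] = sections[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
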