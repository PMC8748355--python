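"""Run configuration: one YAML document drives every stage.

Unknown keys are rejected so a typo in a config fails loudly instead of
silently running defaults.
"""
from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .damage import DamageParams
from .library import LibraryParams


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GenomeConfig(_Model):
    length: int = 100_000
    gc: float = 0.52
    name: str = "chrSim"


class ShearConfig(_Model):
    n_fragments: int = 10_000
    size_mean: float = 350.0
    size_sd: float = 50.0
    end_kind_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # blunt, 5', 3'
    overhang_len_dist: Literal["geometric", "constant"] = "geometric"
    overhang_len_mean: float = 8.0
    nick_rate: float = 1e-3
    gap_rate: float = 3e-4
    gap_len_mean: float = 5.0
    min_length: int = 50

    def overhang_dist(self):
        if self.overhang_len_dist == "constant":
            return ("constant", int(self.overhang_len_mean))
        return ("geometric", self.overhang_len_mean)


class DamageConfig(_Model):
    p_oxog_ss: float = 0.02
    p_iz_ss: float = 0.02
    p_deamc_ss: float = 0.01
    p_ds_damage: float = 0.0
    nick_window: int = 2
    frame_rule: Literal["reference", "damaged_strand"] = "damaged_strand"

    def to_params(self) -> DamageParams:
        return DamageParams(**self.model_dump())


class NucleaseConfig(_Model):
    model: Literal["s1", "mbn", "recjf", "none"] = "none"
    units: float = 0.0


class LibraryConfig(_Model):
    read_length: int = 100
    seq_error_rate: float = 1e-3
    pcr_error_rate: float = 1e-4
    duplicate_dist: Literal["ztgeom", "constant"] = "ztgeom"
    duplicate_mean: float = 3.0
    ligated_amount: Optional[float] = None
    molecules_per_unit: float = 100.0

    def to_params(self) -> LibraryParams:
        return LibraryParams(
            read_length=self.read_length,
            seq_error_rate=self.seq_error_rate,
            pcr_error_rate=self.pcr_error_rate,
            duplicate_dist=(self.duplicate_dist, self.duplicate_mean),
            ligated_amount=self.ligated_amount,
            molecules_per_unit=self.molecules_per_unit,
        )


class SimConfig(_Model):
    genome: GenomeConfig = Field(default_factory=GenomeConfig)
    shear: ShearConfig = Field(default_factory=ShearConfig)
    damage: DamageConfig = Field(default_factory=DamageConfig)
    nuclease: NucleaseConfig = Field(default_factory=NucleaseConfig)
    library: LibraryConfig = Field(default_factory=LibraryConfig)


class ConsensusConfig(_Model):
    min_family_size: int = 1
    agreement_threshold: Optional[float] = None  # None = size-dependent default
    min_mapq: int = 0


class SpectrumConfig(_Model):
    clip: int = 0
    frame: Literal["reference", "fragment"] = "fragment"
    mask_bed: Optional[str] = None
    which: Literal["freq6", "freq12"] = "freq6"
    pseudocount_freq: float = 0.001


class CovqcConfig(_Model):
    n_bins: int = 50_000
    n_cycles: int = 5


class ExperimentConfig(_Model):
    nucleases: list[str] = Field(default_factory=lambda: ["none", "s1"])
    units: list[float] = Field(default_factory=lambda: [0.0, 100.0])
    ligated_amounts: list[Optional[float]] = Field(default_factory=lambda: [None])
    replicates: int = 3


class RunConfig(_Model):
    seed: int = 0
    outdir: str = "ssduplex_out"
    log_level: str = "INFO"
    sim: SimConfig = Field(default_factory=SimConfig)
    consensus: ConsensusConfig = Field(default_factory=ConsensusConfig)
    spectrum: SpectrumConfig = Field(default_factory=SpectrumConfig)
    covqc: CovqcConfig = Field(default_factory=CovqcConfig)
    experiment: ExperimentConfig = Field(default_factory=ExperimentConfig)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())
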