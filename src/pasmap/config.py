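"""Run configuration: one validated, serializable object drives the pipeline.

Every stage parameter defaults to the analysis' canonical value (discard
10 volumes, FD threshold 0.2 mm with 1-back/2-forward scrubbing, 0.01-0.08
Hz band, 4 mm FWHM smoothing, r > 0.2 connectivity threshold, voxel
p < 0.001 / cluster p < 0.05, correlation alpha 0.05). Unknown keys are
rejected, and a config round-trips through YAML unchanged.
"""

from __future__ import annotations

import hashlib

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EffectConfig(_StrictModel):
    mode: str = "raise_intra"  # raise_intra | raise_inter
    strength: float = Field(0.12, ge=0, lt=1)
    group: str = "patients"
    center_mm: tuple[float, float, float] = (-15.0, 12.0, 6.0)
    radius_mm: float = 7.5
    name: str = ""


class SimulateConfig(_StrictModel):
    n_patients: int = Field(40, gt=0)
    n_controls: int = Field(38, gt=0)
    n_timepoints: int = Field(240, gt=0)
    tr_seconds: float = Field(2.0, gt=0)
    grid_shape: tuple[int, int, int] = (20, 24, 20)
    voxel_mm: float = Field(3.0, gt=0)
    noise_sd: float = Field(1.0, gt=0)
    smoothness_fwhm_mm: float = Field(4.0, ge=0)
    base_inter_r: float = 0.30
    base_intra_r: float = 0.35
    motion_spike_rate: float = Field(0.001, ge=0, lt=1)
    effects: list[EffectConfig] = Field(
        default_factory=lambda: [
            EffectConfig(mode="raise_intra", strength=0.12,
                         center_mm=(-15.0, 12.0, 6.0), name="planted_intra"),
            EffectConfig(mode="raise_inter", strength=0.12,
                         center_mm=(15.0, -12.0, -6.0), name="planted_inter"),
        ]
    )


class PreprocessConfig(_StrictModel):
    discard_n: int = Field(10, ge=0)
    fwhm_mm: float = Field(4.0, ge=0)
    low_hz: float = Field(0.01, gt=0)
    high_hz: float = Field(0.08, gt=0)
    fd_threshold: float = Field(0.2, gt=0)
    n_back: int = Field(1, ge=0)
    n_forward: int = Field(2, ge=0)
    head_radius_mm: float = Field(50.0, gt=0)


class PASConfig(_StrictModel):
    r_threshold: float = 0.2
    combine: str = "z_of_mean"  # z_of_mean | mean_of_z
    chunk_size: int | None = None


class GroupConfig(_StrictModel):
    voxel_p: float = Field(0.001, gt=0, lt=1)
    cluster_p: float = Field(0.05, gt=0, lt=1)
    connectivity: int = 26
    two_sided: bool = True
    method: str = "grf"  # grf | permutation
    n_perm: int = Field(1000, gt=0)


class CorrelateConfig(_StrictModel):
    alpha: float = Field(0.05, gt=0, lt=1)
    scores: list[str] = Field(
        default_factory=lambda: ["ybocs_total", "ybocs_obsessive", "ybocs_compulsive"]
    )


class ClassifyConfig(_StrictModel):
    grid: str = "full"  # full | coarse
    inner_folds: int = Field(3, ge=2)


class StagesConfig(_StrictModel):
    simulate: bool = True
    preprocess: bool = True
    pas: bool = True
    group: bool = True
    correlate: bool = True
    classify: bool = True


class RunConfig(_StrictModel):
    seed: int = 0
    stages: StagesConfig = Field(default_factory=StagesConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    pas: PASConfig = Field(default_factory=PASConfig)
    group: GroupConfig = Field(default_factory=GroupConfig)
    correlate: CorrelateConfig = Field(default_factory=CorrelateConfig)
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(text) or {})

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
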