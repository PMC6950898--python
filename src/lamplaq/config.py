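"""Run configuration: a single schema-validated document drives everything.

Every number in the outputs is traceable to one YAML file (unknown keys are
rejected, so typos fail loudly before any computation) plus the master seed;
CLI flags merely override config fields.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .geometry import GeometrySpec
from .presets import PRESET_EFFECTS, PRESET_GEOMETRIES
from .segmentation import SegmentationParams
from .simulate import EffectConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryBlock(_Strict):
    preset: Literal["fig1", "fig2", "fig3"] = "fig3"
    image_size: tuple[int, int] | None = None
    pixel_size: float | None = Field(default=None, gt=0)
    curvature_um: float | None = None

    def build(self) -> GeometrySpec:
        spec = PRESET_GEOMETRIES[self.preset]()
        for name in ("image_size", "pixel_size", "curvature_um"):
            v = getattr(self, name)
            if v is not None:
                setattr(spec, name, v)
        return spec


class EffectBlock(_Strict):
    preset: Literal["fig1", "fig2", "fig3"] = "fig3"
    animal_cv: float | None = Field(default=None, ge=0)
    elisa_control_mean: float | None = Field(default=None, gt=0)
    elisa_reduction: float | None = Field(default=None, ge=0, le=1)
    elisa_cv: float | None = Field(default=None, gt=0)
    cko_density_ratio: dict[str, float] | None = None
    density_scale: float = Field(default=1.0, gt=0)

    def build(self, geometry: GeometrySpec) -> EffectConfig:
        cfg = PRESET_EFFECTS[self.preset](geometry) if self.preset != "fig1" \
            else PRESET_EFFECTS[self.preset]()
        if self.animal_cv is not None:
            cfg.animal_cv = self.animal_cv
        if self.elisa_control_mean is not None:
            cfg.elisa.control_mean = self.elisa_control_mean
        if self.elisa_reduction is not None:
            cfg.elisa.reduction = self.elisa_reduction
        if self.elisa_cv is not None:
            cfg.elisa.cv = self.elisa_cv
        if self.cko_density_ratio is not None:
            cfg.cko_density_ratio = dict(self.cko_density_ratio)
        if self.density_scale != 1.0:
            cfg.baseline_plaque_density = {
                k: v * self.density_scale
                for k, v in cfg.baseline_plaque_density.items()}
        return cfg


class SegmentationBlock(_Strict):
    vglut1_threshold: float | Literal["otsu"] = "otsu"
    wfs1_threshold: float | Literal["otsu"] = "otsu"
    min_band_area_um2: float = 5000.0
    sr_fraction: float = Field(default=0.6, gt=0, lt=1)
    ca_fraction: float = Field(default=200.0 / 300.0, gt=0, lt=1)
    use_truth_regions: bool = False

    def build(self) -> SegmentationParams:
        return SegmentationParams(
            vglut1_threshold=self.vglut1_threshold,
            wfs1_threshold=self.wfs1_threshold,
            min_band_area_um2=self.min_band_area_um2,
            sr_fraction=self.sr_fraction, ca_fraction=self.ca_fraction)


class PlaqueBlock(_Strict):
    min_area_um2: float = Field(default=10.0, ge=0)
    threshold_scope: Literal["hippocampus_crop", "full_frame"] = "hippocampus_crop"


class DesignBlock(_Strict):
    arms: tuple[str, ...] = ("control", "cko")
    n_per_arm: int = Field(default=8, ge=2)
    age_months: float = 3.0
    elisa_n_per_arm: int = Field(default=12, ge=2)


class RunConfig(_Strict):
    """The full pipeline configuration."""
    master_seed: int = 0
    out_dir: str = "results"
    keep_images: bool = False
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    effect: EffectBlock = Field(default_factory=EffectBlock)
    segmentation: SegmentationBlock = Field(default_factory=SegmentationBlock)
    plaque: PlaqueBlock = Field(default_factory=PlaqueBlock)
    design: DesignBlock = Field(default_factory=DesignBlock)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True))
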