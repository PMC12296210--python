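"""Run configuration: schema, validation, hashing.

A :class:`RunConfig` describes one simulation end to end — preset or
explicit shapes, material susceptibilities, grid, acquisition settings —
and is loaded from a structured YAML file with a versioned schema. The
seed and a hash of the canonical config are stamped into every output so
reruns are attributable and bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .constants import CHI_AIR_PPM, DEFAULT_SPECTROMETER_MHZ
from .geometry import (
    Cylinder,
    Difference,
    Ellipsoid,
    HalfSpace,
    Preset,
    Scene,
    Shape,
    Union,
    VoxelGrid,
    build_preset,
)

__all__ = ["RunConfig", "ConfigError", "load_config", "scene_from_config"]


class ConfigError(ValueError):
    """Invalid run configuration (schema violation or bad reference)."""


class GridConfig(BaseModel):
    counts: tuple[int, int, int]
    spacing_mm: float = Field(gt=0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def build(self) -> VoxelGrid:
        s = self.spacing_mm
        origin = tuple(c - (n - 1) * s / 2.0
                       for c, n in zip(self.center_mm, self.counts))
        return VoxelGrid(self.counts, (s, s, s), origin)


class ShapeConfig(BaseModel):
    kind: Literal["half_space", "cylinder", "ellipsoid", "union", "difference"]
    material: Optional[str] = None
    # primitive parameters
    z_top: float = 0.0
    radius: Optional[float] = None
    z_min: Optional[float] = None
    z_max: Optional[float] = None
    center_xy: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    semi_axes: Optional[tuple[float, float, float]] = None
    children: list["ShapeConfig"] = Field(default_factory=list)

    def build(self) -> Shape:
        if self.kind == "half_space":
            return HalfSpace(self.z_top)
        if self.kind == "cylinder":
            if self.radius is None or self.z_min is None or self.z_max is None:
                raise ConfigError("cylinder needs radius, z_min, z_max")
            return Cylinder(self.radius, self.z_min, self.z_max, self.center_xy)
        if self.kind == "ellipsoid":
            if self.semi_axes is None:
                raise ConfigError("ellipsoid needs semi_axes")
            return Ellipsoid(self.center, self.semi_axes)
        if self.kind == "union":
            if not self.children:
                raise ConfigError("union needs children")
            return Union(tuple(c.build() for c in self.children))
        if len(self.children) != 2:
            raise ConfigError("difference needs exactly two children")
        return Difference(self.children[0].build(), self.children[1].build())


class SliceConfig(BaseModel):
    center_mm: float
    thickness_mm: float = Field(default=0.6, gt=0)
    window: Literal["rectangular", "gaussian"] = "rectangular"


class CoilConfig(BaseModel):
    center_mm: float = 0.0
    flat_mm: float = Field(default=16.0, gt=0)
    rolloff_mm: float = Field(default=2.0, ge=0)


class RunConfig(BaseModel):
    """Versioned simulation description (schema version 1)."""

    version: int = 1
    preset: Optional[Literal["shigemi", "plug_in_tube", "microcell"]] = None
    preset_params: dict = Field(default_factory=dict)
    shapes: list[ShapeConfig] = Field(default_factory=list)
    materials: dict[str, float] = Field(default_factory=dict)
    background_chi: float = CHI_AIR_PPM
    grid: GridConfig
    supersampling: int = Field(default=3, ge=1)
    shim_reference: bool = True
    spectrometer_mhz: float = Field(default=DEFAULT_SPECTROMETER_MHZ, gt=0)
    linewidth_hz: float = Field(default=1.0, gt=0)
    solvent_material: str = "chi_solvent"
    coil: Optional[CoilConfig] = None
    slices: list[SliceConfig] = Field(default_factory=list)
    seed: int = 0

    @model_validator(mode="after")
    def _check_scene_source(self):
        if self.version != 1:
            raise ValueError(f"unsupported schema version {self.version}")
        if self.preset is None and not self.shapes:
            raise ValueError("config must give either a preset or shapes")
        if self.preset is not None and self.shapes:
            raise ValueError("give a preset or explicit shapes, not both")
        for chi in self.materials.values():
            if not isinstance(chi, (int, float)):
                raise ValueError("material susceptibilities must be numbers")
        return self

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def solvent_chi(self) -> float:
        try:
            return float(self.materials[self.solvent_material])
        except KeyError:
            raise ConfigError(
                f"materials table lacks {self.solvent_material!r}") from None

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash(), "seed": self.seed,
                "schema_version": self.version}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; raises :class:`ConfigError`
    with field paths on schema violations."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
                 for err in exc.errors()]
        raise ConfigError("invalid config:\n  " + "\n  ".join(lines)) from exc


def scene_from_config(cfg: RunConfig) -> Preset:
    """Materialize the preset/shape description into scene + reference."""
    if cfg.preset is not None:
        params = dict(cfg.preset_params)
        params.update({k: float(v) for k, v in cfg.materials.items()})
        params.setdefault("background_chi", cfg.background_chi)
        try:
            return build_preset(cfg.preset, **params)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
    scene = Scene(background_chi=cfg.background_chi)
    for sc in cfg.shapes:
        if sc.material is None:
            raise ConfigError("each top-level shape needs a material key")
        try:
            chi = float(cfg.materials[sc.material])
        except KeyError:
            raise ConfigError(f"materials table lacks {sc.material!r}") from None
        scene.add(sc.build(), chi)
    return Preset(scene=scene, shim_reference=None)
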