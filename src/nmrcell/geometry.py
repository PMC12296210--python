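"""Sample-cell geometry: shapes, scenes, voxelization, and printable meshes.

Coordinate convention: lengths in mm, z parallel to the static field B0,
z = 0 at the material interface for interface presets. One mm^3 equals
one µL, so voxel volumes and analytic volumes are interchangeable units.

A :class:`Scene` is a constructive description — an ordered list of shapes
painted last-wins over a uniform background susceptibility — and
:func:`voxelize` turns it into a :class:`SusceptibilityMap` on a regular
:class:`VoxelGrid` with supersampled (anti-aliased) boundaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import CHI_AIR_PPM

__all__ = [
    "VoxelGrid",
    "Shape",
    "HalfSpace",
    "Cylinder",
    "Ellipsoid",
    "Union",
    "Difference",
    "Scene",
    "SusceptibilityMap",
    "CellDesign",
    "UnsupportedGeometryError",
    "MeshExportError",
    "voxelize",
    "analytic_volume",
    "build_preset_scene",
    "build_preset",
    "Preset",
    "export_stl",
]


class UnsupportedGeometryError(ValueError):
    """Raised when a closed-form volume is requested for a composite
    without one (caller may fall back to voxel counting)."""


class MeshExportError(RuntimeError):
    """Raised when mesh generation produces a non-watertight solid."""


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid; third axis parallel to B0.

    Parameters
    ----------
    counts : (nx, ny, nz) voxel counts, each >= 4.
    spacing : voxel edge lengths in mm, each > 0.
    origin : coordinates (mm) of the center of voxel (0, 0, 0).
    """

    counts: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        counts = tuple(int(c) for c in self.counts)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(counts) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("counts, spacing and origin must be 3-vectors")
        if any(c < 4 for c in counts):
            raise ValueError(f"need >= 4 voxels per axis, got {counts}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive, got {spacing}")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @classmethod
    def for_interface(cls, counts: Sequence[int], spacing: float,
                      fraction_below: float = 0.4) -> "VoxelGrid":
        """Cubic grid with a voxel *edge* exactly at z = 0 (the material
        interface) and the z = 0 plane splitting the grid with
        ``fraction_below`` of the voxels below it. Lateral axes are
        centered on x = y = 0 with the axis between voxel centers, so no
        voxel straddles the interface and no reading point sits inside a
        partial-contrast voxel."""
        nx, ny, nz = (int(c) for c in counts)
        s = float(spacing)
        n_below = int(round(nz * fraction_below))
        origin = (-(nx / 2.0) * s + s / 2.0,
                  -(ny / 2.0) * s + s / 2.0,
                  -n_below * s + s / 2.0)
        return cls((nx, ny, nz), (s, s, s), origin)

    @classmethod
    def centered(cls, extent_mm: Sequence[float], spacing: float | Sequence[float],
                 center: Sequence[float] = (0.0, 0.0, 0.0)) -> "VoxelGrid":
        """Grid of cubic (or given) spacing covering ``extent_mm`` about ``center``."""
        if np.isscalar(spacing):
            spacing = (float(spacing),) * 3
        counts = tuple(max(4, int(round(e / s))) for e, s in zip(extent_mm, spacing))
        origin = tuple(c - (n - 1) * s / 2.0
                       for c, n, s in zip(center, counts, spacing))
        return cls(counts, tuple(spacing), origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts

    @property
    def voxel_volume_ul(self) -> float:
        """Volume of one voxel in µL (= mm^3)."""
        return float(np.prod(self.spacing))

    def is_cubic(self, rtol: float = 1e-9) -> bool:
        s = self.spacing
        return math.isclose(s[0], s[1], rel_tol=rtol) and math.isclose(s[0], s[2], rel_tol=rtol)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        n = self.counts[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def index_of(self, coord: Sequence[float]) -> tuple[int, int, int]:
        """Index of the voxel whose center is nearest to ``coord``."""
        return tuple(int(round((coord[a] - self.origin[a]) / self.spacing[a]))
                     for a in range(3))


# ---------------------------------------------------------------------------
# shapes
# ---------------------------------------------------------------------------

class Shape:
    """Base class: deterministic point-containment test."""

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask for points of shape (..., 3), coordinates in mm."""
        raise NotImplementedError

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (min, max); ±inf for unbounded axes."""
        raise NotImplementedError


@dataclass(frozen=True)
class HalfSpace(Shape):
    """Lower half-space z < z_top (horizontal interface at ``z_top``)."""

    z_top: float = 0.0

    def contains(self, points):
        return points[..., 2] < self.z_top

    def bounds(self):
        inf = float("inf")
        return (np.array([-inf, -inf, -inf]), np.array([inf, inf, self.z_top]))


@dataclass(frozen=True)
class Cylinder(Shape):
    """Finite circular cylinder with axis parallel to z."""

    radius: float
    z_min: float
    z_max: float
    center_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("cylinder radius must be > 0")
        if self.z_max <= self.z_min:
            raise ValueError("cylinder needs z_max > z_min")

    def contains(self, points):
        dx = points[..., 0] - self.center_xy[0]
        dy = points[..., 1] - self.center_xy[1]
        z = points[..., 2]
        return (dx * dx + dy * dy <= self.radius ** 2) & (z >= self.z_min) & (z <= self.z_max)

    def bounds(self):
        cx, cy = self.center_xy
        r = self.radius
        return (np.array([cx - r, cy - r, self.z_min]),
                np.array([cx + r, cy + r, self.z_max]))


@dataclass(frozen=True)
class Ellipsoid(Shape):
    """Axis-aligned ellipsoid with semi-axes (a, b, c); c along B0."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError("semi-axes must be > 0")

    def contains(self, points):
        a, b, c = self.semi_axes
        dx = (points[..., 0] - self.center[0]) / a
        dy = (points[..., 1] - self.center[1]) / b
        dz = (points[..., 2] - self.center[2]) / c
        return dx * dx + dy * dy + dz * dz <= 1.0

    def bounds(self):
        c = np.asarray(self.center, dtype=float)
        s = np.asarray(self.semi_axes, dtype=float)
        return (c - s, c + s)


@dataclass(frozen=True)
class Union(Shape):
    shapes: tuple[Shape, ...]

    def __post_init__(self):
        if len(self.shapes) < 1:
            raise ValueError("union needs at least one child shape")
        object.__setattr__(self, "shapes", tuple(self.shapes))

    def contains(self, points):
        mask = self.shapes[0].contains(points)
        for s in self.shapes[1:]:
            mask = mask | s.contains(points)
        return mask

    def bounds(self):
        los, his = zip(*(s.bounds() for s in self.shapes))
        return (np.min(los, axis=0), np.max(his, axis=0))


@dataclass(frozen=True)
class Difference(Shape):
    """Points in ``base`` and not in ``cut``."""

    base: Shape
    cut: Shape

    def contains(self, points):
        return self.base.contains(points) & ~self.cut.contains(points)

    def bounds(self):
        return self.base.bounds()


# ---------------------------------------------------------------------------
# scene and voxelization
# ---------------------------------------------------------------------------

@dataclass
class Scene:
    """Ordered (shape, χ/ppm) regions painted last-wins over a background.

    The background defaults to air (+0.36 ppm); for well-shimmed
    same-medium frequency differences the choice is immaterial, and it is
    configurable for scenes embedded in another medium.
    """

    regions: list[tuple[Shape, float]] = field(default_factory=list)
    background_chi: float = CHI_AIR_PPM

    def __post_init__(self):
        for _, chi in self.regions:
            if not np.isfinite(chi):
                raise ValueError("region susceptibilities must be finite")
        if not np.isfinite(self.background_chi):
            raise ValueError("background susceptibility must be finite")

    def add(self, shape: Shape, chi_ppm: float) -> "Scene":
        if not np.isfinite(chi_ppm):
            raise ValueError("region susceptibilities must be finite")
        self.regions.append((shape, float(chi_ppm)))
        return self

    def paint(self, points: np.ndarray) -> np.ndarray:
        """χ (ppm) at each point: last painted region wins, else background."""
        chi = np.full(points.shape[:-1], self.background_chi, dtype=np.float64)
        for shape, value in self.regions:
            chi[shape.contains(points)] = value
        return chi


@dataclass
class SusceptibilityMap:
    """Voxelized volume susceptibility (ppm) on a regular grid."""

    grid: VoxelGrid
    chi: np.ndarray
    background_chi: float = CHI_AIR_PPM

    def __post_init__(self):
        self.chi = np.asarray(self.chi, dtype=np.float64)
        if self.chi.shape != self.grid.shape:
            raise ValueError(f"chi shape {self.chi.shape} != grid {self.grid.shape}")
        if not np.all(np.isfinite(self.chi)):
            raise ValueError("susceptibility map contains non-finite values")

    @property
    def contrast(self) -> np.ndarray:
        """χ − χ_background; the source term of the forward field model."""
        return self.chi - self.background_chi


def _warn_under_resolved(scene: Scene, grid: VoxelGrid) -> None:
    spacing = np.asarray(grid.spacing)
    for shape, _ in scene.regions:
        lo, hi = shape.bounds()
        extent = np.asarray(hi) - np.asarray(lo)
        finite = np.isfinite(extent)
        if np.any(extent[finite] < 2 * spacing[finite]):
            warnings.warn(
                f"{type(shape).__name__} spans < 2 voxels along some axis "
                f"(extent {extent}, spacing {tuple(spacing)}); feature is "
                "under-resolved", UserWarning, stacklevel=3)


def voxelize(scene: Scene, grid: VoxelGrid, supersampling: int = 3) -> SusceptibilityMap:
    """Sample a scene onto a grid, averaging χ over sub-voxel points.

    Each voxel value is the mean of ``supersampling**3`` scene evaluations
    on a regular sub-lattice, so boundary voxels carry partial-volume
    (anti-aliased) susceptibilities. Processes the grid in z-slabs to
    bound memory.
    """
    if supersampling < 1:
        raise ValueError("supersampling must be >= 1")
    _warn_under_resolved(scene, grid)

    nx, ny, nz = grid.counts
    sx, sy, sz = grid.spacing
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    # sub-voxel offsets, centered within the voxel
    sub = (np.arange(supersampling) + 0.5) / supersampling - 0.5
    ox = sub * sx
    oy = sub * sy
    oz = sub * sz

    chi = np.empty(grid.shape, dtype=np.float64)
    # slab size targeting ~4e6 sample points at a time
    n_sub = supersampling ** 3
    slab = max(1, int(4e6 / max(1, nx * ny * n_sub)))
    for z0 in range(0, nz, slab):
        z1 = min(nz, z0 + slab)
        # points: (nx*S, ny*S, (z1-z0)*S, 3) built via broadcasting
        px = (xs[:, None] + ox[None, :]).ravel()
        py = (ys[:, None] + oy[None, :]).ravel()
        pz = (zs[z0:z1, None] + oz[None, :]).ravel()
        pts = np.empty((px.size, py.size, pz.size, 3), dtype=np.float64)
        pts[..., 0] = px[:, None, None]
        pts[..., 1] = py[None, :, None]
        pts[..., 2] = pz[None, None, :]
        vals = scene.paint(pts)
        vals = vals.reshape(nx, supersampling, ny, supersampling,
                            z1 - z0, supersampling)
        chi[:, :, z0:z1] = vals.mean(axis=(1, 3, 5))
    return SusceptibilityMap(grid=grid, chi=chi, background_chi=scene.background_chi)


# ---------------------------------------------------------------------------
# analytic volumes
# ---------------------------------------------------------------------------

def _bounds_disjoint(a: Shape, b: Shape) -> bool:
    lo_a, hi_a = a.bounds()
    lo_b, hi_b = b.bounds()
    return bool(np.any(hi_a < lo_b) or np.any(hi_b < lo_a))


def analytic_volume(shape: Shape) -> float:
    """Closed-form volume in µL for primitives and disjoint unions.

    Raises :class:`UnsupportedGeometryError` for unbounded shapes and for
    composites without a closed form (overlapping unions, differences).
    """
    if isinstance(shape, Ellipsoid):
        a, b, c = shape.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c
    if isinstance(shape, Cylinder):
        return math.pi * shape.radius ** 2 * (shape.z_max - shape.z_min)
    if isinstance(shape, Union):
        kids = shape.shapes
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                if not _bounds_disjoint(kids[i], kids[j]):
                    raise UnsupportedGeometryError(
                        "union children overlap (or touch); no closed form")
        return sum(analytic_volume(k) for k in kids)
    raise UnsupportedGeometryError(
        f"no closed-form volume for {type(shape).__name__}")


# ---------------------------------------------------------------------------
# cell design
# ---------------------------------------------------------------------------

def _ellipsoid_cap_volume(a: float, c: float, z0: float) -> float:
    """Volume of the spheroid cap z in [z0, c] of an a,a,c spheroid, µL."""
    z0 = min(max(z0, -c), c)
    return math.pi * a * a / (c * c) * (2.0 * c ** 3 / 3.0 - c * c * z0 + z0 ** 3 / 3.0)


@dataclass(frozen=True)
class CellDesign:
    """Printable ellipsoidal microcell with a cylindrical access channel.

    ``semi_axes`` are the interior cavity semi-axes (mm), long axis along
    B0. The access channel is a bore of ``channel_diameter`` starting
    where the cavity cross-section narrows to the bore radius and
    extending ``channel_length`` upward. ``wall_thickness`` is added to
    every interior dimension to obtain the printed solid.
    """

    semi_axes: tuple[float, float, float] = (1.65, 1.65, 11.5)
    channel_diameter: float = 1.3
    channel_length: float = 8.5
    wall_thickness: float = 0.3
    with_channel: bool = True

    def __post_init__(self):
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError("semi-axes must be > 0")
        if self.wall_thickness <= 0:
            raise ValueError("wall thickness must be > 0")
        if self.with_channel and (self.channel_diameter <= 0 or self.channel_length <= 0):
            raise ValueError("channel dimensions must be > 0")
        a, b, c = self.semi_axes
        if self.with_channel and self.channel_diameter / 2.0 >= min(a, b):
            raise ValueError("channel bore wider than the cavity")

    @property
    def channel_radius(self) -> float:
        return self.channel_diameter / 2.0

    @property
    def channel_z_start(self) -> float:
        """Height where the bore wall meets the interior ellipsoid."""
        a, _, c = self.semi_axes
        r = self.channel_radius
        return c * math.sqrt(max(0.0, 1.0 - (r / a) ** 2))

    @property
    def channel_z_top(self) -> float:
        return self.channel_z_start + self.channel_length

    @property
    def ellipsoid_volume_ul(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def channel_volume_ul(self) -> float:
        if not self.with_channel:
            return 0.0
        return math.pi * self.channel_radius ** 2 * self.channel_length

    @property
    def overlap_volume_ul(self) -> float:
        """Cavity/channel double-counted volume: the spheroid cap above
        the bore-attachment height (where the cap lies inside the bore)."""
        if not self.with_channel:
            return 0.0
        a, _, c = self.semi_axes
        return _ellipsoid_cap_volume(a, c, self.channel_z_start)

    @property
    def total_volume_ul(self) -> float:
        return self.ellipsoid_volume_ul + self.channel_volume_ul - self.overlap_volume_ul

    @property
    def outer_semi_axes(self) -> tuple[float, float, float]:
        w = self.wall_thickness
        a, b, c = self.semi_axes
        return (a + w, b + w, c + w)

    # -- solid description used by voxel meshing ---------------------------
    def solid_mask(self, points: np.ndarray) -> np.ndarray:
        """True where a point lies in printed resin."""
        inner = Ellipsoid((0, 0, 0), self.semi_axes)
        outer = Ellipsoid((0, 0, 0), self.outer_semi_axes)
        occupied = outer.contains(points)
        hollow = inner.contains(points)
        if self.with_channel:
            r, w = self.channel_radius, self.wall_thickness
            a_o, _, c_o = self.outer_semi_axes
            neck_base = c_o * math.sqrt(max(0.0, 1.0 - ((r + w) / a_o) ** 2))
            neck = Cylinder(r + w, neck_base, self.channel_z_top)
            bore = Cylinder(r, self.channel_z_start, self.channel_z_top + w)
            occupied = occupied | neck.contains(points)
            hollow = hollow | bore.contains(points)
        return occupied & ~hollow


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

@dataclass
class Preset:
    """A measurement scene plus the sample the shims were set on.

    ``shim_reference`` reproduces the experimental protocol of shimming
    on a plain solvent-filled tube at the same fill height; forwarding
    the χ-difference of scene and reference emulates first-order shim
    removal of the tube-bottom gradient.
    """

    scene: Scene
    shim_reference: Scene | None = None
    notes: str = ""


def _shigemi(chi_glass: float, chi_solvent: float, *, tube_id: float = 4.2,
             glass_length: float = 8.0, solvent_top: float = 25.0,
             background_chi: float = CHI_AIR_PPM) -> Preset:
    r = tube_id / 2.0
    scene = Scene(background_chi=background_chi)
    scene.add(Cylinder(r, -glass_length, 0.0), chi_glass)
    scene.add(Cylinder(r, 0.0, solvent_top), chi_solvent)
    ref = Scene(background_chi=background_chi)
    ref.add(Cylinder(r, -glass_length, solvent_top), chi_solvent)
    return Preset(scene, ref, notes="glass-bottom tube; interface at z=0")


def _plug_in_tube(chi_resin: float, chi_solvent: float, *, tube_id: float = 4.2,
                  plug_od: float = 4.0, plug_length: float = 20.0,
                  solvent_top: float = 25.0,
                  background_chi: float = CHI_AIR_PPM) -> Preset:
    scene = Scene(background_chi=background_chi)
    scene.add(Cylinder(tube_id / 2.0, -plug_length, solvent_top), chi_solvent)
    scene.add(Cylinder(plug_od / 2.0, -plug_length, 0.0), chi_resin)
    ref = Scene(background_chi=background_chi)
    ref.add(Cylinder(tube_id / 2.0, -plug_length, solvent_top), chi_solvent)
    return Preset(scene, ref, notes="printed plug below solvent; plug top at z=0")


def _microcell(chi_solvent: float, chi_resin: float, *,
               design: CellDesign | None = None, channel: bool = True,
               include_tube: bool = False, chi_glass: float | None = None,
               tube_id: float = 4.2, tube_od: float = 5.0,
               tube_z: tuple[float, float] = (-30.0, 30.0),
               background_chi: float = CHI_AIR_PPM) -> Preset:
    design = design or CellDesign(with_channel=channel)
    if design.with_channel != channel:
        design = CellDesign(design.semi_axes, design.channel_diameter,
                            design.channel_length, design.wall_thickness,
                            with_channel=channel)
    scene = Scene(background_chi=background_chi)
    if include_tube:
        if chi_glass is None:
            raise ValueError("include_tube=True requires chi_glass")
        tube = Difference(Cylinder(tube_od / 2.0, *tube_z),
                          Cylinder(tube_id / 2.0, *tube_z))
        scene.add(tube, chi_glass)
    scene.add(Ellipsoid((0, 0, 0), design.outer_semi_axes), chi_resin)
    if channel:
        r, w = design.channel_radius, design.wall_thickness
        a_o, _, c_o = design.outer_semi_axes
        neck_base = c_o * math.sqrt(max(0.0, 1.0 - ((r + w) / a_o) ** 2))
        scene.add(Cylinder(r + w, neck_base, design.channel_z_top), chi_resin)
    scene.add(Ellipsoid((0, 0, 0), design.semi_axes), chi_solvent)
    if channel:
        scene.add(Cylinder(design.channel_radius, design.channel_z_start,
                           design.channel_z_top), chi_solvent)
    return Preset(scene, None, notes="solvent-filled ellipsoidal cell in resin shell")


_PRESETS = {"shigemi": _shigemi, "plug_in_tube": _plug_in_tube, "microcell": _microcell}


def build_preset(name: str, **params) -> Preset:
    """Build one of the canonical measurement geometries.

    ``shigemi``: solvent column above a glass half-segment in a 4.2 mm ID
    tube, interface at z = 0. Requires ``chi_glass`` and ``chi_solvent``.

    ``plug_in_tube``: 4.0 mm OD × 20 mm printed cylinder below solvent in
    a 4.2 mm ID tube. Requires ``chi_resin`` and ``chi_solvent``.

    ``microcell``: solvent-filled ellipsoid (optional access channel) in
    a resin shell. Requires ``chi_solvent`` and ``chi_resin``.
    """
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; "
                         f"choose from {sorted(_PRESETS)}") from None
    try:
        return builder(**params)
    except TypeError as exc:
        raise ValueError(f"bad parameters for preset {name!r}: {exc}") from None


def build_preset_scene(name: str, **params) -> Scene:
    """Scene only (no shim reference); see :func:`build_preset`."""
    return build_preset(name, **params).scene


# ---------------------------------------------------------------------------
# STL export
# ---------------------------------------------------------------------------

def _ellipsoid_mesh(semi_axes, subdivisions: int):
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions)
    mesh.apply_scale(semi_axes)
    return mesh


def _shell_mesh_parametric(design: CellDesign, facet_count: int):
    import trimesh

    # two closed surfaces (outer + inverted inner); 20*4^n faces each
    sub = 0
    while 2 * 20 * 4 ** (sub + 1) <= facet_count:
        sub += 1
    outer = _ellipsoid_mesh(design.outer_semi_axes, sub)
    inner = _ellipsoid_mesh(design.semi_axes, sub)
    inner.invert()
    return trimesh.util.concatenate([outer, inner])


def _shell_mesh_voxel(design: CellDesign, facet_count: int):
    """Marching-cubes mesh of the full solid (used when the channel
    pierces the shell and no parametric seam is available)."""
    from skimage import measure
    import trimesh

    a_o, b_o, c_o = design.outer_semi_axes
    # pitch from a facet-count target: triangles ~ 2 * area / pitch^2
    a, b, c = design.semi_axes
    p = 1.6075
    area = 4 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)
    pitch = math.sqrt(4.0 * area / max(64, facet_count))
    pitch = min(pitch, design.wall_thickness / 2.0)

    z_top = design.channel_z_top + design.wall_thickness if design.with_channel else c_o
    lo = np.array([-a_o, -b_o, -c_o]) - 2 * pitch
    hi = np.array([a_o, b_o, z_top]) + 2 * pitch
    ns = np.maximum(8, np.ceil((hi - lo) / pitch).astype(int))
    # occupancy fraction per cell (3^3 sub-samples) -> smooth level set,
    # sub-voxel surface placement under marching-cubes linear interpolation
    sub = (np.arange(3) + 0.5) / 3.0 - 0.5
    axes = [lo[i] + pitch * (np.arange(ns[i])[:, None] + sub[None, :])
            for i in range(3)]
    pts = np.empty((ns[0] * 3, ns[1] * 3, ns[2] * 3, 3))
    pts[..., 0] = axes[0].ravel()[:, None, None]
    pts[..., 1] = axes[1].ravel()[None, :, None]
    pts[..., 2] = axes[2].ravel()[None, None, :]
    occ = design.solid_mask(pts).reshape(ns[0], 3, ns[1], 3, ns[2], 3)
    occ = occ.mean(axis=(1, 3, 5)).astype(np.float64)
    verts, faces, _, _ = measure.marching_cubes(occ, level=0.5, spacing=(pitch,) * 3)
    verts += lo
    return trimesh.Trimesh(vertices=verts, faces=faces)


def export_stl(design: CellDesign, facet_count: int = 10_000, path=None):
    """Write a watertight binary STL of the printed solid.

    The shell (outer minus inner ellipsoid) is meshed parametrically;
    when the access channel is enabled the pierced solid is meshed by
    marching cubes over its implicit description. ``facet_count`` is an
    approximate resolution target; mesh volume converges to the analytic
    solid volume as it grows.
    """
    if facet_count < 64:
        raise ValueError("facet_count must be >= 64")
    if design.with_channel:
        mesh = _shell_mesh_voxel(design, facet_count)
    else:
        mesh = _shell_mesh_parametric(design, facet_count)
    if not mesh.is_watertight:
        raise MeshExportError("generated mesh is not watertight")
    if mesh.volume < 0:
        mesh.invert()
    if path is not None:
        mesh.export(str(path), file_type="stl")
    return mesh
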