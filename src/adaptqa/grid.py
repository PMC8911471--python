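"""Voxel-grid data model and 3D morphological primitives.

Everything downstream (target rules, dosimetry, contour metrics) operates on
binary structure masks sampled on a shared anisotropic voxel lattice in
patient millimetre coordinates.  Conventions:

* voxel-centre semantics: ``origin`` is the physical position (mm) of the
  centre of voxel index ``(0, 0, 0)``;
* array axis order is ``(x, y, z)`` with z the cranio-caudal axis
  (z increases cranially);
* grids are axis-aligned (identity direction cosines) — general
  orientations are rejected at the I/O boundary, never resampled silently;
* two grids are *compatible* iff origin, spacing and shape are equal
  (exact float match); every cross-structure operation requires it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy import ndimage


class GridCompatibilityError(ValueError):
    """Raised when an operation mixes structures on incompatible grids."""


class RasterizationError(ValueError):
    """Raised for degenerate polygons or slices outside the grid extent."""


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned anisotropic sampling lattice in patient millimetres."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        origin = tuple(float(v) for v in self.origin)
        spacing = tuple(float(v) for v in self.spacing)
        shape = tuple(int(v) for v in self.shape)
        if len(origin) != 3 or len(spacing) != 3 or len(shape) != 3:
            raise ValueError("origin, spacing and shape must be length-3")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing components must be > 0, got {spacing}")
        if any(n < 1 for n in shape):
            raise ValueError(f"shape components must be >= 1, got {shape}")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "shape", shape)

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cubic centimetres."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def voxel_diagonal_mm(self) -> float:
        return float(np.linalg.norm(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical centre coordinates (mm) of voxels along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    @property
    def z_coords(self) -> np.ndarray:
        return self.axis_coords(2)

    def compatible_with(self, other: "VoxelGrid") -> bool:
        return (
            self.origin == other.origin
            and self.spacing == other.spacing
            and self.shape == other.shape
        )

    def require_compatible(self, other: "VoxelGrid") -> None:
        if not self.compatible_with(other):
            raise GridCompatibilityError(
                f"incompatible grids: {self} vs {other}"
            )

    def slice_index(self, z_mm: float) -> int:
        """Map a physical z coordinate to the nearest slice index.

        Errors if the coordinate is farther than half a slice spacing from
        any slice centre, or falls outside the grid extent.
        """
        dz = self.spacing[2]
        k = int(round((z_mm - self.origin[2]) / dz))
        if k < 0 or k >= self.shape[2]:
            raise RasterizationError(
                f"slice z={z_mm} mm lies outside grid extent "
                f"[{self.origin[2]}, {self.z_coords[-1]}] mm"
            )
        if abs(z_mm - (self.origin[2] + k * dz)) > dz / 2 + 1e-9:
            raise RasterizationError(
                f"slice z={z_mm} mm is more than half a slice spacing from "
                f"the nearest grid slice"
            )
        return k


class Role(str, enum.Enum):
    TARGET = "TARGET"
    OAR = "OAR"
    DERIVED = "DERIVED"


@dataclass
class StructureMask:
    """Named binary occupancy on a :class:`VoxelGrid`."""

    name: str
    role: Role
    grid: VoxelGrid
    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"mask array shape {self.data.shape} does not match grid "
                f"shape {self.grid.shape}"
            )
        self.role = Role(self.role)

    # -- basic measures ----------------------------------------------------
    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_cc

    @property
    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def same_occupancy(self, other: "StructureMask") -> bool:
        self.grid.require_compatible(other.grid)
        return bool(np.array_equal(self.data, other.data))

    def copy(self, name: str | None = None, role: Role | None = None) -> "StructureMask":
        return StructureMask(
            name=name or self.name,
            role=role or self.role,
            grid=self.grid,
            data=self.data.copy(),
            meta=dict(self.meta),
        )

    # -- set algebra (closed over compatible masks) ------------------------
    def _binary(self, other: "StructureMask", op, name: str) -> "StructureMask":
        self.grid.require_compatible(other.grid)
        return StructureMask(name, Role.DERIVED, self.grid, op(self.data, other.data))

    def union(self, other: "StructureMask") -> "StructureMask":
        return self._binary(other, np.logical_or, f"{self.name}|{other.name}")

    def intersection(self, other: "StructureMask") -> "StructureMask":
        return self._binary(other, np.logical_and, f"{self.name}&{other.name}")

    def difference(self, other: "StructureMask") -> "StructureMask":
        return self._binary(
            other, lambda a, b: a & ~b, f"{self.name}-{other.name}"
        )

    __or__ = union
    __and__ = intersection
    __sub__ = difference


@dataclass
class SlicePolygonSet:
    """Per-axial-slice closed planar contours for one structure.

    ``slices`` maps a physical slice z coordinate (mm) to a list of
    ``(n, 2)`` vertex arrays in patient (x, y) mm.  Polygons are closed
    implicitly (last vertex joins the first).  Holes are expressed as
    additional polygons and resolved by the even-odd rule.
    """

    name: str
    slices: dict[float, list[np.ndarray]]

    def __post_init__(self) -> None:
        cleaned: dict[float, list[np.ndarray]] = {}
        for z, polys in self.slices.items():
            out = []
            for p in polys:
                arr = np.asarray(p, dtype=float)
                if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                    raise RasterizationError(
                        f"degenerate polygon for '{self.name}' at z={z} mm: "
                        f"need >= 3 (x, y) vertices, got shape {arr.shape}"
                    )
                out.append(arr)
            cleaned[float(z)] = out
        self.slices = cleaned

    @property
    def n_slices(self) -> int:
        return len(self.slices)


def rasterize(
    polygons: SlicePolygonSet, grid: VoxelGrid, role: Role = Role.OAR
) -> StructureMask:
    """Rasterize closed planar contours onto a grid.

    A voxel is set iff its centre lies inside an odd number of the slice's
    polygons (even-odd rule), which resolves nested holes the way RT
    structure sets express them.
    """
    data = np.zeros(grid.shape, dtype=bool)
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel()])
    for z, polys in polygons.slices.items():
        k = grid.slice_index(z)
        inside = np.zeros(points.shape[0], dtype=bool)
        for poly in polys:
            # contains_points closes the ring implicitly; passing
            # closed=True would consume the last vertex as a CLOSEPOLY code
            inside ^= _MplPath(poly).contains_points(points)
        data[:, :, k] |= inside.reshape(grid.shape[0], grid.shape[1])
    return StructureMask(polygons.name, role, grid, data)


def expand(mask: StructureMask, margin_mm: float) -> StructureMask:
    """Isotropic physical expansion by a non-negative margin.

    The result contains every voxel whose centre lies within ``margin_mm``
    (inclusive) Euclidean millimetres of the centre of a set voxel, using
    the exact anisotropic distance transform.  ``expand(m, 0)`` is the
    identity.
    """
    if margin_mm < 0:
        raise ValueError(
            f"margin must be >= 0 (got {margin_mm}); contraction is not "
            "provided"
        )
    if margin_mm == 0 or mask.is_empty:
        return mask.copy()
    dist = ndimage.distance_transform_edt(
        ~mask.data, sampling=mask.grid.spacing
    )
    out = mask.copy()
    out.data = dist <= margin_mm
    out.role = Role.DERIVED if out.role is Role.DERIVED else out.role
    return out


def interior_depth_mm(mask: StructureMask) -> np.ndarray:
    """Depth map: for set voxels, Euclidean distance (mm) to the nearest
    cleared voxel; 0 outside the mask.  A boundary voxel has depth > 0."""
    if mask.is_empty:
        return np.zeros(mask.grid.shape, dtype=float)
    return ndimage.distance_transform_edt(mask.data, sampling=mask.grid.spacing)


def trim_to_depth(
    target: StructureMask, organ: StructureMask, max_depth_mm: float
) -> StructureMask:
    """Remove target voxels lying deeper than ``max_depth_mm`` inside the organ.

    Depth of an organ voxel is its distance to the organ's exterior (nearest
    non-organ voxel).  Target voxels outside the organ are untouched; the
    result never gains voxels.
    """
    target.grid.require_compatible(organ.grid)
    if max_depth_mm < 0:
        raise ValueError(f"max depth must be >= 0, got {max_depth_mm}")
    depth = interior_depth_mm(organ)
    too_deep = organ.data & (depth > max_depth_mm)
    out = target.copy()
    out.data = target.data & ~too_deep
    return out


def crop_above(mask: StructureMask, z_limit_mm: float) -> StructureMask:
    """Clear every slice whose centre z coordinate exceeds ``z_limit_mm``."""
    out = mask.copy()
    above = mask.grid.z_coords > z_limit_mm
    out.data[:, :, above] = False
    return out


def superior_extent_mm(mask: StructureMask) -> float:
    """Centre z (mm) of the most cranial slice containing any set voxel."""
    if mask.is_empty:
        raise ValueError(f"structure '{mask.name}' is empty: no superior extent")
    ks = np.nonzero(mask.data.any(axis=(0, 1)))[0]
    return float(mask.grid.z_coords[ks[-1]])
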