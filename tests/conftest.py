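"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
point-in-polygon is a scalar ray cast, distances are all-pairs Euclidean
loops, and volume-indexed dose metrics walk the sorted voxel list in pure
Python.
"""

from __future__ import annotations

import numpy as np
import pytest

from adaptqa.grid import Role, StructureMask, VoxelGrid


@pytest.fixture
def small_grid() -> VoxelGrid:
    return VoxelGrid(origin=(0.0, 0.0, 0.0), spacing=(1.5, 1.5, 3.0), shape=(12, 12, 8))


@pytest.fixture
def iso_grid() -> VoxelGrid:
    return VoxelGrid(origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0), shape=(9, 9, 9))


def random_mask(grid: VoxelGrid, rng: np.random.Generator, p: float = 0.3,
                name: str = "m") -> StructureMask:
    return StructureMask(name, Role.OAR, grid, rng.random(grid.shape) < p)


def voxel_centres(grid: VoxelGrid) -> np.ndarray:
    """(N, 3) physical centre coordinates of every voxel, C-order."""
    axes = [grid.axis_coords(a) for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_point_in_polygon(poly: np.ndarray, x: float, y: float) -> bool:
    """Even-odd crossing-number test for a single closed polygon."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def oracle_point_in_polygons(polys, x: float, y: float) -> bool:
    """Even-odd rule across nested polygons (odd number of containments)."""
    count = sum(oracle_point_in_polygon(p, x, y) for p in polys)
    return count % 2 == 1


def oracle_expand(mask: StructureMask, margin_mm: float) -> np.ndarray:
    """Brute-force expansion: all-pairs distance from every voxel centre."""
    centres = voxel_centres(mask.grid)
    set_centres = centres[mask.data.ravel()]
    if set_centres.size == 0:
        return np.zeros(mask.grid.shape, dtype=bool)
    d2 = ((centres[:, None, :] - set_centres[None, :, :]) ** 2).sum(axis=2)
    return (d2.min(axis=1) <= margin_mm**2 + 1e-12).reshape(mask.grid.shape)


def oracle_depth_map(organ: StructureMask) -> np.ndarray:
    """Brute-force interior depth: distance from each set voxel to the
    nearest cleared voxel centre (0 outside the organ)."""
    centres = voxel_centres(organ.grid)
    inside = organ.data.ravel()
    cleared = centres[~inside]
    depth = np.zeros(centres.shape[0])
    if cleared.size:
        d2 = ((centres[inside, None, :] - cleared[None, :, :]) ** 2).sum(axis=2)
        depth[inside] = np.sqrt(d2.min(axis=1))
    return depth.reshape(organ.grid.shape)


def oracle_dose_at_volume(values, v_cc: float, voxel_cc: float) -> float:
    """Pure-Python sort-and-accumulate: dose exceeded by the hottest v_cc."""
    desc = sorted(values, reverse=True)
    centres = [(i + 0.5) * voxel_cc for i in range(len(desc))]
    if v_cc <= centres[0]:
        return desc[0]
    if v_cc >= centres[-1]:
        return desc[-1]
    for i in range(len(desc) - 1):
        if centres[i] <= v_cc <= centres[i + 1]:
            w = (v_cc - centres[i]) / (centres[i + 1] - centres[i])
            return desc[i] * (1 - w) + desc[i + 1] * w
    raise AssertionError("unreachable")


def oracle_anova(groups) -> tuple[float, float]:
    """Textbook one-way fixed-effects ANOVA from sums of squares."""
    from scipy.stats import f as f_dist

    all_vals = np.concatenate([np.asarray(g, float) for g in groups])
    grand = all_vals.mean()
    k = len(groups)
    n = all_vals.size
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    f_stat = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f_stat, float(f_dist.sf(f_stat, k - 1, n - k))
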