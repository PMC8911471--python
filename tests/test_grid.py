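"""Grid model, rasterization and morphological operator tests."""

import numpy as np
import pytest

from adaptqa.grid import (
    GridCompatibilityError,
    RasterizationError,
    Role,
    SlicePolygonSet,
    StructureMask,
    VoxelGrid,
    crop_above,
    expand,
    interior_depth_mm,
    rasterize,
    superior_extent_mm,
    trim_to_depth,
)

from conftest import (
    oracle_depth_map,
    oracle_expand,
    oracle_point_in_polygons,
    random_mask,
    voxel_centres,
)


class TestVoxelGrid:
    def test_voxel_volume_and_validation(self):
        g = VoxelGrid((0, 0, 0), (1.5, 1.5, 3.0), (10, 10, 5))
        assert g.voxel_volume_cc == pytest.approx(6.75 / 1000)
        with pytest.raises(ValueError):
            VoxelGrid((0, 0, 0), (0.0, 1, 1), (4, 4, 4))
        with pytest.raises(ValueError):
            VoxelGrid((0, 0, 0), (1, 1, 1), (0, 4, 4))

    def test_compatibility_is_exact_metadata_equality(self, small_grid):
        same = VoxelGrid(small_grid.origin, small_grid.spacing, small_grid.shape)
        shifted = VoxelGrid((0, 0, 0.1), small_grid.spacing, small_grid.shape)
        assert small_grid.compatible_with(same)
        with pytest.raises(GridCompatibilityError):
            small_grid.require_compatible(shifted)


class TestSetAlgebra:
    def test_identities_on_random_masks(self, small_grid):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            a = random_mask(small_grid, rng, 0.4, "a")
            b = random_mask(small_grid, rng, 0.4, "b")
            inter = a & b
            union = a | b
            diff = a - b
            assert np.all(inter.data <= a.data)  # A∩B ⊆ A
            assert np.all(diff.data <= a.data)  # A\B ⊆ A
            assert union.voxel_count == a.voxel_count + b.voxel_count - inter.voxel_count

    def test_volume_is_count_times_voxel_volume(self, small_grid):
        m = random_mask(small_grid, np.random.default_rng(3), 0.5)
        assert m.volume_cc == pytest.approx(m.voxel_count * small_grid.voxel_volume_cc)


class TestRasterize:
    def test_square_on_one_slice(self):
        grid = VoxelGrid((0.5, 0.5, 0), (1, 1, 3), (20, 20, 3))
        square = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        mask = rasterize(SlicePolygonSet("sq", {3.0: [square]}), grid)
        assert mask.voxel_count == 100
        assert mask.volume_cc == pytest.approx(0.3)
        assert mask.data[:, :, 1].sum() == 100 and mask.data[:, :, 0].sum() == 0

    def test_empty_polygon_set_gives_empty_mask(self, small_grid):
        mask = rasterize(SlicePolygonSet("none", {}), small_grid)
        assert mask.is_empty and mask.volume_cc == 0.0

    def test_concentric_hole_uses_even_odd_rule(self):
        grid = VoxelGrid((0.5, 0.5, 0), (1, 1, 3), (20, 20, 1))
        outer = np.array([[0, 0], [12, 0], [12, 12], [0, 12]], float)
        inner = np.array([[4, 4], [8, 4], [8, 8], [4, 8]], float)
        mask = rasterize(SlicePolygonSet("ring", {0.0: [outer, inner]}), grid)
        assert mask.voxel_count == 144 - 16

    def test_degenerate_polygon_and_out_of_extent_slice_raise(self, small_grid):
        with pytest.raises(RasterizationError, match="degenerate"):
            SlicePolygonSet("bad", {0.0: [np.array([[0, 0], [1, 1]], float)]})
        polys = SlicePolygonSet(
            "far", {99.0: [np.array([[0, 0], [5, 0], [5, 5]], float)]}
        )
        with pytest.raises(RasterizationError, match="outside grid extent"):
            rasterize(polys, small_grid)

    def test_rasterize_is_idempotent(self):
        grid = VoxelGrid((0.5, 0.5, 0), (1, 1, 3), (20, 20, 1))
        tri = np.array([[1.2, 0.7], [15.3, 2.9], [7.4, 16.1]], float)
        polys = SlicePolygonSet("t", {0.0: [tri]})
        assert rasterize(polys, grid).same_occupancy(rasterize(polys, grid))

    def test_matches_even_odd_oracle_on_random_polygons(self):
        grid = VoxelGrid((0.25, 0.25, 0), (1, 1, 3), (14, 14, 1))
        rng = np.random.default_rng(7)
        centres = voxel_centres(grid)
        for _ in range(50):
            # random star-shaped simple polygon around a random centre
            cx, cy = rng.uniform(3, 10, 2)
            angles = np.sort(rng.uniform(0, 2 * np.pi, rng.integers(3, 9)))
            radii = rng.uniform(1.0, 5.0, angles.size)
            poly = np.column_stack(
                [cx + radii * np.cos(angles), cy + radii * np.sin(angles)]
            )
            mask = rasterize(SlicePolygonSet("r", {0.0: [poly]}), grid)
            expected = np.array(
                [oracle_point_in_polygons([poly], x, y) for x, y, _ in centres]
            ).reshape(grid.shape)
            assert np.array_equal(mask.data, expected)


class TestExpand:
    def test_zero_margin_is_identity(self, small_grid):
        m = random_mask(small_grid, np.random.default_rng(1), 0.2)
        assert expand(m, 0.0).same_occupancy(m)

    def test_negative_margin_rejected(self, small_grid):
        with pytest.raises(ValueError, match="margin"):
            expand(random_mask(small_grid, np.random.default_rng(1)), -1.0)

    def test_single_voxel_isotropic_3mm_ball(self, iso_grid):
        data = np.zeros(iso_grid.shape, bool)
        data[4, 4, 4] = True
        m = StructureMask("pt", Role.OAR, iso_grid, data)
        out = expand(m, 3.0)
        assert out.voxel_count == 123  # lattice points with |d| <= 3 mm
        assert np.array_equal(out.data, oracle_expand(m, 3.0))

    def test_sphere_expansion_matches_analytic_volume(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (56, 56, 56))
        centres = voxel_centres(grid)
        d2 = ((centres - 27.5) ** 2).sum(axis=1).reshape(grid.shape)
        sphere = StructureMask("s", Role.TARGET, grid, d2 <= 20.0**2)
        grown = expand(sphere, 3.0)
        analytic_cc = 4 / 3 * np.pi * 23.0**3 / 1000
        assert abs(grown.volume_cc - analytic_cc) / analytic_cc < 0.05

    def test_monotone_in_mask_and_margin(self, small_grid):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = random_mask(small_grid, rng, 0.1, "a")
            b = a.copy("b")
            b.data |= random_mask(small_grid, rng, 0.1).data
            assert np.all(expand(a, 2.0).data <= expand(b, 2.0).data)
            assert np.all(expand(a, 1.0).data <= expand(a, 2.5).data)
            assert np.all(a.data <= expand(a, 1.0).data)  # result ⊇ input


class TestTrimToDepth:
    def test_disjoint_target_unchanged(self, small_grid):
        rng = np.random.default_rng(2)
        target = random_mask(small_grid, rng, 0.3, "t")
        organ = target.copy("o")
        organ.data = ~target.data
        organ.data[:, :, :2] = False
        trimmed = trim_to_depth(target, organ, 1.0)
        # only voxels of target inside organ may be removed; here overlap
        # exists only if both true somewhere
        assert np.all(trimmed.data <= target.data)
        disjoint_organ = StructureMask(
            "o2", Role.OAR, small_grid, np.zeros(small_grid.shape, bool)
        )
        assert trim_to_depth(target, disjoint_organ, 1.0).same_occupancy(target)

    def test_slab_penetration_limited_voxelwise(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (30, 20, 5))
        organ = np.zeros(grid.shape, bool)
        organ[0:20] = True  # organ slab x in [0,19]
        target = np.zeros(grid.shape, bool)
        target[10:30] = True  # penetrates 10 mm into organ
        organ_m = StructureMask("organ", Role.OAR, grid, organ)
        target_m = StructureMask("tgt", Role.TARGET, grid, target)
        trimmed = trim_to_depth(target_m, organ_m, 3.0)
        depth = oracle_depth_map(organ_m)
        assert not np.any(trimmed.data & (depth > 3.0))
        kept = target & ~(organ & (depth > 3.0))
        assert np.array_equal(trimmed.data, kept)

    def test_depth_zero_subtracts_whole_organ(self, small_grid):
        rng = np.random.default_rng(9)
        target = random_mask(small_grid, rng, 0.5, "t")
        organ = random_mask(small_grid, rng, 0.3, "o")
        trimmed = trim_to_depth(target, organ, 0.0)
        assert np.array_equal(trimmed.data, target.data & ~organ.data)

    def test_infinite_depth_is_identity_and_never_gains(self, small_grid):
        rng = np.random.default_rng(10)
        target = random_mask(small_grid, rng, 0.5, "t")
        organ = random_mask(small_grid, rng, 0.3, "o")
        assert trim_to_depth(target, organ, np.inf).same_occupancy(target)
        assert np.all(trim_to_depth(target, organ, 2.0).data <= target.data)

    def test_incompatible_grids_rejected(self, small_grid, iso_grid):
        t = random_mask(small_grid, np.random.default_rng(0), 0.4)
        o = random_mask(iso_grid, np.random.default_rng(0), 0.4)
        with pytest.raises(GridCompatibilityError):
            trim_to_depth(t, o, 3.0)


class TestCropAbove:
    def test_limits_beyond_grid_are_identity_or_empty(self, small_grid):
        m = random_mask(small_grid, np.random.default_rng(4), 0.5)
        assert crop_above(m, 1e6).same_occupancy(m)
        assert crop_above(m, -1e6).is_empty

    def test_slab_cropped_at_slice_centres(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 3), (4, 4, 11))  # z centres 0..30
        m = StructureMask("slab", Role.OAR, grid, np.ones(grid.shape, bool))
        out = crop_above(m, 15.0)
        kept_z = grid.z_coords[out.data.any(axis=(0, 1))]
        assert kept_z.max() == 15.0 and out.voxel_count == 4 * 4 * 6

    def test_superior_extent_is_top_occupied_slice_centre(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 3), (4, 4, 11))
        data = np.zeros(grid.shape, bool)
        data[1, 1, 4] = True
        assert superior_extent_mm(StructureMask("m", Role.OAR, grid, data)) == 12.0
        with pytest.raises(ValueError, match="empty"):
            superior_extent_mm(StructureMask("e", Role.OAR, grid, np.zeros(grid.shape, bool)))
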