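import math

import numpy as np
import pytest
import shapely

from landepi.metrics import (class_area_over_buffer, class_proportion,
                             clip_roads, delineate_patches, min_perimeter,
                             road_density, road_linearity, shape_index,
                             total_edge, unit_shape_metric)
from landepi.synth import RoadNetwork


def oracle_flood_fill(member, connectivity):
    """Brute-force BFS connected components."""
    nrows, ncols = member.shape
    seen = np.zeros_like(member, dtype=bool)
    if connectivity == 4:
        nbrs = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    comps = []
    for r in range(nrows):
        for c in range(ncols):
            if member[r, c] and not seen[r, c]:
                comp = set()
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in nbrs:
                        r2, c2 = rr + dr, cc + dc
                        if (0 <= r2 < nrows and 0 <= c2 < ncols
                                and member[r2, c2] and not seen[r2, c2]):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
                comps.append(frozenset(comp))
    return set(comps)


def oracle_total_edges(member):
    """Per-cell face enumeration: count faces whose neighbour is outside
    the member set (grid border included)."""
    nrows, ncols = member.shape
    edges = 0
    for r in range(nrows):
        for c in range(ncols):
            if not member[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nrows and 0 <= c2 < ncols) or not member[r2, c2]:
                    edges += 1
    return edges


def full_mask(shape):
    return np.ones(shape, dtype=bool)


class TestPatchDelineation:
    def test_diagonal_cells_connectivity(self):
        grid = np.zeros((3, 3))
        grid[0, 0] = grid[1, 1] = 1.0
        p8 = delineate_patches(grid, full_mask(grid.shape), 1.0, connectivity=8)
        p4 = delineate_patches(grid, full_mask(grid.shape), 1.0, connectivity=4)
        assert len(p8) == 1
        assert len(p4) == 2

    def test_absent_class_gives_no_patches(self):
        grid = np.ones((4, 4))
        assert delineate_patches(grid, full_mask(grid.shape), 9.0) == []

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        grid = rng.choice([0.0, 1.0], size=(20, 20), p=[0.6, 0.4])
        patches = delineate_patches(grid, full_mask(grid.shape), 1.0,
                                    connectivity=connectivity)
        got = {frozenset(map(tuple, p.cells)) for p in patches}
        want = oracle_flood_fill(grid == 1.0, connectivity)
        assert got == want

    def test_every_cell_in_exactly_one_patch(self):
        rng = np.random.default_rng(9)
        grid = rng.choice([0.0, 1.0], size=(15, 15))
        patches = delineate_patches(grid, full_mask(grid.shape), 1.0)
        cells = [tuple(c) for p in patches for c in p.cells]
        assert len(cells) == len(set(cells)) == int((grid == 1.0).sum())


class TestEdgeAndShape:
    def test_isolated_300m_cell_edge(self):
        grid = np.zeros((5, 5))
        grid[2, 2] = 1.0
        patches = delineate_patches(grid, full_mask(grid.shape), 1.0,
                                    cell_size=300.0)
        assert total_edge(patches) == pytest.approx(1200.0)

    def test_domino_patch_edge(self):
        grid = np.zeros((5, 5))
        grid[2, 2] = grid[2, 3] = 1.0
        patches = delineate_patches(grid, full_mask(grid.shape), 1.0,
                                    cell_size=300.0)
        assert total_edge(patches) == pytest.approx(1800.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_total_edge_matches_face_enumeration(self, seed):
        rng = np.random.default_rng(seed + 50)
        grid = rng.choice([0.0, 1.0], size=(18, 18))
        patches = delineate_patches(grid, full_mask(grid.shape), 1.0,
                                    cell_size=1.0)
        assert total_edge(patches) == oracle_total_edges(grid == 1.0)

    def test_square_patch_shape_index_one(self):
        grid = np.zeros((4, 4))
        grid[1:3, 1:3] = 1.0
        patches = delineate_patches(grid, full_mask(grid.shape), 1.0)
        assert shape_index(patches[0]) == pytest.approx(1.0)

    def test_line_patch_shape_index(self):
        grid = np.zeros((3, 6))
        grid[1, 1:5] = 1.0  # 1x4 line: perimeter 10, min perimeter 8
        patches = delineate_patches(grid, full_mask(grid.shape), 1.0)
        assert shape_index(patches[0]) == pytest.approx(1.25)

    def test_single_cell_shape_index_one(self):
        grid = np.zeros((3, 3))
        grid[1, 1] = 1.0
        patches = delineate_patches(grid, full_mask(grid.shape), 1.0)
        assert shape_index(patches[0]) == pytest.approx(1.0)

    def test_min_perimeter_by_enumeration(self):
        # exhaustive check against known most-compact polyomino perimeters
        known = {1: 4, 2: 6, 3: 8, 4: 8, 5: 10, 6: 10, 7: 12, 8: 12, 9: 12,
                 10: 14, 12: 14, 16: 16}
        for a, p in known.items():
            assert min_perimeter(a) == p

    def test_translation_invariance_of_edge(self):
        rng = np.random.default_rng(3)
        block = rng.choice([0.0, 1.0], size=(8, 8))
        g1 = np.zeros((14, 14))
        g2 = np.zeros((14, 14))
        g1[1:9, 1:9] = block
        g2[5:13, 4:12] = block
        e1 = total_edge(delineate_patches(g1, full_mask(g1.shape), 1.0,
                                          cell_size=2.0))
        e2 = total_edge(delineate_patches(g2, full_mask(g2.shape), 1.0,
                                          cell_size=2.0))
        assert e1 == e2

    def test_shape_index_invariant_under_cell_size(self):
        grid = np.zeros((3, 6))
        grid[1, 1:5] = 1.0  # 1x4 line
        for cs in (1.0, 300.0):
            patches = delineate_patches(grid, full_mask(grid.shape), 1.0,
                                        cell_size=cs)
            assert shape_index(patches[0]) == pytest.approx(10 / 8)


class TestUnitShapeMetric:
    def test_one_square_patch(self):
        grid = np.zeros((4, 4))
        grid[1:3, 1:3] = 1.0
        patches = delineate_patches(grid, full_mask(grid.shape), 1.0,
                                    cell_size=300.0)
        area = 4 * 300.0 ** 2
        assert unit_shape_metric(patches, "per_patch") == pytest.approx(area)
        assert unit_shape_metric(patches, "area_weighted") == pytest.approx(1.0)

    def test_two_identical_patches_average_like_one(self):
        grid = np.zeros((3, 7))
        grid[1, 1:3] = 1.0
        grid[1, 4:6] = 1.0
        patches = delineate_patches(grid, full_mask(grid.shape), 1.0,
                                    cell_size=1.0)
        assert len(patches) == 2
        one = [patches[0]]
        assert unit_shape_metric(patches, "per_patch") == pytest.approx(
            unit_shape_metric(one, "per_patch") * 2 / 2)

    def test_direct_summation_oracle(self):
        rng = np.random.default_rng(4)
        grid = rng.choice([0.0, 1.0], size=(15, 15))
        patches = delineate_patches(grid, full_mask(grid.shape), 1.0,
                                    cell_size=2.0)
        if not patches:
            pytest.skip("degenerate draw")
        expect = sum(p.area_m2 * p.perimeter_edges / min_perimeter(p.area_cells)
                     for p in patches) / len(patches)
        assert unit_shape_metric(patches, "per_patch") == pytest.approx(expect)

    def test_no_patches_is_an_error(self):
        with pytest.raises(ValueError):
            unit_shape_metric([], "per_patch")


class TestProportionsAndAreas:
    def test_single_cell_proportion(self):
        grid = np.ones((10, 10))
        grid[0, 0] = 2.0
        assert class_proportion(grid, full_mask(grid.shape), 2.0) == pytest.approx(0.01)

    def test_absent_class_zero(self):
        grid = np.ones((5, 5))
        assert class_proportion(grid, full_mask(grid.shape), 3.0) == 0.0

    def test_proportions_partition_to_one(self):
        rng = np.random.default_rng(5)
        grid = rng.choice([1.0, 2.0, 3.0], size=(12, 12))
        total = sum(class_proportion(grid, full_mask(grid.shape), c)
                    for c in (1.0, 2.0, 3.0))
        assert total == pytest.approx(1.0)

    def test_single_pixel_over_2km_buffer(self):
        grid = np.zeros((3, 3))
        grid[1, 1] = 1.0
        patches = delineate_patches(grid, full_mask(grid.shape), 1.0,
                                    cell_size=300.0)
        frac = class_area_over_buffer(patches, math.pi * 2000.0 ** 2)
        assert frac == pytest.approx(0.09e6 / 12.566e6, rel=1e-3)

    def test_no_patches_zero_area(self):
        assert class_area_over_buffer([], 100.0) == 0.0


class TestRoads:
    def test_density_simple(self):
        seg = shapely.LineString([(0, 0), (5000, 0)])
        assert road_density([seg], 100.0) == pytest.approx(0.05)

    def test_no_roads_zero(self):
        assert road_density([], 100.0) == 0.0

    def test_clipping_halves_density(self):
        seg = shapely.LineString([(0, 0), (2000, 0)])
        box_full = shapely.box(-10, -10, 2010, 10)
        box_half = shapely.box(-10, -10, 1000, 10)
        net = RoadNetwork([np.array([(0.0, 0.0), (2000.0, 0.0)])])
        full_len = sum(g.length for g in clip_roads(net, box_full))
        half_len = sum(g.length for g in clip_roads(net, box_half))
        assert half_len == pytest.approx(full_len / 2)

    def test_linearity_straight_and_bent(self):
        straight = np.array([(0.0, 0.0), (10.0, 0.0)])
        bent = np.array([(0.0, 0.0), (3.0, 0.0), (3.0, 4.0)])
        assert road_linearity(straight) == pytest.approx(1.0)
        assert road_linearity(bent) == pytest.approx(7 / 5)

    def test_closed_loop_rejected(self):
        loop = np.array([(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 0.0)])
        with pytest.raises(ValueError, match="loop"):
            road_linearity(loop)

    def test_unit_mean_linearity(self):
        vals = [1.0, 1.4]
        assert np.mean(vals) == pytest.approx(1.2)
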