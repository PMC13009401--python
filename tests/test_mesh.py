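"""Geometry layer: grids, Purkinje trees, PMJ maps, text round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from purkmyo.mesh import (
    PMJMap,
    build_cuboid_grid,
    build_purkinje_cable,
    build_purkinje_tree,
    map_pmjs,
    read_grid,
    read_network,
    tag_region,
    write_grid,
    write_network,
)


class TestCuboidGrid:
    @pytest.mark.parametrize(
        "extent,h,expected",
        [
            ((1.0, 1.0, 1.0), 0.025, 64_000),      # benchmark cuboid at 250 um
            ((0.05, 0.05, 0.05), 0.05, 1),
            ((1.0, 0.025, 0.025), 0.025, 40),      # 1-D cable arrangement
        ],
    )
    def test_volume_count(self, extent, h, expected):
        grid = build_cuboid_grid(extent, h, (1.0, 1.0, 1.0))
        assert grid.n_volumes == expected

    def test_non_commensurate_extent_names_axis(self):
        with pytest.raises(ValueError, match="axis y"):
            build_cuboid_grid((0.4, 0.41, 0.4), 0.1, (1.0, 1.0, 1.0))

    def test_centers_at_half_offset(self, small_grid):
        assert np.allclose(small_grid.centers, (small_grid.indices + 0.5) * 0.1)

    def test_fiber_triads_orthonormal_for_oblique_axis(self):
        grid = build_cuboid_grid((0.2, 0.2, 0.2), 0.1, (1.0, 0.5, 0.2),
                                 fiber_axis=(1.0, 1.0, 0.0))
        gram = np.einsum("vab,vcb->vac", grid.fibers, grid.fibers)
        assert np.allclose(gram, np.eye(3), atol=1e-12)
        assert np.allclose(grid.fibers[0, 0], [np.sqrt(0.5), np.sqrt(0.5), 0.0])

    @settings(deadline=None, max_examples=20)
    @given(
        nx=st.integers(1, 6), ny=st.integers(1, 6), nz=st.integers(1, 6),
        h=st.sampled_from([0.01, 0.025, 0.05, 0.1]),
    )
    def test_count_is_product_of_axis_counts(self, nx, ny, nz, h):
        grid = build_cuboid_grid((nx * h, ny * h, nz * h), h, (1, 1, 1))
        assert grid.n_volumes == nx * ny * nz


class TestTagRegion:
    def test_whole_grid_retagged(self, small_grid):
        out = tag_region(small_grid, ((0, 0, 0), (1, 1, 1)), "endo", (0.2, 0.2, 0.2))
        assert (out.tags == "endo").all()
        assert np.allclose(out.sigmas, 0.2)

    def test_empty_box_warns_and_leaves_grid_unchanged(self, small_grid):
        with pytest.warns(UserWarning, match="no volume centres"):
            out = tag_region(small_grid, ((2, 2, 2), (3, 3, 3)), "endo", (0.2,) * 3)
        assert (out.tags == "bulk").all()

    def test_half_open_box_covers_lower_half(self, small_grid):
        # lower half along x of the 4^3 grid: centers 0.05, 0.15 < 0.2
        out = tag_region(small_grid, ((0, 0, 0), (0.2, 1, 1)), "lo", (0.5,) * 3)
        assert (out.tags == "lo").sum() == 32
        inside = small_grid.centers[:, 0] < 0.2
        assert (out.tags[inside] == "lo").all()


class TestPurkinjeTree:
    def test_depth_zero_is_straight_cable(self):
        net = build_purkinje_tree(0, 0.5, 0.025, 2.0)
        assert net.n_volumes == 20
        assert len(net.terminals) == 1
        assert net.root == 0

    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_terminal_and_volume_counts(self, depth):
        per = 8  # 0.2 cm branches at h = 0.025
        net = build_purkinje_tree(depth, 0.2, 0.025, 2.0)
        assert len(net.terminals) == 2 ** depth
        assert net.n_volumes == (2 ** (depth + 1) - 1) * per

    def test_bifurcation_volume_has_two_children(self):
        net = build_purkinje_tree(1, 0.2, 0.025, 2.0)
        n_children = [len(c) for c in net.children]
        assert n_children.count(2) == 1  # exactly one branching volume
        assert max(n_children) == 2

    def test_consecutive_spacing_exact(self):
        net = build_purkinje_tree(2, 0.2, 0.025, 2.0)
        nonroot = np.flatnonzero(net.parent >= 0)
        d = np.linalg.norm(net.nodes[nonroot] - net.nodes[net.parent[nonroot]], axis=1)
        assert np.allclose(d, 0.025, atol=1e-12)

    def test_non_commensurate_branch_length_rejected(self):
        with pytest.raises(ValueError):
            build_purkinje_tree(1, 0.21, 0.025, 2.0)


class TestPMJMap:
    def test_coincident_terminal_picks_that_volume(self, small_grid):
        target = small_grid.centers[37]
        # cable of 3 volumes whose last centre lands exactly on the target
        cable = build_purkinje_cable(0.3, 0.1, 2.0, start=target - [0.25, 0, 0])
        m = map_pmjs(cable, small_grid, 1, 1000.0)
        assert np.array_equal(m.coupled[0][0], small_grid.indices[37])

    def test_matches_brute_force_distance_sort(self, small_grid, rng):
        net = build_purkinje_tree(1, 0.2, 0.025, 2.0, start=(0.1, 0.1, 0.45))
        m = map_pmjs(net, small_grid, 7, 500.0)
        for t, lst in zip(net.terminals, m.coupled):
            d = np.linalg.norm(small_grid.centers - net.nodes[t], axis=1)
            order = sorted(range(small_grid.n_volumes),
                           key=lambda r: (d[r], *small_grid.indices[r]))
            expected = small_grid.indices[order[:7]]
            assert np.array_equal(lst, expected)

    def test_full_coverage_has_each_volume_once(self, small_grid):
        cable = build_purkinje_cable(0.2, 0.1, 2.0, start=(0.2, 0.2, 0.6),
                                     direction=(0, 0, -1))
        m = map_pmjs(cable, small_grid, small_grid.n_volumes, 100.0)
        assert len({tuple(v) for v in m.coupled[0]}) == small_grid.n_volumes

    def test_invariant_to_grid_storage_order(self, small_grid, rng):
        perm = rng.permutation(small_grid.n_volumes)
        shuffled = small_grid.replace(
            indices=small_grid.indices[perm], tags=small_grid.tags[perm],
            sigmas=small_grid.sigmas[perm], fibers=small_grid.fibers[perm],
        )
        net = build_purkinje_cable(0.3, 0.1, 2.0, start=(0.21, 0.2, 0.7),
                                   direction=(0, 0, -1))
        a = map_pmjs(net, small_grid, 9, 100.0)
        b = map_pmjs(net, shuffled, 9, 100.0)
        assert np.array_equal(a.coupled[0], b.coupled[0])

    def test_n_pmj_exceeding_volume_count_rejected(self, small_grid):
        cable = build_purkinje_cable(0.2, 0.1, 2.0)
        with pytest.raises(ValueError, match="exceeds"):
            map_pmjs(cable, small_grid, small_grid.n_volumes + 1, 100.0)

    def test_invalid_parameters_rejected(self, small_grid):
        with pytest.raises(ValueError):
            PMJMap(np.array([0]), [small_grid.indices[:2]], r_pmj=-1.0, n_pmj=2)
        with pytest.raises(ValueError):
            PMJMap(np.array([0]), [small_grid.indices[:2]], r_pmj=1.0, n_pmj=0)


class TestTextFormats:
    def test_grid_round_trip_bit_exact(self, tmp_path):
        grid = build_cuboid_grid((0.2, 0.3, 0.1), 0.05, (1.334, 0.176, 0.176),
                                 fiber_axis=(1.0, 2.0, 0.5))
        grid = tag_region(grid, ((0, 0, 0), (0.1, 1, 1)), "endo", (0.4, 0.4, 0.4))
        path = tmp_path / "grid.txt"
        write_grid(grid, path)
        back = read_grid(path)
        assert np.array_equal(back.indices, grid.indices)
        assert (back.tags == grid.tags).all()
        assert np.array_equal(back.sigmas, grid.sigmas)   # repr round-trip is exact
        assert np.array_equal(back.fibers, grid.fibers)
        assert back.h == grid.h

    def test_network_round_trip(self, tmp_path):
        net = build_purkinje_tree(2, 0.2, 0.025, 1.75)
        path = tmp_path / "net.txt"
        write_network(net, path)
        back = read_network(path)
        assert np.array_equal(back.parent, net.parent)
        assert np.array_equal(back.nodes, net.nodes)
        assert np.array_equal(back.sigma, net.sigma)

    def test_empty_volume_list_rejected(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("h 0.1\n")
        with pytest.raises(ValueError, match="empty"):
            read_grid(path)

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("h 0.1\n0 0 zero bulk " + " ".join(["1.0"] * 12) + "\n")
        with pytest.raises(ValueError, match="line 2"):
            read_grid(path)

    def test_network_with_two_roots_rejected(self, tmp_path):
        path = tmp_path / "tworoots.txt"
        path.write_text(
            "h 0.1\n"
            "0 0.0 0.0 0.0\n1 0.1 0.0 0.0\n2 0.5 0.5 0.5\n"
            "0 1 2.0\n"
        )
        with pytest.raises(ValueError, match="exactly one root"):
            read_network(path)
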