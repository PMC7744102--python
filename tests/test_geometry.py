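"""Skeleton resampling, cross-sections, long axis, medians, tips, compartments."""

import numpy as np
import pandas as pd
import pytest

from conftest import straight_skeleton
from glomotopy.errors import (
    DegenerateGeometryError,
    EmptyInputError,
    FormatError,
    InvalidSizeError,
)
from glomotopy.geometry import (
    NODE_COLUMNS,
    LongAxis,
    Skeleton,
    axon_tip_position,
    cross_section_positions,
    glomerulus_long_axis,
    median_axis_position,
    partition_compartments,
    resample_skeleton,
)


def y_skeleton():
    """A Y: a trunk of 10 nodes splitting into a short and a long branch."""
    rows = [(k + 1, k if k else -1, 400.0 * k, 0.0, 0.0, -1.0, "axon") for k in range(10)]
    nid = 10
    parent = 10
    for k in range(1, 4):  # short branch, +y
        nid += 1
        rows.append((nid, parent, 400.0 * 9, 400.0 * k, 0.0, -1.0, "axon"))
        parent = nid
    parent = 10
    for k in range(1, 21):  # long branch, -y
        nid += 1
        rows.append((nid, parent, 400.0 * 9, -400.0 * k, 0.0, -1.0, "axon"))
        parent = nid
    return Skeleton("y", pd.DataFrame(rows, columns=NODE_COLUMNS))


class TestSkeletonValidation:
    def test_self_parent_is_a_cycle(self):
        rows = [(1, -1, 0, 0, 0, -1.0, "axon"), (2, 2, 1, 1, 1, -1.0, "axon")]
        with pytest.raises(FormatError, match="cycle"):
            Skeleton("bad", pd.DataFrame(rows, columns=NODE_COLUMNS))

    def test_multiple_roots_rejected(self):
        rows = [(1, -1, 0, 0, 0, -1.0, "axon"), (2, -1, 1, 1, 1, -1.0, "axon")]
        with pytest.raises(FormatError, match="root"):
            Skeleton("bad", pd.DataFrame(rows, columns=NODE_COLUMNS))


class TestResample:
    def test_straight_segment_gets_uniform_nodes(self):
        rows = [(1, -1, 0.0, 0.0, 0.0, -1.0, "axon"), (2, 1, 4000.0, 0.0, 0.0, -1.0, "axon")]
        skel = Skeleton("s", pd.DataFrame(rows, columns=NODE_COLUMNS))
        out = resample_skeleton(skel, spacing=400.0)
        assert len(out.nodes) == 11
        np.testing.assert_allclose(sorted(out.nodes["x"]), np.arange(0, 4001, 400))

    def test_idempotent_on_already_uniform_skeleton(self):
        skel = straight_skeleton(n_nodes=11, step=400.0)
        out = resample_skeleton(skel, spacing=400.0)
        assert len(out.nodes) == len(skel.nodes)
        np.testing.assert_allclose(
            np.sort(out.positions, axis=0), np.sort(skel.positions, axis=0), atol=1e-9
        )

    def test_branch_point_preserved(self):
        out = resample_skeleton(y_skeleton(), spacing=1000.0)
        # the branch node at (3600, 0, 0) must survive
        at_branch = np.isclose(out.nodes["x"], 3600.0) & np.isclose(out.nodes["y"], 0.0)
        assert at_branch.any()
        # and the topology still has exactly 3 leaf-or-root chain ends
        children = out.nodes.groupby("parent_id").size()
        branch_nodes = children[children > 1]
        assert len(branch_nodes) == 1

    def test_cable_length_preserved(self):
        skel = y_skeleton()
        out = resample_skeleton(skel, spacing=700.0)
        assert out.cable_length() == pytest.approx(skel.cable_length(), abs=3 * 700.0)

    def test_bad_spacing_rejected(self):
        with pytest.raises(InvalidSizeError):
            resample_skeleton(y_skeleton(), spacing=0.0)


class TestCrossSection:
    def _three_parallel(self):
        # three straight axons along x at y = 0, 10000, 5000 (nm)
        mk = lambda nid, y: straight_skeleton(21, 500.0, neuron_id=nid).nodes.assign(y=y)
        skels = [Skeleton(nid, mk(nid, y)) for nid, y in
                 [("a", 0.0), ("b", 10_000.0), ("c", 5_000.0)]]
        return skels

    def test_reference_pair_lands_at_unit_positions(self):
        skels = self._three_parallel()
        pos, omitted = cross_section_positions(
            skels, plane_point=(5000.0, 0, 0), plane_normal=(1, 0, 0),
            thickness=1000.0, ref_pair=("a", "b"),
        )
        np.testing.assert_allclose(pos["a"], [0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(pos["b"], [0.0, 1.0], atol=1e-12)
        assert omitted == []

    def test_midway_neuron_maps_to_half(self):
        skels = self._three_parallel()
        pos, _ = cross_section_positions(
            skels, (5000.0, 0, 0), (1, 0, 0), 1000.0, ref_pair=("a", "b"))
        np.testing.assert_allclose(pos["c"], [0.0, 0.5], atol=1e-12)

    def test_in_plane_nodes_averaged(self):
        skels = self._three_parallel()
        pos, _ = cross_section_positions(skels, (5000.0, 0, 0), (1, 0, 0), 2000.0)
        # slab [4000, 6000] holds nodes at x = 4000..6000 -> centroid x = 5000
        assert "a" in pos and "b" in pos

    def test_missing_reference_raises(self):
        skels = self._three_parallel()
        with pytest.raises(EmptyInputError):
            cross_section_positions(skels, (1e9, 0, 0), (1, 0, 0), 1000.0,
                                    ref_pair=("a", "b"))

    def test_rigid_invariance(self):
        from scipy.spatial.transform import Rotation

        skels = self._three_parallel()
        base, _ = cross_section_positions(skels, (5000.0, 0, 0), (1, 0, 0),
                                          1000.0, ref_pair=("a", "b"))
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True)
        shift = np.array([1e6, -3e5, 7e4])
        moved = []
        for s in skels:
            nodes = s.nodes.copy()
            xyz = rot.apply(s.positions) + shift
            nodes[["x", "y", "z"]] = xyz
            moved.append(Skeleton(s.neuron_id, nodes))
        plane_pt = rot.apply(np.array([5000.0, 0, 0])) + shift
        normal = rot.apply(np.array([1.0, 0, 0]))
        got, _ = cross_section_positions(moved, plane_pt, normal, 1000.0,
                                         ref_pair=("a", "b"))
        for k in base:
            np.testing.assert_allclose(got[k], base[k], atol=1e-6)


class TestLongAxis:
    def test_x_axis_cloud(self):
        pts = np.column_stack([np.linspace(0, 100, 50), np.zeros(50), np.zeros(50)])
        axis = glomerulus_long_axis(pts + np.random.default_rng(0).normal(0, 0.1, (50, 3)))
        assert abs(axis.direction @ [1, 0, 0]) > 0.999

    def test_synthetic_cylinder_recovered_within_two_degrees(self):
        rng = np.random.default_rng(1)
        n = 2000
        x = rng.uniform(0, 40_000, n)
        th = rng.uniform(0, 2 * np.pi, n)
        r = 5000 * np.sqrt(rng.uniform(size=n))
        pts = np.column_stack([x, r * np.cos(th), r * np.sin(th)])
        axis = glomerulus_long_axis(pts)
        ang = np.rad2deg(np.arccos(abs(axis.direction @ [1, 0, 0])))
        assert ang < 2.0
        assert not axis.near_isotropic

    def test_isotropic_cloud_flagged(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(5000, 3))
        assert glomerulus_long_axis(pts).near_isotropic

    def test_single_point_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            glomerulus_long_axis(np.zeros((1, 3)))


class TestMedianAxisPosition:
    axis = LongAxis(origin=np.zeros(3), direction=np.array([1.0, 0, 0]), extent=(0, 100))

    def test_symmetric_set(self):
        pts = np.array([[4.0, 0, 0], [6.0, 0, 0], [5.0, 3, -2]])
        assert median_axis_position(pts, self.axis) == 5.0

    def test_robust_to_outlier(self):
        pts = np.array([[1.0, 0, 0], [2.0, 0, 0], [100.0, 0, 0]])
        assert median_axis_position(pts, self.axis) == 2.0

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            median_axis_position(np.empty((0, 3)), self.axis)

    def test_skeleton_and_presynapse_medians_agree_on_uniform_neuron(self):
        skel = straight_skeleton(n_nodes=101, step=400.0)
        rng = np.random.default_rng(3)
        syn = np.column_stack([rng.uniform(0, 40_000, 500), np.zeros(500), np.zeros(500)])
        m_skel = median_axis_position(skel, self.axis)
        m_syn = median_axis_position(syn, self.axis)
        assert abs(m_skel - m_syn) < 1000.0


class TestAxonTip:
    def test_straight_axon_tip_is_mean_of_last_tenth(self):
        skel = straight_skeleton(n_nodes=100, step=400.0)
        tip = axon_tip_position(skel, entry_point=(0, 0, 0))
        expected_x = np.mean([400.0 * k for k in range(90, 100)])
        np.testing.assert_allclose(tip, [expected_x, 0, 0])

    def test_ten_node_axon_uses_single_farthest_node(self):
        skel = straight_skeleton(n_nodes=10, step=400.0)
        tip = axon_tip_position(skel, entry_point=(0, 0, 0))
        np.testing.assert_allclose(tip, [3600.0, 0, 0])

    def test_branched_axon_tip_on_long_branch(self):
        tip = axon_tip_position(y_skeleton(), entry_point=(0, 0, 0))
        assert tip[1] < -400.0 * 15  # deep into the long (-y) branch

    def test_geodesic_beats_euclidean_on_curled_axon(self):
        # a hook: the geodesically farthest node curls back near the entry
        rows = [(1, -1, 0.0, 0.0, 0.0, -1.0, "axon")]
        angles = np.linspace(0, 1.75 * np.pi, 40)
        for k, a in enumerate(angles[1:], start=2):
            rows.append((k, k - 1, 5000 * np.sin(a), 5000 * (1 - np.cos(a)), 0.0,
                         -1.0, "axon"))
        skel = Skeleton("hook", pd.DataFrame(rows, columns=NODE_COLUMNS))
        geo = axon_tip_position(skel, (0, 0, 0), distance="geodesic")
        euc = axon_tip_position(skel, (0, 0, 0), distance="euclidean")
        assert not np.allclose(geo, euc)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(InvalidSizeError):
            axon_tip_position(straight_skeleton(n_nodes=5), (0, 0, 0))


class TestCompartments:
    axis = LongAxis(origin=np.zeros(3), direction=np.array([1.0, 0, 0]), extent=(0, 100))

    def _points(self, n, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        return np.column_stack([rng.uniform(0, 100, n), np.zeros(n), np.zeros(n)])

    def test_exact_division(self):
        part = partition_compartments(self._points(100), self.axis, k=10)
        assert part.counts().tolist() == [10] * 10

    def test_remainder_spread_by_at_most_one(self):
        part = partition_compartments(self._points(101), self.axis, k=10)
        counts = part.counts()
        assert counts.sum() == 101
        assert sorted(counts)[:9] == [10] * 9 and max(counts) == 11

    def test_boundaries_non_decreasing_and_are_quantiles(self):
        pts = self._points(200)
        part = partition_compartments(pts, self.axis, k=10)
        assert np.all(np.diff(part.boundaries) >= 0)
        np.testing.assert_allclose(
            part.boundaries, np.quantile(pts[:, 0], np.arange(1, 10) / 10))

    def test_all_coincident_flagged_degenerate_but_deterministic(self):
        pts = np.zeros((50, 3))
        p1 = partition_compartments(pts, self.axis, k=10)
        p2 = partition_compartments(pts, self.axis, k=10)
        assert p1.degenerate
        np.testing.assert_array_equal(p1.assignment, p2.assignment)
        assert p1.counts().tolist() == [5] * 10

    def test_fewer_points_than_compartments_rejected(self):
        with pytest.raises(InvalidSizeError):
            partition_compartments(self._points(5), self.axis, k=10)
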