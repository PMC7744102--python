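"""Connectivity matrix, shuffle bias test, synapse-based distances, profiles."""

import numpy as np
import pandas as pd
import pytest

from conftest import straight_skeleton
from glomotopy.connectivity import (
    build_connectivity_matrix,
    compartment_ri,
    lc_lc_distance_bias,
    presynapse_distance,
    presynapse_distance_matrix,
    synapse_density_per_cable,
    target_proximity_profile,
)
from glomotopy.errors import EmptyInputError, InvalidSizeError, UnknownIdError
from glomotopy.geometry import LongAxis, glomerulus_long_axis, partition_compartments
from glomotopy.synthetic import ConnectomeConfig, generate

X_AXIS = LongAxis(origin=np.zeros(3), direction=np.array([1.0, 0, 0]), extent=(0.0, 80_000.0))


def _syn_df(rows):
    return pd.DataFrame(rows, columns=["pre_id", "post_id", "x", "y", "z"])


class TestConnectivityMatrix:
    types = {"l1": ("LC6", "R"), "l2": ("LC6", "R"), "g1": ("G1", "R"), "g2": ("G1", "L")}

    def test_empty_table_gives_zero_matrix(self):
        cm = build_connectivity_matrix(_syn_df([]), self.types)
        assert (cm.matrix.to_numpy() == 0).all()

    def test_threshold_zeroes_weak_cell_pairs(self):
        rows = [("l1", "g1", 0, 0, 0)] * 14
        cm = build_connectivity_matrix(_syn_df(rows), self.types, threshold=15)
        assert cm.matrix.loc[("LC6", "R"), ("G1", "R")] == 0
        assert cm.pair_counts["count"].iloc[0] == 14  # archived, not lost
        cm2 = build_connectivity_matrix(_syn_df(rows + rows[:1]), self.types, threshold=15)
        assert cm2.matrix.loc[("LC6", "R"), ("G1", "R")] == 15

    def test_grouping_pools_cells_of_a_type(self):
        rows = [("l1", "g1", 0, 0, 0)] * 3 + [("l2", "g1", 0, 0, 0)] * 4
        cm = build_connectivity_matrix(_syn_df(rows), self.types)
        assert cm.matrix.loc[("LC6", "R"), ("G1", "R")] == 7

    def test_unmapped_id_rejected(self):
        with pytest.raises(UnknownIdError):
            build_connectivity_matrix(_syn_df([("zzz", "g1", 0, 0, 0)]), self.types)

    def test_round_trip_against_generator_truth(self, default_connectome):
        conn = default_connectome
        rows = []
        for (target, nid), c in conn.target_synapse_counts.items():
            rows += [(nid, target, 0.0, 0.0, 0.0)] * c
        types = {nid: ("LC6", "R") for nid in conn.eye_centers}
        types.update({t: (t, "R") for t in conn.truth.rf_centers})
        cm = build_connectivity_matrix(_syn_df(rows), types)
        for t in conn.truth.rf_centers:
            expected = sum(v for (name, _), v in conn.target_synapse_counts.items()
                           if name == t)
            assert cm.matrix.loc[("LC6", "R"), (t, "R")] == expected


class TestDistanceBias:
    def _centers(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        return {f"n{k}": (rng.uniform(-80, 80), rng.uniform(0, 150)) for k in range(n)}

    def test_uniform_counts_give_half_p_and_observed_equals_null(self):
        centers = self._centers()
        counts = {(a, b): 5 for a in centers for b in centers if a != b}
        res = lc_lc_distance_bias(centers, counts, n_shuffles=200, seed=1)
        assert res.p_value == 0.5
        assert res.observed_mean == pytest.approx(res.null_means.mean())

    def test_distance_decay_connectivity_detected(self):
        conn = generate(ConnectomeConfig(seed=11, lc_lc_decay_scale=10.0))
        counts = conn.lc_lc_synapses.groupby(["pre_id", "post_id"]).size().to_dict()
        res = lc_lc_distance_bias(conn.eye_centers, counts, n_shuffles=1000, seed=2)
        assert res.p_value < 0.05
        assert res.observed_mean < res.null_means.mean()

    def test_shuffle_preserves_distance_and_weight_multisets(self):
        # permutation-invariant summaries of the null must match the observed
        centers = self._centers(6)
        rng = np.random.default_rng(3)
        counts = {(a, b): int(rng.integers(1, 9)) for a in centers for b in centers if a != b}
        res = lc_lc_distance_bias(centers, counts, n_shuffles=150, seed=4)
        # unweighted-count version: equal weights -> every null mean = observed
        flat = {k: 1 for k in counts}
        res_flat = lc_lc_distance_bias(centers, flat, n_shuffles=150, seed=5)
        assert np.allclose(res_flat.null_means, res_flat.observed_mean)
        assert res.null_means.std() > 0

    def test_two_neurons_degenerate_but_defined(self):
        centers = {"a": (0.0, 0.0), "b": (10.0, 0.0)}
        res = lc_lc_distance_bias(centers, {("a", "b"): 3, ("b", "a")
: 1}, n_shuffles=100, seed=0)
        assert np.isfinite(res.observed_mean)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(EmptyInputError):
            lc_lc_distance_bias(self._centers(4), {}, n_shuffles=100)


class TestPresynapseDistance:
    def test_identical_clouds_are_zero(self):
        pts = np.random.default_rng(0).normal(size=(40, 3))
        assert presynapse_distance(pts, pts) == 0.0

    def test_three_four_five(self):
        assert presynapse_distance([[0.0, 0, 0]], [[3.0, 4.0, 0]]) == 5.0

    def test_symmetric_on_random_sets(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a = rng.normal(size=(rng.integers(1, 20), 3))
            b = rng.normal(size=(rng.integers(1, 20), 3))
            assert presynapse_distance(a, b) == pytest.approx(presynapse_distance(b, a))

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            presynapse_distance(np.empty((0, 3)), np.zeros((2, 3)))


class TestCompartmentRI:
    def _labeled_presyn(self, conn):
        pts = conn.presynapses[["x", "y", "z"]].to_numpy()
        axis = glomerulus_long_axis(pts)
        part = partition_compartments(pts, axis, k=10)
        return conn.presynapses.assign(
            compartment=part.assignment, neuron_id=conn.presynapses["pre_id"])

    def test_retinotopic_connectome_beats_randomized_control(self, default_connectome):
        presyn = self._labeled_presyn(default_connectome)
        comp = compartment_ri(presyn, default_connectome.eye_centers,
                              compartments=[3, 4, 5])
        ctrl = compartment_ri(presyn, default_connectome.eye_centers,
                              compartments=[3, 4, 5], randomize=True, seed=0)
        assert comp.population_ri > ctrl.population_ri
        assert comp.population_ri > 0.1

    def test_randomized_control_centers_on_zero(self, default_connectome):
        presyn = self._labeled_presyn(default_connectome)
        vals = [
            compartment_ri(presyn, default_connectome.eye_centers,
                           compartments=[3, 4, 5], randomize=True, seed=s).population_ri
            for s in range(60)
        ]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < max(3 * se, 0.02)

    def test_all_compartments_equals_union(self, default_connectome):
        presyn = self._labeled_presyn(default_connectome)
        all_sel = compartment_ri(presyn, default_connectome.eye_centers)
        union = compartment_ri(presyn, default_connectome.eye_centers,
                               compartments=list(range(10)))
        assert all_sel.per_point_ri == union.per_point_ri

    def test_too_few_neurons_rejected(self, default_connectome):
        presyn = self._labeled_presyn(default_connectome).iloc[:5]
        with pytest.raises(InvalidSizeError):
            compartment_ri(presyn.assign(neuron_id="only_one"),
                           default_connectome.eye_centers)


class TestTargetProximity:
    def _scene(self):
        target = straight_skeleton(81, 1000.0, neuron_id="target")
        near = straight_skeleton(81, 1000.0, neuron_id="near")
        near.nodes["y"] += 2000.0
        far = straight_skeleton(81, 1000.0, neuron_id="far")
        far.nodes["y"] += 6000.0
        return target, {"near": [near], "far": [far]}

    def test_parallel_offsets_recovered(self):
        target, groups = self._scene()
        prof = target_proximity_profile(target, groups, X_AXIS,
                                        slice_thickness=1000.0, n_slices=80)
        valid = prof.dropna()
        assert np.allclose(valid["near"], 2000.0, atol=10)
        assert np.allclose(valid["far"], 6000.0, atol=10)

    def test_coincident_neuron_has_zero_distance(self):
        target, _ = self._scene()
        twin = straight_skeleton(81, 1000.0, neuron_id="twin")
        prof = target_proximity_profile(target, {"twin": [twin]}, X_AXIS,
                                        slice_thickness=1000.0, n_slices=80)
        assert np.allclose(prof.dropna()["twin"], 0.0, atol=1e-9)

    def test_absent_target_slices_reported_missing(self):
        target, groups = self._scene()
        prof = target_proximity_profile(target, groups, X_AXIS,
                                        slice_thickness=1000.0, n_slices=80,
                                        start=-20_000.0)
        assert prof.loc[0].drop(["s_lo", "s_hi"]).isna().all()


class TestSynapseDensity:
    def test_uniform_synapses_on_uniform_cable(self):
        skel = straight_skeleton(81, 1000.0)
        syn = np.column_stack([np.linspace(500, 79_500, 160),
                               np.zeros(160), np.zeros(160)])
        df = synapse_density_per_cable(skel, syn, X_AXIS, slice_thickness=8000.0)
        assert df.attrs["max_relative_deviation"] < 0.15

    def test_concentrated_synapses_flagged(self):
        skel = straight_skeleton(81, 1000.0)
        syn = np.column_stack([np.full(100, 500.0), np.zeros(100), np.zeros(100)])
        df = synapse_density_per_cable(skel, syn, X_AXIS, slice_thickness=8000.0)
        assert df.attrs["max_relative_deviation"] > 0.5

    def test_total_count_conserved_across_thickness(self):
        skel = straight_skeleton(81, 1000.0)
        rng = np.random.default_rng(5)
        syn = np.column_stack([rng.uniform(0, 80_000, 137), np.zeros(137), np.zeros(137)])
        d1 = synapse_density_per_cable(skel, syn, X_AXIS, slice_thickness=8000.0)
        d2 = synapse_density_per_cable(skel, syn, X_AXIS, slice_thickness=4000.0)
        assert d1["count"].sum() == d2["count"].sum() == 137
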