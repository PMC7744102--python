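"""Connectivity matrices and spatial-bias statistics of synaptic wiring.

Covers the grouped synapse-count matrix, the distance-weighted shuffle
test for whether projection neurons preferentially synapse onto
eye-neighbors, the nearest-presynapse distance between two neurons'
presynapse clouds (a synapse-based metric that can feed the Retinotopy
Index), target-proximity profiles along the glomerulus, and synapse
density per unit cable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptyInputError, InvalidSizeError, UnknownIdError
from .geometry import LongAxis, Skeleton
from .ri import PointMapping, RIResult, ri_population
from .sphere import great_circle_matrix

__all__ = [
    "ConnectivityMatrix",
    "build_connectivity_matrix",
    "DistanceBiasResult",
    "lc_lc_distance_bias",
    "presynapse_distance",
    "presynapse_distance_matrix",
    "compartment_ri",
    "target_proximity_profile",
    "synapse_density_per_cable",
]


@dataclass
class ConnectivityMatrix:
    """Grouped pre->post synapse totals with a per-cell-pair threshold.

    ``matrix`` is indexed by (cell_type, side) groups on both axes;
    ``pair_counts`` archives every pre->post cell pair with its raw
    count and whether it survived the threshold.
    """

    matrix: pd.DataFrame
    pair_counts: pd.DataFrame
    threshold: int


def build_connectivity_matrix(synapses: pd.DataFrame, type_map: dict, threshold: int = 0) -> ConnectivityMatrix:
    """Total synapse counts between cell groups.

    ``synapses`` needs pre_id and post_id columns (one row per synapse);
    ``type_map`` maps every id to a ``(cell_type, side)`` tuple.  The
    threshold zeroes pre->post *cell pairs* with fewer synapses before
    grouping (weak, possibly spurious edges), but the raw counts are
    kept in ``pair_counts``.
    """
    syn = synapses.dropna(subset=["post_id"])
    ids = set(syn["pre_id"]) | set(syn["post_id"])
    unmapped = sorted(i for i in ids if i not in type_map)
    if unmapped:
        raise UnknownIdError(f"ids missing from type_map: {unmapped[:10]}")

    pair = (
        syn.groupby(["pre_id", "post_id"], sort=True).size().rename("count").reset_index()
        if len(syn)
        else pd.DataFrame(columns=["pre_id", "post_id", "count"])
    )
    pair["kept"] = pair["count"] >= threshold

    groups = sorted(set(type_map.values()))
    index = pd.MultiIndex.from_tuples(groups, names=["cell_type", "side"])
    mat = pd.DataFrame(0, index=index, columns=index, dtype=int)
    for _, row in pair.iterrows():
        if not row["kept"]:
            continue
        g_pre = type_map[row["pre_id"]]
        g_post = type_map[row["post_id"]]
        mat.loc[g_pre, g_post] += int(row["count"])
    return ConnectivityMatrix(matrix=mat, pair_counts=pair, threshold=threshold)


@dataclass
class DistanceBiasResult:
    """Outcome of the distance-weighted shuffle test."""

    observed_per_neuron: dict
    observed_mean: float
    null_means: np.ndarray
    p_value: float


def lc_lc_distance_bias(
    eye_centers: dict,
    counts: dict,
    n_shuffles: int = 1000,
    seed=None,
) -> DistanceBiasResult:
    """Are neuron-neuron synapses biased toward eye-coordinate neighbors?

    For each presynaptic neuron the observed statistic is the
    synapse-count-weighted mean of the great-circle distances (degrees)
    between its dendrite center and those of its partners.  The null
    permutes each neuron's partner distances (synapse counts fixed,
    positions fixed — only identity labels are scrambled, so the
    non-uniform density of dendrite centers is preserved in the null).
    The p-value is one-sided for *smaller* observed distances, with ties
    against the null counted at half weight (mid-p), so a
    permutation-invariant statistic — e.g. uniform counts — yields
    p = 0.5 rather than a spurious extreme.

    ``counts`` maps ordered (pre_id, post_id) pairs to synapse counts;
    absent pairs count zero.
    """
    ids = sorted(eye_centers)
    n = len(ids)
    if n < 2:
        raise InvalidSizeError("need at least 2 neurons")
    if n_shuffles < 100:
        raise InvalidSizeError("need at least 100 shuffles for a stable null")
    idx = {i: k for k, i in enumerate(ids)}
    d = great_circle_matrix(np.array([eye_centers[i] for i in ids], dtype=float))
    w = np.zeros((n, n))
    for (pre, post), c in counts.items():
        if pre in idx and post in idx and pre != post:
            w[idx[pre], idx[post]] += c
    if w.sum() == 0:
        raise EmptyInputError("all synapse counts are zero; weighted mean undefined")

    rng = np.random.default_rng(seed)
    mask = ~np.eye(n, dtype=bool)

    def weighted_means(dist: np.ndarray) -> np.ndarray:
        num = (dist * w * mask).sum(axis=1)
        den = (w * mask).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return num / den

    obs = weighted_means(d)
    valid = ~np.isnan(obs)
    observed_mean = float(obs[valid].mean())

    null_means = np.empty(n_shuffles)
    for s in range(n_shuffles):
        d_perm = np.empty_like(d)
        for i in range(n):
            partners = np.flatnonzero(mask[i])
            d_perm[i, partners] = d[i, partners[rng.permutation(n - 1)]]
            d_perm[i, i] = 0.0
        nm = weighted_means(d_perm)
        null_means[s] = nm[valid].mean()

    less = np.sum(null_means < observed_mean - 1e-12)
    equal = np.sum(np.abs(null_means - observed_mean) <= 1e-12)
    p = float((less + 0.5 * equal) / n_shuffles)
    return DistanceBiasResult(
        observed_per_neuron={ids[k]: float(obs[k]) for k in range(n) if valid[k]},
        observed_mean=observed_mean,
        null_means=null_means,
        p_value=p,
    )


def presynapse_distance(presyn_a: np.ndarray, presyn_b: np.ndarray) -> float:
    """Mean nearest-presynapse distance between two clouds, pooled both ways.

    For every presynapse of A the distance to the closest presynapse of
    B is found, the same is done from B into A, and the pooled mean is
    returned.  Symmetric by construction; d(A, A) = 0; the triangle
    inequality is NOT guaranteed for this quantity.
    """
    a = np.atleast_2d(np.asarray(presyn_a, dtype=float))
    b = np.atleast_2d(np.asarray(presyn_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise EmptyInputError("presynapse sets must be non-empty")
    d_ab, _ = cKDTree(b).query(a)
    d_ba, _ = cKDTree(a).query(b)
    return float(np.concatenate([np.atleast_1d(d_ab), np.atleast_1d(d_ba)]).mean())


def presynapse_distance_matrix(clouds: dict) -> tuple[list, np.ndarray]:
    """Pairwise presynapse distances between neurons' presynapse clouds."""
    ids = sorted(clouds)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = presynapse_distance(clouds[ids[i]], clouds[ids[j]])
    return ids, mat


def compartment_ri(
    presynapses: pd.DataFrame,
    eye_centers: dict,
    compartments=None,
    randomize: bool = False,
    seed=None,
) -> RIResult:
    """RI of eye positions vs the synapse-based distance within compartments.

    ``presynapses`` needs columns neuron_id, x, y, z and compartment.
    The source space is the eye centers (great-circle degrees); the
    target space is the neurons under the presynapse-cloud distance
    restricted to the selected compartments.  With ``randomize`` the
    neuron identities of the clouds are permuted first — the
    identity-randomized control.
    """
    df = presynapses
    if compartments is not None:
        comps = {compartments} if np.isscalar(compartments) else set(compartments)
        df = df[df["compartment"].isin(comps)]
    clouds = {
        nid: grp[["x", "y", "z"]].to_numpy(dtype=float)
        for nid, grp in df.groupby("neuron_id")
    }
    clouds = {nid: pts for nid, pts in clouds.items() if nid in eye_centers and len(pts)}
    if len(clouds) < 3:
        raise InvalidSizeError(
            f"selected compartments contain presynapses from only {len(clouds)} neurons"
        )
    if randomize:
        rng = np.random.default_rng(seed)
        nids = sorted(clouds)
        perm = rng.permutation(len(nids))
        clouds = {nids[k]: clouds[nids[perm[k]]] for k in range(len(nids))}
    ids, target_d = presynapse_distance_matrix(clouds)
    source = np.array([eye_centers[i] for i in ids], dtype=float)
    source_d = great_circle_matrix(source)
    mapping = PointMapping.from_distance_matrices(ids, source_d, target_d)
    return ri_population(mapping)


def target_proximity_profile(
    target_skel: Skeleton,
    lc_groups: dict,
    axis: LongAxis,
    slice_thickness: float = 1000.0,
    n_slices: int = 80,
    start: float = None,
) -> pd.DataFrame:
    """Mean target-to-projection-neuron distance per slice along the axis.

    The axis range is tiled into ``n_slices`` consecutive slices of
    ``slice_thickness`` nm, centered on the axis extent unless ``start``
    is given.  Within each slice every projection neuron is reduced to a
    unique position (the centroid of its in-slice nodes — the pruning
    step), all target nodes in the slice are collected, and the mean
    over all neuron-position x target-node pairs is reported per group.
    Slices where the target is absent are NaN (missing, not zero).
    """
    if start is None:
        mid = 0.5 * (axis.extent[0] + axis.extent[1])
        start = mid - n_slices * slice_thickness / 2.0
    edges = start + slice_thickness * np.arange(n_slices + 1)

    t_pos = target_skel.positions
    t_s = axis.project(t_pos)
    group_nodes = {
        g: [(skel.positions, axis.project(skel.positions)) for skel in skels]
        for g, skels in lc_groups.items()
    }

    records = []
    for k in range(n_slices):
        lo, hi = edges[k], edges[k + 1]
        in_t = (t_s >= lo) & (t_s < hi)
        row = {"slice": k, "s_lo": lo, "s_hi": hi}
        if not in_t.any():
            for g in lc_groups:
                row[g] = np.nan
            records.append(row)
            continue
        t_nodes = t_pos[in_t]
        for g, members in group_nodes.items():
            dists = []
            for pos, s in members:
                in_lc = (s >= lo) & (s < hi)
                if not in_lc.any():
                    continue
                lc_point = pos[in_lc].mean(axis=0)  # unique position per neuron
                dists.append(np.linalg.norm(t_nodes - lc_point, axis=1))
            row[g] = float(np.concatenate(dists).mean()) if dists else np.nan
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("slice")


def synapse_density_per_cable(
    target_skel: Skeleton,
    synapse_points: np.ndarray,
    axis: LongAxis,
    slice_thickness: float = 1000.0,
) -> pd.DataFrame:
    """Synapses per unit cable length in slices along the long axis.

    Synapses are assigned to their nearest skeleton node; each edge's
    cable length is credited to the slice containing its midpoint.  The
    returned frame has one row per slice (count, cable_nm, density) and
    carries the maximum relative deviation of density from its mean in
    ``df.attrs["max_relative_deviation"]``.
    """
    pos = target_skel.positions
    node_ids = target_skel.nodes["node_id"].to_numpy()
    syn = np.atleast_2d(np.asarray(synapse_points, dtype=float))
    _, nearest = cKDTree(pos).query(syn)
    syn_s = axis.project(pos[nearest])

    id_to_row = {nid: k for k, nid in enumerate(node_ids)}
    mids, lengths = [], []
    for nid, pid in zip(target_skel.nodes["node_id"], target_skel.nodes["parent_id"]):
        if pid == -1:
            continue
        a, b = pos[id_to_row[nid]], pos[id_to_row[pid]]
        mids.append(0.5 * (a + b))
        lengths.append(np.linalg.norm(a - b))
    mid_s = axis.project(np.array(mids))
    lengths = np.asarray(lengths)

    lo = min(syn_s.min(), mid_s.min()) if len(syn_s) else mid_s.min()
    hi = max(syn_s.max(), mid_s.max()) if len(syn_s) else mid_s.max()
    edges = np.arange(lo, hi + slice_thickness, slice_thickness)
    if len(edges) < 2:
        edges = np.array([lo, lo + slice_thickness])

    counts, _ = np.histogram(syn_s, bins=edges)
    cable, _ = np.histogram(mid_s, bins=edges, weights=lengths)
    if np.any((counts > 0) & (cable == 0)):
        raise EmptyInputError("synapses assigned to a slice with zero cable")
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(cable > 0, counts / cable, np.nan)
    df = pd.DataFrame(
        {"s_lo": edges[:-1], "s_hi": edges[1:], "count": counts,
         "cable_nm": cable, "density": density}
    )
    occupied = df["cable_nm"] > 0
    mean_density = df.loc[occupied, "density"].mean()
    dev = np.abs(df.loc[occupied, "density"] - mean_density) / mean_density
    df.attrs["max_relative_deviation"] = float(dev.max()) if len(dev) else 0.0
    return df
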