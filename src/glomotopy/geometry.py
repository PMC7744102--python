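"""Skeleton and synapse-cloud geometry in the glomerulus.

All coordinates are nanometres.  A :class:`Skeleton` is a rooted tree of
3-D nodes; the operations here cover arclength resampling, cross-section
positions with reference-pair normalization, the principal long axis of
a presynapse cloud, median positions along that axis, axon-tip
positions, and the equal-count compartment partition of presynapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, cKDTree

from .errors import (
    DegenerateGeometryError,
    EmptyInputError,
    FormatError,
    InvalidSizeError,
)

__all__ = [
    "Skeleton",
    "LongAxis",
    "CompartmentPartition",
    "resample_skeleton",
    "cross_section_positions",
    "glomerulus_long_axis",
    "median_axis_position",
    "axon_tip_position",
    "partition_compartments",
    "glomerulus_mask",
]

NODE_COLUMNS = ["node_id", "parent_id", "x", "y", "z", "radius", "label"]


@dataclass
class Skeleton:
    """A rooted tree of 3-D nodes (nm) for one neuron.

    ``nodes`` columns: node_id, parent_id (-1 for the root), x, y, z,
    radius, label (one of dendrite/axon/soma/unlabeled).
    """

    neuron_id: object
    nodes: pd.DataFrame

    def __post_init__(self):
        df = self.nodes
        missing = [c for c in ("node_id", "parent_id", "x", "y", "z") if c not in df.columns]
        if missing:
            raise FormatError(f"skeleton table missing columns: {missing}")
        if "radius" not in df.columns:
            df = df.assign(radius=-1.0)
        if "label" not in df.columns:
            df = df.assign(label="unlabeled")
        df = df[NODE_COLUMNS].reset_index(drop=True)
        if df["node_id"].duplicated().any():
            raise FormatError("duplicate node ids")
        roots = df.index[df["parent_id"] == -1]
        if len(roots) != 1:
            raise FormatError(f"skeleton must have exactly one root, found {len(roots)}")
        ids = set(df["node_id"])
        parents = set(df.loc[df["parent_id"] != -1, "parent_id"])
        if not parents <= ids:
            raise FormatError(f"dangling parent references: {sorted(parents - ids)[:5]}")
        if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
            raise FormatError("non-finite coordinates")
        self.nodes = df
        self._check_acyclic()

    def _check_acyclic(self):
        parent = dict(zip(self.nodes["node_id"], self.nodes["parent_id"]))
        state: dict = {}
        for start in parent:
            if state.get(start):
                continue
            path = []
            node = start
            while node != -1 and state.get(node) is None:
                state[node] = False
                path.append(node)
                node = parent[node]
            if node != -1 and state.get(node) is False:
                raise FormatError(f"cycle detected through node {node}")
            for p in path:
                state[p] = True

    @classmethod
    def _trusted(cls, neuron_id, nodes: pd.DataFrame) -> "Skeleton":
        """Skip validation for trees constructed valid by design (generator
        internals); external inputs must go through the normal constructor."""
        self = cls.__new__(cls)
        self.neuron_id = neuron_id
        self.nodes = nodes
        return self

    @property
    def positions(self) -> np.ndarray:
        return self.nodes[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def root_id(self):
        return self.nodes.loc[self.nodes["parent_id"] == -1, "node_id"].iloc[0]

    def graph(self) -> nx.Graph:
        """Undirected tree with edge lengths (nm) as weights."""
        g = nx.Graph()
        pos = {nid: p for nid, p in zip(self.nodes["node_id"], self.positions)}
        g.add_nodes_from(pos)
        for nid, pid in zip(self.nodes["node_id"], self.nodes["parent_id"]):
            if pid != -1:
                g.add_edge(nid, pid, weight=float(np.linalg.norm(pos[nid] - pos[pid])))
        return g

    def cable_length(self) -> float:
        pos = {nid: p for nid, p in zip(self.nodes["node_id"], self.positions)}
        total = 0.0
        for nid, pid in zip(self.nodes["node_id"], self.nodes["parent_id"]):
            if pid != -1:
                total += float(np.linalg.norm(pos[nid] - pos[pid]))
        return total

    def restrict(self, mask: np.ndarray) -> pd.DataFrame:
        """Node rows selected by a boolean mask over rows (order preserved)."""
        return self.nodes.loc[np.asarray(mask, bool)]


def _segments(skel: Skeleton):
    """Decompose the tree into maximal unbranched root/branch-to-branch/leaf paths."""
    children: dict = {}
    for nid, pid in zip(skel.nodes["node_id"], skel.nodes["parent_id"]):
        if pid != -1:
            children.setdefault(pid, []).append(nid)
    breakpoints = {skel.root_id}
    for nid in skel.nodes["node_id"]:
        kids = children.get(nid, [])
        if len(kids) != 1:
            breakpoints.add(nid)  # branch points and leaves
    segs = []
    for bp in sorted(breakpoints, key=repr):
        for child in children.get(bp, []):
            path = [bp, child]
            while path[-1] not in breakpoints:
                path.append(children[path[-1]][0])
            segs.append(path)
    return segs


def resample_skeleton(skel: Skeleton, spacing: float = 400.0) -> Skeleton:
    """Place nodes at ~uniform arclength intervals along every path.

    Each unbranched segment is resampled at ``round(L / spacing)`` equal
    arclength intervals (at least one), so branch points and leaves are
    always preserved and a skeleton already sampled at exactly
    ``spacing`` is left unchanged.
    """
    if spacing <= 0:
        raise InvalidSizeError("spacing must be positive")
    pos = {nid: p for nid, p in zip(skel.nodes["node_id"], skel.positions)}
    label = dict(zip(skel.nodes["node_id"], skel.nodes["label"]))
    radius = dict(zip(skel.nodes["node_id"], skel.nodes["radius"]))

    rows = []
    new_id = {}
    next_id = 1

    def emit(x, y, z, parent_key, lab, rad, key=None):
        nonlocal next_id
        nid = next_id
        next_id += 1
        rows.append((nid, new_id[parent_key] if parent_key is not None else -1,
                     float(x), float(y), float(z), float(rad), lab))
        if key is not None:
            new_id[key] = nid
        return nid

    root = skel.root_id
    emit(*pos[root], None, label[root], radius[root], key=root)

    # emit segments root-outward so every segment's start is registered
    pending = list(_segments(skel))
    ordered = []
    while pending:
        ready = [p for p in pending if p[0] in new_id or any(p[0] == q[-1] for q in ordered)]
        if not ready:
            raise FormatError("disconnected skeleton segments")
        for p in ready:
            pending.remove(p)
        ordered.extend(ready)

    for path in ordered:
        pts = np.array([pos[n] for n in path])
        seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = cum[-1]
        n_int = max(1, int(round(total / spacing))) if total > 0 else 1
        targets = np.linspace(0.0, total, n_int + 1)[1:]
        parent_key = path[0]
        for k, s in enumerate(targets):
            j = int(np.searchsorted(cum, s, side="right")) - 1
            j = min(j, len(seg_len) - 1)
            t = 0.0 if seg_len[j] == 0 else (s - cum[j]) / seg_len[j]
            p = pts[j] * (1 - t) + pts[j + 1] * t
            # carry forward the label/radius of the nearest original node
            src = path[j] if t < 0.5 else path[j + 1]
            is_end = k == len(targets) - 1
            key = path[-1] if is_end else ("seg", id(path), k)
            emit(*p, parent_key, label[src], radius[src], key=key)
            parent_key = key

    df = pd.DataFrame(rows, columns=NODE_COLUMNS)
    return Skeleton(skel.neuron_id, df)


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def cross_section_positions(
    skels,
    plane_point,
    plane_normal,
    thickness: float = 1000.0,
    ref_pair: tuple = None,
):
    """Per-neuron 2-D positions in a slab, normalized to a reference pair.

    Each neuron's position is the centroid of its nodes with
    |signed distance to plane| <= thickness/2, projected into the plane.
    When ``ref_pair = (id0, id1)`` is given, the similarity transform
    (translation + rotation + uniform scale, no reflection) sending
    id0 -> (0, 0) and id1 -> (0, 1) is applied; neurons absent from the
    slab are omitted and reported.

    Returns ``(positions, omitted)`` with positions a dict id -> (x, y).
    """
    point = np.asarray(plane_point, dtype=float)
    normal = np.asarray(plane_normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    u, v = _plane_basis(normal)

    positions = {}
    omitted = []
    for skel in skels:
        p = skel.positions
        dist = (p - point) @ normal
        in_slab = np.abs(dist) <= thickness / 2.0
        if not in_slab.any():
            omitted.append(skel.neuron_id)
            continue
        centroid = p[in_slab].mean(axis=0)
        rel = centroid - point
        positions[skel.neuron_id] = np.array([rel @ u, rel @ v])

    if ref_pair is not None:
        id0, id1 = ref_pair
        for rid in (id0, id1):
            if rid not in positions:
                raise EmptyInputError(f"reference neuron {rid!r} does not intersect the slab")
        z0 = complex(*positions[id0])
        z1 = complex(*positions[id1])
        if z1 == z0:
            raise DegenerateGeometryError("reference neurons coincide in the slab")
        scale = 1j / (z1 - z0)  # sends id0 -> 0, id1 -> i == (0, 1)
        positions = {
            k: np.array([( (complex(*p) - z0) * scale ).real,
                         ( (complex(*p) - z0) * scale ).imag])
            for k, p in positions.items()
        }
    return positions, omitted


@dataclass
class LongAxis:
    """Principal elongation axis of a 3-D point cloud (nm)."""

    origin: np.ndarray
    direction: np.ndarray
    extent: tuple[float, float]
    eigenvalues: np.ndarray = None
    near_isotropic: bool = False

    def project(self, points) -> np.ndarray:
        """Scalar coordinates of points along the axis."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.origin) @ self.direction


def glomerulus_long_axis(presynapse_points: np.ndarray) -> LongAxis:
    """Long axis of the glomerulus: first principal axis of the presynapse cloud.

    Flagged ``near_isotropic`` when the top two covariance eigenvalues
    are within 5% of each other (the direction is then unstable).
    """
    pts = np.asarray(presynapse_points, dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 presynapse points")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0:
        raise DegenerateGeometryError("presynapse cloud has no spread")
    direction = evecs[:, -1]
    # deterministic sign: largest-magnitude component positive
    k = int(np.argmax(np.abs(direction)))
    if direction[k] < 0:
        direction = -direction
    proj = centered @ direction
    near_iso = evals[-2] > 0.95 * evals[-1]
    return LongAxis(
        origin=pts.mean(axis=0),
        direction=direction,
        extent=(float(proj.min()), float(proj.max())),
        eigenvalues=evals[::-1],
        near_isotropic=bool(near_iso),
    )


def median_axis_position(points_or_skeleton, axis: LongAxis) -> float:
    """Median coordinate along the long axis of nodes or synapse positions.

    For a skeleton, resample first (so node density is arclength
    density) and restrict to the glomerulus mask; this function only
    takes the median of the projections it is handed.
    """
    if isinstance(points_or_skeleton, Skeleton):
        pts = points_or_skeleton.positions
    else:
        pts = np.atleast_2d(np.asarray(points_or_skeleton, dtype=float))
    if len(pts) == 0:
        raise EmptyInputError("no points to take a median of")
    return float(np.median(axis.project(pts)))


def axon_tip_position(
    skel: Skeleton,
    entry_point,
    fraction: float = 0.1,
    distance: str = "geodesic",
) -> np.ndarray:
    """Mean position of the nodes farthest from the glomerulus entry.

    "Farthest" defaults to geodesic (along-skeleton) distance from the
    node nearest ``entry_point``, which is robust to curled axons;
    ``distance="euclidean"`` uses straight-line distance instead.  The
    averaged set is the ceil(fraction * n) most distant nodes.
    """
    n = len(skel.nodes)
    if n < 10:
        raise InvalidSizeError(f"need at least 10 nodes for a tip estimate, got {n}")
    pos = skel.positions
    entry = np.asarray(entry_point, dtype=float)
    node_ids = skel.nodes["node_id"].to_numpy()
    if distance == "geodesic":
        start = node_ids[int(np.argmin(np.linalg.norm(pos - entry, axis=1)))]
        dist_map = nx.single_source_dijkstra_path_length(skel.graph(), start)
        d = np.array([dist_map[nid] for nid in node_ids])
    elif distance == "euclidean":
        d = np.linalg.norm(pos - entry, axis=1)
    else:
        raise ValueError("distance must be 'geodesic' or 'euclidean'")
    k = int(np.ceil(fraction * n))
    order = np.lexsort((node_ids, -d))  # ties broken by ascending node id
    return pos[order[:k]].mean(axis=0)


@dataclass
class CompartmentPartition:
    """Equal-count partition of presynapses along the glomerulus long axis."""

    boundaries: np.ndarray  # k-1 scalars
    assignment: np.ndarray  # compartment index (0..k-1) per presynapse
    k: int
    degenerate: bool = False

    def counts(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)


def partition_compartments(
    presynapse_points: np.ndarray, axis: LongAxis, k: int = 10
) -> CompartmentPartition:
    """Split presynapses into k compartments each holding ~1/k of them.

    Boundaries sit at the (j/k)-quantiles of the projected positions;
    assignment is by sorted rank so compartment sizes differ by at most
    one, with boundary ties going to the lower compartment (stable in
    input order).  An all-coincident cloud is assigned deterministically
    and flagged degenerate.
    """
    pts = np.atleast_2d(np.asarray(presynapse_points, dtype=float))
    n = len(pts)
    if n < k:
        raise InvalidSizeError(f"need at least k={k} presynapses, got {n}")
    s = axis.project(pts)
    order = np.argsort(s, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    assignment = ranks * k // n
    boundaries = np.quantile(s, np.arange(1, k) / k)
    return CompartmentPartition(
        boundaries=boundaries,
        assignment=assignment,
        k=k,
        degenerate=bool(np.all(s == s[0])),
    )


def glomerulus_mask(presynapse_points: np.ndarray, margin: float = 0.0):
    """Membership test for the glomerulus volume.

    The volume is the convex hull of all presynapse positions; a
    positive margin dilates it approximately by pushing the hull
    vertices radially outward from the centroid.  Returns a callable
    mapping (m, 3) points to a boolean mask.
    """
    pts = np.asarray(presynapse_points, dtype=float)
    if len(pts) < 4:
        raise DegenerateGeometryError("need at least 4 points for a 3-D hull")
    centroid = pts.mean(axis=0)
    hull = ConvexHull(pts)
    verts = pts[hull.vertices]
    if margin != 0.0:
        rel = verts - centroid
        norms = np.linalg.norm(rel, axis=1, keepdims=True)
        verts = centroid + rel * (1.0 + margin / np.where(norms > 0, norms, 1.0))
    tri = Delaunay(verts)

    def contains(query: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(np.asarray(query, dtype=float))
        return tri.find_simplex(q) >= 0

    return contains
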