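"""The Retinotopy Index: how much neighborhood order a mapping preserves.

Given the same set of points placed in two metric spaces (for instance,
dendrite centers on the eye and axon positions in a glomerulus
cross-section), pick one point as a reference and rank all the others by
distance to it, separately in each space.  The two rankings are
permutations of one another, and the number of adjacent transpositions
(inversions, as counted by bubble sort) needed to turn one into the
other measures how much the mapping scrambled that reference point's
neighborhood.  With S inversions and A = (N-1)(N-2)/4 the expected
inversion count under a uniformly random permutation, the per-point
index is

    RI_i = 1 - S / A            in [-1, 1],

and the population index is the mean of RI_i over all reference points.
RI = 1 for any order-preserving (e.g. similarity) transform, -1 when
every distance ranking is exactly reversed, and 0 on average for random
mappings.  For tie-free rankings RI_i coincides with Kendall's tau-a
between the two distance-rank vectors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy import stats

from .errors import InvalidSizeError, MismatchError, UnknownIdError
from .sphere import great_circle_matrix

__all__ = [
    "PointMapping",
    "RankList",
    "RIResult",
    "rank_by_distance",
    "count_inversions",
    "expected_swaps",
    "ri_point",
    "ri_population",
    "ri_significance",
]

Metric = str | Callable[[np.ndarray], np.ndarray]


def _distance_matrix(positions: np.ndarray, metric: Metric) -> np.ndarray:
    if callable(metric):
        return np.asarray(metric(positions), dtype=float)
    if metric == "greatcircle":
        if positions.shape[1] != 2:
            raise MismatchError("great-circle metric requires (lon, lat) columns")
        return great_circle_matrix(positions)
    return squareform(pdist(positions, metric=metric))


class PointMapping:
    """Paired placements of one id set in two metric spaces.

    Parameters
    ----------
    ids:
        Hashable, sortable identifiers; at least three.
    source_positions, target_positions:
        Either a mapping id -> coordinate sequence, or an array aligned
        with ``ids``.  One-dimensional positions may be given as scalars.
    source_metric, target_metric:
        A ``scipy.spatial.distance.pdist`` metric name, the string
        ``"greatcircle"`` for (lon, lat) degree coordinates, or a
        callable returning a full distance matrix.

    Use :meth:`from_distance_matrices` when a space has no coordinate
    representation (e.g. the presynapse-cloud distance between neurons).
    """

    def __init__(
        self,
        ids: Sequence[Hashable],
        source_positions,
        target_positions,
        source_metric: Metric = "euclidean",
        target_metric: Metric = "euclidean",
    ):
        self.ids = list(ids)
        if len(self.ids) < 3:
            raise InvalidSizeError("a PointMapping needs at least 3 points")
        if len(set(self.ids)) != len(self.ids):
            raise MismatchError("duplicate ids in PointMapping")
        src = self._coerce(source_positions)
        tgt = self._coerce(target_positions)
        if not (np.isfinite(src).all() and np.isfinite(tgt).all()):
            raise MismatchError("positions must be finite")
        self._source_d = _distance_matrix(src, source_metric)
        self._target_d = _distance_matrix(tgt, target_metric)
        self.source_positions = src
        self.target_positions = tgt

    def _coerce(self, positions) -> np.ndarray:
        if isinstance(positions, Mapping):
            missing = [i for i in self.ids if i not in positions]
            if missing:
                raise MismatchError(f"ids missing from one space: {missing}")
            if len(positions) != len(self.ids):
                raise MismatchError("id sets differ between the two spaces")
            rows = [np.atleast_1d(np.asarray(positions[i], dtype=float)) for i in self.ids]
            return np.vstack(rows)
        arr = np.asarray(positions, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != len(self.ids):
            raise MismatchError("positions not aligned with ids")
        return arr

    @classmethod
    def from_distance_matrices(
        cls, ids: Sequence[Hashable], source_d: np.ndarray, target_d: np.ndarray
    ) -> "PointMapping":
        """Build a mapping directly from two precomputed distance matrices."""
        self = cls.__new__(cls)
        self.ids = list(ids)
        if len(self.ids) < 3:
            raise InvalidSizeError("a PointMapping needs at least 3 points")
        source_d = np.asarray(source_d, dtype=float)
        target_d = np.asarray(target_d, dtype=float)
        n = len(self.ids)
        for d in (source_d, target_d):
            if d.shape != (n, n):
                raise MismatchError("distance matrix shape does not match ids")
            if not np.isfinite(d).all():
                raise MismatchError("distances must be finite")
        self._source_d = source_d
        self._target_d = target_d
        self.source_positions = None
        self.target_positions = None
        return self

    @property
    def n(self) -> int:
        return len(self.ids)

    def distances(self, space: str) -> np.ndarray:
        if space == "source":
            return self._source_d
        if space == "target":
            return self._target_d
        raise ValueError(f"space must be 'source' or 'target', got {space!r}")


@dataclass
class RankList:
    """Distance ranking of all points around one reference point.

    ``tie_flags[k]`` is True when ``ordered_ids[k]`` and
    ``ordered_ids[k+1]`` are exactly equidistant from the reference (the
    ordering between them then falls back to ascending id).
    """

    reference_id: Hashable
    ordered_ids: list
    tie_flags: list = field(default_factory=list)


def rank_by_distance(mapping: PointMapping, space: str, reference_id) -> RankList:
    """Order the non-reference ids by ascending distance to the reference.

    Exact distance ties are broken by ascending id — identically in both
    spaces, so ties never contribute spurious inversions downstream.
    """
    try:
        ref_idx = mapping.ids.index(reference_id)
    except ValueError:
        raise UnknownIdError(f"reference id {reference_id!r} not in mapping") from None
    d = mapping.distances(space)[ref_idx]
    others = [k for k in range(mapping.n) if k != ref_idx]
    try:
        id_rank = {i: r for r, i in enumerate(sorted(mapping.ids))}
    except TypeError:  # mixed-type ids: fall back to a stable textual order
        id_rank = {i: r for r, i in enumerate(sorted(mapping.ids, key=repr))}
    order = sorted(others, key=lambda k: (d[k], id_rank[mapping.ids[k]]))
    ordered_ids = [mapping.ids[k] for k in order]
    tie_flags = [d[order[k]] == d[order[k + 1]] for k in range(len(order) - 1)]
    return RankList(reference_id, ordered_ids, tie_flags)


def count_inversions(list_a: Sequence, list_b: Sequence) -> int:
    """Minimal number of adjacent swaps turning ``list_b`` into ``list_a``.

    Equivalently the number of discordant pairs between the two
    orderings; computed by merge-counting in O(n log n).
    """
    if len(list_a) != len(list_b) or set(list_a) != set(list_b):
        raise MismatchError("inputs must be permutations of each other")
    pos = {x: k for k, x in enumerate(list_a)}
    seq = [pos[x] for x in list_b]
    return _merge_count(seq)


def _merge_count(seq: list[int]) -> int:
    n = len(seq)
    if n < 2:
        return 0
    mid = n // 2
    left, right = seq[:mid], seq[mid:]
    inv = _merge_count(left) + _merge_count(right)
    merged = []
    i = j = 0
    while i < len(left) and j < len(right):
        if left[i] <= right[j]:
            merged.append(left[i])
            i += 1
        else:
            merged.append(right[j])
            j += 1
            inv += len(left) - i
    merged.extend(left[i:])
    merged.extend(right[j:])
    seq[:] = merged
    return inv


def expected_swaps(n_points: int) -> float:
    """Expected inversion count A = (N-1)(N-2)/4 under a random permutation.

    This is half the maximum (N-1)(N-2)/2 — the count needed to fully
    reverse an ordered list — by the symmetry pairing each permutation x
    swaps away from sorted with one (N-1)(N-2)/2 - x away.
    """
    if n_points < 3:
        raise InvalidSizeError("expected_swaps undefined for fewer than 3 points")
    return (n_points - 1) * (n_points - 2) / 4.0


def ri_point(mapping: PointMapping, reference_id) -> float:
    """Per-reference-point Retinotopy Index, RI_i = 1 - S/A."""
    src = rank_by_distance(mapping, "source", reference_id)
    tgt = rank_by_distance(mapping, "target", reference_id)
    s = count_inversions(src.ordered_ids, tgt.ordered_ids)
    return 1.0 - s / expected_swaps(mapping.n)


@dataclass
class RIResult:
    """Per-point and population Retinotopy Index with significance."""

    per_point_ri: dict
    population_ri: float
    swaps: dict
    expected_swaps: float
    p_value_vs_zero: float
    n: int


def ri_population(mapping: PointMapping) -> RIResult:
    """Population RI: mean of RI_i over all reference points.

    The per-point values share points and are therefore statistically
    dependent; the attached p-value (see :func:`ri_significance`) treats
    them as a sample and is approximate.
    """
    a = expected_swaps(mapping.n)
    swaps: dict = {}
    per_point: dict = {}
    for ref in mapping.ids:
        src = rank_by_distance(mapping, "source", ref)
        tgt = rank_by_distance(mapping, "target", ref)
        s = count_inversions(src.ordered_ids, tgt.ordered_ids)
        swaps[ref] = s
        per_point[ref] = 1.0 - s / a
    values = np.array(list(per_point.values()))
    p = ri_significance(values)
    return RIResult(
        per_point_ri=per_point,
        population_ri=float(values.mean()),
        swaps=swaps,
        expected_swaps=a,
        p_value_vs_zero=p,
        n=mapping.n,
    )


def ri_significance(per_point_ri, null_sample=None) -> float:
    """Two-sided p-value for the null that the RI population centers on 0.

    By default a Wilcoxon signed-rank test against zero.  When
    ``null_sample`` is given (e.g. RIs of matched randomized mappings) a
    Mann-Whitney U test between the two samples is used instead — the
    rank-test reading of "comparing the population to 0".  Per-point RIs
    of one mapping are mutually dependent, so either p-value is
    approximate.
    """
    values = np.asarray(per_point_ri, dtype=float)
    if values.size < 3:
        raise InvalidSizeError("need at least 3 RI values for a test")
    if null_sample is not None:
        return float(stats.mannwhitneyu(values, np.asarray(null_sample, float),
                                        alternative="two-sided").pvalue)
    if np.all(values == 0):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nonzero = values[values != 0]
        res = stats.wilcoxon(nonzero, alternative="two-sided", method="auto")
    return float(res.pvalue)
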