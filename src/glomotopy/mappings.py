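"""Null and synthetic mappings of point sets, and the idealized 1-D projection.

These are the comparison mappings the Retinotopy Index is scored
against: rigid transforms (order-preserving, RI = 1), block- and fully
randomized permutations of point identities (RI between 1 and 0, and
~0), and the sweep of projections of eye coordinates onto a rotated
1-D "idealized glomerulus" line-space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, InvalidSizeError
from .ri import PointMapping, ri_population
from .sphere import unit_vectors

__all__ = [
    "ProjectionAxis",
    "apply_rigid",
    "block_randomize",
    "full_randomize",
    "axis_projection",
    "projection_sweep",
]


@dataclass
class ProjectionAxis:
    """A 1-D projection axis on the eye sphere.

    ``angle`` is taken modulo 180 degrees (a line-space has no
    orientation); the default pivot is the lobula mid-point at 73 deg
    longitude, 0 deg latitude.  Angle 0 is the anterior-posterior axis
    (projection = raw longitude); angle 90 is dorso-ventral.
    """

    angle: float
    pivot: tuple[float, float] = (73.0, 0.0)

    def __post_init__(self):
        self.angle = float(self.angle) % 180.0


def apply_rigid(points: np.ndarray, rotation_deg: float = 0.0, translation=None) -> np.ndarray:
    """Rotate (2-D, about the origin) and translate a planar point set."""
    pts = np.asarray(points, dtype=float)
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    th = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    out = pts @ rot.T
    if translation is not None:
        out = out + np.asarray(translation, dtype=float)
    return out


def block_randomize(points: np.ndarray, block_rows: int, block_cols: int, seed) -> np.ndarray:
    """Permute point positions uniformly at random within spatial blocks.

    The bounding rectangle is tiled into ``block_rows x block_cols``
    blocks anchored at its minimum corner; positions are shuffled among
    the points of each block while the global block layout is kept.
    With one block this is a full randomization; with one point per
    block it is the identity.
    """
    pts = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    col = np.minimum((pts[:, 0] - lo[0]) / span[0] * block_cols, block_cols - 1).astype(int)
    row = np.minimum((pts[:, 1] - lo[1]) / span[1] * block_rows, block_rows - 1).astype(int)
    block = row * block_cols + col
    out = pts.copy()
    for b in np.unique(block):
        idx = np.flatnonzero(block == b)
        out[idx] = pts[idx][rng.permutation(len(idx))]
    return out


def full_randomize(points: np.ndarray, seed) -> np.ndarray:
    """Permute point positions by a uniform random permutation."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise InvalidSizeError("need at least 3 points")
    rng = np.random.default_rng(seed)
    return pts[rng.permutation(len(pts))]


def axis_projection(eye_points: np.ndarray, axis: ProjectionAxis) -> np.ndarray:
    """Project eye coordinates onto a 1-D line-space at the given angle.

    The points are placed on the unit sphere, the sphere is rotated by
    ``axis.angle`` about the axis through the pivot point, and the new
    azimuths are taken as the 1-D positions (degrees).  Angle 0
    therefore returns the raw longitudes.
    """
    pts = np.asarray(eye_points, dtype=float)
    vec = unit_vectors(pts[:, 0], pts[:, 1])
    pivot = unit_vectors(*axis.pivot)
    rot = Rotation.from_rotvec(np.deg2rad(axis.angle) * pivot)
    out = rot.apply(vec)
    if np.any(np.abs(out[:, 2]) > 1 - 1e-12):
        raise DegenerateGeometryError("a point lies at a rotation pole; azimuth undefined")
    return np.rad2deg(np.arctan2(out[:, 1], out[:, 0]))


def projection_sweep(
    eye_points: dict,
    glomerulus_positions: dict,
    angles=None,
    pivot: tuple[float, float] = (73.0, 0.0),
) -> pd.DataFrame:
    """RI of lobula->line and line->glomerulus mappings across axis angles.

    Parameters
    ----------
    eye_points:
        id -> (lon, lat) degrees.
    glomerulus_positions:
        id -> observed scalar position along the glomerulus long axis.
    angles:
        Projection angles in degrees; default 0..170 in 10-degree steps.

    Returns a DataFrame with one row per angle: the RI of the synthetic
    2-D -> 1-D mapping, the RI of the 1-D line to the observed
    glomerulus positions, and their p-values.
    """
    if angles is None:
        angles = np.arange(0, 180, 10)
    ids = sorted(eye_points)
    if set(ids) != set(glomerulus_positions):
        raise InvalidSizeError("eye and glomerulus id sets differ")
    eye = np.array([eye_points[i] for i in ids], dtype=float)
    glom = np.array([glomerulus_positions[i] for i in ids], dtype=float)
    rows = []
    for angle in angles:
        line = axis_projection(eye, ProjectionAxis(angle, pivot))
        m1 = PointMapping(ids, eye, line, source_metric="greatcircle")
        m2 = PointMapping(ids, line, glom)
        r1 = ri_population(m1)
        r2 = ri_population(m2)
        rows.append(
            dict(
                angle=float(angle),
                ri_lobula_to_line=r1.population_ri,
                p_lobula_to_line=r1.p_value_vs_zero,
                ri_line_to_glom=r2.population_ri,
                p_line_to_glom=r2.p_value_vs_zero,
            )
        )
    return pd.DataFrame(rows)
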