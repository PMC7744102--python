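"""Mapping dendrites in the 3-D lobula onto eye coordinates.

A second-order surface is fit through all dendrite nodes, anchored by
two reference points — one at the center of the eye and one on the
central meridian — and queries on the surface are carried to the
spherical lune by geodesic polar coordinates about the center reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateGeometryError, EmptyInputError, InvalidSizeError
from .geometry import Skeleton
from .sphere import LUNE_CENTER, great_circle_deg, lonlat_from_vectors, unit_vectors

__all__ = [
    "DendriteSurface",
    "fit_dendrite_surface",
    "map_to_eye",
    "dendrite_center",
    "coverage_polygon",
]


@dataclass
class DendriteSurface:
    """Quadratic height field z = f(u, v) over a best-fit tangent frame.

    ``basis`` rows are the frame axes (u, v, w) in world coordinates;
    ``coeffs`` are (c0, cu, cv, cuu, cuv, cvv) of
    f(u, v) = c0 + cu u + cv v + cuu u^2 + cuv u v + cvv v^2.
    """

    origin: np.ndarray
    basis: np.ndarray
    coeffs: np.ndarray
    rms_residual: float

    def to_frame(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.origin) @ self.basis.T

    def height(self, u, v):
        c0, cu, cv, cuu, cuv, cvv = self.coeffs
        return c0 + cu * u + cv * v + cuu * u * u + cuv * u * v + cvv * v * v

    def embed(self, u, v) -> np.ndarray:
        """World coordinates of the surface point above frame coords (u, v)."""
        w = self.height(u, v)
        local = np.stack([np.asarray(u, float), np.asarray(v, float),
                          np.asarray(w, float)], axis=-1)
        return self.origin + local @ self.basis

    def off_surface_distance(self, points) -> np.ndarray:
        local = self.to_frame(points)
        return np.abs(local[:, 2] - self.height(local[:, 0], local[:, 1]))


def fit_dendrite_surface(dendrite_nodes: np.ndarray) -> DendriteSurface:
    """Least-squares quadratic surface through all dendrite nodes.

    The tangent frame is the principal frame of the point cloud (the
    normal is the least-variance axis); a quadratic in the in-plane
    coordinates is then fit to the out-of-plane coordinate.
    """
    pts = np.asarray(dendrite_nodes, dtype=float)
    if pts.ndim != 2 or len(pts) < 6:
        raise InvalidSizeError("need at least 6 points to fit a quadratic surface")
    origin = pts.mean(axis=0)
    centered = pts - origin
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] <= 0:
        raise DegenerateGeometryError("points are collinear; no surface frame")
    basis = vt  # rows: u (most spread), v, w (normal)
    local = centered @ basis.T
    u, v, w = local[:, 0], local[:, 1], local[:, 2]
    design = np.column_stack([np.ones_like(u), u, v, u * u, u * v, v * v])
    coeffs, _, rank, _ = np.linalg.lstsq(design, w, rcond=None)
    if rank < 6:
        raise DegenerateGeometryError("rank-deficient quadratic fit")
    resid = w - design @ coeffs
    return DendriteSurface(
        origin=origin,
        basis=basis,
        coeffs=coeffs,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def _surface_arclength_and_direction(surface, uv_from, uv_to, n_steps=256):
    """Arclength along the surface image of the straight (u,v) segment,
    and the initial 3-D tangent direction at the start."""
    t = np.linspace(0.0, 1.0, n_steps + 1)
    u = uv_from[0] + (uv_to[0] - uv_from[0]) * t
    v = uv_from[1] + (uv_to[1] - uv_from[1]) * t
    path = surface.embed(u, v)
    steps = np.diff(path, axis=0)
    arclen = float(np.linalg.norm(steps, axis=1).sum())
    d0 = steps[0]
    norm = np.linalg.norm(d0)
    if norm == 0:
        raise DegenerateGeometryError("query coincides with the center reference")
    return arclen, d0 / norm


def map_to_eye(
    surface: DendriteSurface,
    center_ref,
    meridian_ref,
    query,
    center_eye: tuple[float, float] = LUNE_CENTER,
    meridian_eye: tuple[float, float] = (0.0, 0.0),
    orientation: int = 1,
) -> np.ndarray:
    """Carry 3-D points near the dendrite surface to eye coordinates.

    The map is geodesic-polar about ``center_ref``: a query's radial
    surface distance from the center (arclength along the surface) and
    its tangent angle relative to the direction toward ``meridian_ref``
    are measured, then replayed on the sphere starting from
    ``center_eye`` with the meridian direction pointing at
    ``meridian_eye``.  The radial scale is set so the meridian reference
    lands exactly at its known eye position, which also pins it to
    longitude 0.  ``orientation`` (+1/-1) selects the handedness of the
    angular coordinate (the two brain hemispheres are mirror images).

    Returns an (n, 2) array of (lon_deg, lat_deg).  Queries farther off
    the surface than 3x the fit residual trigger a warning.
    """
    queries = np.atleast_2d(np.asarray(query, dtype=float))
    for name, ref in (("center_ref", center_ref), ("meridian_ref", meridian_ref)):
        off = surface.off_surface_distance(np.asarray(ref, float)[None])[0]
        if surface.rms_residual > 0 and off > 3 * surface.rms_residual:
            raise DegenerateGeometryError(
                f"{name} is {off:.1f} nm off the surface (> 3x rms residual)"
            )
    off = surface.off_surface_distance(queries)
    tol = 3 * surface.rms_residual
    if surface.rms_residual > 0 and np.any(off > tol):
        warnings.warn(
            f"{int(np.sum(off > tol))} queries are > 3x rms residual off-surface "
            f"(max {off.max():.1f} nm)",
            stacklevel=2,
        )

    c_uv = surface.to_frame(center_ref)[0, :2]
    m_uv = surface.to_frame(meridian_ref)[0, :2]
    q_uv = surface.to_frame(queries)[:, :2]

    # tangent frame at the center on the surface
    m_len, m_dir = _surface_arclength_and_direction(surface, c_uv, m_uv)
    eps = 1e-6 * max(1.0, np.abs(m_uv - c_uv).max())
    _, eu = _surface_arclength_and_direction(surface, c_uv, c_uv + np.array([eps, 0.0]), 2)
    _, ev = _surface_arclength_and_direction(surface, c_uv, c_uv + np.array([0.0, eps]), 2)
    normal = np.cross(eu, ev)
    normal /= np.linalg.norm(normal)

    # spherical anchors
    c_vec = unit_vectors(*center_eye)
    m_vec = unit_vectors(*meridian_eye)
    t_m = m_vec - (m_vec @ c_vec) * c_vec
    t_m /= np.linalg.norm(t_m)
    sep = float(great_circle_deg(np.array(center_eye), np.array(meridian_eye)))
    scale = np.deg2rad(sep) / m_len  # radians of eye angle per nm of surface

    out = np.empty((len(queries), 2))
    for k, uv in enumerate(q_uv):
        if np.allclose(uv, c_uv):
            out[k] = center_eye
            continue
        arclen, d0 = _surface_arclength_and_direction(surface, c_uv, uv)
        cosang = float(np.clip(d0 @ m_dir, -1.0, 1.0))
        sinang = float(np.cross(m_dir, d0) @ normal) * orientation
        # replay (rho, phi) on the sphere from the center anchor
        t_q = t_m * cosang + np.cross(c_vec, t_m) * sinang
        t_q /= np.linalg.norm(t_q)
        rho = arclen * scale
        dest = c_vec * np.cos(rho) + t_q * np.sin(rho)
        lon, lat = lonlat_from_vectors(dest)
        out[k] = (lon, lat)
    return out


def dendrite_center(skel: Skeleton) -> np.ndarray:
    """Center-of-mass of the dendrite-labeled nodes (resample first so the
    mean is arclength-weighted)."""
    dend = skel.nodes[skel.nodes["label"] == "dendrite"]
    if len(dend) == 0:
        raise EmptyInputError(f"neuron {skel.neuron_id!r} has no dendrite-labeled nodes")
    return dend[["x", "y", "z"]].to_numpy(dtype=float).mean(axis=0)


def coverage_polygon(eye_points: np.ndarray) -> np.ndarray:
    """Convex hull (in lune coordinates) of a neuron's mapped dendrite nodes.

    Returns the hull vertices in counter-clockwise order, not closed.
    """
    pts = np.atleast_2d(np.asarray(eye_points, dtype=float))
    if len(pts) < 3:
        raise InvalidSizeError("need at least 3 mapped nodes")
    try:
        hull = ConvexHull(pts)
    except QhullError as err:
        raise DegenerateGeometryError(f"degenerate (collinear?) hull: {err}") from err
    return pts[hull.vertices]
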