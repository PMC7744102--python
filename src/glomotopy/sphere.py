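"""Spherical-lune eye coordinates and small spherical-geometry helpers.

One eye's field of view is modelled as a spherical lune spanning
[-90, +90] degrees in longitude and [-10, +160] degrees in latitude.
Longitude is the azimuth of the standard spherical parameterization, so
latitudes beyond 90 degrees wrap over the pole (the eye looks partly
backwards over the top of the head).
"""

from __future__ import annotations

import numpy as np

LUNE_LON = (-90.0, 90.0)
LUNE_LAT = (-10.0, 160.0)

#: Centre of the lune (used as the default anchoring point of eye maps).
LUNE_CENTER = (0.0, 75.0)


def unit_vectors(lon_deg, lat_deg) -> np.ndarray:
    """Unit 3-vectors for (longitude, latitude) pairs in degrees.

    Longitude is the azimuth about z; latitude the elevation from the
    x-y plane.  Output shape is ``(..., 3)``.
    """
    lon = np.deg2rad(np.asarray(lon_deg, dtype=float))
    lat = np.deg2rad(np.asarray(lat_deg, dtype=float))
    return np.stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)],
        axis=-1,
    )


def lonlat_from_vectors(vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`unit_vectors`; returns (lon_deg, lat_deg)."""
    v = np.asarray(vec, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    v = v / n
    lat = np.rad2deg(np.arcsin(np.clip(v[..., 2], -1.0, 1.0)))
    lon = np.rad2deg(np.arctan2(v[..., 1], v[..., 0]))
    return lon, lat


def great_circle_deg(lonlat_a, lonlat_b) -> np.ndarray:
    """Great-circle distance in degrees between two (lon, lat) arrays."""
    a = np.asarray(lonlat_a, dtype=float)
    b = np.asarray(lonlat_b, dtype=float)
    va = unit_vectors(a[..., 0], a[..., 1])
    vb = unit_vectors(b[..., 0], b[..., 1])
    dot = np.clip(np.sum(va * vb, axis=-1), -1.0, 1.0)
    return np.rad2deg(np.arccos(dot))


def great_circle_matrix(lonlat: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distance matrix (degrees) for (n, 2) input."""
    pts = np.asarray(lonlat, dtype=float)
    v = unit_vectors(pts[:, 0], pts[:, 1])
    dot = np.clip(v @ v.T, -1.0, 1.0)
    return np.rad2deg(np.arccos(dot))


def in_lune(lon_deg, lat_deg) -> np.ndarray:
    """Boolean mask of points inside the lune bounds (inclusive)."""
    lon = np.asarray(lon_deg, dtype=float)
    lat = np.asarray(lat_deg, dtype=float)
    return (
        (lon >= LUNE_LON[0]) & (lon <= LUNE_LON[1])
        & (lat >= LUNE_LAT[0]) & (lat <= LUNE_LAT[1])
    )
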