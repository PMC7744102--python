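"""Synapse-weighted Gaussian receptive-field estimates on the eye.

An anatomical receptive field places one 2-D Gaussian per projection
neuron at its dendrite center in eye coordinates, with height
proportional to its synapse count onto the target and a common
half-width (half-width at half-maximum, ~30 degrees — roughly the
dendritic arbor radius), then sums the Gaussians.  Absolute field values
are in arbitrary units; contours and peak locations are scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from skimage import measure

from .errors import EmptyInputError, InvalidSizeError, MismatchError
from .sphere import LUNE_LAT, LUNE_LON, great_circle_deg

__all__ = [
    "RFGrid",
    "lune_grid",
    "anatomical_rf",
    "population_rf",
    "rf_contour",
    "compartment_rf",
    "hwhm_to_sigma",
]


def hwhm_to_sigma(half_width: float) -> float:
    """Gaussian sigma for a given half-width at half-maximum."""
    return half_width / np.sqrt(2.0 * np.log(2.0))


@dataclass
class RFGrid:
    """A non-negative density on a regular lon/lat grid over the lune.

    ``values`` has shape (n_lat, n_lon).  ``contour_sets`` maps a
    fraction-of-peak to the list of polylines computed for it (each a
    dict with ``vertices`` (m, 2) lon/lat and a ``closed`` flag).
    """

    lon: np.ndarray
    lat: np.ndarray
    values: np.ndarray
    provenance: str = "anatomical"
    contour_sets: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.shape != (len(self.lat), len(self.lon)):
            raise MismatchError("values shape must be (n_lat, n_lon)")
        if np.any(self.values < 0):
            raise MismatchError("RF values must be non-negative")

    def same_grid(self, other: "RFGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.lon, other.lon)
            and np.allclose(self.lat, other.lat)
        )

    @property
    def peak_value(self) -> float:
        return float(self.values.max())

    def argmax_coord(self) -> tuple[float, float]:
        k = int(np.argmax(self.values))
        i, j = np.unravel_index(k, self.values.shape)
        return float(self.lon[j]), float(self.lat[i])

    def interpolate(self, lon, lat):
        """Bilinear sample of the field at (lon, lat) degrees."""
        itp = RegularGridInterpolator(
            (self.lat, self.lon), self.values, bounds_error=True
        )
        pts = np.column_stack([np.atleast_1d(lat), np.atleast_1d(lon)])
        out = itp(pts)
        return out if out.size > 1 else float(out[0])


def lune_grid(step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Default regular grid over the eye lune at ``step`` degrees."""
    lon = np.arange(LUNE_LON[0], LUNE_LON[1] + step / 2, step)
    lat = np.arange(LUNE_LAT[0], LUNE_LAT[1] + step / 2, step)
    return lon, lat


def anatomical_rf(
    eye_centers: dict,
    weights: dict,
    half_width: float = 30.0,
    grid: tuple[np.ndarray, np.ndarray] = None,
    metric: str = "planar",
    provenance: str = "anatomical",
) -> RFGrid:
    """Sum of per-neuron Gaussians weighted by synapse count.

    value(g) = sum_i w_i exp(-d(g, c_i)^2 / (2 sigma^2)) with sigma from
    the half-width at half-maximum and d either planar lon/lat degrees
    (default — the maps are flattened lune plots) or great-circle
    degrees (``metric="greatcircle"``) for sensitivity checks.
    """
    if grid is None:
        grid = lune_grid()
    lon, lat = grid
    ids = [i for i in eye_centers if weights.get(i, 0) > 0]
    if not ids:
        raise EmptyInputError("all synapse weights are zero; empty field")
    if any(weights.get(i, 0) < 0 for i in eye_centers):
        raise MismatchError("weights must be non-negative")
    sigma = hwhm_to_sigma(half_width)
    glon, glat = np.meshgrid(lon, lat)
    values = np.zeros_like(glon, dtype=float)
    for i in ids:
        c_lon, c_lat = eye_centers[i]
        if metric == "planar":
            d2 = (glon - c_lon) ** 2 + (glat - c_lat) ** 2
        elif metric == "greatcircle":
            pts = np.stack([glon, glat], axis=-1)
            d2 = great_circle_deg(pts, np.array([c_lon, c_lat])) ** 2
        else:
            raise ValueError("metric must be 'planar' or 'greatcircle'")
        values += weights[i] * np.exp(-d2 / (2.0 * sigma**2))
    return RFGrid(lon=np.asarray(lon, float), lat=np.asarray(lat, float),
                  values=values, provenance=provenance)


def population_rf(cell_rfs) -> RFGrid:
    """Pointwise sum of per-cell fields — the population-indicator mimic."""
    rfs = list(cell_rfs)
    if not rfs:
        raise EmptyInputError("no fields to sum")
    first = rfs[0]
    total = first.values.copy()
    for rf in rfs[1:]:
        if not first.same_grid(rf):
            raise MismatchError("RF grids differ; cannot sum")
        total = total + rf.values
    return RFGrid(lon=first.lon, lat=first.lat, values=total, provenance="population")


def rf_contour(grid: RFGrid, fraction: float) -> list[dict]:
    """Fraction-of-peak level set, via bilinear-interpolated marching squares.

    Each contour is returned as ``{"vertices": (m, 2) lon/lat array,
    "closed": bool}``; contours clipped at the lune boundary are open
    and flagged.  The result is also cached on ``grid.contour_sets``.
    """
    if not 0.0 < fraction < 1.0:
        raise InvalidSizeError("fraction must lie strictly between 0 and 1")
    if grid.peak_value <= 0:
        raise EmptyInputError("grid has no positive values")
    level = fraction * grid.peak_value
    contours = []
    for arr in measure.find_contours(grid.values, level):
        lat_v = np.interp(arr[:, 0], np.arange(len(grid.lat)), grid.lat)
        lon_v = np.interp(arr[:, 1], np.arange(len(grid.lon)), grid.lon)
        vertices = np.column_stack([lon_v, lat_v])
        closed = bool(np.allclose(arr[0], arr[-1]))
        contours.append({"vertices": vertices, "closed": closed})
    grid.contour_sets[fraction] = contours
    return contours


def compartment_rf(
    presynapses: pd.DataFrame,
    eye_centers: dict,
    compartment: int,
    half_width: float = 30.0,
    grid=None,
) -> RFGrid:
    """Anatomical RF weighted by per-neuron presynapse counts in one compartment."""
    sel = presynapses[presynapses["compartment"] == compartment]
    if len(sel) == 0:
        raise EmptyInputError(f"compartment {compartment} holds no presynapses")
    counts = sel.groupby("neuron_id").size().to_dict()
    weights = {nid: counts.get(nid, 0) for nid in eye_centers}
    return anatomical_rf(eye_centers, weights, half_width=half_width, grid=grid,
                         provenance="compartment")
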