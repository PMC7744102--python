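"""Calcium-trace summary statistics.

ΔF/F with a sliding-percentile baseline, per-fly percentile
normalization, peak responses, functional receptive-field maps with
per-location tests under Benjamini-Hochberg FDR control, log-log tuning
comparison, and the paired test for contralateral (bilateral-stimulus)
suppression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import griddata

from .errors import EmptyInputError, InvalidSizeError, MismatchError
from .rf import RFGrid, lune_grid, rf_contour

__all__ = [
    "sliding_percentile_baseline",
    "delta_f_over_f",
    "normalize_responses",
    "peak_response",
    "FunctionalRF",
    "functional_rf",
    "tuning_comparison",
    "bilateral_suppression_test",
]


def sliding_percentile_baseline(f: np.ndarray, window: int = 300, percentile: float = 10.0) -> np.ndarray:
    """Per-frame baseline F0: the percentile of a centered window.

    The window is clipped (truncated) at the trace edges rather than
    padded, so the first and last frames use one-sided windows.
    """
    f = np.asarray(f, dtype=float)
    n = len(f)
    half = window // 2
    if n >= window and n > 2 * half:
        from numpy.lib.stride_tricks import sliding_window_view

        width = 2 * half + 1
        interior = np.percentile(sliding_window_view(f, width), percentile, axis=1)
        f0 = np.empty(n)
        f0[half:n - half] = interior
        for i in range(half):
            f0[i] = np.percentile(f[: i + half + 1], percentile)
        for i in range(n - half, n):
            f0[i] = np.percentile(f[i - half:], percentile)
        return f0
    return np.array([
        np.percentile(f[max(0, i - half): min(n, i + half + 1)], percentile)
        for i in range(n)
    ])


def delta_f_over_f(
    f: np.ndarray,
    window: int = 300,
    percentile: float = 10.0,
    mode: str = "sliding",
) -> np.ndarray:
    """ΔF/F = (F - F0) / F0 with a robust percentile baseline.

    ``mode="sliding"`` uses the per-frame centered-window percentile
    (requires the trace to be at least one window long);
    ``mode="epoch"`` uses a single global percentile of the whole trace
    — the variant used for stimulation-protocol periods.
    """
    f = np.asarray(f, dtype=float)
    if not np.isfinite(f).all():
        raise MismatchError("fluorescence must be finite")
    if mode == "sliding":
        if len(f) < window:
            raise InvalidSizeError(f"trace ({len(f)} frames) shorter than window ({window})")
        f0 = sliding_percentile_baseline(f, window=window, percentile=percentile)
    elif mode == "epoch":
        f0 = np.full_like(f, np.percentile(f, percentile))
    else:
        raise ValueError("mode must be 'sliding' or 'epoch'")
    if np.any(f0 <= 0):
        raise EmptyInputError("nonpositive baseline F0; ΔF/F undefined")
    return (f - f0) / f0


def normalize_responses(per_fly_values: dict, percentile: float = 98.0) -> dict:
    """Divide each fly's ΔF/F values by that fly's 98th percentile.

    Removes per-animal gain (indicator expression, optical path) before
    averaging across animals; the output 98th percentile is 1 per fly.
    """
    out = {}
    for fly, values in per_fly_values.items():
        v = np.asarray(values, dtype=float)
        if v.size < 50:
            raise InvalidSizeError(
                f"fly {fly!r}: need >= 50 values for a stable 98th percentile, got {v.size}"
            )
        p = np.percentile(v, percentile)
        if p <= 0:
            raise EmptyInputError(f"fly {fly!r}: nonpositive normalization percentile")
        out[fly] = v / p
    return out


def peak_response(dff: np.ndarray, epoch: tuple[int, int], grace: int = 0) -> float:
    """Maximum ΔF/F within a stimulus epoch (+ optional post-epoch grace
    frames for slow indicators)."""
    dff = np.asarray(dff, dtype=float)
    start, stop = epoch
    stop = min(stop + grace, len(dff))
    if not 0 <= start < stop <= len(dff):
        raise EmptyInputError(f"epoch ({start}, {stop}) empty or outside trace")
    return float(dff[start:stop].max())


@dataclass
class FunctionalRF:
    """Functional RF map with per-location significance."""

    grid: RFGrid
    stats: pd.DataFrame  # per location: lon, lat, mean, p, q, significant
    alpha: float
    contours: list


def functional_rf(
    peaks: dict,
    locations: dict,
    alpha: float = 0.05,
    grid=None,
    contour_fraction: float = 0.6,
    grid_step: float = 1.0,
) -> FunctionalRF:
    """Mean peak response per stimulus location, tested and interpolated.

    ``peaks`` maps stimulus id -> per-fly normalized peak values (one
    value per fly, all locations covering the same flies); ``locations``
    maps stimulus id -> (lon, lat).  Per location, a one-sided one-sample
    t-test asks whether the mean response exceeds zero; the p-values are
    Benjamini-Hochberg corrected at ``alpha``.  Means are linearly
    interpolated onto the grid (negative interpolants floored at zero)
    and the fraction-of-peak contour is attached.
    """
    stim_ids = sorted(peaks)
    if set(stim_ids) != set(locations):
        raise MismatchError("peaks and locations cover different stimulus ids")
    n_flies = {len(np.atleast_1d(peaks[s])) for s in stim_ids}
    if len(n_flies) != 1:
        raise MismatchError("unequal fly counts across locations")
    if min(n_flies) < 3:
        raise InvalidSizeError("need at least 3 flies per location")

    rows = []
    for s in stim_ids:
        v = np.asarray(peaks[s], dtype=float)
        if np.ptp(v) == 0:
            p = 0.0 if v.mean() > 0 else 1.0  # zero-variance degenerate case
        else:
            p = float(stats.ttest_1samp(v, 0.0, alternative="greater").pvalue)
        lon, lat = locations[s]
        rows.append(dict(stim_id=s, lon=lon, lat=lat, mean=float(v.mean()), p=p))
    df = pd.DataFrame(rows)
    df["q"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
    df["significant"] = df["q"] < alpha

    if grid is None:
        lons = df["lon"].to_numpy()
        lats = df["lat"].to_numpy()
        lon_ax = np.arange(lons.min(), lons.max() + grid_step / 2, grid_step)
        lat_ax = np.arange(lats.min(), lats.max() + grid_step / 2, grid_step)
    else:
        lon_ax, lat_ax = grid
    glon, glat = np.meshgrid(lon_ax, lat_ax)
    interp = griddata(
        df[["lon", "lat"]].to_numpy(), df["mean"].to_numpy(),
        (glon, glat), method="linear", fill_value=0.0,
    )
    values = np.clip(interp, 0.0, None)
    rf = RFGrid(lon=np.asarray(lon_ax, float), lat=np.asarray(lat_ax, float),
                values=values, provenance="functional")
    contours = rf_contour(rf, contour_fraction) if rf.peak_value > 0 else []
    return FunctionalRF(grid=rf, stats=df, alpha=alpha, contours=contours)


@dataclass
class TuningComparison:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    identity_deviation: np.ndarray  # log(b) - log(a), per stimulus


def tuning_comparison(peaks_a, peaks_b) -> TuningComparison:
    """Log-log regression of one cell type's tuning against another's.

    Both peak-response vectors are log-transformed and regressed (least
    squares); a slope of 1 with high r means the downstream type
    inherits the upstream tuning, a slope below 1 means compressed
    tuning.  Per-stimulus deviations from the identity line are kept.
    """
    a = np.asarray(peaks_a, dtype=float)
    b = np.asarray(peaks_b, dtype=float)
    if a.shape != b.shape:
        raise MismatchError("paired tuning vectors must have equal length")
    if np.any(a <= 0) or np.any(b <= 0):
        raise EmptyInputError("log normalization requires strictly positive peaks")
    la, lb = np.log10(a), np.log10(b)
    res = stats.linregress(la, lb)
    return TuningComparison(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        identity_deviation=lb - la,
    )


@dataclass
class SuppressionResult:
    p_value: float
    mean_difference: float  # mean(both) - mean(ipsi); negative = suppression
    suppressed: bool


def bilateral_suppression_test(ipsi_peaks, both_peaks) -> SuppressionResult:
    """Two-sided paired t-test: does a simultaneous contralateral stimulus
    change the response to the ipsilateral one?"""
    ipsi = np.asarray(ipsi_peaks, dtype=float)
    both = np.asarray(both_peaks, dtype=float)
    if ipsi.shape != both.shape:
        raise MismatchError("peaks must be paired by fly")
    if len(ipsi) < 3:
        raise InvalidSizeError("need at least 3 flies")
    diff = both - ipsi
    if np.ptp(diff) == 0 and diff[0] == 0:
        p = 1.0
    else:
        p = float(stats.ttest_rel(both, ipsi).pvalue)
    mean_diff = float(diff.mean())
    return SuppressionResult(p_value=p, mean_difference=mean_diff,
                             suppressed=bool(mean_diff < 0 and p < 0.05))
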