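"""Synthetic connectomes with a tunable degree of retinotopy.

The generator emulates the structures the analyses assume: ~65
projection neurons whose dendrite centers tile the eye lune with higher
density toward the visual midline, axons converging into an elongated
(cylindrical) glomerulus where each axon's extent along the long axis is
a scramble-weighted mixture of its latitude rank and a random rank,
presynapse clouds spread uniformly along each axon, neuron-neuron
synapses whose probability decays with eye-coordinate distance, and
downstream targets whose per-neuron synapse counts follow a Gaussian
receptive field in eye coordinates.

``scramble=0`` yields perfect retinotopy of the glomerulus axis
(latitude order preserved exactly), ``scramble=1`` a fully random axis
order; every draw is reproducible bit-for-bit from the config seed, with
independent substreams per component so adding one component never
perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, InvalidSizeError
from .geometry import NODE_COLUMNS, Skeleton
from .rf import RFGrid
from .ri import PointMapping
from .sphere import LUNE_LAT, LUNE_LON

__all__ = [
    "TargetSpec",
    "ConnectomeConfig",
    "SyntheticConnectome",
    "Truth",
    "TraceSet",
    "make_lobula_grid",
    "generate",
    "make_traces",
]

# Layout constants (nm): the lobula sheet sits at z = 0 with 400 nm per
# eye degree; the glomerulus is a cylinder along +x entered at GLOM_ENTRY.
NM_PER_DEG = 400.0
GLOM_ENTRY = np.array([120_000.0, 0.0, 0.0])
GLOM_LENGTH = 40_000.0
GLOM_RADIUS = 5_000.0


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass
class TargetSpec:
    """One downstream target neuron: a Gaussian receptive field in eye
    coordinates and a total synapse budget distributed across the
    projection neurons."""

    name: str
    rf_center: tuple[float, float]
    rf_spread: float  # Gaussian sigma, degrees
    total_synapses: int
    transmitter: str = "excitatory"


def _default_targets() -> list[TargetSpec]:
    # three targets with synapse budgets on the order of the strongly,
    # moderately and weakly connected glomerulus interneurons
    return [
        TargetSpec("G1", rf_center=(0.0, 60.0), rf_spread=40.0, total_synapses=912),
        TargetSpec("G2a", rf_center=(25.0, 95.0), rf_spread=30.0, total_synapses=428,
                   transmitter="inhibitory"),
        TargetSpec("G2b", rf_center=(-20.0, 40.0), rf_spread=30.0, total_synapses=207,
                   transmitter="inhibitory"),
    ]


@dataclass
class ConnectomeConfig:
    n_neurons: int = 65
    grid_shape: tuple[int, int] = (6, 11)
    jitter_sd: float = 3.0
    scramble: float = 0.0
    axis_coupling: float = 0.8
    presyn_per_neuron: int = 80
    presyn_span_nm: float = 15_000.0  # presynapse-bearing terminal stretch of the axon
    lc_lc_decay_scale: float = 20.0
    lc_lc_base_rate: float = 4.5
    midline_bias: float = 1.3  # longitude-warp exponent; >1 densifies near lon 0
    target_specs: list[TargetSpec] = field(default_factory=_default_targets)
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.grid_shape
        if self.n_neurons < 3 or rows * cols < self.n_neurons:
            raise ConfigError("need 3 <= n_neurons <= rows*cols")
        if not 0.0 <= self.scramble <= 1.0:
            raise ConfigError("scramble must lie in [0, 1]")
        if not -1.0 <= self.axis_coupling <= 1.0:
            raise ConfigError("axis_coupling must lie in [-1, 1]")
        if self.jitter_sd < 0:
            raise ConfigError("jitter_sd must be >= 0")
        if self.presyn_per_neuron < 1 or self.lc_lc_decay_scale <= 0:
            raise ConfigError("counts must be positive")
        for t in self.target_specs:
            if t.total_synapses < 1 or t.rf_spread < 0:
                raise ConfigError(f"invalid target spec {t.name!r}")


@dataclass
class Truth:
    """Generating parameters, kept for parameter-recovery tests."""

    scramble: float
    axis_coupling: float
    eye_centers: dict
    axis_positions: dict  # neuron id -> axial coordinate of the axon tip (nm from entry)
    rf_centers: dict  # target name -> (lon, lat)
    rf_spreads: dict
    config: ConnectomeConfig = None


@dataclass
class SyntheticConnectome:
    neurons: list  # of Skeleton
    eye_centers: dict
    presynapses: pd.DataFrame  # pre_id, post_id (NaN), x, y, z
    lc_lc_synapses: pd.DataFrame  # pre_id, post_id, x, y, z
    target_synapse_counts: dict  # (target name, neuron id) -> count
    truth: Truth

    def axis_mapping(self) -> PointMapping:
        """The canonical scramble-sensitive mapping: 1-D latitude of each
        neuron's eye center mapped to its glomerulus-axis coordinate."""
        ids = sorted(self.eye_centers)
        lat = np.array([self.eye_centers[i][1] for i in ids])
        axial = np.array([self.truth.axis_positions[i] for i in ids])
        return PointMapping(ids, lat, axial)

    def presynapse_clouds(self) -> dict:
        return {
            nid: grp[["x", "y", "z"]].to_numpy(dtype=float)
            for nid, grp in self.presynapses.groupby("pre_id")
        }

    def target_weights(self, name: str) -> dict:
        return {
            nid: self.target_synapse_counts.get((name, nid), 0)
            for nid in self.eye_centers
        }


def make_lobula_grid(rows: int, cols: int, jitter_sd: float, seed) -> np.ndarray:
    """A jittered regular grid of rows*cols points spanning the eye lune.

    Nominal positions lie on a lattice inset by half a lattice step from
    the lune boundary; each point is perturbed by isotropic Gaussian
    jitter of sd ``jitter_sd`` degrees.  Deterministic given the seed.
    """
    if rows * cols < 3:
        raise InvalidSizeError("need at least 3 grid points")
    rng = np.random.default_rng(seed)
    lon_step = (LUNE_LON[1] - LUNE_LON[0]) / cols
    lat_step = (LUNE_LAT[1] - LUNE_LAT[0]) / rows
    lon = LUNE_LON[0] + lon_step * (np.arange(cols) + 0.5)
    lat = LUNE_LAT[0] + lat_step * (np.arange(rows) + 0.5)
    glon, glat = np.meshgrid(lon, lat)
    pts = np.column_stack([glon.ravel(), glat.ravel()])
    return pts + rng.normal(0.0, jitter_sd, size=pts.shape)


def _warp_midline(lon: np.ndarray, exponent: float) -> np.ndarray:
    """Compress longitudes toward the visual midline (lon = 0).

    A power warp |lon|^e scaled back to the lune keeps the boundary fixed
    while raising point density near the midline for e > 1.
    """
    half = LUNE_LON[1]
    return np.sign(lon) * half * (np.abs(lon) / half) ** exponent


def _axon_skeleton(neuron_id, lobula_pos, radial_offset, tip_x, node_step=2000.0) -> Skeleton:
    """A minimal neuron: a 5-node dendrite star at the lobula position and
    an axon polyline running to the glomerulus entry and along its axis."""
    rows = []
    nid = 1
    x0, y0, z0 = lobula_pos
    rows.append((nid, -1, x0, y0, z0, -1.0, "dendrite"))
    root = nid
    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nid += 1
        rows.append((nid, root, x0 + dx * 2000.0, y0 + dy * 2000.0, z0, -1.0, "dendrite"))
    entry = GLOM_ENTRY + np.array([0.0, radial_offset[0], radial_offset[1]])
    tip = entry + np.array([tip_x, 0.0, 0.0])
    path = np.vstack([lobula_pos, entry, tip])
    parent = root
    for seg_start, seg_end in zip(path[:-1], path[1:]):
        seg = seg_end - seg_start
        length = np.linalg.norm(seg)
        n_nodes = max(1, int(round(length / node_step)))
        for k in range(1, n_nodes + 1):
            p = seg_start + seg * (k / n_nodes)
            nid += 1
            rows.append((nid, parent, p[0], p[1], p[2], -1.0, "axon"))
            parent = nid
    return Skeleton._trusted(neuron_id, pd.DataFrame(rows, columns=NODE_COLUMNS))


def generate(config: ConnectomeConfig) -> SyntheticConnectome:
    """Draw one synthetic connectome from the configured conditions."""
    rows, cols = config.grid_shape
    grid = make_lobula_grid(rows, cols, config.jitter_sd,
                            substream(config.seed, "grid"))
    grid[:, 0] = _warp_midline(grid[:, 0], config.midline_bias)
    pick = substream(config.seed, "pick").choice(len(grid), size=config.n_neurons,
                                                 replace=False)
    pick.sort()
    points = grid[pick]
    ids = [f"n{k:03d}" for k in range(config.n_neurons)]
    eye_centers = {i: (float(p[0]), float(p[1])) for i, p in zip(ids, points)}

    # --- glomerulus axial coordinates: rank mixing ---------------------
    n = config.n_neurons
    lat = points[:, 1]
    score = config.axis_coupling * lat
    rng_axis = substream(config.seed, "axis")
    true_rank = np.empty(n)
    true_rank[np.argsort(score, kind="stable")] = np.arange(n)
    rand_rank = rng_axis.permutation(n).astype(float)
    mixed = (1.0 - config.scramble) * true_rank + config.scramble * rand_rank
    final_rank = np.empty(n, dtype=int)
    # re-rank; random tie-break keeps scramble=1 uniform even for tied mixes
    final_rank[np.lexsort((rng_axis.random(n), mixed))] = np.arange(n)
    axial = (final_rank + 0.5) / n * GLOM_LENGTH  # nm from glomerulus entry

    # --- skeletons and presynapses -------------------------------------
    rng_geom = substream(config.seed, "geometry")
    rng_presyn = substream(config.seed, "presynapses")
    neurons = []
    presyn_rows = []
    lobula_xyz = np.column_stack([points * NM_PER_DEG, np.zeros(n)])
    for k, i in enumerate(ids):
        theta = rng_geom.uniform(0, 2 * np.pi)
        r = 0.8 * GLOM_RADIUS * np.sqrt(rng_geom.uniform())
        offset = (r * np.cos(theta), r * np.sin(theta))
        neurons.append(_axon_skeleton(i, lobula_xyz[k], offset, axial[k]))
        # presynapses sit on the terminal stretch of the axon, uniformly
        # along its arclength, so each cloud tracks its axon's extent
        lo = max(0.0, axial[k] - config.presyn_span_nm)
        xs = rng_presyn.uniform(lo, axial[k], size=config.presyn_per_neuron)
        jit = rng_presyn.normal(0.0, 500.0, size=(config.presyn_per_neuron, 2))
        for x, (jy, jz) in zip(xs, jit):
            presyn_rows.append((i, np.nan,
                                GLOM_ENTRY[0] + x,
                                GLOM_ENTRY[1] + offset[0] + jy,
                                GLOM_ENTRY[2] + offset[1] + jz))
    presynapses = pd.DataFrame(presyn_rows, columns=["pre_id", "post_id", "x", "y", "z"])

    # --- neuron-neuron synapses with distance-decayed probability ------
    rng_lc = substream(config.seed, "lc_lc")
    from .sphere import great_circle_matrix

    d = great_circle_matrix(points)
    rate = config.lc_lc_base_rate * np.exp(-d / config.lc_lc_decay_scale)
    np.fill_diagonal(rate, 0.0)
    counts = rng_lc.poisson(rate)
    lc_rows = []
    presyn_by_id = {i: grp[["x", "y", "z"]].to_numpy()
                    for i, grp in presynapses.groupby("pre_id")}
    for a in range(n):
        for b in range(n):
            c = counts[a, b]
            if c == 0:
                continue
            sites = presyn_by_id[ids[a]]
            chosen = sites[rng_lc.integers(0, len(sites), size=c)]
            for p in chosen:
                lc_rows.append((ids[a], ids[b], p[0], p[1], p[2]))
    lc_lc = pd.DataFrame(lc_rows, columns=["pre_id", "post_id", "x", "y", "z"])

    # --- target synapse counts: Gaussian RF in eye coordinates ---------
    rng_tgt = substream(config.seed, "targets")
    target_counts = {}
    for spec in config.target_specs:
        c_lon, c_lat = spec.rf_center
        d2 = (points[:, 0] - c_lon) ** 2 + (points[:, 1] - c_lat) ** 2
        if spec.rf_spread > 0:
            w = np.exp(-d2 / (2.0 * spec.rf_spread**2))
        else:
            w = np.zeros(n)
        if w.sum() <= 0:  # degenerate spread: everything on the nearest neuron
            w = np.zeros(n)
            w[int(np.argmin(d2))] = 1.0
        draws = rng_tgt.multinomial(spec.total_synapses, w / w.sum())
        for k, i in enumerate(ids):
            target_counts[(spec.name, i)] = int(draws[k])

    truth = Truth(
        scramble=config.scramble,
        axis_coupling=config.axis_coupling,
        eye_centers=eye_centers,
        axis_positions={i: float(axial[k]) for k, i in enumerate(ids)},
        rf_centers={t.name: t.rf_center for t in config.target_specs},
        rf_spreads={t.name: t.rf_spread for t in config.target_specs},
        config=config,
    )
    return SyntheticConnectome(
        neurons=neurons,
        eye_centers=eye_centers,
        presynapses=presynapses,
        lc_lc_synapses=lc_lc,
        target_synapse_counts=target_counts,
        truth=truth,
    )


@dataclass
class TraceSet:
    """Synthetic calcium traces, one per stimulus location."""

    traces: pd.DataFrame  # stim_id, frame, F
    epochs: dict  # stim_id -> (start_frame, stop_frame)
    baseline: float
    stimulus_centers: dict  # stim_id -> (lon, lat)


def make_traces(
    rf: RFGrid,
    stimulus_centers,
    gain: float = 1.0,
    noise_sd: float = 0.0,
    frames_per_epoch: int = 20,
    baseline: float = 1.0,
    seed=0,
) -> TraceSet:
    """Fluorescence time series for looming-style stimuli at many positions.

    Each stimulus evokes a transient whose amplitude is
    ``gain * rf(stimulus center)``: a linear rise across the stimulus
    epoch peaking at its last frame, then an exponential decay, on top of
    a constant baseline F0 plus Gaussian noise.  With zero noise the peak
    ΔF/F is exactly gain * rf(center) / F0.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    fpe = int(frames_per_epoch)
    n_frames = 3 * fpe
    rise = np.arange(1, fpe + 1) / fpe
    decay = np.exp(-3.0 * np.arange(1, fpe + 1) / fpe)
    shape = np.concatenate([np.zeros(fpe), rise, decay])

    rows = []
    epochs = {}
    centers = {}
    for k, (lon, lat) in enumerate(stimulus_centers):
        stim_id = f"s{k:03d}"
        try:
            amp = gain * rf.interpolate(lon, lat)
        except ValueError as err:
            raise EmptyInputError(
                f"stimulus center ({lon}, {lat}) outside the RF grid"
            ) from err
        f = baseline + amp * shape
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, size=n_frames)
        for frame, value in enumerate(f):
            rows.append((stim_id, frame, float(value)))
        epochs[stim_id] = (fpe, 2 * fpe)
        centers[stim_id] = (float(lon), float(lat))
    traces = pd.DataFrame(rows, columns=["stim_id", "frame", "F"])
    return TraceSet(traces=traces, epochs=epochs, baseline=baseline,
                    stimulus_centers=centers)
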