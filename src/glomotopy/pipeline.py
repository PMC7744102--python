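"""Run configuration and the end-to-end analysis pipeline.

The pipeline runs the standard analysis order on a synthetic connectome:
glomerulus long axis -> per-neuron median positions -> Retinotopy Index
of the lobula-to-glomerulus mapping -> idealized projection sweep ->
neuron-neuron distance-bias shuffle test -> compartment partition and
compartment RI -> anatomical receptive fields per target.  Every stage's
numbers land in one machine-readable summary; identical config + seed
reproduce it byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import connectivity, geometry, io, mappings, rf, synthetic
from .errors import ConfigError

__all__ = ["RunConfig", "run_pipeline", "save_connectome", "load_connectome"]

_PARAM_DEFAULTS = dict(
    resample_spacing_nm=400.0,
    slice_thickness_nm=1000.0,
    n_compartments=10,
    n_proximity_slices=80,
    rf_half_width_deg=30.0,
    contour_fractions=(0.7, 0.6),
    synapse_threshold=15,
    dff_window_frames=300,
    dff_percentile=10.0,
    normalization_percentile=98.0,
    sweep_step_deg=10.0,
    n_shuffles=1000,
)


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run.

    Defaults are the standard analysis values: 400 nm skeleton
    resampling, 1 um slices, 10 compartments, 80 proximity slices, 30
    degree RF half-width, 70%/60% contours, 15-synapse threshold,
    300-frame/10th-percentile ΔF/F baseline and 98th-percentile
    normalization.  Unknown keys are rejected.
    """

    seed: int = 0
    out_dir: str = "glomotopy_out"
    connectome: dict = field(default_factory=dict)  # ConnectomeConfig overrides
    params: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.params) - set(_PARAM_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
        merged = dict(_PARAM_DEFAULTS)
        merged.update(self.params)
        self.params = merged
        allowed = {f.name for f in dataclasses.fields(synthetic.ConnectomeConfig)}
        unknown = set(self.connectome) - allowed
        if unknown:
            raise ConfigError(f"unknown connectome keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        out["params"]["contour_fractions"] = list(out["params"]["contour_fractions"])
        return out

    def digest(self) -> str:
        """Hash of everything that affects the numbers (not where they go)."""
        payload = self.resolved()
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def save_connectome(conn: synthetic.SyntheticConnectome, out_dir) -> None:
    """Write a connectome as SWC + CSV + JSON text files."""
    out = Path(out_dir)
    (out / "skeletons").mkdir(parents=True, exist_ok=True)
    for skel in conn.neurons:
        io.write_swc(skel, out / "skeletons" / f"{skel.neuron_id}.swc")
    io.write_synapses(conn.presynapses, out / "presynapses.csv")
    io.write_synapses(conn.lc_lc_synapses, out / "synapses.csv")
    io.write_eye_centers(conn.eye_centers, out / "eye_centers.csv")
    truth = dict(
        scramble=conn.truth.scramble,
        axis_coupling=conn.truth.axis_coupling,
        eye_centers=conn.truth.eye_centers,
        axis_positions=conn.truth.axis_positions,
        rf_centers=conn.truth.rf_centers,
        rf_spreads=conn.truth.rf_spreads,
        target_synapse_counts={f"{t}|{n}": c for (t, n), c in
                               conn.target_synapse_counts.items()},
    )
    io.write_json(truth, out / "truth.json")


def load_connectome(out_dir):
    """Reload the pieces written by :func:`save_connectome`."""
    out = Path(out_dir)
    skels = [io.read_swc(p) for p in sorted((out / "skeletons").glob("*.swc"))]
    presyn = io.read_synapses(out / "presynapses.csv")
    lc_lc = io.read_synapses(out / "synapses.csv")
    eye = io.read_eye_centers(out / "eye_centers.csv")
    with open(out / "truth.json") as fh:
        truth = json.load(fh)
    return skels, presyn, lc_lc, eye, truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis chain on a generated connectome.

    Returns the summary dict; all outputs (summary.json, eye_centers.csv,
    sweep.csv, compartment assignments) are also written under
    ``config.out_dir``.  Any stage failure halts with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    summary: dict = {"config_hash": config.digest(), "seed": config.seed, "stages": {}}

    stage = "generate"
    try:
        cc = synthetic.ConnectomeConfig(seed=config.seed, **config.connectome)
        conn = synthetic.generate(cc)
        save_connectome(conn, out / "connectome")
        summary["stages"][stage] = dict(
            n_neurons=cc.n_neurons,
            n_presynapses=int(len(conn.presynapses)),
            n_lc_lc_synapses=int(len(conn.lc_lc_synapses)),
        )

        stage = "long_axis"
        presyn_xyz = conn.presynapses[["x", "y", "z"]].to_numpy()
        axis = geometry.glomerulus_long_axis(presyn_xyz)
        summary["stages"][stage] = dict(
            direction=axis.direction.tolist(),
            extent=list(axis.extent),
            near_isotropic=axis.near_isotropic,
        )

        stage = "median_ri"
        clouds = conn.presynapse_clouds()
        medians = {nid: geometry.median_axis_position(pts, axis)
                   for nid, pts in clouds.items()}
        from .ri import PointMapping, ri_population

        ids = sorted(conn.eye_centers)
        eye_pts = np.array([conn.eye_centers[i] for i in ids])
        med = np.array([medians[i] for i in ids])
        res = ri_population(PointMapping(ids, eye_pts, med, source_metric="greatcircle"))
        summary["stages"][stage] = dict(
            population_ri=res.population_ri, p_value=res.p_value_vs_zero, n=res.n
        )

        stage = "projection_sweep"
        angles = np.arange(0.0, 180.0, p["sweep_step_deg"])
        sweep = mappings.projection_sweep(conn.eye_centers, medians, angles)
        sweep.to_csv(out / "sweep.csv", index=False)
        best = sweep.loc[sweep["ri_lobula_to_line"].idxmax()]
        summary["stages"][stage] = dict(
            best_angle=float(best["angle"]),
            best_ri=float(best["ri_lobula_to_line"]),
        )

        stage = "distance_bias"
        counts = (
            conn.lc_lc_synapses.groupby(["pre_id", "post_id"]).size().to_dict()
        )
        bias = connectivity.lc_lc_distance_bias(
            conn.eye_centers, counts, n_shuffles=p["n_shuffles"],
            seed=synthetic.substream(config.seed, "bias"),
        )
        summary["stages"][stage] = dict(
            observed_mean_deg=bias.observed_mean,
            null_mean_deg=float(bias.null_means.mean()),
            p_value=bias.p_value,
        )

        stage = "compartments"
        part = geometry.partition_compartments(presyn_xyz, axis, k=p["n_compartments"])
        presyn = conn.presynapses.assign(compartment=part.assignment,
                                         neuron_id=conn.presynapses["pre_id"])
        mid = p["n_compartments"] // 2
        comp_res = connectivity.compartment_ri(
            presyn, conn.eye_centers, compartments=[mid - 1, mid, mid + 1]
        )
        ctrl_res = connectivity.compartment_ri(
            presyn, conn.eye_centers, compartments=[mid - 1, mid, mid + 1],
            randomize=True, seed=synthetic.substream(config.seed, "compartment-ctrl"),
        )
        summary["stages"][stage] = dict(
            counts=part.counts().tolist(),
            compartment_ri=comp_res.population_ri,
            randomized_control_ri=ctrl_res.population_ri,
        )

        stage = "anatomical_rf"
        rf_summaries = {}
        for spec in cc.target_specs:
            weights = conn.target_weights(spec.name)
            grid = rf.anatomical_rf(conn.eye_centers, weights,
                                    half_width=p["rf_half_width_deg"])
            for frac in p["contour_fractions"]:
                rf.rf_contour(grid, frac)
            rf_summaries[spec.name] = dict(
                peak_lonlat=list(grid.argmax_coord()),
                true_center=list(conn.truth.rf_centers[spec.name]),
            )
        summary["stages"][stage] = rf_summaries
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    io.write_json(summary, out / "summary.json")
    return summary
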