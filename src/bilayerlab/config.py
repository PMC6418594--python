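"""End-to-end pipeline orchestration from a single YAML config.

A config names the trajectory and group file, the stages to run, per-stage
parameters, an output directory and a seed. Stages run in dependency order
(the RDF stage before clustering when the cluster cutoff is "auto"); every
stage writes CSV output and contributes to one JSON summary that embeds the
fully resolved config — defaults included — for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from bilayerlab.errors import ValidationError
from bilayerlab import cluster_analysis, diffusion, pair_correlation, structure
from bilayerlab.trajectory import Trajectory, load_trajectory, unwrap

logger = logging.getLogger("bilayerlab")

KNOWN_STAGES = ("gen", "diffusion", "rdf", "angles", "zprofile", "clusters")


@dataclass
class AnalysisConfig:
    """Resolved pipeline configuration; every field has a default."""

    trajectory: str | None = None
    group_file: str | None = None
    stages: list[str] = field(default_factory=lambda: ["diffusion"])
    output_dir: str = "bilayerlab_out"
    seed: int = 0
    log_level: str = "INFO"
    skip_time: float = 0.0  # ns discarded from the start (equilibration)
    diffusion_params: dict = field(default_factory=dict)
    rdf_params: dict = field(default_factory=dict)
    angles_params: dict = field(default_factory=dict)
    zprofile_params: dict = field(default_factory=dict)
    clusters_params: dict = field(default_factory=dict)
    gen_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ValidationError(f"unknown stages {unknown}; valid: {KNOWN_STAGES}")
        for name in ("trajectory", "group_file"):
            p = getattr(self, name)
            if p is not None and "gen" not in self.stages and not Path(p).exists():
                raise ValidationError(f"{name} does not exist: {p}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "AnalysisConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - fields
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _skip_equilibration(traj: Trajectory, skip_time: float) -> Trajectory:
    if skip_time <= 0:
        return traj
    k = int(round(skip_time / traj.dt))
    if k >= traj.n_frames - 1:
        raise ValidationError("skip_time leaves fewer than 2 frames")
    return Trajectory(
        positions=traj.positions[k:], box=traj.box[k:], dt=traj.dt, wrapped=traj.wrapped
    )


def _stage_gen(config: AnalysisConfig, outdir: Path) -> dict:
    """Generate a Brownian fixture and point the config at it."""
    from bilayerlab import synthetic
    from bilayerlab.trajectory import write_group_file, write_xyz

    params = dict(config.gen_params)
    params.setdefault("seed", config.seed)
    spec = synthetic.BrownianSpec(**params)
    traj, gspec = synthetic.gen_brownian2d(spec)
    xyz = outdir / "generated.xyz"
    grp = outdir / "generated.groups.yaml"
    write_xyz(traj, xyz)
    write_group_file(gspec, grp, dt=traj.dt)
    config.trajectory = str(xyz)
    config.group_file = str(grp)
    return {"spec": dataclasses.asdict(spec), "trajectory": str(xyz), "group_file": str(grp)}


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the requested stages and write summary.json plus per-stage CSVs.

    Returns the summary dict. A failing stage raises, after logging which
    stage failed; the CLI maps that to a nonzero exit status.
    """
    logging.basicConfig(level=config.log_level)
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"stages": {}, "decisions": {}}

    ordered = [s for s in KNOWN_STAGES if s in config.stages]
    if "clusters" in ordered:
        auto_cutoff = config.clusters_params.get("cutoff", "auto") in (None, "auto")
        if auto_cutoff and "rdf" not in ordered:
            raise ValidationError(
                "stage 'clusters' with cutoff=auto requires the 'rdf' stage"
            )

    if "gen" in ordered:
        logger.info("stage gen")
        summary["stages"]["gen"] = _stage_gen(config, outdir)

    traj, gspec = load_trajectory(config.trajectory, group_file=config.group_file)
    traj = _skip_equilibration(traj, config.skip_time)
    summary["decisions"]["skip_time_ns"] = config.skip_time
    unwrapped = unwrap(traj) if traj.wrapped else traj

    rdf_cache: pair_correlation.RDFResult | None = None
    for stage in ordered:
        if stage == "gen":
            continue
        logger.info("stage %s", stage)
        try:
            if stage == "diffusion":
                p = dict(config.diffusion_params)
                group = gspec.group(p.pop("group", "lipids"))
                ref = gspec.group(p.pop("reference", "lipids"))
                est = diffusion.block_diffusion(unwrapped, group, ref, **p)
                curve = diffusion.compute_msd(
                    unwrapped, group, ref,
                    max_lag=p.get("max_lag"), lateral=p.get("lateral", True),
                )
                _write_csv(outdir / "msd.csv", ["lag_ns", "msd_A2", "n_pairs"],
                           np.column_stack([curve.lags, curve.msd, curve.n_pairs]))
                summary["stages"]["diffusion"] = dataclasses.asdict(est)
            elif stage == "rdf":
                p = dict(config.rdf_params)
                cor = pair_correlation.cor_positions(traj, gspec)
                rdf_cache = pair_correlation.compute_rdf(
                    traj, cor,
                    r_max=p.get("r_max", 30.0), dr=p.get("dr", 0.2),
                    mode=p.get("mode", "lateral"),
                )
                peaks = pair_correlation.find_peaks(rdf_cache)
                _write_csv(outdir / "rdf_cor_cor.csv", ["r_A", "g"],
                           np.column_stack([rdf_cache.bin_centers, rdf_cache.g]))
                summary["stages"]["rdf"] = {
                    "mode": rdf_cache.mode,
                    "peak_positions_A": peaks.positions.tolist(),
                    "peak_heights": peaks.heights.tolist(),
                }
                summary["decisions"]["rdf_mode"] = rdf_cache.mode
            elif stage == "angles":
                p = dict(config.angles_params)
                series = structure.backbone_angles(traj, gspec)
                rows = {}
                for name, vals in (("alpha1", series.alpha1), ("alpha2", series.alpha2),
                                   ("beta", series.beta)):
                    hist = structure.angle_histogram(vals, p.get("bin_width", 2.0))
                    _write_csv(outdir / f"angles_{name}.csv", ["angle_deg", "density"],
                               np.column_stack([hist.bin_centers, hist.density]))
                    rows[name] = {"mean_deg": float(np.mean(vals))}
                summary["stages"]["angles"] = rows
            elif stage == "zprofile":
                p = dict(config.zprofile_params)
                ref_name = p.get("reference")
                if ref_name is not None:
                    ref = gspec.group(ref_name)
                else:
                    ref = np.arange(traj.n_particles)  # whole-system COM
                out = {}
                for gname in p.get("groups", ["headgroups"]):
                    prof = structure.z_profile(
                        traj, gspec.group(gname), ref,
                        bin_width=p.get("bin_width", 1.0),
                        z_range=p.get("z_range", 34.0), group_label=gname,
                    )
                    _write_csv(outdir / f"zprofile_{gname}.csv", ["z_A", "density"],
                               np.column_stack([prof.z_bin_centers, prof.density]))
                    entry = {"midplane_ratio": structure.midplane_ratio(prof)}
                    if gname == "headgroups":
                        entry["thickness_A"] = structure.bilayer_thickness(prof)
                    out[gname] = entry
                summary["stages"]["zprofile"] = out
            elif stage == "clusters":
                p = dict(config.clusters_params)
                cutoff = p.get("cutoff", "auto")
                if cutoff in (None, "auto"):
                    cutoff = pair_correlation.first_minimum(rdf_cache)
                    summary["decisions"]["cluster_cutoff_source"] = "rdf_first_minimum"
                cts = cluster_analysis.cluster_timeseries(
                    traj, gspec, cutoff=float(cutoff), mode=p.get("mode", "lateral")
                )
                est = cluster_analysis.characteristic_timescale(
                    cts.trimer_indicator, traj.dt, max_lag=p.get("max_lag")
                )
                _write_csv(outdir / "clusters.csv",
                           ["frame", "largest_size", "trimer_indicator"],
                           np.column_stack([np.arange(cts.n_frames),
                                            cts.largest_size, cts.trimer_indicator]))
                summary["stages"]["clusters"] = {
                    "cutoff_A": cts.cutoff_used,
                    "tau_ns": est.tau,
                    "stationary_fraction": est.stationary_fraction,
                }
        except Exception:
            logger.exception("stage %r failed", stage)
            raise

    summary["config"] = config.to_dict()
    with (outdir / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _write_csv(path: Path, header: list[str], data: np.ndarray) -> None:
    np.savetxt(path, data, delimiter=",", header=",".join(header), comments="", fmt="%.10g")
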