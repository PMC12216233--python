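"""End-to-end orchestration: config in, text outputs + manifest out.

Three modes: ``md-sd`` (gap tables -> state assignment -> windowed ACF ->
spectral density -> summaries), ``vg-sd`` (normal modes -> broadened VG
spectral density) and ``geometry`` (two trajectories -> ensemble deviation
tables, dihedral histograms, RDFs).  Every output directory receives a
``manifest.json`` with the fully resolved configuration (defaults
included) and the seed, sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .gap_io import read_gap_table, read_geometry_trajectory
from .geometry_stats import (
    dihedral_distribution,
    ensemble_deviation,
    ensemble_stats,
    internal_coordinates,
    rdf,
    read_internal_coordinates,
)
from .spectral_density import (
    acf_to_sd,
    average_acfs,
    find_peaks,
    reorganization_energy,
    window_acf,
    write_acf,
    write_spectral_density,
)
from .state_tracking import ReferenceAxes, assign_states, relabel_energies
from .synthetic import BathSpec, generate_replicas
from .vertical_gradient import read_mode_table, vg_sd
from .gap_io import write_gap_table

log = logging.getLogger("gapspec")

DEFAULTS = {
    "seed": 0,
    "acf": {
        "window_length_fs": 4000.0,
        "overlap": 0.0,
        "estimator": "unbiased",
        "mean_subtraction": "window",
    },
    "sd": {
        "freq_min_cm1": 0.0,
        "freq_max_cm1": 2500.0,
        "freq_step_cm1": 1.0,
        "taper_tau_fs": None,
        "min_prominence": 0.05,
        "smooth_sigma_cm1": None,
    },
    "state_tracking": {
        "mixing_threshold_deg": 60.0,
        "continuity_penalty_deg": 0.0,
    },
    "temperature_K": 300.0,
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for the CLI message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config", f"{path} does not hold a mapping")
    return cfg


def _merge_defaults(cfg: dict) -> dict:
    out = copy.deepcopy(DEFAULTS)
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def _freq_grid(sd_cfg: dict) -> np.ndarray:
    return np.arange(sd_cfg["freq_min_cm1"],
                     sd_cfg["freq_max_cm1"] + sd_cfg["freq_step_cm1"] / 2,
                     sd_cfg["freq_step_cm1"])


def _write_manifest(outdir: Path, resolved: dict, mode: str) -> None:
    manifest = {"tool": "gapspec", "version": __version__, "mode": mode,
                "config": resolved}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _reference_axes(block: dict) -> ReferenceAxes:
    labels, vectors, pairs = [], [], []
    for label, spec in block.items():
        labels.append(label)
        if isinstance(spec, dict):
            pairs.append(tuple(spec["atoms"]))
        else:
            vectors.append([float(x) for x in spec])
    if vectors and pairs:
        raise PipelineError("state-tracking",
                            "mix of vector and atom-pair axes is not supported")
    if pairs:
        return ReferenceAxes(labels=tuple(labels), atom_pairs=pairs)
    return ReferenceAxes(labels=tuple(labels), vectors=np.array(vectors))


def run_md_sd(config: dict, outdir) -> dict:
    """Gap tables -> (optional) diabatic relabelling -> pooled ACF -> SD.

    Window-ACFs are pooled across replicas before the single cosine
    transform per state.  Writes per-state ACF/SD/peak-table files, an
    assignment report and the manifest; returns the in-memory results.
    """
    cfg = _merge_defaults(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    block = cfg.get("md_sd")
    if not block:
        raise PipelineError("config", "md_sd block missing")
    paths = block.get("gap_tables", [])
    if not paths:
        raise PipelineError("ingest", "no gap tables configured")
    temperature = float(block.get("temperature_K", cfg["temperature_K"]))
    replicas = []
    for p in paths:
        try:
            replicas.append(read_gap_table(p, temperature=temperature))
        except (OSError, ValueError) as err:
            raise PipelineError("ingest", f"{p}: {err}") from err
    log.info("ingest: %d replicas, %d frames each",
             len(replicas), replicas[0].n_frames)

    labels = tuple(f"S{i + 1}" for i in range(replicas[0].n_states))
    n_mixed = 0
    st_block = block.get("state_tracking")
    if st_block:
        try:
            refs = _reference_axes(st_block["axes"])
            geometry = None
            if st_block.get("geometry"):
                geometry = read_geometry_trajectory(st_block["geometry"])
            relabelled = []
            report_rows = []
            for traj in replicas:
                asn = assign_states(
                    traj, refs, geometry=geometry,
                    mixing_threshold_deg=cfg["state_tracking"]
                    ["mixing_threshold_deg"],
                    continuity_penalty_deg=cfg["state_tracking"]
                    ["continuity_penalty_deg"],
                )
                relabelled.append(relabel_energies(traj, asn))
                n_mixed += int(asn.mixing_flags.sum())
                report_rows.append({
                    "replica": traj.replica_id,
                    "mean_deviation_deg": {
                        lab: float(asn.deviation_angles[:, i].mean())
                        for i, lab in enumerate(asn.labels)},
                    "frames_flagged_mixed": int(asn.mixing_flags.sum()),
                })
            replicas = relabelled
            labels = refs.labels
            with open(outdir / "assignment_report.json", "w") as fh:
                json.dump(report_rows, fh, indent=2)
        except (KeyError, ValueError) as err:
            raise PipelineError("state-tracking", str(err)) from err
        log.info("state-tracking: %d frames flagged mixed", n_mixed)

    acf_cfg, sd_cfg = cfg["acf"], cfg["sd"]
    grid = _freq_grid(sd_cfg)
    results = {}
    for i, label in enumerate(labels):
        try:
            acfs = [
                window_acf(
                    traj.energies[:, i], traj.dt,
                    acf_cfg["window_length_fs"],
                    overlap=acf_cfg["overlap"],
                    mean_subtraction=acf_cfg["mean_subtraction"],
                    estimator=acf_cfg["estimator"],
                    temperature=temperature,
                ) for traj in replicas
            ]
        except ValueError as err:
            raise PipelineError("acf", str(err)) from err
        pooled = average_acfs(acfs)
        sd = acf_to_sd(pooled, freq_grid=grid,
                       taper_tau=sd_cfg["taper_tau_fs"])
        lam = reorganization_energy(sd)
        peaks = find_peaks(sd, min_prominence=sd_cfg["min_prominence"],
                           smooth_sigma_cm1=sd_cfg["smooth_sigma_cm1"])
        write_acf(pooled, outdir / f"acf_{label}.dat")
        write_spectral_density(sd, outdir / f"sd_{label}.dat")
        peaks.to_csv(outdir / f"peaks_{label}.csv", index=False,
                     float_format="%.6f")
        log.info("sd[%s]: %d windows, lambda = %.1f cm^-1, %d peaks",
                 label, pooled.n_windows, lam, len(peaks))
        results[label] = {"acf": pooled, "sd": sd, "lambda_cm1": lam,
                          "peaks": peaks}
    _write_manifest(outdir, cfg, "md-sd")
    return results


def run_vg_sd(config: dict, outdir) -> dict:
    """Normal-mode table -> Lorentzian-broadened VG spectral densities."""
    cfg = _merge_defaults(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    block = cfg.get("vg_sd")
    if not block or "mode_table" not in block:
        raise PipelineError("config", "vg_sd block with mode_table required")
    try:
        modes = read_mode_table(block["mode_table"])
    except (OSError, ValueError) as err:
        raise PipelineError("ingest", str(err)) from err
    if modes.n_modes == 0:
        raise PipelineError("ingest", "empty mode list")
    hwhms = block.get("hwhm_cm1", [15.0, 35.0])
    if np.isscalar(hwhms):
        hwhms = [hwhms]
    grid = _freq_grid(cfg["sd"])
    results = {}
    for hwhm in hwhms:
        try:
            sd = vg_sd(modes, float(hwhm), freq_grid=grid)
        except ValueError as err:
            raise PipelineError("vg-sd", str(err)) from err
        lam = reorganization_energy(sd)
        tag = f"hwhm{hwhm:g}"
        write_spectral_density(sd, outdir / f"sd_vg_{tag}.dat")
        log.info("vg-sd[%s]: lambda = %.2f cm^-1 (modes total %.2f)",
                 tag, lam, modes.total_lambda)
        results[tag] = {"sd": sd, "lambda_cm1": lam}
    _write_manifest(outdir, cfg, "vg-sd")
    return results


def run_geometry(config: dict, outdir) -> dict:
    """Two geometry ensembles -> deviation tables, histograms, RDFs."""
    cfg = _merge_defaults(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    block = cfg.get("geometry")
    if not block:
        raise PipelineError("config", "geometry block missing")
    for key in ("test_trajectory", "reference_trajectory", "coordinates"):
        if key not in block:
            raise PipelineError("config", f"geometry block lacks {key!r}")
    try:
        test = read_geometry_trajectory(block["test_trajectory"])
        ref = read_geometry_trajectory(block["reference_trajectory"])
        defs = read_internal_coordinates(block["coordinates"])
    except (OSError, ValueError) as err:
        raise PipelineError("ingest", str(err)) from err
    log.info("geometry: %d test frames, %d reference frames",
             test.n_frames, ref.n_frames)
    try:
        stats_test = ensemble_stats(internal_coordinates(test, defs))
        stats_ref = ensemble_stats(internal_coordinates(ref, defs))
        deviation = ensemble_deviation(stats_test, stats_ref)
    except ValueError as err:
        raise PipelineError("geometry-stats", str(err)) from err
    deviation = deviation.sort_values(
        ["kind", "abs_deviation"], ascending=[True, False]
    ).reset_index(drop=True)
    stats_test.table.to_csv(outdir / "stats_test.csv", index=False,
                            float_format="%.8f")
    stats_ref.table.to_csv(outdir / "stats_reference.csv", index=False,
                           float_format="%.8f")
    deviation.to_csv(outdir / "deviation.csv", index=False,
                     float_format="%.8f")
    results = {"deviation": deviation, "stats_test": stats_test,
               "stats_reference": stats_ref}

    bins = int(block.get("dihedral_bins", 36))
    hists = {}
    for name, traj in (("test", test), ("reference", ref)):
        for d, label in zip(defs.dihedrals, defs.dihedral_labels):
            edges, mass = dihedral_distribution(traj, d, bins=bins)
            mids = 0.5 * (edges[:-1] + edges[1:])
            np.savetxt(outdir / f"dihedral_{label}_{name}.dat",
                       np.column_stack([mids, mass]),
                       header="angle_deg mass", fmt="%.8g")
            hists[(label, name)] = (edges, mass)
    results["dihedral_histograms"] = hists

    rdf_block = block.get("rdf")
    if rdf_block:
        try:
            for name, traj in (("test", test), ("reference", ref)):
                r, g = rdf(
                    traj,
                    centers=rdf_block["centers"],
                    targets=rdf_block["targets"],
                    r_max=float(rdf_block["r_max"]),
                    n_bins=int(rdf_block.get("n_bins", 100)),
                    pbc=bool(rdf_block.get("pbc", traj.box is not None)),
                )
                np.savetxt(outdir / f"rdf_{name}.dat",
                           np.column_stack([r, g]),
                           header="r_A g", fmt="%.8g")
                results[f"rdf_{name}"] = (r, g)
        except ValueError as err:
            raise PipelineError("rdf", str(err)) from err
    _write_manifest(outdir, cfg, "geometry")
    return results


def run_synth(config: dict, outdir) -> list:
    """Generate gap-table fixtures from a BathSpec block, in gap_io's dialect."""
    cfg = _merge_defaults(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    block = cfg.get("synth")
    if not block or "peaks" not in block:
        raise PipelineError("config", "synth block with peaks required")
    spec = BathSpec(
        peaks=[tuple(p) for p in block["peaks"]],
        temperature=float(block.get("temperature_K", cfg["temperature_K"])),
        dt=float(block.get("dt_fs", 5.0)),
        n_frames=int(block.get("n_frames", 4000)),
        n_replicas=int(block.get("n_replicas", 5)),
        seed=int(block.get("seed", cfg["seed"])),
    )
    replicas = generate_replicas(spec)
    paths = []
    for r, traj in enumerate(replicas):
        path = outdir / f"gap_replica{r}.dat"
        write_gap_table(traj, path)
        paths.append(path)
    log.info("synth: wrote %d replicas of %d frames", len(paths),
             spec.n_frames)
    _write_manifest(outdir, cfg, "synth")
    return paths
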