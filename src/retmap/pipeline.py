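"""End-to-end pipeline: simulate -> analyze -> project -> delineate -> evaluate.

Each stage reads its inputs from and writes its artifacts into one
output directory under fixed filenames, so stages can run individually
(CLI subcommands) or together (:func:`run_pipeline`).  A manifest
records every artifact with its stage and SHA-256 checksum; identical
configuration and seeds reproduce identical checksums.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import fieldsign, io, phase, surface, synth
from .config import PipelineConfig
from .types import PhaseSNRMap, RunTimeSeries, VolumeGrid

__all__ = ["run_pipeline", "STAGES", "stage_simulate", "stage_analyze",
           "stage_project", "stage_delineate", "stage_evaluate"]

_COORDS = ("eccentricity", "polar")
_DIRS = ("forward", "backward")


@dataclass
class _Artifacts:
    files: list[tuple[str, str]]  # (stage, filename)

    def add(self, stage: str, *names: str) -> None:
        self.files.extend((stage, n) for n in names)


def _run_name(coord: str, direction: str) -> str:
    return f"run_{coord}_{direction}.nii"


def stage_simulate(cfg: PipelineConfig, out: Path, art: _Artifacts) -> None:
    stim = cfg.stimulus()
    layout = cfg.layout()
    mesh = synth.build_flat_patch(
        cfg.patch_width_mm, cfg.height_mm, cfg.spacing_mm, cfg.hemisphere
    )
    vf, truth = synth.synthesize_ground_truth(mesh, layout, stim)
    runs = synth.simulate_runs(
        vf, stim, cfg.amplitude, cfg.noise_sd, cfg.drift_per_run, cfg.seed
    )
    clusters = synth.make_activation_clusters(
        mesh, truth, cfg.n_clusters, cfg.fraction_in_v4, cfg.cluster_radius_mm,
        seed=cfg.seed + 1,
    )

    io.save_mesh_gifti(mesh, out / "mesh.surf.gii")
    io.save_mesh_text(mesh, out / "mesh.txt")
    io.save_vertex_arrays(
        {
            "eccentricity": vf.eccentricity,
            "polar_angle": vf.polar_angle,
            "valid": vf.valid.astype(float),
        },
        out / "truth_field.func.gii",
    )
    io.save_labeling(truth, out / "truth_labels.func.gii")
    io.write_label_legend(out / "labels_legend.tsv")
    for (coord, direction), run in runs.items():
        grid = synth.rasterize_to_volume(mesh, run.series, cfg.voxel_size_mm)
        io.save_volume(grid, out / _run_name(coord, direction))
    pd.DataFrame(
        {"vertex": clusters.member_ids}
    ).to_csv(out / "activation_vertices.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"cluster_size": clusters.cluster_sizes}
    ).to_csv(out / "activation_cluster_sizes.tsv", sep="\t", index=False)
    art.add(
        "simulate",
        "mesh.surf.gii", "mesh.txt", "truth_field.func.gii",
        "truth_labels.func.gii", "labels_legend.tsv",
        *[_run_name(c, d) for c in _COORDS for d in _DIRS],
        "activation_vertices.tsv", "activation_cluster_sizes.tsv",
    )


def _load_run(path: Path, coord: str, direction: str, cfg: PipelineConfig
              ) -> tuple[RunTimeSeries, VolumeGrid]:
    grid = io.load_volume(path)
    series = grid.values.reshape(-1, grid.values.shape[-1])
    locations = np.flatnonzero(grid.valid.reshape(-1))
    run = RunTimeSeries(
        series=np.nan_to_num(series[locations]),
        coordinate=coord,  # type: ignore[arg-type]
        direction=direction,  # type: ignore[arg-type]
        params=cfg.stimulus(),
        locations=locations,
    )
    return run, grid


def _to_volume_map(m, grid: VolumeGrid, locations: np.ndarray,
                   coord: str) -> PhaseSNRMap:
    """Scatter per-location phase/snr back onto the full voxel grid."""
    nvox = int(np.prod(grid.dims))
    phase_v = np.full(nvox, np.nan)
    amp_v = np.zeros(nvox)
    snr_v = np.zeros(nvox)
    def_v = np.zeros(nvox, dtype=bool)
    phase_v[locations] = m.phase
    amp_v[locations] = m.amplitude
    snr_v[locations] = m.snr
    def_v[locations] = m.defined
    return PhaseSNRMap(
        phase=phase_v, amplitude=amp_v, snr=snr_v,
        coordinate=coord,  # type: ignore[arg-type]
        space="volume", defined=def_v,
        grid=VolumeGrid(grid.dims, grid.voxel_size_mm, grid.affine,
                        np.zeros(grid.dims), def_v.reshape(grid.dims)),
    )


def stage_analyze(cfg: PipelineConfig, out: Path, art: _Artifacts) -> None:
    stim = cfg.stimulus()
    for coord in _COORDS:
        fwd, grid = _load_run(out / _run_name(coord, "forward"), coord, "forward", cfg)
        bwd, _ = _load_run(out / _run_name(coord, "backward"), coord, "backward", cfg)
        fwd = phase.detrend_series(fwd, cfg.detrend_cutoff_cycles)
        bwd = phase.detrend_series(bwd, cfg.detrend_cutoff_cycles)
        if cfg.method == "phase-combine":
            mf = phase.dft_phase_snr(fwd, cutoff_cycles_per_run=cfg.detrend_cutoff_cycles)
            mb = phase.dft_phase_snr(bwd, cutoff_cycles_per_run=cfg.detrend_cutoff_cycles)
            combined, delay = phase.combine_opposite_directions(mf, mb, stim.period_s)
            stim_phase, snr = combined.phase, combined.snr
            amp = combined.amplitude
            delay_v = np.full(int(np.prod(grid.dims)), np.nan)
            delay_v[fwd.locations] = delay
            io.save_volume(
                VolumeGrid(grid.dims, grid.voxel_size_mm, grid.affine,
                           delay_v.reshape(grid.dims),
                           np.isfinite(delay_v).reshape(grid.dims)),
                out / f"delay_{coord}.nii",
            )
            art.add("analyze", f"delay_{coord}.nii")
        else:
            comb, offset = phase.reverse_average_combine(fwd, bwd)
            mc = phase.dft_phase_snr(comb, cutoff_cycles_per_run=cfg.detrend_cutoff_cycles)
            if cfg.method == "correlation":
                fit = phase.correlation_phase_fit(comb)
                raw = np.where(fit.defined, fit.phase, np.nan)
                stim_phase = np.where(
                    fit.defined,
                    phase.wrap_phase(-raw - offset),
                    np.nan,
                )
            else:
                stim_phase = phase.stimulus_phase_from_reverse_average(mc, offset)
                stim_phase = np.where(mc.defined, stim_phase, np.nan)
            snr, amp = mc.snr, mc.amplitude

        from types import SimpleNamespace

        m = SimpleNamespace(
            phase=stim_phase, amplitude=amp, snr=snr,
            defined=np.isfinite(stim_phase),
        )
        vol_map = _to_volume_map(m, grid, fwd.locations, coord)
        io.save_volume(
            VolumeGrid(grid.dims, grid.voxel_size_mm, grid.affine,
                       vol_map.phase.reshape(grid.dims),
                       vol_map.defined.reshape(grid.dims)),
            out / f"phase_{coord}.nii",
        )
        io.save_volume(
            VolumeGrid(grid.dims, grid.voxel_size_mm, grid.affine,
                       np.where(np.isinf(vol_map.snr), np.finfo(np.float32).max,
                                vol_map.snr).reshape(grid.dims),
                       vol_map.defined.reshape(grid.dims)),
            out / f"snr_{coord}.nii",
        )
        art.add("analyze", f"phase_{coord}.nii", f"snr_{coord}.nii")


def _load_volume_map(out: Path, coord: str) -> PhaseSNRMap:
    pgrid = io.load_volume(out / f"phase_{coord}.nii")
    sgrid = io.load_volume(out / f"snr_{coord}.nii")
    phase_v = pgrid.values.reshape(-1)
    snr_v = sgrid.values.reshape(-1)
    defined = np.isfinite(phase_v)
    return PhaseSNRMap(
        phase=phase_v, amplitude=np.where(defined, 1.0, 0.0), snr=snr_v,
        coordinate=coord,  # type: ignore[arg-type]
        space="volume", defined=defined, grid=pgrid,
    )


def stage_project(cfg: PipelineConfig, out: Path, art: _Artifacts) -> None:
    mesh = io.load_mesh_gifti(out / "mesh.surf.gii")
    smoother = surface.SurfaceSmoother(mesh, cfg.kernel_mm)
    for coord in _COORDS:
        vol_map = _load_volume_map(out, coord)
        surf_map = surface.assign_volume_phases_to_mesh(
            vol_map, mesh, cfg.max_dist_mm, cfg.snr_assign
        )
        smooth = smoother.smooth_map(surf_map)
        io.save_vertex_arrays(
            {
                "phase": smooth.phase,
                "snr": np.where(np.isinf(smooth.snr), np.finfo(np.float64).max,
                                smooth.snr),
                "defined": smooth.defined.astype(float),
            },
            out / f"surf_phase_{coord}.func.gii",
        )
        art.add("project", f"surf_phase_{coord}.func.gii")


def _load_surface_map(out: Path, coord: str) -> PhaseSNRMap:
    arrs = io.load_vertex_arrays(out / f"surf_phase_{coord}.func.gii")
    defined = arrs["defined"] > 0.5
    return PhaseSNRMap(
        phase=np.where(defined, arrs["phase"], np.nan),
        amplitude=defined.astype(float),
        snr=arrs["snr"],
        coordinate=coord,  # type: ignore[arg-type]
        space="surface",
        defined=defined,
    )


def stage_delineate(cfg: PipelineConfig, out: Path, art: _Artifacts) -> None:
    mesh = io.load_mesh_gifti(out / "mesh.surf.gii")
    ecc_map = _load_surface_map(out, "eccentricity")
    pol_map = _load_surface_map(out, "polar")
    vf = surface.decode_visual_coordinates(ecc_map, pol_map, cfg.stimulus())
    fsm = fieldsign.compute_vfr(mesh, vf)
    auto = fieldsign.label_areas(
        mesh, fsm, ecc_map, pol_map, vf,
        snr_min=cfg.snr_delineate, ecc_bounds=cfg.ecc_bounds,
        vfr_tol=cfg.vfr_tol,
    )
    io.save_labeling(auto, out / "auto_labels.func.gii")
    truth = io.load_labeling(out / "truth_labels.func.gii", "ground_truth")
    manual = fieldsign.perturb_labeling(
        truth, mesh, cfg.boundary_shift_mm, seed=cfg.seed + 2
    )
    io.save_labeling(manual, out / "manual_labels.func.gii")
    # back-project the automatic labeling for volume export
    grid = io.load_volume(out / "phase_eccentricity.nii")
    lab_vol = surface.project_labels_to_volume(auto, mesh, grid, cfg.max_dist_mm)
    io.save_volume(lab_vol, out / "auto_labels_vol.nii", dtype=np.int32)
    art.add("delineate", "auto_labels.func.gii", "manual_labels.func.gii",
            "auto_labels_vol.nii")


def stage_evaluate(cfg: PipelineConfig, out: Path, art: _Artifacts) -> None:
    truth = io.load_labeling(out / "truth_labels.func.gii", "ground_truth")
    auto = io.load_labeling(out / "auto_labels.func.gii", "automatic")
    manual = io.load_labeling(out / "manual_labels.func.gii", "perturbed")
    report = ev.compare_labelings([(auto, truth), (auto, manual), (manual, truth)])
    long, summary = ev.report_to_frames(report)
    long.insert(0, "pair", long["case"].map(
        {0: "auto_vs_truth", 1: "auto_vs_manual", 2: "manual_vs_truth"}
    ))
    long.to_csv(out / "overlap_long.tsv", sep="\t", index=False)
    summary.to_csv(out / "overlap_summary.tsv", sep="\t", index=False)

    ids = pd.read_csv(out / "activation_vertices.tsv", sep="\t")["vertex"].to_numpy()
    from .types import ActivationMask

    mask = ActivationMask(member_ids=ids, space="surface")
    rows = []
    for name, lab in (("automatic", auto), ("ground_truth", truth),
                      ("perturbed", manual)):
        rows.append({
            "labeling": name,
            "v4_overlap_pct": ev.v4_overlap_fraction(mask, lab),
        })
    pd.DataFrame(rows).to_csv(out / "v4_overlap.tsv", sep="\t", index=False)
    art.add("evaluate", "overlap_long.tsv", "overlap_summary.tsv", "v4_overlap.tsv")


STAGES = {
    "simulate": stage_simulate,
    "analyze": stage_analyze,
    "project": stage_project,
    "delineate": stage_delineate,
    "evaluate": stage_evaluate,
}


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path,
                 stages: list[str] | None = None) -> dict:
    """Run the requested stages (default: all) and write the manifest.

    Returns the manifest dict.  On a stage failure the partial manifest
    is written before the exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    art = _Artifacts(files=[])
    manifest: dict = {"config": cfg.to_dict(), "artifacts": []}
    try:
        for name in stages or list(STAGES):
            STAGES[name](cfg, out, art)
    finally:
        manifest["artifacts"] = [
            {"stage": stage, "file": fname, "sha256": io.sha256_file(out / fname)}
            for stage, fname in art.files
        ]
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
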