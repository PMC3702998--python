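"""End-to-end orchestration: schedule -> synthesis -> GLM -> FIR -> DCM.

Each stage writes its artifacts under the configured output directory and
returns plain objects, so stages can also be re-run individually from the
CLI against files on disk.  All randomness derives from the single
configured seed; reports carry provenance (config hash, seeds, version)
and no timestamps, so identical configurations produce byte-identical
reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import __version__, dcm, fir, glm, paradigm, synthetic
from .config import PipelineConfig, REGION_NAMES, validate_config

log = logging.getLogger(__name__)

STAGES = ("schedule", "synth", "glm", "fir", "dcm", "report")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; earlier outputs are preserved."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def derive_seeds(master: int, n: int = 6) -> list[int]:
    """Independent per-stage seeds derived from the master seed."""
    ss = np.random.SeedSequence(master)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


@dataclass
class RunReport:
    """Collected results of one pipeline run, serialisable to JSON."""

    behaviour: dict
    glm_results: dict
    fir_results: dict
    dcm_results: dict
    connectivity: list[dict]
    provenance: dict
    artifacts: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "behaviour": self.behaviour,
            "glm": self.glm_results,
            "fir": self.fir_results,
            "dcm": self.dcm_results,
            "connectivity": self.connectivity,
            "provenance": self.provenance,
            "artifacts": self.artifacts,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_json_default)
        )
        return path


# --------------------------------------------------------------------------
# individual stages
# --------------------------------------------------------------------------


def stage_schedule(cfg: PipelineConfig, out: Path, seeds: list[int]) -> paradigm.TrialSchedule:
    p = cfg.paradigm
    sch = paradigm.generate_schedule(
        n_runs=p.n_runs,
        composition=paradigm.default_composition(p.n_bilateral, p.n_unilateral),
        iti_range=p.iti_range,
        seed=seeds[0],
        tr=p.tr,
        run_length=p.run_length,
    )
    sch = paradigm.simulate_responses(
        sch,
        p_extinguish=p.p_extinguish,
        p_miss_left=p.p_miss_left,
        p_miss_right=p.p_miss_right,
        mode=p.response_mode,
        seed=seeds[1],
    )
    sch = paradigm.classify_trials(sch)
    sch.to_tsv(out / "events")
    return sch


def stage_synth(
    cfg: PipelineConfig, sch: paradigm.TrialSchedule, out: Path, seeds: list[int]
) -> synthetic.SyntheticDataset:
    ds = synthetic.generate_dataset(
        sch,
        cfg.truth,
        seed=seeds[2],
        fine_dt=cfg.dcm.fine_dt,
        prestim_len=cfg.dcm.prestim_len,
    )
    ds.roi_to_tsv(out / "roi_timeseries.tsv")
    ds.truth_to_yaml(out / "ground_truth.yaml")
    if cfg.volume.enabled:
        ds = synthetic.embed_volume(
            ds,
            grid_shape=cfg.volume.grid_shape,
            blob_sigma=cfg.volume.blob_sigma,
            seed=seeds[4],
        )
        ds.volume_to_nifti(out / "bold.nii.gz")
    return ds


def stage_glm(
    cfg: PipelineConfig,
    sch: paradigm.TrialSchedule,
    ds: synthetic.SyntheticDataset,
    out: Path,
    seeds: list[int],
) -> dict:
    motion = glm.make_motion_confounds(
        sch.n_scans, cfg.glm.n_motion_confounds, seed=seeds[3]
    )
    design = glm.build_design(
        sch,
        confounds=motion,
        hp_cutoff=cfg.glm.hp_cutoff,
        prestim_offset=cfg.glm.prestim_offset,
        prestim_duration=cfg.glm.prestim_duration,
    )
    design.to_tsv(out / "design.tsv")
    weights = design.contrast_vector("BS_baseline - BU_baseline")
    results: dict[str, Any] = {"contrast": "BS_baseline - BU_baseline", "roi": {}}

    fit_roi = glm.fit_glm(ds.roi_series, design)
    stat_roi = glm.contrast_t(fit_roi, weights, cfg.glm.threshold_rule)
    for r, name in enumerate(REGION_NAMES):
        results["roi"][name] = {
            "t": float(np.atleast_1d(stat_roi.t_values)[r]),
            "p": float(np.atleast_1d(stat_roi.p_values)[r]),
            "suprathreshold": bool(np.atleast_1d(stat_roi.suprathreshold_mask)[r]),
        }
    results["dof"] = stat_roi.dof
    results["threshold_rule"] = stat_roi.threshold_rule

    if ds.volume is not None:
        vol2d = ds.volume.reshape(-1, ds.n_scans).T
        fit_vol = glm.fit_glm(vol2d, design)
        stat = glm.contrast_t(fit_vol, weights, cfg.glm.threshold_rule)
        prestim_mask = stat.suprathreshold_mask.reshape(ds.volume.shape[:3])
        # visually responsive voxels (evoked responses of any kind): the
        # within-dataset analogue of a stimulus localiser
        evoked = design.contrast_vector(
            " + ".join(n for n in design.column_names if n.endswith("_evoked"))
        )
        stat_loc = glm.contrast_t(fit_vol, evoked, cfg.glm.threshold_rule)
        loc_mask = stat_loc.suprathreshold_mask.reshape(ds.volume.shape[:3])
        results["volume"] = {
            "n_prestim_voxels": int(prestim_mask.sum()),
            "overlap_with_localiser": glm.overlap_percentage(prestim_mask, loc_mask),
            "overlap_with_truth_blobs": glm.overlap_percentage(
                prestim_mask, ds.roi_masks.any(axis=0)
            ),
        }
        import nibabel as nib

        tmap = stat.t_values.reshape(ds.volume.shape[:3]).astype(np.float32)
        nib.save(nib.Nifti1Image(tmap, np.eye(4)), str(out / "prestim_tmap.nii.gz"))
        nib.save(
            nib.Nifti1Image(prestim_mask.astype(np.uint8), np.eye(4)),
            str(out / "prestim_mask.nii.gz"),
        )
        (out / "prestim_tmap.json").write_text(
            json.dumps(
                {
                    "contrast": results["contrast"],
                    "threshold_rule": stat.threshold_rule,
                    "threshold_p": stat.threshold_p,
                    "dof": stat.dof,
                },
                indent=2,
                default=_json_default,
            )
        )
    (out / "glm_results.json").write_text(json.dumps(results, indent=2, default=_json_default))
    return results


def stage_fir(
    cfg: PipelineConfig,
    sch: paradigm.TrialSchedule,
    ds: synthetic.SyntheticDataset,
    out: Path,
    seeds: list[int],
) -> dict:
    motion = glm.make_motion_confounds(
        sch.n_scans, cfg.glm.n_motion_confounds, seed=seeds[3]
    )
    results: dict[str, Any] = {}
    estimates = {}
    for r, name in enumerate(REGION_NAMES):
        est = fir.fit_fir(
            ds.roi_series[:, r],
            sch,
            bin_width=cfg.fir.bin_width,
            window=cfg.fir.window,
            confounds=motion,
            hp_cutoff=cfg.glm.hp_cutoff,
        )
        est.to_tsv(out / f"fir_{name}.tsv")
        d = fir.difference_curve(est)
        d.to_csv(out / f"fir_diff_{name}.tsv", sep="\t", index=False)
        results[name] = {
            "first_divergence_s": fir.first_divergence_bin(d),
            "bins": d.to_dict(orient="records"),
        }
        estimates[name] = est
    fir.plot_curves(estimates, out / "fir_curves.png")
    return results


def stage_dcm(
    cfg: PipelineConfig,
    sch: paradigm.TrialSchedule,
    ds: synthetic.SyntheticDataset,
    out: Path,
) -> tuple[dict, list[dict]]:
    X0, _ = glm.nuisance_matrix(
        sch.n_scans, sch.run_length, sch.tr, cfg.glm.hp_cutoff
    )
    result = dcm.two_step_search(
        ds.roi_series,
        ds.inputs,
        tr=sch.tr,
        fine_dt=cfg.dcm.fine_dt,
        confounds=X0,
        max_iter=cfg.dcm.max_iter,
        f_tol=cfg.dcm.f_tol,
        converge_streak=cfg.dcm.converge_streak,
    )
    result.to_json(out / "dcm_comparison.json")
    win_fit = result.fits[result.winning_model_index]
    report = dcm.connectivity_report(win_fit)
    report.to_csv(out / "connectivity_report.tsv", sep="\t", index=False)
    (out / "dcm_winning_fit.json").write_text(json.dumps(win_fit.to_dict(), indent=2))
    conn = json.loads(report.to_json(orient="records"))
    return result.to_dict(), conn


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute every stage in order, writing artifacts along the way.

    Raises :class:`StageError` naming the failing stage; outputs of earlier
    stages remain on disk.
    """
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    seeds = derive_seeds(cfg.seed)

    timings: dict[str, float] = {}

    def run(stage: str, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(stage, exc) from exc
        timings[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %-8s done in %.2f s", stage, timings[stage])
        return result

    sch = run("schedule", stage_schedule, cfg, out, seeds)
    behaviour = paradigm.summarize_behaviour(sch).as_dict()
    ds = run("synth", stage_synth, cfg, sch, out, seeds)
    glm_results = run("glm", stage_glm, cfg, sch, ds, out, seeds)
    fir_results = run("fir", stage_fir, cfg, sch, ds, out, seeds)
    dcm_results, connectivity = run("dcm", stage_dcm, cfg, sch, ds, out)

    report = RunReport(
        behaviour=behaviour,
        glm_results=glm_results,
        fir_results=fir_results,
        dcm_results=dcm_results,
        connectivity=connectivity,
        provenance={
            "config_hash": cfg.hash(),
            "seed": cfg.seed,
            "stage_seeds": seeds,
            "version": __version__,
        },
        artifacts={
            "events": "events/",
            "roi_timeseries": "roi_timeseries.tsv",
            "design": "design.tsv",
            "dcm_comparison": "dcm_comparison.json",
            "connectivity_report": "connectivity_report.tsv",
        },
    )
    report.to_json(out / "report.json")
    (out / "timings.json").write_text(json.dumps(timings, indent=2))
    return report
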