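"""Ground-truth two-region BOLD generation.

Seen/unseen structure is *caused* here the way the analysis assumes: a
prestimulus input, active only before seen bilateral trials, additively
modulates the intrinsic (self) and extrinsic (between-region) coupling of
a two-region bilinear neural model; BOLD follows via balloon-Windkessel
hemodynamics, plus white observation noise, a slow drift and per-run
offsets.  Optionally the two ROI series are embedded as Gaussian blobs in
a small 4-D volume for the voxelwise GLM stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import forward
from .config import FINE_DT, GroundTruth, REGION_NAMES
from .paradigm import TrialSchedule

#: DCM driving/modulatory input indices
PRESTIM_ALL, STIM_ONSET, PRESTIM_SEEN = 0, 1, 2


def build_dcm_inputs(
    schedule: TrialSchedule,
    prestim_len: float = 7.0,
    fine_dt: float = FINE_DT,
) -> np.ndarray:
    """Construct the three DCM inputs on the concatenated fine time grid.

    1. unit boxcar over ``[onset - prestim_len, onset)`` for every bilateral
       trial; 2. unit impulse (one fine bin) at every bilateral onset;
    3. the same prestimulus boxcar restricted to trials labelled BS.
    Boxcars are clipped at run starts.  Returns ``(n_fine, 3)``.
    """
    if prestim_len <= 0:
        raise ValueError("prestim_len must be > 0")
    n_sub = round(schedule.tr / fine_dt)
    if abs(n_sub * fine_dt - schedule.tr) > 1e-9:
        raise ValueError("fine_dt must divide TR")
    bil = schedule.events[schedule.events["trial_type"] == "bilateral"]
    if bil["label"].isna().any():
        raise ValueError("bilateral trials are unlabelled; classify_trials first")

    n_fine = schedule.n_scans * n_sub
    fine_per_run = schedule.run_length * n_sub
    U = np.zeros((n_fine, 3))
    for row in bil.itertuples():
        run0 = row.run * fine_per_run
        onset_idx = run0 + int(round(row.onset / fine_dt))
        start_idx = max(run0, onset_idx - int(round(prestim_len / fine_dt)))
        U[start_idx:onset_idx, PRESTIM_ALL] = 1.0
        if onset_idx < n_fine:
            U[onset_idx, STIM_ONSET] = 1.0
        if row.label == "BS":
            U[start_idx:onset_idx, PRESTIM_SEEN] = 1.0
    return U


@dataclass
class SyntheticDataset:
    """ROI BOLD series with full provenance of how they were generated."""

    roi_series: np.ndarray  # (n_scans, 2), % signal, observation noise added
    clean_bold: np.ndarray  # (n_scans, 2), noiseless forward-model output
    inputs: np.ndarray  # (n_fine, 3) DCM inputs used to drive the simulation
    fine_dt: float
    schedule: TrialSchedule
    truth: GroundTruth
    volume: Optional[np.ndarray] = None  # (nx, ny, nz, n_scans)
    roi_masks: Optional[np.ndarray] = None  # (2, nx, ny, nz) boolean
    blob_centres: Optional[np.ndarray] = None  # (2, 3) voxel indices
    seed: int = 0

    @property
    def n_scans(self) -> int:
        return self.roi_series.shape[0]

    # -- I/O ---------------------------------------------------------------
    def roi_to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(
            {
                "scan_index": np.arange(self.n_scans),
                f"region_{REGION_NAMES[0]}": self.roi_series[:, 0],
                f"region_{REGION_NAMES[1]}": self.roi_series[:, 1],
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
        return path

    def truth_to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        t = self.truth
        doc = {
            "A": t.A.tolist(),
            "B": [b.tolist() for b in t.B],
            "C": t.C.tolist(),
            "hemo": dict(t.hemo.__dict__),
            "sigma_noise": t.sigma_noise,
            "drift_amp": t.drift_amp,
            "drift_period": t.drift_period,
            "run_offset_amp": t.run_offset_amp,
            "seed": self.seed,
            "fine_dt": self.fine_dt,
        }
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path

    def volume_to_nifti(self, path: str | Path, voxel_mm: float = 3.0) -> Path:
        if self.volume is None:
            raise ValueError("dataset holds no volume; run embed_volume first")
        img = nib.Nifti1Image(self.volume.astype(np.float32), affine=np.eye(4) * voxel_mm)
        zooms = (voxel_mm,) * 3 + (self.schedule.tr,)
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
        path = Path(path)
        nib.save(img, str(path))
        return path


def read_roi_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c.startswith("region_")]
    return df[cols].to_numpy()


def simulate_neural(
    truth: GroundTruth, inputs: np.ndarray, fine_dt: float = FINE_DT
) -> np.ndarray:
    """Neuronal states of the ground-truth bilinear model (fine grid)."""
    return forward.simulate_neural_states(truth.A, truth.B, truth.C, inputs, fine_dt)


def simulate_bold(
    neural: np.ndarray, hemo, tr: float, fine_dt: float = FINE_DT
) -> np.ndarray:
    """Balloon-Windkessel BOLD per region, decimated to scan times."""
    fine = forward.simulate_bold_fine(neural, hemo, fine_dt)
    return forward.decimate(fine, round(tr / fine_dt))


def generate_dataset(
    schedule: TrialSchedule,
    truth: GroundTruth | None = None,
    seed: int = 0,
    fine_dt: float = FINE_DT,
    prestim_len: float = 7.0,
) -> SyntheticDataset:
    """Simulate the full ROI dataset for a labelled schedule.

    Runs are simulated independently (state reset at run starts, which the
    clipped input boxcars guarantee given the pre-first-trial lead-in) and
    concatenated; observation noise, a slow sinusoidal drift (period longer
    than the GLM high-pass cut-off) and per-run constant offsets are added
    on top of the noiseless series.  Deterministic given ``seed``.
    """
    truth = truth or GroundTruth()
    bad = truth.validate()
    if bad:
        raise ValueError("; ".join(bad))
    U = build_dcm_inputs(schedule, prestim_len=prestim_len, fine_dt=fine_dt)
    Z = simulate_neural(truth, U, fine_dt)
    clean = simulate_bold(Z, truth.hemo, schedule.tr, fine_dt)

    rng = np.random.default_rng(seed)
    n_scans = clean.shape[0]
    t = np.arange(n_scans) * schedule.tr
    noisy = clean + rng.normal(0.0, truth.sigma_noise, size=clean.shape)
    for r in range(2):
        phase = rng.uniform(0, 2 * np.pi)
        noisy[:, r] += truth.drift_amp * np.sin(2 * np.pi * t / truth.drift_period + phase)
    offsets = rng.normal(0.0, truth.run_offset_amp, size=(schedule.n_runs, 2))
    run_idx = np.repeat(np.arange(schedule.n_runs), schedule.run_length)
    noisy += offsets[run_idx]

    return SyntheticDataset(
        roi_series=noisy,
        clean_bold=clean,
        inputs=U,
        fine_dt=fine_dt,
        schedule=schedule,
        truth=truth,
        seed=seed,
    )


def embed_volume(
    dataset: SyntheticDataset,
    grid_shape: tuple[int, int, int] = (14, 10, 8),
    blob_sigma: float = 1.0,
    seed: int = 0,
    noise_sd: float | None = None,
) -> SyntheticDataset:
    """Embed the two ROI series as Gaussian blobs in a 4-D volume.

    Region 0 (left hemisphere) is centred in the low-x half of the grid,
    region 1 in the high-x half; every voxel additionally receives white
    noise.  Returns a copy of the dataset carrying the volume, the
    ground-truth blob masks and the blob centres.
    """
    nx, ny, nz = grid_shape
    centres = np.array(
        [[nx // 4, ny // 2, nz // 2], [(3 * nx) // 4, ny // 2, nz // 2]], dtype=int
    )
    support = max(1.0, 3.0 * blob_sigma)
    if np.linalg.norm(centres[0] - centres[1]) < 2 * support:
        raise ValueError("blobs overlap: enlarge the grid or shrink blob_sigma")
    for c in centres:
        if np.any(c - support < -0.5) or np.any(c + support > np.array(grid_shape) - 0.5):
            raise ValueError("blob support exceeds the grid")

    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    vol = np.zeros(grid_shape + (dataset.n_scans,), dtype=float)
    masks = np.zeros((2,) + grid_shape, dtype=bool)
    for r, c in enumerate(centres):
        d2 = (ix - c[0]) ** 2 + (iy - c[1]) ** 2 + (iz - c[2]) ** 2
        if blob_sigma > 0:
            kernel = np.exp(-0.5 * d2 / blob_sigma**2)
            masks[r] = d2 <= (2.0 * blob_sigma) ** 2
        else:  # delta limit: a single voxel carries the signal
            kernel = (d2 == 0).astype(float)
            masks[r] = d2 == 0
        vol += kernel[..., None] * dataset.roi_series[:, r]

    sd = dataset.truth.sigma_noise if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    vol += rng.normal(0.0, sd, size=vol.shape)

    out = SyntheticDataset(**{**dataset.__dict__})
    out.volume = vol
    out.roi_masks = masks
    out.blob_centres = centres
    return out
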