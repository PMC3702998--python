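"""Prestimulus-baseline GLM: design construction, OLS fitting, t-contrasts
and thresholded maps, and localiser-overlap arithmetic.

The design carries, per trial type present in the schedule, a *baseline*
regressor (6 s boxcar starting 7 s before onset, leaving a 1 s gap before
the stimulus) and an *evoked* regressor (stick at onset), both convolved
with the canonical double-gamma HRF and deliberately not orthogonalised:
any baseline effect then cannot be an artefact of evoked differences.
Nuisance columns are motion stand-ins, a per-run discrete-cosine high-pass
basis (128 s cut-off) and per-run intercepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import config as cfg
from .paradigm import TrialSchedule, round_half_away

CONDITIONS = ("UL", "UR", "BS", "BU")


def canonical_hrf(dt: float, length: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt``, peak-normalised to 1.

    Response gamma peaks at 6 s, undershoot gamma at 16 s, peak/undershoot
    ratio 6; the kernel spans 32 s and is zero at t = 0.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0.0, length, dt)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    return h / h.max()


@dataclass
class DesignMatrix:
    """Per-scan regressor values with ordered column labels."""

    values: np.ndarray
    column_names: list[str]
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ValueError("values/column_names shape mismatch")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path

    def contrast_vector(self, expr: str) -> np.ndarray:
        """Weights from an expression like ``"BS_baseline - BU_baseline"``."""
        w = np.zeros(len(self.column_names))
        sign = 1.0
        for tok in expr.replace("-", " - ").replace("+", " + ").split():
            if tok == "-":
                sign = -1.0
            elif tok == "+":
                sign = 1.0
            else:
                if tok not in self.column_names:
                    raise KeyError(f"no design column named {tok!r}")
                w[self.column_names.index(tok)] += sign
                sign = 1.0
        return w


def dct_highpass_basis(n_scans: int, tr: float, cutoff: float = cfg.HP_CUTOFF) -> np.ndarray:
    """Discrete-cosine drift basis: all non-constant cosines with period
    above ``cutoff`` seconds (the standard 128 s high-pass set)."""
    order = int(np.floor(2.0 * n_scans * tr / cutoff))
    n = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * n + 1) * k / (2.0 * n_scans))
        for k in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def make_motion_confounds(
    n_scans: int, n_columns: int = 6, seed: int = 0, smooth_scans: float = 10.0
) -> np.ndarray:
    """Seeded smooth-noise stand-ins for realignment parameters (z-scored)."""
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.normal(size=(n_scans, n_columns)), axis=0)
    k = int(3 * smooth_scans)
    kernel = np.exp(-0.5 * ((np.arange(-k, k + 1)) / smooth_scans) ** 2)
    kernel /= kernel.sum()
    sm = np.column_stack(
        [np.convolve(walk[:, j], kernel, mode="same") for j in range(n_columns)]
    )
    sm -= sm.mean(axis=0)
    sd = sm.std(axis=0)
    sd[sd == 0] = 1.0
    return sm / sd


def nuisance_matrix(
    n_scans: int,
    run_length: int,
    tr: float,
    hp_cutoff: float = cfg.HP_CUTOFF,
    motion: Optional[np.ndarray] = None,
    include_constants: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Motion + per-run DCT drift + per-run intercept columns."""
    n_runs = n_scans // run_length
    if n_runs * run_length != n_scans:
        raise ValueError("n_scans must be a whole number of runs")
    cols: list[np.ndarray] = []
    names: list[str] = []
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, float))
        if motion.shape[0] != n_scans:
            raise ValueError("motion confounds must have one row per scan")
        cols.extend(motion.T)
        names.extend(f"motion_{j + 1}" for j in range(motion.shape[1]))
    dct_run = dct_highpass_basis(run_length, tr, hp_cutoff)
    for r in range(n_runs):
        block = np.zeros((n_scans, dct_run.shape[1]))
        block[r * run_length : (r + 1) * run_length] = dct_run
        cols.extend(block.T)
        names.extend(f"run{r + 1}_dct{k + 1}" for k in range(dct_run.shape[1]))
    if include_constants:
        for r in range(n_runs):
            c = np.zeros(n_scans)
            c[r * run_length : (r + 1) * run_length] = 1.0
            cols.append(c)
            names.append(f"run{r + 1}_constant")
    X = np.column_stack(cols) if cols else np.empty((n_scans, 0))
    return X, names


def build_design(
    schedule: TrialSchedule,
    tr: float | None = None,
    confounds: Optional[np.ndarray] = None,
    hp_cutoff: float = cfg.HP_CUTOFF,
    prestim_offset: float = cfg.PRESTIM_GLM_OFFSET,
    prestim_duration: float = cfg.PRESTIM_GLM_DURATION,
    fine_dt: float = cfg.FINE_DT,
    conditions: Sequence[str] = CONDITIONS,
) -> DesignMatrix:
    """Build the extinction-paradigm design matrix.

    Per trial type present in the labelled schedule: an HRF-convolved
    baseline boxcar on ``[onset - prestim_offset, onset - prestim_offset +
    prestim_duration)`` and an HRF-convolved stick at onset.  Boxcars are
    half-open on the fine grid and sampled at scan onsets; the condition
    regressors are not orthogonalised against each other.
    """
    tr = tr or schedule.tr
    n_sub = round(tr / fine_dt)
    if abs(n_sub * fine_dt - tr) > 1e-9:
        raise ValueError("fine_dt must divide TR")
    ev = schedule.events
    run_dur = schedule.run_length * tr
    if len(ev) and ((ev["onset"] < 0) | (ev["onset"] + ev["duration"] > run_dur)).any():
        raise ValueError("events fall outside the scanned interval")

    hrf = canonical_hrf(fine_dt)
    n_fine_run = schedule.run_length * n_sub
    present = [c for c in conditions if len(ev) and (ev["label"] == c).any()]
    cols: list[np.ndarray] = []
    names: list[str] = []
    for lab in present:
        base = np.zeros(schedule.n_runs * n_fine_run)
        stick = np.zeros_like(base)
        for row in ev[ev["label"] == lab].itertuples():
            run0 = row.run * n_fine_run
            onset_idx = run0 + int(round(row.onset / fine_dt))
            b0 = run0 + int(round((row.onset - prestim_offset) / fine_dt))
            b1 = b0 + int(round(prestim_duration / fine_dt))
            base[max(run0, b0) : max(run0, b1)] = 1.0
            stick[onset_idx] = 1.0 / fine_dt  # unit-area impulse
        for sig, kind in ((base, "baseline"), (stick, "evoked")):
            conv = np.zeros_like(sig)
            for r in range(schedule.n_runs):  # convolution restarts per run
                seg = sig[r * n_fine_run : (r + 1) * n_fine_run]
                conv[r * n_fine_run : (r + 1) * n_fine_run] = (
                    np.convolve(seg, hrf)[:n_fine_run] * fine_dt
                )
            cols.append(conv[::n_sub])
            names.append(f"{lab}_{kind}")
    X_nuis, nuis_names = nuisance_matrix(
        schedule.n_scans, schedule.run_length, tr, hp_cutoff, motion=confounds
    )
    X = np.column_stack(cols + [X_nuis]) if cols else X_nuis
    return DesignMatrix(X, names + nuis_names, tr)


@dataclass
class GLMFit:
    """OLS estimates for one or many voxels against a common design."""

    betas: np.ndarray  # (n_columns,) or (n_columns, n_voxels)
    residual_variance: np.ndarray  # scalar array or (n_voxels,)
    dof: int
    design: DesignMatrix
    xtx_pinv: np.ndarray = field(repr=False, default=None)

    def contrast_estimate(self, weights: np.ndarray) -> np.ndarray:
        return np.asarray(weights) @ self.betas


def fit_glm(data: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares via pseudoinverse.

    ``data`` is (n_scans,) or (n_scans, n_voxels).  A rank-deficient design
    triggers a warning and yields the minimum-norm solution; dof is
    ``n_scans - rank(design)``.
    """
    X = design.values
    data = np.asarray(data, float)
    if data.shape[0] != X.shape[0]:
        raise ValueError("data rows must match design rows")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            "betas are the minimum-norm solution",
            stacklevel=2,
        )
    Xp = np.linalg.pinv(X)
    betas = Xp @ data
    resid = data - X @ betas
    dof = int(X.shape[0] - rank)
    rss = np.sum(resid**2, axis=0)
    # residuals at rounding level (exact fits) count as zero variance
    rss = np.where(rss <= X.shape[0] * 1e-20, 0.0, rss)
    sigma2 = rss / dof if dof > 0 else np.full_like(np.atleast_1d(rss), np.nan)
    return GLMFit(
        betas=betas,
        residual_variance=np.asarray(sigma2, float),
        dof=dof,
        design=design,
        xtx_pinv=np.linalg.pinv(X.T @ X),
    )


THRESHOLD_RULES = ("uncorrected_p001", "bonferroni_p05")


@dataclass
class StatMap:
    """Voxelwise t statistics with one-sided p-values and a threshold mask."""

    t_values: np.ndarray
    p_values: np.ndarray
    threshold_rule: str
    threshold_p: float
    suprathreshold_mask: np.ndarray
    dof: int
    zero_variance: np.ndarray  # voxels where t was forced to 0


def contrast_t(
    fit: GLMFit, weights: np.ndarray, threshold_rule: str = "uncorrected_p001"
) -> StatMap:
    """One-sided t map for a contrast of design columns.

    ``t = c'beta / sqrt(sigma^2 c'(X'X)^- c)``; thresholding is either
    p < 0.001 uncorrected or Bonferroni p < 0.05 over voxels (the standing
    replacement for random-field FWE here).  Voxels with zero residual
    variance get t = 0 and are flagged.
    """
    weights = np.asarray(weights, float)
    if weights.shape[0] != len(fit.design.column_names):
        raise ValueError("contrast length must equal the number of design columns")
    if threshold_rule not in THRESHOLD_RULES:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    est = np.atleast_1d(fit.contrast_estimate(weights))
    var_scale = float(weights @ fit.xtx_pinv @ weights)
    var = np.atleast_1d(fit.residual_variance) * var_scale
    zero = var <= 0
    t = np.zeros_like(est, dtype=float)
    np.divide(est, np.sqrt(np.where(zero, 1.0, var)), out=t, where=~zero)
    p = stats.t.sf(t, fit.dof)
    thr = 0.001 if threshold_rule == "uncorrected_p001" else 0.05 / t.size
    return StatMap(
        t_values=t,
        p_values=p,
        threshold_rule=threshold_rule,
        threshold_p=thr,
        suprathreshold_mask=p <= thr,
        dof=fit.dof,
        zero_variance=zero,
    )


def overlap_percentage(mask_a: np.ndarray, mask_b: np.ndarray) -> dict:
    """Share of ``mask_a`` voxels also in ``mask_b``: counts plus the
    rounded integer percentage (None when ``mask_a`` is empty)."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    n_a = int(a.sum())
    n_ab = int((a & b).sum())
    pct = None if n_a == 0 else round_half_away(100.0 * n_ab / n_a)
    return {"n_intersection": n_ab, "n_a": n_a, "percent": pct}
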