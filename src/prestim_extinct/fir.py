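"""Finite-impulse-response peristimulus time courses.

Estimates per-condition BOLD amplitudes in contiguous 2 s bins spanning
[-7, +9) s around stimulus onset with an FIR convolution design: one
column per condition and bin, whose value at a scan is the number of
events of that condition placing the scan in that bin.  Fitting jointly
with the nuisance columns deconvolves overlapping trials rather than
averaging over them.  The seen-unseen (BS - BU) difference curve carries
a per-bin dispersion derived from the fit covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import config as cfg
from .glm import DesignMatrix, GLMFit, fit_glm, nuisance_matrix
from .paradigm import TrialSchedule

log = logging.getLogger(__name__)

CONDITIONS = ("UL", "UR", "BS", "BU")


def bin_edges(window: tuple[float, float] = cfg.FIR_WINDOW, bin_width: float = cfg.FIR_BIN_WIDTH) -> np.ndarray:
    lo, hi = window
    n_bins = (hi - lo) / bin_width
    if n_bins <= 0 or abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("window must span a positive whole number of bins")
    return lo + bin_width * np.arange(round(n_bins) + 1)


@dataclass
class FIREstimate:
    """Per-condition peristimulus bin amplitudes from one FIR fit."""

    bin_edges: np.ndarray  # seconds relative to onset, length n_bins + 1
    conditions: list[str]
    amplitudes: dict[str, np.ndarray]  # condition -> (n_bins,) % signal
    fit: GLMFit
    column_index: dict[tuple[str, int], int]  # (condition, bin) -> design col

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def to_tsv(self, path: str | Path) -> Path:
        rows = [
            {
                "condition": c,
                "bin_start_s": self.bin_edges[b],
                "amplitude": self.amplitudes[c][b],
            }
            for c in self.conditions
            for b in range(self.n_bins)
        ]
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
        return path


def _fir_columns(
    schedule: TrialSchedule,
    conditions: Sequence[str],
    window: tuple[float, float],
    bin_width: float,
) -> tuple[np.ndarray, list[str], dict[tuple[str, int], int], list[str]]:
    """FIR convolution design: for every event of a condition, the scan at
    peristimulus time t contributes to bin ``floor((t - window_start) /
    bin_width)``; contributions from overlapping events add, so joint least
    squares deconvolves them."""
    edges = bin_edges(window, bin_width)
    n_bins = len(edges) - 1
    ev = schedule.events
    if len(ev) and ev["label"].isna().any():
        raise ValueError("schedule must be labelled before FIR fitting")
    present = [c for c in conditions if len(ev) and (ev["label"] == c).any()]
    scan_t = (np.arange(schedule.run_length) * schedule.tr)  # within-run times
    n_scans = schedule.n_scans

    X = np.zeros((n_scans, len(present) * n_bins))
    col_of = {
        (c, b): i * n_bins + b for i, c in enumerate(present) for b in range(n_bins)
    }
    for ci, cond in enumerate(present):
        sub = ev[ev["label"] == cond]
        for run in range(schedule.n_runs):
            onsets = sub[sub["run"] == run]["onset"].to_numpy()
            if window[0] < 0:
                dropped = onsets[onsets + window[0] < 0]
                if len(dropped):
                    log.info(
                        "FIR: dropping %d %s trial(s) in run %d whose window "
                        "precedes the first scan",
                        len(dropped),
                        cond,
                        run,
                    )
                onsets = onsets[onsets + window[0] >= 0]
            if not len(onsets):
                continue
            # peristimulus time of every scan relative to every event
            rel = scan_t[:, None] - onsets[None, :]
            covered = (rel >= window[0]) & (rel < window[1])
            bins = np.floor((rel - window[0]) / bin_width).astype(int)
            rows0 = run * schedule.run_length
            scan_idx, ev_idx = np.nonzero(covered)
            np.add.at(
                X,
                (rows0 + scan_idx, ci * n_bins + bins[scan_idx, ev_idx]),
                1.0,
            )
    names = [f"{c}_bin{b}" for c in present for b in range(n_bins)]
    return X, names, col_of, present


def fit_fir(
    roi_series: np.ndarray,
    schedule: TrialSchedule,
    bin_width: float = cfg.FIR_BIN_WIDTH,
    window: tuple[float, float] = cfg.FIR_WINDOW,
    confounds: Optional[np.ndarray] = None,
    hp_cutoff: float | None = cfg.HP_CUTOFF,
    conditions: Sequence[str] = CONDITIONS,
) -> FIREstimate:
    """Fit the FIR model to one region's series (or one column per region).

    Returns per-condition bin amplitudes; nuisance columns (motion, per-run
    drift basis unless ``hp_cutoff`` is None, per-run intercepts) are
    estimated jointly.
    """
    roi_series = np.asarray(roi_series, float)
    edges = bin_edges(window, bin_width)
    Xf, names, col_of, present = _fir_columns(schedule, conditions, window, bin_width)
    X_nuis, nuis_names = nuisance_matrix(
        schedule.n_scans,
        schedule.run_length,
        schedule.tr,
        hp_cutoff if hp_cutoff is not None else np.inf,
        motion=confounds,
    )
    design = DesignMatrix(
        np.column_stack([Xf, X_nuis]), names + nuis_names, schedule.tr
    )
    fit = fit_glm(roi_series, design)
    n_bins = len(edges) - 1
    amplitudes = {
        c: np.array([np.atleast_1d(fit.betas[col_of[(c, b)]]) for b in range(n_bins)]).squeeze()
        for c in present
    }
    return FIREstimate(
        bin_edges=edges,
        conditions=present,
        amplitudes=amplitudes,
        fit=fit,
        column_index=col_of,
    )


def difference_curve(est: FIREstimate, cond_a: str = "BS", cond_b: str = "BU") -> pd.DataFrame:
    """Per-bin ``cond_a - cond_b`` amplitude difference with its dispersion.

    The dispersion is the standard deviation of the contrast estimate under
    the fit covariance, ``sqrt(sigma^2 c'(X'X)^- c)`` per bin.
    """
    for c in (cond_a, cond_b):
        if c not in est.conditions:
            raise ValueError(f"condition {c!r} missing from the FIR estimate")
    n_cols = len(est.fit.design.column_names)
    rows = []
    sigma2 = float(np.atleast_1d(est.fit.residual_variance)[0])
    for b in range(est.n_bins):
        c = np.zeros(n_cols)
        c[est.column_index[(cond_a, b)]] = 1.0
        c[est.column_index[(cond_b, b)]] = -1.0
        diff = float(np.atleast_1d(est.fit.contrast_estimate(c))[0])
        sd = float(np.sqrt(sigma2 * (c @ est.fit.xtx_pinv @ c)))
        rows.append({"bin_start_s": est.bin_edges[b], "difference": diff, "sd": sd})
    return pd.DataFrame(rows)


def first_divergence_bin(diff: pd.DataFrame, n_sd: float = 2.0) -> float | None:
    """Start time (s, relative to onset) of the earliest bin whose
    difference exceeds ``n_sd`` dispersions; None if no bin does."""
    exceeds = diff["difference"] > n_sd * diff["sd"]
    if not exceeds.any():
        return None
    return float(diff.loc[exceeds.idxmax(), "bin_start_s"])


def plot_curves(
    estimates: dict[str, FIREstimate] | FIREstimate,
    path: str | Path,
    cond_a: str = "BS",
    cond_b: str = "BU",
) -> Path:
    """Three-panel peristimulus figure per region: both condition curves
    plus their difference with a +/-1 SD band."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if isinstance(estimates, FIREstimate):
        estimates = {"roi": estimates}
    fig, axes = plt.subplots(
        len(estimates), 1, figsize=(6, 3 * len(estimates)), squeeze=False
    )
    for ax, (name, est) in zip(axes[:, 0], estimates.items()):
        centers = est.bin_edges[:-1] + np.diff(est.bin_edges) / 2
        for c in (cond_a, cond_b):
            ax.plot(centers, est.amplitudes[c], marker="o", label=c)
        d = difference_curve(est, cond_a, cond_b)
        ax.plot(centers, d["difference"], color="tab:blue", ls="--", label=f"{cond_a}-{cond_b}")
        ax.fill_between(
            centers,
            d["difference"] - d["sd"],
            d["difference"] + d["sd"],
            alpha=0.3,
            color="tab:blue",
        )
        ax.axvline(0, color="k", lw=0.8)
        ax.set_title(name)
        ax.set_xlabel("peristimulus time (s)")
        ax.set_ylabel("% signal")
        ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
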