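"""Pipeline configuration: dataclasses, YAML (de)serialisation, validation.

Every timing and design constant of the experiment appears here exactly
once; downstream modules take these values as arguments rather than
hard-coding them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

# --- experiment constants -------------------------------------------------
TR = 2.0  # scan repetition time, s
N_RUNS = 9  # extinction runs (two sessions)
N_BILATERAL = 23  # bilateral trials per run
N_UNILATERAL = 6  # per side, per run
ITI_RANGE = (4.0, 20.0)  # randomized inter-trial interval, s
STIM_DURATION_EARLY = 0.140  # runs 1-6, s
STIM_DURATION_LATE = 0.120  # runs 7-9, s
LATE_RUN_START = 6  # 0-based run index at which duration shortens
RUN_LENGTH = 420  # scans per run (total scheduled time + tail; not printed
#                   in the source report, configurable)
PRESTIM_GLM_OFFSET = 7.0  # baseline boxcar starts this long before onset, s
PRESTIM_GLM_DURATION = 6.0  # baseline boxcar length, s (1 s gap pre-onset)
PRESTIM_DCM_LEN = 7.0  # DCM prestimulus boxcar runs up to onset, s
HP_CUTOFF = 128.0  # high-pass cut-off, s
FIR_WINDOW = (-7.0, 9.0)  # peristimulus window, s
FIR_BIN_WIDTH = 2.0  # s
FINE_DT = TR / 16.0  # forward-model integration step, s
P_EXTINGUISH = 94 / 207  # observed fraction of unseen bilateral trials
P_MISS_LEFT = 4 / 54  # unilateral-left misses
P_MISS_RIGHT = 1 / 54  # unilateral-right misses

#: region index convention used throughout: 0 = left visual area
#: (lesioned hemisphere), 1 = right visual area.
LEFT, RIGHT = 0, 1
REGION_NAMES = ("left", "right")


@dataclass
class ParadigmConfig:
    n_runs: int = N_RUNS
    n_bilateral: int = N_BILATERAL
    n_unilateral: int = N_UNILATERAL
    iti_range: tuple[float, float] = ITI_RANGE
    run_length: int = RUN_LENGTH
    tr: float = TR
    p_extinguish: float = P_EXTINGUISH
    p_miss_left: float = P_MISS_LEFT
    p_miss_right: float = P_MISS_RIGHT
    response_mode: str = "exact_counts"  # or "bernoulli"


@dataclass
class HemodynamicParams:
    """Balloon-Windkessel constants (standard priors from the DCM
    literature; the source analysis prints none)."""

    kappa: float = 0.64  # vasodilatory signal decay, 1/s
    gamma: float = 0.32  # flow-dependent elimination, 1/s
    tau: float = 2.0  # hemodynamic transit time, s
    alpha: float = 0.32  # Grubb vessel stiffness exponent
    rho: float = 0.4  # resting oxygen extraction fraction
    V0: float = 0.04  # resting blood volume fraction

    def validate(self) -> list[str]:
        out = []
        for name in ("kappa", "gamma", "tau", "alpha", "rho", "V0"):
            if getattr(self, name) <= 0:
                out.append(f"hemodynamic parameter {name} must be > 0")
        for name in ("alpha", "rho", "V0"):
            if not (0 < getattr(self, name) < 1):
                out.append(f"hemodynamic parameter {name} must lie in (0, 1)")
        return out


def _default_A() -> np.ndarray:
    # self-inhibition plus weakly inhibitory reciprocal coupling, Hz
    return np.array([[-0.5, -0.1], [-0.1, -0.5]])


def _default_B3() -> np.ndarray:
    # seen-trial modulation: reduced self-inhibition (more on the left),
    # off-diagonals pushed from inhibitory to excitatory, the right-to-left
    # change the larger.  rows = target region, cols = source region.
    return np.array([[0.30, 0.25], [0.15, 0.10]])


def _default_C() -> np.ndarray:
    # driving strengths, rows = regions, cols = inputs (prestimulus boxcar,
    # stimulus stick, seen-prestimulus boxcar).  Input 3 never drives.
    return np.array([[0.15, 1.0, 0.0], [0.15, 1.0, 0.0]])


@dataclass
class GroundTruth:
    """Generative two-region bilinear DCM used by the synthetic-data module."""

    A: np.ndarray = field(default_factory=_default_A)
    B: list[np.ndarray] = field(
        default_factory=lambda: [np.zeros((2, 2)), np.zeros((2, 2)), _default_B3()]
    )
    C: np.ndarray = field(default_factory=_default_C)
    hemo: HemodynamicParams = field(default_factory=HemodynamicParams)
    sigma_noise: float = 0.3  # observation noise SD, % BOLD signal
    drift_amp: float = 0.5  # slow drift amplitude, % signal
    drift_period: float = 300.0  # s, > 128 s so the GLM high-pass removes it
    run_offset_amp: float = 0.3  # per-run constant offset SD, % signal

    def n_inputs(self) -> int:
        return self.C.shape[1]

    def stable(self) -> bool:
        return ground_truth_stable(self.A, self.B)

    def validate(self) -> list[str]:
        out = self.hemo.validate()
        if np.any(np.diag(self.A) >= 0):
            out.append("diagonal of A must be negative (self-inhibition)")
        if not self.stable():
            out.append("A (or A plus some active modulation) is unstable")
        if self.sigma_noise < 0 or self.drift_amp < 0:
            out.append("noise amplitudes must be non-negative")
        return out


def ground_truth_stable(A: np.ndarray, B: list[np.ndarray]) -> bool:
    """True when A and A + any combination of modulations are stable.

    Inputs are boxcars/sticks bounded by 1, so it suffices to check every
    on/off combination of the B matrices.
    """
    n_inputs = len(B)
    for mask in range(2**n_inputs):
        M = A.copy()
        for j in range(n_inputs):
            if mask >> j & 1:
                M = M + B[j]
        if np.max(np.real(np.linalg.eigvals(M))) >= 0:
            return False
    return True


def strong_modulation_truth(sigma_noise: float = 0.05) -> GroundTruth:
    """High-SNR scenario for model/family recovery studies: all four
    connections strongly modulated before seen trials, low observation
    noise, no drift or run offsets."""
    B3 = np.array([[0.35, 0.25], [0.20, 0.25]])
    return GroundTruth(
        B=[np.zeros((2, 2)), np.zeros((2, 2)), B3],
        sigma_noise=sigma_noise,
        drift_amp=0.0,
        run_offset_amp=0.0,
    )


def null_truth(sigma_noise: float = 0.3) -> GroundTruth:
    """No seen/unseen connectivity difference (all modulations zero):
    the calibration scenario in which no family should win decisively."""
    return GroundTruth(
        B=[np.zeros((2, 2)) for _ in range(3)],
        sigma_noise=sigma_noise,
        drift_amp=0.0,
        run_offset_amp=0.0,
    )


def reduced_dcm_paradigm() -> ParadigmConfig:
    """Scaled-down paradigm used for model-inversion studies: 3 runs of
    10 bilateral + 2 + 2 unilateral trials in 150 scans each (enough for
    the worst-case ITI draw), which keeps a 16-model inversion sweep to
    about a minute per seed."""
    return ParadigmConfig(
        n_runs=3, n_bilateral=10, n_unilateral=2, run_length=150
    )


@dataclass
class GLMConfig:
    hp_cutoff: float = HP_CUTOFF
    prestim_offset: float = PRESTIM_GLM_OFFSET
    prestim_duration: float = PRESTIM_GLM_DURATION
    threshold_rule: str = "uncorrected_p001"  # or "bonferroni_p05"
    n_motion_confounds: int = 6


@dataclass
class FIRConfig:
    window: tuple[float, float] = FIR_WINDOW
    bin_width: float = FIR_BIN_WIDTH


@dataclass
class VolumeConfig:
    enabled: bool = False
    grid_shape: tuple[int, int, int] = (14, 10, 8)
    blob_sigma: float = 1.0


@dataclass
class DCMConfig:
    prestim_len: float = PRESTIM_DCM_LEN
    fine_dt: float = FINE_DT
    max_iter: int = 128
    f_tol: float = 1e-2
    converge_streak: int = 4


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "prestim_out"
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    truth: GroundTruth = field(default_factory=GroundTruth)
    glm: GLMConfig = field(default_factory=GLMConfig)
    fir: FIRConfig = field(default_factory=FIRConfig)
    dcm: DCMConfig = field(default_factory=DCMConfig)
    volume: VolumeConfig = field(default_factory=VolumeConfig)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if dataclasses.is_dataclass(x):
                return {f.name: conv(getattr(x, f.name)) for f in dataclasses.fields(x)}
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        return conv(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        kw: dict[str, Any] = {}
        if "paradigm" in d:
            p = dict(d.pop("paradigm"))
            if "iti_range" in p:
                p["iti_range"] = tuple(p["iti_range"])
            kw["paradigm"] = ParadigmConfig(**p)
        if "truth" in d:
            t = dict(d.pop("truth"))
            if "A" in t:
                t["A"] = np.asarray(t["A"], float)
            if "B" in t:
                t["B"] = [np.asarray(b, float) for b in t["B"]]
            if "C" in t:
                t["C"] = np.asarray(t["C"], float)
            if "hemo" in t:
                t["hemo"] = HemodynamicParams(**t["hemo"])
            kw["truth"] = GroundTruth(**t)
        if "glm" in d:
            kw["glm"] = GLMConfig(**d.pop("glm"))
        if "fir" in d:
            f = dict(d.pop("fir"))
            if "window" in f:
                f["window"] = tuple(f["window"])
            kw["fir"] = FIRConfig(**f)
        if "dcm" in d:
            kw["dcm"] = DCMConfig(**d.pop("dcm"))
        if "volume" in d:
            v = dict(d.pop("volume"))
            if "grid_shape" in v:
                v["grid_shape"] = tuple(v["grid_shape"])
            kw["volume"] = VolumeConfig(**v)
        kw.update(d)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        doc = self.to_dict()
        doc.pop("out_dir", None)  # where results land is not what they are
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    out: list[str] = []
    p = cfg.paradigm
    if p.n_runs < 0 or p.n_bilateral < 0 or p.n_unilateral < 0:
        out.append("paradigm: trial counts must be non-negative")
    if p.iti_range[0] > p.iti_range[1]:
        out.append("paradigm: iti_range min exceeds max")
    if p.iti_range[0] < 0:
        out.append("paradigm: iti_range must be non-negative")
    if not 0 <= p.p_extinguish <= 1:
        out.append("paradigm: p_extinguish outside [0, 1]")
    if p.response_mode not in ("bernoulli", "exact_counts"):
        out.append(f"paradigm: unknown response_mode {p.response_mode!r}")
    out.extend("truth: " + v for v in cfg.truth.validate())
    lo, hi = cfg.fir.window
    span = hi - lo
    if span <= 0 or abs(span / cfg.fir.bin_width - round(span / cfg.fir.bin_width)) > 1e-9:
        out.append("fir: window must be a positive whole number of bins")
    if cfg.glm.threshold_rule not in ("uncorrected_p001", "bonferroni_p05"):
        out.append(f"glm: unknown threshold_rule {cfg.glm.threshold_rule!r}")
    n_sub = round(cfg.paradigm.tr / cfg.dcm.fine_dt)
    if abs(n_sub * cfg.dcm.fine_dt - cfg.paradigm.tr) > 1e-9:
        out.append("dcm: fine_dt must divide TR")
    return out
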