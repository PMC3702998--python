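"""Extinction-paradigm trial schedules, response simulation and behaviour.

The paradigm presents brief face stimuli left, right or bilaterally while
the observer reports what was seen.  Bilateral trials are classified after
the fact as *bilateral seen* (BS, both sides reported) or *bilateral
unseen* (BU, only the right side reported — the signature of left visual
extinction).  Schedules are represented as a tidy events table (one row
per trial) in the BIDS ``events.tsv`` dialect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import config as cfg

EVENT_COLUMNS = ["run", "onset", "duration", "trial_type", "response", "label"]
SIDES = ("left", "right", "bilateral")
RESPONSES = ("left", "right", "both", "none")

#: (stimulus_side, response) -> trial label.  Bilateral trials with a
#: "left" or "none" response do not fit the seen/unseen dichotomy and are
#: labelled "other", as are incorrect unilateral reports.
_LABEL_TABLE: dict[tuple[str, str], str] = {
    ("bilateral", "both"): "BS",
    ("bilateral", "right"): "BU",
    ("left", "left"): "UL",
    ("right", "right"): "UR",
}


def classify_one(stimulus_side: str, response: str) -> str:
    """Label a single trial from its stimulus side and the report."""
    return _LABEL_TABLE.get((stimulus_side, response), "other")


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class TrialSchedule:
    """Ordered trial events across runs plus the scan geometry."""

    events: pd.DataFrame
    n_runs: int
    tr: float = cfg.TR
    run_length: int = cfg.RUN_LENGTH

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"events table lacks columns {missing}")
        self.events = self.events.reset_index(drop=True)

    @property
    def n_scans(self) -> int:
        return self.n_runs * self.run_length

    @property
    def n_events(self) -> int:
        return len(self.events)

    def run_events(self, run: int) -> pd.DataFrame:
        return self.events[self.events["run"] == run]

    def concat_onsets(self) -> np.ndarray:
        """Onsets on the concatenated (all-runs) time axis, seconds."""
        ev = self.events
        return (ev["onset"] + ev["run"] * self.run_length * self.tr).to_numpy()

    def copy(self) -> "TrialSchedule":
        return TrialSchedule(self.events.copy(), self.n_runs, self.tr, self.run_length)

    # -- I/O (BIDS events.tsv dialect, one file per run) -------------------
    def to_tsv(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for run in range(self.n_runs):
            p = out_dir / f"run-{run + 1:02d}_events.tsv"
            self.run_events(run).drop(columns="run").to_csv(
                p, sep="\t", index=False, na_rep="n/a"
            )
            paths.append(p)
        return paths

    @classmethod
    def from_tsv(
        cls,
        in_dir: str | Path,
        tr: float = cfg.TR,
        run_length: int = cfg.RUN_LENGTH,
    ) -> "TrialSchedule":
        paths = sorted(Path(in_dir).glob("run-*_events.tsv"))
        if not paths:
            raise FileNotFoundError(f"no run-*_events.tsv under {in_dir}")
        frames = []
        for run, p in enumerate(paths):
            df = pd.read_csv(p, sep="\t", na_values=["n/a"], keep_default_na=False)
            df.insert(0, "run", run)
            frames.append(df)
        ev = pd.concat(frames, ignore_index=True)
        for col in ("response", "label"):
            if col not in ev.columns:
                ev[col] = pd.NA
        return cls(ev[EVENT_COLUMNS], n_runs=len(paths), tr=tr, run_length=run_length)


def default_composition(
    n_bilateral: int = cfg.N_BILATERAL, n_unilateral: int = cfg.N_UNILATERAL
) -> dict[str, int]:
    return {"bilateral": n_bilateral, "left": n_unilateral, "right": n_unilateral}


def _run_durations(n_runs: int, durations: Sequence[float] | None) -> list[float]:
    if durations is not None:
        if len(durations) != n_runs:
            raise ValueError("durations must supply one value per run")
        return list(durations)
    return [
        cfg.STIM_DURATION_EARLY if r < cfg.LATE_RUN_START else cfg.STIM_DURATION_LATE
        for r in range(n_runs)
    ]


def generate_schedule(
    n_runs: int = cfg.N_RUNS,
    composition: Mapping[str, int] | None = None,
    iti_range: tuple[float, float] = cfg.ITI_RANGE,
    durations: Sequence[float] | None = None,
    seed: int = 0,
    tr: float = cfg.TR,
    run_length: int = cfg.RUN_LENGTH,
    fir_tail: float = 9.0,
) -> TrialSchedule:
    """Draw a randomized trial schedule.

    Per run, the requested composition of bilateral / unilateral trials is
    presented in seeded random order with inter-trial intervals drawn
    uniformly from ``iti_range``; consecutive onsets are separated by the
    stimulus duration plus that interval.  Raises if the schedule (plus the
    peristimulus tail) cannot fit within ``run_length`` scans.
    """
    if n_runs < 0:
        raise ValueError("n_runs must be >= 0")
    if iti_range[0] > iti_range[1] or iti_range[0] < 0:
        raise ValueError(f"invalid ITI range {iti_range}")
    composition = dict(composition or default_composition())
    if any(v < 0 for v in composition.values()):
        raise ValueError("composition counts must be >= 0")
    unknown = set(composition) - set(SIDES)
    if unknown:
        raise ValueError(f"unknown trial types {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    dur_per_run = _run_durations(n_runs, durations)
    rows = []
    for run in range(n_runs):
        types = [t for t, k in composition.items() for _ in range(k)]
        order = rng.permutation(len(types))
        itis = rng.uniform(iti_range[0], iti_range[1], size=len(types))
        t = itis[0] if len(types) else 0.0  # lead-in before the first trial
        for i, j in enumerate(order):
            if i > 0:
                t += dur_per_run[run] + itis[i]
            rows.append(
                {
                    "run": run,
                    "onset": t,
                    "duration": dur_per_run[run],
                    "trial_type": types[j],
                    "response": pd.NA,
                    "label": pd.NA,
                }
            )
        if rows and rows[-1]["run"] == run:
            t_end = rows[-1]["onset"] + dur_per_run[run] + fir_tail
            if t_end > run_length * tr:
                raise ValueError(
                    f"run {run}: schedule ({t_end:.1f} s) exceeds "
                    f"{run_length} scans at TR={tr}"
                )
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return TrialSchedule(events, n_runs=n_runs, tr=tr, run_length=run_length)


def simulate_responses(
    schedule: TrialSchedule,
    p_extinguish: float = cfg.P_EXTINGUISH,
    p_miss_left: float = cfg.P_MISS_LEFT,
    p_miss_right: float = cfg.P_MISS_RIGHT,
    mode: str = "exact_counts",
    seed: int = 0,
) -> TrialSchedule:
    """Fill in simulated button presses.

    Bilateral trials are answered "right" (left stimulus extinguished) with
    probability ``p_extinguish`` and "both" otherwise; unilateral trials are
    missed (response "none") with the per-side miss probability.  In
    ``exact_counts`` mode, exactly ``round(p * n)`` trials of each kind (a
    seeded random subset) receive the rare outcome, reproducing fixed
    observed counts; ``bernoulli`` draws independently per trial.
    """
    for name, p in (
        ("p_extinguish", p_extinguish),
        ("p_miss_left", p_miss_left),
        ("p_miss_right", p_miss_right),
    ):
        if not 0 <= p <= 1:
            raise ValueError(f"{name}={p} outside [0, 1]")
    if mode not in ("bernoulli", "exact_counts"):
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    out = schedule.copy()
    ev = out.events

    def pick(idx: np.ndarray, p: float) -> np.ndarray:
        """Boolean mask over idx marking trials with the rare outcome."""
        if mode == "bernoulli":
            return rng.random(len(idx)) < p
        k = round_half_away(p * len(idx))
        mask = np.zeros(len(idx), dtype=bool)
        mask[rng.choice(len(idx), size=k, replace=False)] = True
        return mask

    for side, hit, miss, p in (
        ("bilateral", "both", "right", p_extinguish),
        ("left", "left", "none", p_miss_left),
        ("right", "right", "none", p_miss_right),
    ):
        idx = ev.index[ev["trial_type"] == side].to_numpy()
        if len(idx) == 0:
            continue
        rare = pick(idx, p)
        ev.loc[idx, "response"] = hit
        ev.loc[idx[rare], "response"] = miss
    return out


def classify_trials(schedule: TrialSchedule) -> TrialSchedule:
    """Assign BS/BU/UL/UR/other labels from stimulus side and response."""
    ev = schedule.events
    if ev["response"].isna().any():
        n = int(ev["response"].isna().sum())
        raise ValueError(f"{n} events lack a response; classify after responses")
    out = schedule.copy()
    out.events["label"] = [
        classify_one(s, r) for s, r in zip(ev["trial_type"], ev["response"])
    ]
    return out


@dataclass
class BehaviourSummary:
    """Counts and rounded percentages of the behavioural report."""

    n_bilateral: int
    n_BS: int
    n_BU: int
    n_UL: int
    n_UL_seen: int
    n_UR: int
    n_UR_seen: int
    pct_BU: int | None = field(default=None)
    pct_UL_seen: int | None = field(default=None)
    pct_UR_seen: int | None = field(default=None)

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _pct(k: int, n: int) -> int | None:
    return None if n == 0 else round_half_away(100.0 * k / n)


def summarize_behaviour(schedule: TrialSchedule) -> BehaviourSummary:
    """Tabulate seen/unseen counts and their integer percentages.

    Percentages are undefined (``None``) when the denominator is zero.
    """
    ev = schedule.events
    if ev["label"].isna().any():
        raise ValueError("events lack labels; run classify_trials first")
    lab = ev["label"].value_counts()
    n_bi = int((ev["trial_type"] == "bilateral").sum())
    n_ul = int((ev["trial_type"] == "left").sum())
    n_ur = int((ev["trial_type"] == "right").sum())
    n_bs, n_bu = int(lab.get("BS", 0)), int(lab.get("BU", 0))
    n_ul_seen, n_ur_seen = int(lab.get("UL", 0)), int(lab.get("UR", 0))
    return BehaviourSummary(
        n_bilateral=n_bi,
        n_BS=n_bs,
        n_BU=n_bu,
        n_UL=n_ul,
        n_UL_seen=n_ul_seen,
        n_UR=n_ur,
        n_UR_seen=n_ur_seen,
        pct_BU=_pct(n_bu, n_bi),
        pct_UL_seen=_pct(n_ul_seen, n_ul),
        pct_UR_seen=_pct(n_ur_seen, n_ur),
    )
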