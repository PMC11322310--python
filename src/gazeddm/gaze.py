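"""Fixation sequences, gaze proportions, and the attention-allocation measure.

This module consumes *fixation lists* (AOI label + onset + duration); turning
raw gaze samples into fixations is an upstream, hardware-specific step and is
deliberately outside the contract. Two AOIs are used, one per option, plus
``none`` for dwell outside both. Per trial, the gaze proportion on an option
is its AOI dwell time relative to the total dwell on either AOI; ``none``
time is ignored. The attention-allocation process measure is the gaze
proportion on whichever option has the higher expected value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .task import ChoiceProblem, ProblemType, classify_problem

__all__ = [
    "Fixation",
    "TrialGaze",
    "TrialRecord",
    "NoAOIFixationsError",
    "UndefinedMeasureError",
    "compute_gaze_proportions",
    "attention_to_higher_ev",
    "filter_trials",
    "participant_attention_summary",
    "read_fixations_csv",
    "read_trials_csv",
]

AOI_LABELS = ("option_a", "option_b", "none")


class NoAOIFixationsError(ValueError):
    """Trial has no fixation in either option AOI; gaze proportions undefined."""


class UndefinedMeasureError(ValueError):
    """Attention-to-higher-EV is undefined (e.g. equal-EV problem)."""


@dataclass(frozen=True)
class Fixation:
    aoi: str
    duration: float  # ms, > 0
    onset: float = 0.0  # ms, >= 0

    def __post_init__(self):
        if self.aoi not in AOI_LABELS:
            raise ValueError(f"unknown AOI {self.aoi!r}")
        if self.duration <= 0:
            raise ValueError("fixation duration must be > 0")
        if self.onset < 0:
            raise ValueError("fixation onset must be >= 0")


@dataclass(frozen=True)
class TrialGaze:
    gaze_a: float
    gaze_b: float

    def __post_init__(self):
        if abs(self.gaze_a + self.gaze_b - 1.0) > 1e-9:
            raise ValueError("gaze proportions must sum to 1")

    def gaze_on(self, option_label: str) -> float:
        return self.gaze_a if option_label == "option_a" else self.gaze_b


@dataclass
class TrialRecord:
    """One decision: problem, fixations, choice, response time."""

    participant_id: str
    trial_id: str
    problem: ChoiceProblem
    fixations: list[Fixation]
    choice: str  # 'option_a' | 'option_b'
    rt_ms: float
    gaze: TrialGaze | None = field(default=None)

    def ensure_gaze(self) -> TrialGaze:
        if self.gaze is None:
            self.gaze = compute_gaze_proportions(self.fixations)
        return self.gaze


def compute_gaze_proportions(fixations: Iterable[Fixation]) -> TrialGaze:
    """Dwell-time share on each option's AOI; ``none`` dwell is ignored."""
    dwell_a = sum(f.duration for f in fixations if f.aoi == "option_a")
    dwell_b = sum(f.duration for f in fixations if f.aoi == "option_b")
    total = dwell_a + dwell_b
    if total <= 0:
        raise NoAOIFixationsError("no AOI fixations in trial")
    return TrialGaze(gaze_a=dwell_a / total, gaze_b=dwell_b / total)


def attention_to_higher_ev(trial: TrialRecord, problem_type: str | None = None) -> float:
    """Gaze proportion on the higher-EV option (the attention-allocation score)."""
    ptype = problem_type or classify_problem(trial.problem)
    if ptype == ProblemType.EQUAL_EV:
        raise UndefinedMeasureError("attention-to-higher-EV undefined for equal-EV problems")
    gaze = trial.ensure_gaze()
    return gaze.gaze_on(trial.problem.higher_ev_option())


def filter_trials(
    trials: Sequence[TrialRecord],
) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Apply trial-level exclusions.

    Drops trials with no AOI dwell at all and trials on excluded problems
    (equal-EV, safe-safe). Returns (kept, exclusion_log) with one reason per
    excluded trial; problem-level exclusion takes precedence in the log.
    """
    kept: list[TrialRecord] = []
    log_rows: list[dict] = []
    for t in trials:
        ptype = classify_problem(t.problem)
        if ptype in (ProblemType.EQUAL_EV, ProblemType.TRIVIAL_SAFE_SAFE):
            log_rows.append(
                {"participant_id": t.participant_id, "trial_id": t.trial_id, "reason": ptype}
            )
            continue
        try:
            t.ensure_gaze()
        except NoAOIFixationsError:
            log_rows.append(
                {"participant_id": t.participant_id, "trial_id": t.trial_id, "reason": "no.aoi.fixations"}
            )
            continue
        kept.append(t)
    log = pd.DataFrame(log_rows, columns=["participant_id", "trial_id", "reason"])
    return kept, log


def participant_attention_summary(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Mean attention-to-higher-EV per (participant, problem type) cell.

    Cells with no analyzable trial are simply absent (missing, never zero).
    """
    rows = []
    for t in trials:
        ptype = classify_problem(t.problem)
        rows.append(
            {
                "participant_id": t.participant_id,
                "problem_type": ptype,
                "attention": attention_to_higher_ev(t, ptype),
            }
        )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return pd.DataFrame(columns=["participant_id", "problem_type", "attention"])
    return (
        frame.groupby(["participant_id", "problem_type"], as_index=False)["attention"]
        .mean()
    )


# ---------------------------------------------------------------------------
# Readers for the long-format CSV dialects.


def read_fixations_csv(path) -> pd.DataFrame:
    """Fixations CSV: participant_id, trial_id, aoi, onset_ms, duration_ms."""
    frame = pd.read_csv(path, dtype={"participant_id": str, "trial_id": str})
    required = {"participant_id", "trial_id", "aoi", "onset_ms", "duration_ms"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"fixations CSV missing columns: {sorted(missing)}")
    return frame


def read_trials_csv(path) -> pd.DataFrame:
    """Trial table CSV: participant_id, trial_id, problem_id, choice, rt_ms."""
    frame = pd.read_csv(path, dtype={"participant_id": str, "trial_id": str, "problem_id": str})
    required = {"participant_id", "trial_id", "problem_id", "choice", "rt_ms"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    return frame


def assemble_trials(
    trials_frame: pd.DataFrame,
    fixations_frame: pd.DataFrame,
    problems: Sequence[ChoiceProblem],
) -> list[TrialRecord]:
    """Join the trial table with fixations and problem definitions."""
    by_id = {p.id: p for p in problems}
    fix_groups = dict(tuple(fixations_frame.groupby(["participant_id", "trial_id"])))
    records = []
    for _, row in trials_frame.iterrows():
        key = (row["participant_id"], row["trial_id"])
        fixes = []
        if key in fix_groups:
            part = fix_groups[key].sort_values("onset_ms")
            fixes = [
                Fixation(aoi=r["aoi"], duration=r["duration_ms"], onset=r["onset_ms"])
                for _, r in part.iterrows()
            ]
        records.append(
            TrialRecord(
                participant_id=row["participant_id"],
                trial_id=row["trial_id"],
                problem=by_id[row["problem_id"]],
                fixations=fixes,
                choice=row["choice"],
                rt_ms=float(row["rt_ms"]),
            )
        )
    return records
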