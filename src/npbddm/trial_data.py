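"""Trial records, task configuration, and the CSV trial-table format.

One row per trial of the random-dot motion task: signed motion coherence,
the randomly assigned correct side, the choice, reaction time, outcome
(correct / error / canceled / aborted), phase, and the provisional-deadline
bookkeeping used in Phase II.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Signed coherence values of the task.  The design draws from a 12-entry
#: list (+-0, +-3.2, +-6.4, +-12.8, +-25.6, +-51.2 %); zero appears once here
#: and carries double sampling weight so the mixture is unchanged.
COHERENCES: tuple[float, ...] = (
    -0.512, -0.256, -0.128, -0.064, -0.032,
    0.0,
    0.032, 0.064, 0.128, 0.256, 0.512,
)

#: Default per-entry sampling weights (zero counted twice out of 12).
COHERENCE_WEIGHTS: tuple[float, ...] = tuple(
    (2 / 12 if c == 0.0 else 1 / 12) for c in COHERENCES
)

MOTION_STRENGTHS: tuple[float, ...] = (0.0, 0.032, 0.064, 0.128, 0.256, 0.512)

PHASES = ("I", "II", "III")
OUTCOMES = ("correct", "error", "canceled", "aborted")
SIDES = ("left", "right")

#: Column order of the CSV trial table.
COLUMNS = (
    "participant", "phase", "session", "trial_index", "coherence",
    "correct_side", "has_deadline", "deadline_s", "choice", "rt_s",
    "outcome", "points_delta",
)


class TrialValidationError(ValueError):
    """A trial table violated the record invariants."""


class TrialSchemaError(ValueError):
    """A trial table is missing required columns."""


@dataclass(frozen=True)
class DeadlineSpec:
    """Time-shifted Rayleigh distribution of provisional deadlines.

    ``t0`` shifts the support (minimum possible deadline); ``sigma_dl`` is
    the Rayleigh scale.  Density: ``(t - t0)/sigma^2 * exp(-(t-t0)^2 / (2 sigma^2))``
    for ``t >= t0``.
    """

    t0: float
    sigma_dl: float

    def __post_init__(self) -> None:
        if self.t0 < 0:
            raise ValueError("t0 must be non-negative")
        if self.sigma_dl <= 0:
            raise ValueError("sigma_dl must be positive")


@dataclass(frozen=True)
class TaskConfig:
    """Timing and scoring parameters of one task phase."""

    coherences: tuple[float, ...] = COHERENCES
    weights: tuple[float, ...] = COHERENCE_WEIGHTS
    max_viewing_s: float = 5.0
    iti_s: float = 2.0
    misc_s: float = 0.7
    misc_cancel_s: float = 0.4
    reward_correct: int = 1
    reward_error: int = -1
    reward_cancel: int = 0
    deadline_fraction: float = 0.0
    deadline: DeadlineSpec | None = None
    abort_rate: float = 0.0
    abort_cost_s: float | None = None  # default: misc_cancel_s + iti_s

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.coherences) != len(w):
            raise ValueError("coherences and weights must have equal length")
        if not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("sampling weights must sum to 1")
        for name in ("max_viewing_s", "iti_s", "misc_s", "misc_cancel_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.deadline_fraction <= 1.0:
            raise ValueError("deadline_fraction must lie in [0, 1]")
        if self.deadline_fraction > 0 and self.deadline is None:
            raise ValueError("deadline_fraction > 0 requires a DeadlineSpec")
        if not 0.0 <= self.abort_rate < 1.0:
            raise ValueError("abort_rate must lie in [0, 1)")

    @property
    def abort_elapsed_s(self) -> float:
        """Time consumed by an aborted trial (blink / broken fixation)."""
        if self.abort_cost_s is not None:
            return self.abort_cost_s
        return self.misc_cancel_s + self.iti_s

    def for_phase(self, phase: str, deadline: DeadlineSpec | None = None) -> "TaskConfig":
        """Phase-specific variant: deadlines on half the trials in Phase II only."""
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        if phase == "II":
            return replace(self, deadline_fraction=0.5, deadline=deadline or self.deadline)
        return replace(self, deadline_fraction=0.0, deadline=None)


@dataclass(frozen=True)
class TrialRecord:
    participant: str
    phase: str
    session: int
    trial_index: int
    coherence: float
    correct_side: str
    has_deadline: bool
    deadline_s: float | None
    choice: str | None
    rt_s: float | None
    outcome: str
    points_delta: int

    def __post_init__(self) -> None:
        errs = self.violations()
        if errs:
            raise TrialValidationError("; ".join(errs))

    def violations(self) -> list[str]:
        errs: list[str] = []
        if self.phase not in PHASES:
            errs.append(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.session < 1:
            errs.append("session must be >= 1")
        if self.trial_index < 1:
            errs.append("trial_index must be >= 1")
        if abs(self.coherence) > 0.512 + 1e-12:
            errs.append("|coherence| must not exceed 0.512")
        if self.correct_side not in SIDES:
            errs.append(f"correct_side must be in {SIDES}")
        if self.outcome not in OUTCOMES:
            errs.append(f"outcome must be in {OUTCOMES}")
        if self.outcome in ("correct", "error"):
            if self.choice not in SIDES:
                errs.append("completed trial requires a choice")
            if self.rt_s is None:
                errs.append("completed trial requires rt_s")
            elif not 0.0 < self.rt_s <= 5.0:
                errs.append("rt_s must lie in (0, 5] for completed trials")
        if self.outcome == "canceled":
            if not self.has_deadline:
                errs.append("canceled trial must carry a deadline")
            if self.rt_s is not None:
                errs.append("canceled trial has no rt_s")
        if self.has_deadline and self.deadline_s is None:
            errs.append("has_deadline requires deadline_s")
        expected = {"correct": 1, "error": -1}.get(self.outcome, 0)
        if self.points_delta != expected:
            errs.append(f"points_delta must be {expected} for outcome {self.outcome}")
        return errs

    @property
    def motion_strength(self) -> float:
        return abs(self.coherence)

    @property
    def completed(self) -> bool:
        return self.outcome in ("correct", "error")


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Tabulate records in the canonical column order."""
    rows = [
        {
            "participant": r.participant,
            "phase": r.phase,
            "session": r.session,
            "trial_index": r.trial_index,
            "coherence": r.coherence,
            "correct_side": r.correct_side,
            "has_deadline": r.has_deadline,
            "deadline_s": r.deadline_s,
            "choice": r.choice,
            "rt_s": r.rt_s,
            "outcome": r.outcome,
            "points_delta": r.points_delta,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(COLUMNS))


def frame_to_records(frame: pd.DataFrame, *, source: str = "<frame>") -> list[TrialRecord]:
    """Convert and validate a trial table; raises listing offending rows."""
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise TrialSchemaError(f"{source}: missing columns {missing}")
    records: list[TrialRecord] = []
    bad: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        def _opt(v):
            return None if pd.isna(v) else float(v)

        choice = None if pd.isna(row.choice) or row.choice in ("", "none") else str(row.choice)
        try:
            rec = TrialRecord(
                participant=str(row.participant),
                phase=str(row.phase),
                session=int(row.session),
                trial_index=int(row.trial_index),
                coherence=float(row.coherence),
                correct_side=str(row.correct_side),
                has_deadline=_parse_bool(row.has_deadline),
                deadline_s=_opt(row.deadline_s),
                choice=choice,
                rt_s=_opt(row.rt_s),
                outcome=str(row.outcome),
                points_delta=int(row.points_delta),
            )
        except (TrialValidationError, ValueError) as exc:
            bad.append(f"row {i + 1}: {exc}")
            continue
        records.append(rec)
    if bad:
        raise TrialValidationError(f"{source}: invalid rows:\n" + "\n".join(bad))
    return records


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("true", "1", "yes")


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read a CSV trial table, validating every row against the invariants."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"participant": str, "phase": str},
                        float_precision="round_trip")
    return frame_to_records(frame, source=str(path))


def write_trials(records: Sequence[TrialRecord], path: str | Path) -> Path:
    """Write records as CSV with deterministic column order.

    Missing values (absent rt, deadline, choice) are written as empty cells.
    """
    path = Path(path)
    frame = records_to_frame(records)
    # shortest round-trip float repr keeps read(write(x)) lossless
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    return path


def filter_standard_trials(records: Iterable[TrialRecord]) -> list[TrialRecord]:
    """Completed (correct/error) trials without a provisional deadline.

    Deadline trials are excluded from model fits because requiring
    RT < deadline truncates the RT distribution; aborted and canceled trials
    carry no usable choice/RT.  Order is preserved.
    """
    return [r for r in records if r.completed and not r.has_deadline]


def points_tally(records: Iterable[TrialRecord]) -> int:
    return sum(r.points_delta for r in records)


def empirical_priors(
    records: Iterable[TrialRecord],
    coherences: Sequence[float] = COHERENCES,
) -> np.ndarray:
    """Per-signed-coherence trial frequencies over the given coherence set."""
    coherences = np.asarray(coherences, dtype=float)
    counts = np.zeros(len(coherences))
    for r in records:
        idx = int(np.argmin(np.abs(coherences - r.coherence)))
        if not math.isclose(coherences[idx], r.coherence, abs_tol=1e-9):
            raise ValueError(f"coherence {r.coherence} not in the coherence set")
        counts[idx] += 1
    if counts.sum() == 0:
        raise ValueError("no records")
    return counts / counts.sum()
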