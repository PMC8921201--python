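"""Data model for percept-report streams and the pre-processing rules applied to them.

A multistability experiment (binocular rivalry or interocular grouping) yields, per
trial, an ordered stream of button-press reports: at every moment the observer holds
one of four buttons for an exclusively horizontal, exclusively vertical, piecemeal, or
superimposed percept.  This module defines the on-disk CSV schema for those streams,
reads and validates them, and applies the standard cleaning rules before any dynamics
analysis:

1. the final response of every trial is dropped (trials end when a button is
   released after the minimum trial duration, so the last report is truncated
   by design and its duration is not interpretable);
2. responses lasting 180 ms or less are dropped as motor noise — they are too
   brief to be deliberate perceptual reports;
3. runs of consecutive identical states created by step 2 are merged into a
   single phase whose duration is the sum of the merged reports (the time
   occupied by the removed short reports is discarded, not re-attributed).

The product is a :class:`CleanTrial`: an ordered list of (state, duration) phases in
which no two adjacent phases share a state and every duration exceeds 180 ms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

#: Reports at or below this duration (seconds) are treated as motor noise.
SHORT_RESPONSE_CUTOFF_S = 0.180

#: Gap/overlap between consecutive reports tolerated before a warning (seconds).
CONTIGUITY_TOL_S = 0.001


class PerceptState(str, Enum):
    """The four principal perceptual states of a rivalry/grouping trial."""

    HORIZONTAL = "H"
    VERTICAL = "V"
    PIECEMEAL = "PM"
    SUPERIMPOSED = "SI"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical state ordering used by every 4x4 matrix in the package.
STATE_ORDER: tuple[PerceptState, ...] = (
    PerceptState.HORIZONTAL,
    PerceptState.VERTICAL,
    PerceptState.PIECEMEAL,
    PerceptState.SUPERIMPOSED,
)

#: The two exclusive percepts jointly form the "exclusive" class.
EXCLUSIVE_STATES: frozenset[PerceptState] = frozenset(
    {PerceptState.HORIZONTAL, PerceptState.VERTICAL}
)

STATE_INDEX = {s: i for i, s in enumerate(STATE_ORDER)}

RESPONSE_COLUMNS = [
    "participant_id",
    "group",
    "paradigm",
    "condition",
    "orientation",
    "trial",
    "state",
    "onset_s",
    "duration_s",
]

META_COLUMNS = ["participant_id", "group", "age", "sex", "aq", "eq"]

AQ_RANGE = (0.0, 50.0)
EQ_RANGE = (0.0, 80.0)


class ResponseParseError(ValueError):
    """A response-stream file violated the schema; the message names the row."""


@dataclass(frozen=True)
class PerceptResponse:
    """One timed button-press report of a perceptual state."""

    state: PerceptState
    onset: float  # seconds, trial-relative
    duration: float  # seconds, > 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.onset) or self.onset < 0:
            raise ValueError(f"onset must be finite and >= 0, got {self.onset}")
        if not math.isfinite(self.duration) or self.duration <= 0:
            raise ValueError(f"duration must be finite and > 0, got {self.duration}")


@dataclass
class Trial:
    """A raw response stream plus its design labels."""

    participant_id: str
    group: str
    paradigm: str
    condition: str
    orientation: str
    trial_index: int
    responses: list[PerceptResponse] = field(default_factory=list)

    def key(self) -> tuple[str, str, str, int]:
        return (self.participant_id, self.paradigm, self.condition, self.trial_index)

    def validate_contiguity(self, strict: bool = False) -> list[str]:
        """Check that reports tile the trial without gaps or overlaps.

        Returns the list of warning messages; in strict mode any discrepancy
        beyond :data:`CONTIGUITY_TOL_S` raises instead.
        """
        problems: list[str] = []
        for a, b in zip(self.responses, self.responses[1:]):
            gap = b.onset - (a.onset + a.duration)
            if abs(gap) > CONTIGUITY_TOL_S:
                kind = "gap" if gap > 0 else "overlap"
                problems.append(
                    f"trial {self.key()}: {kind} of {abs(gap):.4f}s before onset {b.onset:.4f}"
                )
        if problems and strict:
            raise ResponseParseError("; ".join(problems))
        for msg in problems:
            log.warning(msg)
        return problems


@dataclass
class CleanTrial:
    """A pre-processed trial: merged phases with design labels.

    Invariants: no two consecutive phases share a state; every duration exceeds
    the short-response cutoff.  May be empty (e.g. a single-report trial, fully
    consumed by the last-response rule) — an empty clean trial is valid and is
    excluded from aggregation by downstream code.
    """

    participant_id: str
    group: str
    paradigm: str
    condition: str
    orientation: str
    trial_index: int
    phases: list[tuple[PerceptState, float]] = field(default_factory=list)

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def is_empty(self) -> bool:
        return not self.phases

    @property
    def total_time(self) -> float:
        return float(sum(d for _, d in self.phases))

    def states(self) -> list[PerceptState]:
        return [s for s, _ in self.phases]

    def durations(self) -> list[float]:
        return [d for _, d in self.phases]


@dataclass
class ParticipantMeta:
    """Per-participant demographics and questionnaire scores (AQ/EQ)."""

    participant_id: str
    group: str
    age: float | None = None
    sex: str | None = None
    aq: float | None = None
    eq: float | None = None

    def __post_init__(self) -> None:
        if self.aq is not None and not AQ_RANGE[0] <= self.aq <= AQ_RANGE[1]:
            raise ValueError(f"AQ {self.aq} outside instrument range {AQ_RANGE}")
        if self.eq is not None and not EQ_RANGE[0] <= self.eq <= EQ_RANGE[1]:
            raise ValueError(f"EQ {self.eq} outside instrument range {EQ_RANGE}")


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------


def preprocess_trial(
    trial: Trial, cutoff_s: float = SHORT_RESPONSE_CUTOFF_S
) -> CleanTrial:
    """Apply the cleaning rules to one trial.

    Order of operations is fixed: (1) drop the final (truncated) response,
    (2) drop every remaining response with duration <= ``cutoff_s`` (the rule
    is inclusive: a report of exactly 180 ms is removed), (3) merge runs of
    consecutive identical states, summing their durations.  Time occupied by
    removed short responses is discarded.
    """
    kept = trial.responses[:-1]  # rule 1: last response has no valid duration
    kept = [r for r in kept if r.duration > cutoff_s]  # rule 2: <= cutoff out
    phases: list[tuple[PerceptState, float]] = []
    for r in kept:  # rule 3: merge same-state runs
        if phases and phases[-1][0] == r.state:
            phases[-1] = (r.state, phases[-1][1] + r.duration)
        else:
            phases.append((r.state, r.duration))
    clean = CleanTrial(
        participant_id=trial.participant_id,
        group=trial.group,
        paradigm=trial.paradigm,
        condition=trial.condition,
        orientation=trial.orientation,
        trial_index=trial.trial_index,
        phases=phases,
    )
    if clean.is_empty:
        log.info("trial %s empty after pre-processing", trial.key())
    return clean


def preprocess_trials(
    trials: Iterable[Trial], cutoff_s: float = SHORT_RESPONSE_CUTOFF_S
) -> list[CleanTrial]:
    return [preprocess_trial(t, cutoff_s) for t in trials]


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

_STATE_LABELS = {s.value: s for s in PerceptState}


def read_responses(path: str | Path, strict: bool = False) -> list[Trial]:
    """Read a response-stream CSV into trials.

    Rows are grouped into trials by (participant, paradigm, condition, trial)
    and ordered by onset within each trial.  Schema violations raise
    :class:`ResponseParseError` naming the offending row (1-based, counting
    the header as row 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"participant_id": str, "condition": str})
    except Exception as exc:  # malformed CSV as a whole
        raise ResponseParseError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ResponseParseError(f"{path}: missing column(s) {missing}")

    trials: dict[tuple, Trial] = {}
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # header is row 1
        state_label = str(row["state"])
        if state_label not in _STATE_LABELS:
            raise ResponseParseError(
                f"{path} row {rownum}: unknown state label {state_label!r} "
                f"(expected one of {sorted(_STATE_LABELS)})"
            )
        try:
            resp = PerceptResponse(
                state=_STATE_LABELS[state_label],
                onset=float(row["onset_s"]),
                duration=float(row["duration_s"]),
            )
        except (TypeError, ValueError) as exc:
            raise ResponseParseError(f"{path} row {rownum}: {exc}") from exc
        try:
            trial_index = int(row["trial"])
        except (TypeError, ValueError) as exc:
            raise ResponseParseError(
                f"{path} row {rownum}: bad trial index {row['trial']!r}"
            ) from exc
        key = (str(row["participant_id"]), str(row["paradigm"]),
               str(row["condition"]), trial_index)
        if key not in trials:
            trials[key] = Trial(
                participant_id=key[0],
                group=str(row["group"]),
                paradigm=key[1],
                condition=key[2],
                orientation=str(row["orientation"]),
                trial_index=key[3],
            )
        trials[key].responses.append(resp)

    out = []
    for t in trials.values():
        t.responses.sort(key=lambda r: r.onset)
        t.validate_contiguity(strict=strict)
        out.append(t)
    out.sort(key=lambda t: t.key())
    return out


def trials_to_frame(trials: Iterable[Trial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        for r in t.responses:
            rows.append(
                {
                    "participant_id": t.participant_id,
                    "group": t.group,
                    "paradigm": t.paradigm,
                    "condition": t.condition,
                    "orientation": t.orientation,
                    "trial": t.trial_index,
                    "state": r.state.value,
                    "onset_s": r.onset,
                    "duration_s": r.duration,
                }
            )
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def write_responses(trials: Iterable[Trial], path: str | Path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def clean_trials_to_frame(cleans: Iterable[CleanTrial]) -> pd.DataFrame:
    rows = []
    for c in cleans:
        for i, (s, d) in enumerate(c.phases):
            rows.append(
                {
                    "participant_id": c.participant_id,
                    "group": c.group,
                    "paradigm": c.paradigm,
                    "condition": c.condition,
                    "orientation": c.orientation,
                    "trial": c.trial_index,
                    "phase_index": i,
                    "state": s.value,
                    "duration_s": d,
                }
            )
    cols = ["participant_id", "group", "paradigm", "condition", "orientation",
            "trial", "phase_index", "state", "duration_s"]
    return pd.DataFrame(rows, columns=cols)


def frame_to_clean_trials(df: pd.DataFrame) -> list[CleanTrial]:
    cleans: dict[tuple, CleanTrial] = {}
    for _, row in df.sort_values(["participant_id", "paradigm", "condition",
                                  "trial", "phase_index"]).iterrows():
        key = (str(row["participant_id"]), str(row["paradigm"]),
               str(row["condition"]), int(row["trial"]))
        if key not in cleans:
            cleans[key] = CleanTrial(
                participant_id=key[0],
                group=str(row["group"]),
                paradigm=key[1],
                condition=key[2],
                orientation=str(row["orientation"]),
                trial_index=key[3],
            )
        cleans[key].phases.append(
            (_STATE_LABELS[str(row["state"])], float(row["duration_s"]))
        )
    return sorted(cleans.values(), key=lambda c: (c.participant_id, c.paradigm,
                                                  c.condition, c.trial_index))


def read_clean_trials(path: str | Path) -> list[CleanTrial]:
    return frame_to_clean_trials(pd.read_csv(path, dtype={"participant_id": str,
                                                          "condition": str}))


def write_clean_trials(cleans: Iterable[CleanTrial], path: str | Path) -> None:
    clean_trials_to_frame(cleans).to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the participant-metadata CSV; validates score ranges, allows missing."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ResponseParseError(f"{path}: missing column(s) {missing}")
    for col, (lo, hi) in (("aq", AQ_RANGE), ("eq", EQ_RANGE)):
        vals = df[col].dropna()
        bad = vals[(vals < lo) | (vals > hi)]
        if len(bad):
            raise ResponseParseError(
                f"{path}: {col} values outside [{lo}, {hi}]: {bad.tolist()}"
            )
        n_missing = df[col].isna().sum()
        if n_missing:
            log.warning("%s: %d participants missing %s", path, n_missing, col.upper())
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
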