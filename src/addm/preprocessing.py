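"""Trial/fixation table I/O, fixation-stream cleaning, and proximity coding.

A trial couples the two stimulus angular distances (``delta``, degrees from
the target orientation, in 5° steps between −15° and +15°) with an ordered
stream of gaze events and the behavioural outcome (choice, reaction time).
Raw gaze events carry one of three locations: ``left``/``right`` item
fixations, or ``blank`` for gaze anywhere else.

Cleaning applies three rules to the blank events:

* trials whose blank time exceeds half the reaction time are discarded;
* a blank sandwiched between two fixations on the *same* item is treated as
  a blink/tracker dropout and absorbed into a single fixation on that item;
* a blank between fixations on *different* items is kept and interpreted as
  an inter-fixation transition (drift-free time in the model).

Leading blank time before the first item fixation is the trial latency;
trailing blank time after the last item fixation is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "RawEvent",
    "Trial",
    "CleanResult",
    "relative_proximity",
    "clean_trial",
    "clean_dataset",
    "read_dataset",
    "write_dataset",
    "VALID_DELTAS",
]

#: Allowed angular distances (degrees) between a stimulus and the target.
VALID_DELTAS = (-15, -10, -5, 0, 5, 10, 15)

_LOCATIONS = ("left", "right", "blank")


@dataclass(frozen=True)
class RawEvent:
    """One gaze event: a fixation on an item or a blank interval."""

    location: str  # "left" | "right" | "blank"
    duration: int  # milliseconds, > 0

    def __post_init__(self) -> None:
        if self.location not in _LOCATIONS:
            raise ValueError(f"unknown event location {self.location!r}")
        if int(self.duration) != self.duration or self.duration <= 0:
            raise ValueError(f"event duration must be a positive integer ms, got {self.duration!r}")

    @property
    def is_item(self) -> bool:
        return self.location in ("left", "right")


def relative_proximity(delta: int) -> int:
    """Map an angular distance to the relative-proximity scale {0, 1, 2, 3}.

    ``3 - |delta| / 5``: 3 is an orientation equal to the target, 0 is the
    farthest allowed distance (±15°). The map is even in ``delta``.
    """
    if delta not in VALID_DELTAS:
        raise ValueError(f"delta must be one of {VALID_DELTAS}, got {delta!r}")
    return 3 - abs(delta) // 5


@dataclass
class Trial:
    """One two-alternative decision with its gaze-event stream."""

    subject_id: str
    trial_index: int
    delta_left: int
    delta_right: int
    events: list[RawEvent]
    choice: str  # "left" | "right"
    rt: int  # milliseconds
    bias_target: str = "none"  # "left" | "right" | "none" (gaze-manipulation trials)
    timed_out: bool = False

    def __post_init__(self) -> None:
        if self.delta_left == self.delta_right:
            raise ValueError("delta_left and delta_right must differ")
        for d in (self.delta_left, self.delta_right):
            if d not in VALID_DELTAS:
                raise ValueError(f"delta {d!r} outside {VALID_DELTAS}")
        if self.choice not in ("left", "right"):
            raise ValueError(f"choice must be left/right, got {self.choice!r}")
        if self.rt <= 0:
            raise ValueError("rt must be positive")
        if self.bias_target not in ("left", "right", "none"):
            raise ValueError(f"bias_target must be left/right/none, got {self.bias_target!r}")

    @property
    def r_left(self) -> int:
        return relative_proximity(self.delta_left)

    @property
    def r_right(self) -> int:
        return relative_proximity(self.delta_right)

    @property
    def parity(self) -> str:
        """"odd" or "even" by trial index; odd trials are the fitting split."""
        return "odd" if self.trial_index % 2 == 1 else "even"

    @property
    def item_fixations(self) -> list[RawEvent]:
        return [e for e in self.events if e.is_item]

    def net_fixation_time(self) -> int:
        """Total left-fixation ms minus total right-fixation ms."""
        return sum(e.duration for e in self.events if e.location == "left") - sum(
            e.duration for e in self.events if e.location == "right"
        )

    def latency(self) -> int:
        """Blank time preceding the first item fixation."""
        total = 0
        for e in self.events:
            if e.is_item:
                break
            total += e.duration
        return total


@dataclass
class CleanResult:
    events: list[RawEvent]
    keep: bool
    reason: str = ""


def _merge_adjacent(events: list[RawEvent]) -> list[RawEvent]:
    out: list[RawEvent] = []
    for e in events:
        if out and out[-1].location == e.location:
            out[-1] = RawEvent(e.location, out[-1].duration + e.duration)
        else:
            out.append(e)
    return out


def clean_trial(events: Sequence[RawEvent], rt: int) -> CleanResult:
    """Apply the blank-fixation rules to one event stream.

    Returns the cleaned stream and whether the trial should be kept. Blanks
    between same-item fixations are absorbed (no duration cap is imposed);
    blanks between different-item fixations remain in place as transitions;
    trailing blanks are dropped. The stream never gains total duration.
    """
    if not events:
        return CleanResult([], False, "empty event stream")
    if rt <= 0:
        raise ValueError("rt must be positive")

    blank_total = sum(e.duration for e in events if e.location == "blank")
    if blank_total > 0.5 * rt:
        return CleanResult(list(events), False, "blank time exceeds 50% of RT")

    evs = _merge_adjacent(list(events))
    # Absorb blanks strictly between same-item fixations, to a fixed point:
    # each absorption can create new same-item adjacency.
    changed = True
    while changed:
        changed = False
        for i in range(1, len(evs) - 1):
            e = evs[i]
            if (
                e.location == "blank"
                and evs[i - 1].is_item
                and evs[i + 1].location == evs[i - 1].location
            ):
                merged = RawEvent(
                    evs[i - 1].location,
                    evs[i - 1].duration + e.duration + evs[i + 1].duration,
                )
                evs = evs[: i - 1] + [merged] + evs[i + 2 :]
                changed = True
                break
        evs = _merge_adjacent(evs)

    # Drop trailing blanks (only between-fixation blanks are transitions).
    while evs and evs[-1].location == "blank":
        evs.pop()

    if not any(e.is_item for e in evs):
        return CleanResult(evs, False, "no item fixation after cleaning")
    return CleanResult(evs, True)


def clean_dataset(trials: Iterable[Trial]) -> tuple[list[Trial], pd.DataFrame]:
    """Clean every trial; return kept trials plus a log of discarded ones."""
    kept: list[Trial] = []
    log_rows = []
    for t in trials:
        res = clean_trial(t.events, t.rt)
        if res.keep:
            kept.append(replace(t, events=res.events))
        else:
            log_rows.append(
                {"subject_id": t.subject_id, "trial_index": t.trial_index, "reason": res.reason}
            )
    log = pd.DataFrame(log_rows, columns=["subject_id", "trial_index", "reason"])
    return kept, log


# ---------------------------------------------------------------------------
# CSV schema: trials.csv (one row per trial) + fixations.csv (one row per event)

_TRIAL_COLUMNS = [
    "subject_id",
    "trial_index",
    "delta_left",
    "delta_right",
    "choice",
    "rt_ms",
    "parity",
    "bias_target",
    "timed_out",
]
_EVENT_COLUMNS = ["subject_id", "trial_index", "event_index", "location", "duration_ms"]


def write_dataset(trials: Sequence[Trial], trials_path: str | Path, fixations_path: str | Path) -> None:
    """Write the flat trial and event tables (lossless round trip)."""
    trial_rows = []
    event_rows = []
    for t in trials:
        trial_rows.append(
            {
                "subject_id": t.subject_id,
                "trial_index": t.trial_index,
                "delta_left": t.delta_left,
                "delta_right": t.delta_right,
                "choice": t.choice,
                "rt_ms": t.rt,
                "parity": t.parity,
                "bias_target": t.bias_target,
                "timed_out": int(t.timed_out),
            }
        )
        for i, e in enumerate(t.events):
            event_rows.append(
                {
                    "subject_id": t.subject_id,
                    "trial_index": t.trial_index,
                    "event_index": i,
                    "location": e.location,
                    "duration_ms": e.duration,
                }
            )
    pd.DataFrame(trial_rows, columns=_TRIAL_COLUMNS).to_csv(trials_path, index=False)
    pd.DataFrame(event_rows, columns=_EVENT_COLUMNS).to_csv(fixations_path, index=False)


def _parse_int(value, row: int, column: str, path) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ValueError(f"{path}: malformed value {value!r} in column {column!r} at row {row}") from None


def read_dataset(trials_path: str | Path, fixations_path: str | Path) -> list[Trial]:
    """Read the CSV pair back into Trial objects.

    Malformed rows raise ``ValueError`` naming the (0-based data) row.
    """
    tdf = pd.read_csv(trials_path, dtype=str, keep_default_na=False)
    fdf = pd.read_csv(fixations_path, dtype=str, keep_default_na=False)
    for col in _TRIAL_COLUMNS:
        if col not in tdf.columns:
            raise ValueError(f"{trials_path}: missing column {col!r}")
    for col in _EVENT_COLUMNS:
        if col not in fdf.columns:
            raise ValueError(f"{fixations_path}: missing column {col!r}")

    events_by_key: dict[tuple[str, int], list[tuple[int, RawEvent]]] = {}
    for row, rec in enumerate(fdf.itertuples(index=False)):
        loc = rec.location
        if loc not in _LOCATIONS:
            raise ValueError(f"{fixations_path}: unknown location {loc!r} at row {row}")
        dur = _parse_int(rec.duration_ms, row, "duration_ms", fixations_path)
        idx = _parse_int(rec.event_index, row, "event_index", fixations_path)
        tid = _parse_int(rec.trial_index, row, "trial_index", fixations_path)
        events_by_key.setdefault((rec.subject_id, tid), []).append((idx, RawEvent(loc, dur)))

    trials: list[Trial] = []
    for row, rec in enumerate(tdf.itertuples(index=False)):
        tid = _parse_int(rec.trial_index, row, "trial_index", trials_path)
        if rec.choice not in ("left", "right"):
            raise ValueError(f"{trials_path}: unknown choice {rec.choice!r} at row {row}")
        if rec.bias_target not in ("left", "right", "none"):
            raise ValueError(f"{trials_path}: unknown bias_target {rec.bias_target!r} at row {row}")
        evs = [e for _, e in sorted(events_by_key.get((rec.subject_id, tid), []))]
        trials.append(
            Trial(
                subject_id=rec.subject_id,
                trial_index=tid,
                delta_left=_parse_int(rec.delta_left, row, "delta_left", trials_path),
                delta_right=_parse_int(rec.delta_right, row, "delta_right", trials_path),
                events=evs,
                choice=rec.choice,
                rt=_parse_int(rec.rt_ms, row, "rt_ms", trials_path),
                bias_target=rec.bias_target,
                timed_out=bool(_parse_int(rec.timed_out, row, "timed_out", trials_path)),
            )
        )
    return trials
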