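"""Empirical fixation process: duration pools partitioned by fixation class.

Out-of-sample simulation replays the *observed* fixation dynamics rather
than a parametric model: latencies, inter-fixation transitions, and maximal
item-fixation durations are drawn with replacement from pools built from
the data. Item fixations are partitioned into first, second, and other
middle fixations, each keyed by the relative proximity difference
Δr = r_fixated − r_unfixated ∈ {−3, …, +3}; latencies and transitions are
sampled from their own pools without further conditioning.

The final item fixation of every trial is excluded from the pools: it is
truncated by the barrier crossing, so its duration is endogenous and would
bias the simulated process.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocessing import Trial

__all__ = ["FixationPools", "build_pools", "sample_event", "REFERENCE_P_FIRST_LEFT"]

logger = logging.getLogger(__name__)

#: Group-level first-fixation-left probability reported for the task.
REFERENCE_P_FIRST_LEFT = 0.65

_DR_VALUES = tuple(range(-3, 4))
_CLASSES = ("first", "second", "other_middle")


@dataclass
class FixationPools:
    """Duration multisets (ms) for the empirical fixation process."""

    latencies: np.ndarray
    transitions: np.ndarray
    first: dict[int, np.ndarray]
    second: dict[int, np.ndarray]
    other_middle: dict[int, np.ndarray]
    p_first_left: float
    n_trials: int = 0

    def cell(self, kind: str, dr: int | None = None) -> np.ndarray:
        if kind == "latency":
            return self.latencies
        if kind == "transition":
            return self.transitions
        if kind in _CLASSES:
            table = getattr(self, {"first": "first", "second": "second", "other_middle": "other_middle"}[kind])
            if dr is None:
                return np.concatenate([v for v in table.values()]) if table else np.array([], dtype=int)
            return table.get(int(dr), np.array([], dtype=int))
        raise ValueError(f"unknown pool kind {kind!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.latencies:
            rows.append(("latency", "", int(d)))
        for d in self.transitions:
            rows.append(("transition", "", int(d)))
        for kind in _CLASSES:
            for dr, arr in getattr(self, kind).items():
                for d in arr:
                    rows.append((kind, dr, int(d)))
        return pd.DataFrame(rows, columns=["kind", "delta_r", "duration_ms"])

    def save(self, pools_path: str | Path, meta_path: str | Path) -> None:
        self.to_frame().to_csv(pools_path, index=False)
        Path(meta_path).write_text(f"p_first_left={self.p_first_left}\nn_trials={self.n_trials}\n")

    @classmethod
    def load(cls, pools_path: str | Path, meta_path: str | Path) -> "FixationPools":
        df = pd.read_csv(pools_path, keep_default_na=False)
        meta = dict(
            line.split("=", 1) for line in Path(meta_path).read_text().splitlines() if "=" in line
        )
        tables: dict[str, dict[int, list[int]]] = {k: {} for k in _CLASSES}
        lat: list[int] = []
        trans: list[int] = []
        for rec in df.itertuples(index=False):
            if rec.kind == "latency":
                lat.append(int(rec.duration_ms))
            elif rec.kind == "transition":
                trans.append(int(rec.duration_ms))
            else:
                tables[rec.kind].setdefault(int(rec.delta_r), []).append(int(rec.duration_ms))
        return cls(
            latencies=np.asarray(lat, dtype=int),
            transitions=np.asarray(trans, dtype=int),
            first={k: np.asarray(v, dtype=int) for k, v in tables["first"].items()},
            second={k: np.asarray(v, dtype=int) for k, v in tables["second"].items()},
            other_middle={k: np.asarray(v, dtype=int) for k, v in tables["other_middle"].items()},
            p_first_left=float(meta["p_first_left"]),
            n_trials=int(meta.get("n_trials", 0)),
        )


def build_pools(trials: Sequence[Trial]) -> FixationPools:
    """Build the empirical pools from cleaned trials.

    Latency = blank time before the first item fixation; transitions =
    blank time between item fixations; item fixations minus each trial's
    final one go to first/second/other-middle cells keyed by the fixated
    item's Δr. ``p_first_left`` is the fraction of trials whose first item
    fixation is to the left item.
    """
    if not trials:
        raise ValueError("cannot build pools from an empty trial list")

    latencies: list[int] = []
    transitions: list[int] = []
    tables: dict[str, dict[int, list[int]]] = {k: {dr: [] for dr in _DR_VALUES} for k in _CLASSES}
    n_first_left = 0
    n_with_fix = 0

    for t in trials:
        item_positions = [i for i, e in enumerate(t.events) if e.is_item]
        if not item_positions:
            continue
        n_with_fix += 1
        first_pos = item_positions[0]
        lat = sum(t.events[i].duration for i in range(first_pos))
        if lat > 0:
            latencies.append(lat)
        if t.events[first_pos].location == "left":
            n_first_left += 1
        for i, e in enumerate(t.events):
            if e.location == "blank" and i > first_pos:
                transitions.append(e.duration)
        # exclude the trial's final (truncated) item fixation
        for ordinal, pos in enumerate(item_positions[:-1]):
            e = t.events[pos]
            if e.location == "left":
                dr = t.r_left - t.r_right
            else:
                dr = t.r_right - t.r_left
            cls = "first" if ordinal == 0 else ("second" if ordinal == 1 else "other_middle")
            tables[cls][dr].append(e.duration)

    if n_with_fix == 0:
        raise ValueError("no trial contains an item fixation")

    return FixationPools(
        latencies=np.asarray(latencies, dtype=int),
        transitions=np.asarray(transitions, dtype=int),
        first={dr: np.asarray(v, dtype=int) for dr, v in tables["first"].items() if v},
        second={dr: np.asarray(v, dtype=int) for dr, v in tables["second"].items() if v},
        other_middle={dr: np.asarray(v, dtype=int) for dr, v in tables["other_middle"].items() if v},
        p_first_left=n_first_left / n_with_fix,
        n_trials=n_with_fix,
    )


def resolve_cell(pools: FixationPools, kind: str, dr: int | None = None) -> np.ndarray:
    """Return the sampling cell, applying the empty-cell fallback chain.

    (class, Δr) → (class pooled over Δr) → (other_middle pooled). Each
    fallback is logged; an exhausted chain raises.
    """
    cell = pools.cell(kind, dr)
    if cell.size:
        return cell
    if kind in _CLASSES and dr is not None:
        pooled = pools.cell(kind, None)
        if pooled.size:
            logger.warning("empty pool cell (%s, %+d); falling back to pooled %s", kind, dr, kind)
            return pooled
    if kind != "other_middle":
        pooled = pools.cell("other_middle", None)
        if pooled.size:
            logger.warning("empty pool %s; falling back to pooled other_middle", kind)
            return pooled
    raise ValueError(f"no durations available for pool ({kind}, {dr})")


def sample_event(
    pools: FixationPools,
    kind: str,
    dr: int | None = None,
    rng: np.random.Generator | None = None,
) -> int:
    """Uniform draw with replacement from the designated pool cell."""
    rng = rng if rng is not None else np.random.default_rng()
    cell = resolve_cell(pools, kind, dr)
    return int(cell[rng.integers(cell.size)])
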