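"""Out-of-sample simulation with empirical fixation pools.

Condition-level simulation replays the model's assumed fixation process:
a sampled latency (noise only), then item fixations alternating between
sides — the first to the left with probability ``p_first_left`` — with
durations drawn from the first/second/other-middle pools conditioned on
Δr = r_fixated − r_unfixated, separated by sampled inter-fixation
transitions. A run ends when the RDV crosses a barrier; runs that cross
during a transition can be discarded and redrawn (their count is kept).

Three out-of-sample prediction exercises are provided, all based on a bank
of simulations per (r_left, r_right) pair:

* unconditional — sample (choice, RT) given the stimuli only (the DDM
  comparison: fixations carry no information when θ = 1);
* conditional on net fixation time — sample from bank runs whose simulated
  net fixation time is nearest the trial's observed value;
* conditional on the fixation path — re-run the model driving it with the
  trial's realized fixations, sampling further fixations from the pools if
  no barrier is crossed by the observed RT.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .model import DT_MS, ModelParams, TrialOutcome, drift
from .pools import FixationPools, resolve_cell
from .preprocessing import VALID_DELTAS, RawEvent, Trial, relative_proximity

__all__ = [
    "all_conditions",
    "all_r_pairs",
    "ConditionSpec",
    "SimulatedTrialSet",
    "simulate_condition",
    "outcomes_to_trials",
    "PredictionBank",
    "predict_unconditional",
    "predict_conditional_net_fixation",
    "predict_conditional_path",
    "evaluate_predictions",
]

logger = logging.getLogger(__name__)

_KIND_LAT, _KIND_FIX, _KIND_TRANS = 0, 1, 2


def all_conditions() -> list[tuple[int, int]]:
    """The 42 (delta_left, delta_right) stimulus conditions (Δs differ)."""
    return [(dl, dr) for dl in VALID_DELTAS for dr in VALID_DELTAS if dl != dr]


def all_r_pairs() -> list[tuple[int, int]]:
    """Distinct (r_left, r_right) pairs reachable from the 42 conditions."""
    return sorted({(relative_proximity(dl), relative_proximity(dr)) for dl, dr in all_conditions()})


@dataclass(frozen=True)
class ConditionSpec:
    delta_left: int
    delta_right: int
    n_sims: int = 400

    def __post_init__(self) -> None:
        if self.delta_left == self.delta_right:
            raise ValueError("delta_left and delta_right must differ")

    @property
    def r_left(self) -> int:
        return relative_proximity(self.delta_left)

    @property
    def r_right(self) -> int:
        return relative_proximity(self.delta_right)


@dataclass
class SimulatedTrialSet:
    condition: ConditionSpec
    outcomes: list[TrialOutcome]
    n_discarded_on_transition: int


class _Cells:
    """Resolved pool cells, in 10 ms bins, for one (r_left, r_right) pair."""

    def __init__(self, pools: FixationPools, r_left: int, r_right: int):
        dr_l = r_left - r_right
        dr_r = r_right - r_left

        def bins(arr: np.ndarray, minimum: int) -> np.ndarray:
            if arr.size == 0:
                return arr.astype(int)
            return np.maximum(arr // DT_MS, minimum).astype(int)

        # Empty latency/transition pools mean "no such periods in the data":
        # treated as zero duration rather than routed through the fixation
        # fallback chain.
        self.latency = bins(pools.latencies, 0)
        self.transition = bins(pools.transitions, 0)
        self.fix = {
            (0, 0): bins(resolve_cell(pools, "first", dr_l), 1),
            (0, 1): bins(resolve_cell(pools, "first", dr_r), 1),
            (1, 0): bins(resolve_cell(pools, "second", dr_l), 1),
            (1, 1): bins(resolve_cell(pools, "second", dr_r), 1),
            (2, 0): bins(resolve_cell(pools, "other_middle", dr_l), 1),
            (2, 1): bins(resolve_cell(pools, "other_middle", dr_r), 1),
        }

    def draw(self, kind: str, m: int, rng: np.random.Generator, cls: int = 0, side: int = 0) -> np.ndarray:
        cell = {"latency": self.latency, "transition": self.transition}.get(kind)
        if cell is None:
            cell = self.fix[(cls, side)]
        if cell.size == 0:
            return np.zeros(m, dtype=int)
        return cell[rng.integers(cell.size, size=m)]


@dataclass
class _Batch:
    choice_left: np.ndarray
    rt_ms: np.ndarray
    net_ms: np.ndarray
    discarded: np.ndarray  # crossed during latency/transition
    censored: np.ndarray
    events: list[list[RawEvent]] | None


def _sim_batch(
    params: ModelParams,
    r_left: int,
    r_right: int,
    cells: _Cells,
    n: int,
    rng: np.random.Generator,
    p_first_left: float,
    max_steps: int,
    store_events: bool,
) -> _Batch:
    mu_left = drift(params, r_left, r_right, "left_fixation")
    mu_right = drift(params, r_left, r_right, "right_fixation")
    sigma = params.sigma

    rdv = np.zeros(n)
    steps = np.zeros(n, dtype=int)
    net = np.zeros(n, dtype=int)
    kind = np.full(n, _KIND_LAT, dtype=int)
    side = np.zeros(n, dtype=int)  # 0 left, 1 right; valid during fixations
    ordinal = np.zeros(n, dtype=int)  # fixations started so far
    rem = cells.draw("latency", n, rng)
    ev_used = np.zeros(n, dtype=int)

    finished = np.zeros(n, dtype=bool)
    choice_left = np.zeros(n, dtype=bool)
    rt_ms = np.zeros(n, dtype=int)
    net_ms = np.zeros(n, dtype=int)
    discarded = np.zeros(n, dtype=bool)
    censored = np.zeros(n, dtype=bool)
    events: list[list[RawEvent]] | None = [[] for _ in range(n)] if store_events else None

    def record_event(i: int) -> None:
        if events is not None and ev_used[i] > 0:
            loc = ("left", "right")[side[i]] if kind[i] == _KIND_FIX else "blank"
            events[i].append(RawEvent(loc, int(ev_used[i]) * DT_MS))

    def advance(idx: np.ndarray) -> None:
        """Move runs whose current event is exhausted to their next event."""
        while idx.size:
            if events is not None:
                for i in idx:
                    record_event(i)
            to_fix = idx[kind[idx] != _KIND_FIX]
            to_trans = idx[kind[idx] == _KIND_FIX]
            if to_trans.size:
                kind[to_trans] = _KIND_TRANS
                rem[to_trans] = cells.draw("transition", to_trans.size, rng)
                ev_used[to_trans] = 0
            if to_fix.size:
                first = to_fix[ordinal[to_fix] == 0]
                later = to_fix[ordinal[to_fix] > 0]
                if first.size:
                    side[first] = (rng.random(first.size) >= p_first_left).astype(int)
                if later.size:
                    side[later] = 1 - side[later]
                cls_of = np.minimum(ordinal[to_fix], 2)
                for cls in (0, 1, 2):
                    for sd in (0, 1):
                        grp = to_fix[(cls_of == cls) & (side[to_fix] == sd)]
                        if grp.size:
                            rem[grp] = cells.draw("fix", grp.size, rng, cls=cls, side=sd)
                kind[to_fix] = _KIND_FIX
                ordinal[to_fix] += 1
                ev_used[to_fix] = 0
            idx = idx[rem[idx] == 0]

    advance(np.flatnonzero(rem == 0))

    while True:
        act = np.flatnonzero(~finished)
        if act.size == 0:
            break
        z = rng.standard_normal(act.size)
        is_fix = kind[act] == _KIND_FIX
        mu = np.where(is_fix, np.where(side[act] == 0, mu_left, mu_right), 0.0)
        rdv[act] += mu + sigma * z
        steps[act] += 1
        ev_used[act] += 1
        net[act] += np.where(is_fix, np.where(side[act] == 0, DT_MS, -DT_MS), 0)

        crossed = act[np.abs(rdv[act]) >= 1.0]
        over = act[(np.abs(rdv[act]) < 1.0) & (steps[act] >= max_steps)]
        if events is not None:
            for i in crossed:
                record_event(i)
        finished[crossed] = True
        choice_left[crossed] = rdv[crossed] >= 1.0
        rt_ms[crossed] = steps[crossed] * DT_MS
        net_ms[crossed] = net[crossed]
        discarded[crossed] = kind[crossed] != _KIND_FIX
        if over.size:
            for i in over:
                record_event(i)
            finished[over] = True
            censored[over] = True
            choice_left[over] = rdv[over] >= 0.0
            rt_ms[over] = steps[over] * DT_MS
            net_ms[over] = net[over]

        live = act[~finished[act]]
        rem[live] -= 1
        advance(live[rem[live] == 0])

    return _Batch(choice_left, rt_ms, net_ms, discarded, censored, events)


def simulate_condition(
    params: ModelParams,
    pools: FixationPools,
    condition: ConditionSpec | tuple[int, int],
    n_sims: int | None = None,
    discard_transition_end: bool = True,
    rng: np.random.Generator | int | None = None,
    p_first_left: float | None = None,
    max_steps: int = 20_000,
    store_events: bool = True,
) -> SimulatedTrialSet:
    """Simulate one stimulus condition with pool-sampled fixations.

    With ``discard_transition_end`` the retained outcome count is exactly
    ``n_sims``: runs that terminate during a latency or transition are
    discarded (counted) and fresh runs drawn in their place.
    """
    if not isinstance(condition, ConditionSpec):
        condition = ConditionSpec(*condition, n_sims=n_sims or 400)
    n_target = n_sims if n_sims is not None else condition.n_sims
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p_first = pools.p_first_left if p_first_left is None else p_first_left
    cells = _Cells(pools, condition.r_left, condition.r_right)

    outcomes: list[TrialOutcome] = []
    n_discarded = 0
    n_needed = n_target
    for _round in range(200):
        batch = _sim_batch(
            params, condition.r_left, condition.r_right, cells, n_needed, rng,
            p_first, max_steps, store_events,
        )
        for i in range(n_needed):
            if discard_transition_end and batch.discarded[i] and not batch.censored[i]:
                n_discarded += 1
                continue
            outcomes.append(
                TrialOutcome(
                    choice="left" if batch.choice_left[i] else "right",
                    rt=int(batch.rt_ms[i]),
                    events=batch.events[i] if batch.events is not None else [],
                    ended_on_none=bool(batch.discarded[i]),
                    censored=bool(batch.censored[i]),
                )
            )
        n_needed = n_target - len(outcomes)
        if n_needed <= 0:
            break
    else:
        raise RuntimeError("could not accumulate the requested simulations (discard rate too high)")

    frac = n_discarded / max(n_discarded + n_target, 1)
    if frac > 0.5:
        warnings.warn(f"{frac:.0%} of simulated runs ended on a transition and were discarded")
    return SimulatedTrialSet(condition, outcomes, n_discarded)


def outcomes_to_trials(
    outcomes: Sequence[TrialOutcome],
    delta_left: int,
    delta_right: int,
    subject_id: str = "sim",
    start_index: int = 0,
) -> list[Trial]:
    """Wrap simulated outcomes in the shared Trial representation."""
    trials = []
    for k, o in enumerate(outcomes):
        trials.append(
            Trial(
                subject_id=subject_id,
                trial_index=start_index + k,
                delta_left=delta_left,
                delta_right=delta_right,
                events=list(o.events),
                choice=o.choice,
                rt=max(o.rt, DT_MS),
                timed_out=o.censored,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# Prediction banks and the three prediction exercises


@dataclass
class _BankEntry:
    choice_left: np.ndarray
    rt_ms: np.ndarray
    net_ms: np.ndarray
    net_order: np.ndarray  # argsort of net_ms


class PredictionBank:
    """Per-(r_left, r_right) banks of simulated (choice, RT, net time)."""

    def __init__(self, entries: dict[tuple[int, int], _BankEntry], n_bank: int):
        self.entries = entries
        self.n_bank = n_bank

    @classmethod
    def build(
        cls,
        params: ModelParams,
        pools: FixationPools,
        n_bank: int = 100_000,
        rng: np.random.Generator | int | None = None,
        r_pairs: Sequence[tuple[int, int]] | None = None,
        p_first_left: float | None = None,
        max_steps: int = 20_000,
    ) -> "PredictionBank":
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        p_first = pools.p_first_left if p_first_left is None else p_first_left
        entries: dict[tuple[int, int], _BankEntry] = {}
        for rl, rr in (r_pairs or all_r_pairs()):
            cells = _Cells(pools, rl, rr)
            batch = _sim_batch(params, rl, rr, cells, n_bank, rng, p_first, max_steps, False)
            keep = ~batch.censored
            net = batch.net_ms[keep]
            entries[(rl, rr)] = _BankEntry(
                choice_left=batch.choice_left[keep],
                rt_ms=batch.rt_ms[keep],
                net_ms=net,
                net_order=np.argsort(net, kind="stable"),
            )
        return cls(entries, n_bank)

    def entry(self, trial: Trial) -> _BankEntry:
        key = (trial.r_left, trial.r_right)
        e = self.entries.get(key)
        if e is None or e.choice_left.size == 0:
            raise ValueError(f"no bank entries for stimuli {key}")
        return e


def predict_unconditional(
    bank: PredictionBank, trial: Trial, rng: np.random.Generator | int | None = None
) -> tuple[str, int]:
    """Sample (choice, RT) conditional on the stimuli only."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    e = bank.entry(trial)
    i = rng.integers(e.choice_left.size)
    return ("left" if e.choice_left[i] else "right", int(e.rt_ms[i]))


def predict_conditional_net_fixation(
    bank: PredictionBank,
    trial: Trial,
    rng: np.random.Generator | int | None = None,
    window_ms: float = 100.0,
    min_candidates: int = 50,
) -> tuple[str, int]:
    """Sample (choice, RT) conditional on stimuli and observed net fixation time.

    Bank runs whose net fixation time lies within ``window_ms`` of the
    observed value are candidates; the window doubles until at least
    ``min_candidates`` are available. ``window_ms=inf`` reduces to the
    unconditional prediction.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    e = bank.entry(trial)
    net_obs = trial.net_fixation_time()
    nets_sorted = e.net_ms[e.net_order]
    want = min(min_candidates, nets_sorted.size)
    w = window_ms
    while True:
        if np.isinf(w):
            cand = np.arange(e.choice_left.size)  # identical to the unconditional draw
            break
        lo = np.searchsorted(nets_sorted, net_obs - w, side="left")
        hi = np.searchsorted(nets_sorted, net_obs + w, side="right")
        if hi - lo >= want:
            cand = e.net_order[lo:hi]
            break
        logger.debug("net-fixation window %g ms too narrow (%d hits); doubling", w, hi - lo)
        w *= 2.0
    i = cand[rng.integers(cand.size)]
    return ("left" if e.choice_left[i] else "right", int(e.rt_ms[i]))


def _continuation_events(
    trial: Trial, pools: FixationPools, rng: np.random.Generator
) -> Iterator[RawEvent]:
    """Observed cleaned events, then pool-sampled alternation if needed."""
    yield from trial.events
    item_fix = trial.item_fixations
    side = item_fix[-1].location if item_fix else ("left" if rng.random() < pools.p_first_left else "right")
    ordinal = len(item_fix)
    while True:
        trans = pools.transitions
        if trans.size:
            yield RawEvent("blank", int(trans[rng.integers(trans.size)]))
        side = "right" if side == "left" else "left"
        dr = (trial.r_left - trial.r_right) if side == "left" else (trial.r_right - trial.r_left)
        cls = "first" if ordinal == 0 else ("second" if ordinal == 1 else "other_middle")
        cell = resolve_cell(pools, cls, dr)
        yield RawEvent(side, max(int(cell[rng.integers(cell.size)]), DT_MS))
        ordinal += 1


def predict_conditional_path(
    params: ModelParams,
    trial: Trial,
    pools: FixationPools,
    rng: np.random.Generator | int | None = None,
    max_steps: int = 20_000,
) -> tuple[str, int]:
    """Sample (choice, RT) by replaying the trial's fixation path.

    The model is driven by the trial's realized events; if no barrier is
    crossed by the observed RT, additional alternating fixations are
    sampled from the pools until one is.
    """
    from .model import simulate_trial  # local import to avoid cycle at module load

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    source = _continuation_events(trial, pools, rng)
    out = simulate_trial(params, trial.r_left, trial.r_right, source, rng, max_steps=max_steps)
    return (out.choice, out.rt)


def evaluate_predictions(
    trials: Sequence[Trial], predictions: Sequence[tuple[str, int]]
) -> dict[str, float]:
    """Choice prediction accuracy (%) and mean absolute RT error (s)."""
    if len(trials) != len(predictions):
        raise ValueError("trials and predictions must align")
    hits = sum(t.choice == p[0] for t, p in zip(trials, predictions))
    mae = float(np.mean([abs(t.rt - p[1]) for t, p in zip(trials, predictions)])) / 1000.0
    return {"choice_accuracy_pct": 100.0 * hits / len(trials), "rt_mae_s": mae}
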