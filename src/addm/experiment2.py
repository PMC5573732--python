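"""Simulation and analysis of the gaze-manipulation (minimum-exposure) task.

In each trial one item is secretly designated the *bias-target*. It is
shown first; the other item appears after an onset lag. The display ends
("stopping rule") as soon as cumulative exposure reaches 800 ms for the
bias-target and 200 ms for the other item, with a hard cap at 3 s
(timed-out trials are excluded from analysis). The lag is calibrated per
subject by a 3-down/1-up staircase (start 300 ms, step 30 ms, bounds
100–500 ms, 48 trials). The lag itself counts toward the bias-target's
exposure; after the other item's onset, exposure accrues through overt
fixations.

The simulated agent is an aDDM whose fixation stream comes from the
empirical pools but whose first fixation is directed at the bias-target
(covering the lag). The RDV integrates with gaze-gated drift until the
stopping rule fires, is frozen, and the choice is its sign (ties broken at
random); if a barrier is reached early the decision stands. A trial is
*effective* when it did not time out and the bias-target accumulated more
fixation time than the other item.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .analyses import CurveSummary, _binned_curve, contingency_chi2, corrected_choice_probability
from .model import DT_MS, ModelParams, drift
from .pools import FixationPools, resolve_cell
from .preprocessing import RawEvent, Trial
from .simulate import all_conditions

__all__ = [
    "ManipulationConfig",
    "Exp2Trial",
    "stopping_rule",
    "staircase",
    "simulate_exp2",
    "exp2_analysis",
]


@dataclass(frozen=True)
class ManipulationConfig:
    min_bias_ms: int = 800
    min_other_ms: int = 200
    cap_ms: int = 3000
    lag_start_ms: int = 300
    lag_step_ms: int = 30
    lag_min_ms: int = 100
    lag_max_ms: int = 500
    staircase_trials: int = 48

    def __post_init__(self) -> None:
        if not (0 < self.min_other_ms < self.min_bias_ms < self.cap_ms):
            raise ValueError("require 0 < min_other_ms < min_bias_ms < cap_ms")
        if not (self.lag_min_ms <= self.lag_start_ms <= self.lag_max_ms):
            raise ValueError("lag bounds must bracket the starting lag")


@dataclass
class Exp2Trial:
    trial: Trial
    lag_ms: int
    stop_time_ms: int
    effective: bool
    timed_out: bool
    rdv_at_stop: float = math.nan


def _exposures(
    events: Sequence[RawEvent], bias_side: str, lag_ms: int, until_ms: int | None = None
) -> tuple[float, float]:
    """Cumulative (bias, other) exposure credit up to ``until_ms``.

    Time 0 is bias-target onset. During [0, lag) the bias-target accrues
    display credit regardless of the event labels; afterwards credit is
    fixation-based.
    """
    t = 0
    bias = 0.0
    other = 0.0
    horizon = math.inf if until_ms is None else until_ms
    for e in events:
        if t >= horizon:
            break
        seg = min(e.duration, horizon - t)
        start, end = t, t + seg
        pre = max(0.0, min(end, lag_ms) - start)  # lag portion: display credit to bias
        post = seg - pre
        bias += pre
        if post > 0 and e.is_item:
            if e.location == bias_side:
                bias += post
            else:
                other += post
        t = end
    return bias, other


def stopping_rule(
    events: Sequence[RawEvent],
    bias_side: str,
    lag_ms: int,
    config: ManipulationConfig = ManipulationConfig(),
) -> tuple[int, bool]:
    """Earliest time both minimum exposures are met, or the cap.

    Returns ``(stop_time_ms, timed_out)``. Exposure is monotone in time, so
    the stop is the later of the two first-crossing times; if either
    requirement is unmet by the cap the trial times out at the cap.
    """

    def first_crossing(target: str, need: float) -> float:
        t = 0.0
        acc = 0.0
        for e in events:
            # accrual rate within this event, split at the lag boundary
            for seg_start, seg_end in ((t, min(t + e.duration, lag_ms)), (max(t, lag_ms), t + e.duration)):
                if seg_end <= seg_start:
                    continue
                in_lag = seg_end <= lag_ms
                if in_lag:
                    rate = 1.0 if target == "bias" else 0.0
                else:
                    if e.is_item and ((e.location == bias_side) == (target == "bias")):
                        rate = 1.0
                    else:
                        rate = 0.0
                if rate > 0:
                    if acc + (seg_end - seg_start) >= need:
                        return seg_start + (need - acc)
                    acc += seg_end - seg_start
            t += e.duration
        return math.inf

    t_bias = first_crossing("bias", config.min_bias_ms)
    t_other = first_crossing("other", config.min_other_ms)
    stop = max(t_bias, t_other)
    if stop > config.cap_ms:
        return config.cap_ms, True
    return int(round(stop)), False


def staircase(
    effective_flags: Sequence[bool], config: ManipulationConfig = ManipulationConfig()
) -> tuple[int, list[int]]:
    """3-down/1-up onset-lag staircase.

    After 3 consecutive effective trials the lag decreases one step; after
    any ineffective trial it increases one step; the consecutive counter
    resets on each decrease and on any ineffective trial. Returns the lag
    in force at the final staircase trial, plus the per-trial trajectory.
    """
    lag = config.lag_start_ms
    run = 0
    trajectory: list[int] = []
    for flag in list(effective_flags)[: config.staircase_trials]:
        trajectory.append(lag)
        if flag:
            run += 1
            if run == 3:
                lag = max(config.lag_min_ms, lag - config.lag_step_ms)
                run = 0
        else:
            lag = min(config.lag_max_ms, lag + config.lag_step_ms)
            run = 0
    final = trajectory[-1] if trajectory else lag
    return final, trajectory


def _exp2_event_stream(
    bias_side: str,
    lag_bins: int,
    dr_bias: int,
    pools: FixationPools,
    rng: np.random.Generator,
    total_bins: int,
) -> list[RawEvent]:
    """Fixation stream for one manipulation trial, covering ``total_bins``.

    The first fixation is to the bias-target and covers at least the onset
    lag (the agent is looking at the only item on screen); fixations then
    alternate, separated by sampled transitions.
    """
    other_side = "right" if bias_side == "left" else "left"
    events: list[RawEvent] = []
    first_cell = resolve_cell(pools, "first", dr_bias)
    first_bins = max(int(first_cell[rng.integers(first_cell.size)]) // DT_MS, 1)
    events.append(RawEvent(bias_side, (lag_bins + first_bins) * DT_MS))
    covered = lag_bins + first_bins
    side = bias_side
    ordinal = 2  # next fixation is the second one
    while covered < total_bins:
        if pools.transitions.size:
            tb = int(pools.transitions[rng.integers(pools.transitions.size)]) // DT_MS
            if tb > 0:
                events.append(RawEvent("blank", tb * DT_MS))
                covered += tb
        side = other_side if side == bias_side else bias_side
        dr = dr_bias if side == bias_side else -dr_bias
        cls = "second" if ordinal == 2 else "other_middle"
        cell = resolve_cell(pools, cls, dr)
        fb = max(int(cell[rng.integers(cell.size)]) // DT_MS, 1)
        events.append(RawEvent(side, fb * DT_MS))
        covered += fb
        ordinal += 1
    return events


def simulate_exp2(
    params: ModelParams,
    pools: FixationPools,
    config: ManipulationConfig = ManipulationConfig(),
    n_trials: int = 5000,
    rng: np.random.Generator | int | None = None,
    lag_ms: int | None = None,
    subject_id: str = "sim2",
    conditions: Sequence[tuple[int, int]] | None = None,
) -> list[Exp2Trial]:
    """Simulate the manipulation protocol with an aDDM agent.

    Stimuli are drawn uniformly from the 42 conditions (or a supplied
    subset, e.g. only the equal-proximity conditions when measuring the
    bias at Δr = 0) and the bias-target side at random. The RDV integrates (gaze-gated drift, absorbing at ±1)
    up to the stopping time; the recorded choice is the sign of the frozen
    RDV, ties uniform at random. Timed-out trials are flagged for
    exclusion, mirroring the task's a-priori discard rule.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lag = config.lag_start_ms if lag_ms is None else lag_ms
    lag_bins = lag // DT_MS
    conditions = list(conditions) if conditions is not None else all_conditions()
    out: list[Exp2Trial] = []
    cap_bins = config.cap_ms // DT_MS + lag_bins + 2

    for k in range(n_trials):
        dl, dr_ = conditions[rng.integers(len(conditions))]
        trial_proto = Trial(
            subject_id=subject_id, trial_index=k, delta_left=dl, delta_right=dr_,
            events=[RawEvent("blank", DT_MS)], choice="left", rt=DT_MS,
        )
        rl, rr = trial_proto.r_left, trial_proto.r_right
        bias_side = "left" if rng.random() < 0.5 else "right"
        dr_bias = (rl - rr) if bias_side == "left" else (rr - rl)
        events = _exp2_event_stream(bias_side, lag_bins, dr_bias, pools, rng, cap_bins)
        stop_ms, timed_out = stopping_rule(events, bias_side, lag, config)
        stop_bins = max(stop_ms // DT_MS, 1)

        # integrate the RDV over the stream up to the stop, absorbing at ±1
        rdv = 0.0
        absorbed = False
        step = 0
        realized: list[RawEvent] = []
        for e in events:
            if step >= stop_bins:
                break
            gaze = {"left": "left_fixation", "right": "right_fixation", "blank": "none"}[e.location]
            mu = drift(params, rl, rr, gaze)
            n_bins = min(e.duration // DT_MS, stop_bins - step)
            used = 0
            for _ in range(n_bins):
                if not absorbed:
                    rdv += mu + params.sigma * rng.standard_normal()
                    if abs(rdv) >= 1.0:
                        absorbed = True
                step += 1
                used += 1
            if used:
                realized.append(RawEvent(e.location, used * DT_MS))

        if rdv > 0:
            choice = "left"
        elif rdv < 0:
            choice = "right"
        else:
            choice = "left" if rng.random() < 0.5 else "right"

        bias_exp, other_exp = _exposures(realized, bias_side, lag, until_ms=stop_ms)
        effective = (not timed_out) and (bias_exp > other_exp)
        trial = replace(
            trial_proto,
            events=realized,
            choice=choice,
            rt=stop_bins * DT_MS,
            bias_target=bias_side,
            timed_out=timed_out,
        )
        out.append(
            Exp2Trial(
                trial=trial, lag_ms=lag, stop_time_ms=stop_ms,
                effective=effective, timed_out=timed_out, rdv_at_stop=rdv,
            )
        )
    return out


@dataclass
class Exp2Report:
    curves: dict[str, CurveSummary]
    corrected_net_time_curve: CurveSummary
    p_choose_bias_at_dr0: float | None
    chi2_at_dr0: float | None
    chi2_p_at_dr0: float | None
    bias_effective: float | None
    bias_ineffective: float | None
    frac_timed_out: float
    frac_effective: float


def _bias_target_curves(records: pd.DataFrame, tag: str) -> dict[str, CurveSummary]:
    curves = {}
    for side in ("left", "right"):
        sub = records[records["bias_target"] == side]
        if len(sub):
            curves[f"p_left_vs_dr_bias_{side}{tag}"] = _binned_curve(
                f"p_left_vs_dr_bias_{side}{tag}", sub["dr"].values, sub["choice_left"].values
            )
    return curves


def exp2_analysis(trials: Sequence[Exp2Trial]) -> Exp2Report:
    """Choice curves by bias-target side and by effective/ineffective split.

    Timed-out trials are excluded. Also reports P(choose bias-target) at
    Δr = 0, a 2×2 choice-by-bias-target contingency χ² at Δr = 0, and the
    bias split by whether the manipulation was effective.
    """
    n_total = len(trials)
    frac_timed_out = sum(t.timed_out for t in trials) / n_total if n_total else math.nan
    kept = [t for t in trials if not t.timed_out]
    if not kept:
        raise ValueError("no analysable trials (all timed out)")
    frac_effective = sum(t.effective for t in kept) / len(kept)

    rec = pd.DataFrame(
        {
            "dr": [t.trial.r_left - t.trial.r_right for t in kept],
            "choice_left": [1.0 if t.trial.choice == "left" else 0.0 for t in kept],
            "bias_target": [t.trial.bias_target for t in kept],
            "effective": [t.effective for t in kept],
            "chose_bias": [1.0 if t.trial.choice == t.trial.bias_target else 0.0 for t in kept],
        }
    )
    curves = _bias_target_curves(rec, "")
    curves.update(_bias_target_curves(rec[rec["effective"]], "_effective"))
    curves.update(_bias_target_curves(rec[~rec["effective"]], "_ineffective"))

    at0 = rec[rec["dr"] == 0]
    p_bias0 = float(at0["chose_bias"].mean()) if len(at0) else None
    chi2 = chi2_p = None
    if len(at0):
        table = pd.crosstab(at0["bias_target"], at0["choice_left"])
        if table.shape == (2, 2) and (table.values > 0).all():
            chi2, chi2_p = contingency_chi2(table.values)

    def _bias(sub: pd.DataFrame) -> float | None:
        s0 = sub[sub["dr"] == 0]
        return float(s0["chose_bias"].mean()) if len(s0) else None

    return Exp2Report(
        curves=curves,
        corrected_net_time_curve=corrected_choice_probability([t.trial for t in kept], "net_time"),
        p_choose_bias_at_dr0=p_bias0,
        chi2_at_dr0=chi2,
        chi2_p_at_dr0=chi2_p,
        bias_effective=_bias(rec[rec["effective"]]),
        bias_ineffective=_bias(rec[~rec["effective"]]),
        frac_timed_out=frac_timed_out,
        frac_effective=frac_effective,
    )
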