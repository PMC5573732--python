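"""The attentional drift-diffusion model (aDDM) generative process.

A relative decision value (RDV) starts at zero and accumulates Gaussian
increments on a 10 ms grid until it is absorbed at +1 (choose left) or −1
(choose right). The mean increment (drift) is gated by gaze: while the left
item is fixated it is ``d * (r_left − θ * r_right)``, while the right item
is fixated ``d * (θ * r_left − r_right)``, and zero before the first item
fixation, during blank fixations, and during inter-fixation transitions.
``θ = 1`` removes the gaze dependence and recovers the standard DDM.

The noise term accrues at the same σ in every regime, including latency and
transitions (configurable via ``noise_in_none``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from .preprocessing import RawEvent

__all__ = ["ModelParams", "TrialOutcome", "drift", "simulate_trial", "trial_rng", "DT_MS"]

#: Width of the simulation / likelihood time step in milliseconds.
DT_MS = 10


@dataclass(frozen=True)
class ModelParams:
    """aDDM parameter vector.

    d
        Drift scale per 10 ms step (> 0).
    theta
        Attentional discount on the unfixated item, in [0, 1]; 1 = DDM.
    sigma
        Standard deviation of the Gaussian increment per 10 ms step (> 0).

    Barriers are fixed at ±1 and the time step at 10 ms: scaling barriers,
    d and σ by a common constant leaves the model's predictions unchanged,
    so these conventions cost no generality.
    """

    d: float
    theta: float
    sigma: float
    noise_in_none: bool = True  # noise accrues during latency/blank/transition

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError("d must be positive")
        if not 0 <= self.theta <= 1:
            raise ValueError("theta must lie in [0, 1]")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass
class TrialOutcome:
    """Result of one forward simulation (last event truncated at crossing)."""

    choice: str  # "left" | "right"
    rt: int  # ms, equals total realized event time
    events: list[RawEvent]
    ended_on_none: bool  # barrier crossed during latency/blank/transition
    censored: bool = False  # step cap reached without crossing
    rdv_path: np.ndarray | None = None  # RDV after each step, if recorded


def drift(params: ModelParams, r_left: int, r_right: int, gaze: str) -> float:
    """Mean RDV increment per 10 ms step under the given gaze regime.

    ``gaze`` is one of ``"left_fixation"``, ``"right_fixation"``, ``"none"``
    (latency, blank fixations, and transitions all map to ``"none"``).
    """
    for r in (r_left, r_right):
        if r not in (0, 1, 2, 3):
            raise ValueError(f"proximity must be in {{0,1,2,3}}, got {r!r}")
    if gaze == "left_fixation":
        return params.d * (r_left - params.theta * r_right)
    if gaze == "right_fixation":
        return params.d * (params.theta * r_left - r_right)
    if gaze == "none":
        return 0.0
    raise ValueError(f"unknown gaze regime {gaze!r}")


def trial_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Per-trial generator derived from a master seed and trial key.

    Using a key sequence keeps single trials reproducible in isolation.
    """
    return np.random.default_rng([int(master_seed) & 0x7FFFFFFF, *map(int, key)])


def _gaze_of(location: str) -> str:
    return {"left": "left_fixation", "right": "right_fixation", "blank": "none"}[location]


def simulate_trial(
    params: ModelParams,
    r_left: int,
    r_right: int,
    fixation_source: Iterator[RawEvent] | Sequence[RawEvent],
    rng: np.random.Generator | int,
    max_steps: int = 20_000,
    record_path: bool = False,
    noise: np.ndarray | None = None,
) -> TrialOutcome:
    """Run the aDDM forward until a barrier crossing.

    ``fixation_source`` yields the intended event stream (a latency blank,
    then alternating item fixations separated by blank transitions); events
    are consumed as needed and the final one is truncated at the crossing
    step. Crossing is evaluated once per 10 ms step, exact hits count, and
    overshoot is not interpolated. If ``noise`` is given it supplies the
    standard-normal increments (for exact mirror/invariance checks);
    otherwise they are drawn from ``rng``.

    Non-terminating runs are cut at ``max_steps`` and returned with
    ``censored=True`` — never silently dropped.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    source = iter(fixation_source)

    rdv = 0.0
    step = 0
    events_out: list[RawEvent] = []
    path: list[float] = [] if record_path else None  # type: ignore[assignment]
    choice = ""
    ended_on_none = False
    censored = False
    done = False

    while not done:
        try:
            event = next(source)
        except StopIteration:
            raise ValueError("fixation_source exhausted before a barrier crossing") from None
        gaze = _gaze_of(event.location)
        mu = drift(params, r_left, r_right, gaze)
        sig = params.sigma if (gaze != "none" or params.noise_in_none) else 0.0
        n_bins = max(1, event.duration // DT_MS)
        used_bins = 0
        for _ in range(n_bins):
            z = noise[step] if noise is not None else rng.standard_normal()
            rdv += mu + sig * z
            step += 1
            used_bins += 1
            if record_path:
                path.append(rdv)
            if abs(rdv) >= 1.0:
                choice = "left" if rdv >= 1.0 else "right"
                ended_on_none = gaze == "none"
                done = True
                break
            if step >= max_steps:
                censored = True
                choice = "left" if rdv >= 0 else "right"
                done = True
                break
        if used_bins > 0:
            events_out.append(RawEvent(event.location, used_bins * DT_MS))

    return TrialOutcome(
        choice=choice,
        rt=step * DT_MS,
        events=events_out,
        ended_on_none=ended_on_none,
        censored=censored,
        rdv_path=np.asarray(path) if record_path else None,
    )
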