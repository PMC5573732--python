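"""Fixation-conditional trial likelihood and iterative grid-refinement MLE.

The likelihood of one trial's (choice, RT) given its observed fixation
stream is computed deterministically by propagating a discretised
probability mass over the RDV state space. States span [−1, +1]; the
endpoints are absorbing barriers. Each 10 ms step applies a Gaussian
transition kernel whose mean is the gaze-gated drift of the current event
and whose sd is σ; mass beyond the barriers is absorbed and accumulated as
choice-at-step probability. The trial's likelihood is the mass absorbed at
the observed RT bin on the chosen side, so the truncation of the final
observed fixation is handled for free.

Interior kernel mass uses midpoint-rule integration of the normal density
and is rescaled so each row's interior + absorbed mass is exactly the true
Gaussian split — mass is conserved to machine precision at every step.

Fitting follows an iterative grid search: evaluate the dataset
log-likelihood on a coarse 3×3×3 grid Ω₁, then repeatedly re-centre a grid
of halved step size on the best point, stopping when the relative
log-likelihood improvement falls below 1%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .model import DT_MS, ModelParams, drift
from .preprocessing import Trial

__all__ = [
    "LikelihoodSettings",
    "FitResult",
    "GridStep",
    "OMEGA1",
    "trial_loglik",
    "dataset_loglik",
    "grid_mle",
    "fit_ddm",
    "PropagationEngine",
    "absorption_profile",
    "trial_regime_bins",
]

logger = logging.getLogger(__name__)

#: Initial coarse parameter grid: cross product of per-parameter sets.
OMEGA1 = {
    "d": (0.001, 0.005, 0.01),
    "theta": (0.1, 0.5, 0.9),
    "sigma": (0.01, 0.05, 0.1),
}

_PARAM_EPS = 1e-6  # positivity floor for d and sigma when refining


@dataclass(frozen=True)
class LikelihoodSettings:
    """Numerical settings for the state-space propagation."""

    n_states: int = 101  # grid points spanning [-1, +1], odd so a state sits at 0
    rt_cap_ms: int = 100_000
    floor_prob: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_states < 11 or self.n_states % 2 == 0:
            raise ValueError("n_states must be an odd integer >= 11")


@dataclass
class GridStep:
    index: int
    grid: list[tuple[float, float, float]]
    best_params: tuple[float, float, float]
    best_loglik: float


@dataclass
class FitResult:
    params: ModelParams
    log_likelihood: float
    trace: list[GridStep]
    converged: bool
    n_steps: int
    final_step_sizes: dict[str, float] = field(default_factory=dict)


class PropagationEngine:
    """Caches transition kernels (and their binary powers) for one σ.

    Kernel layout: index 0 = absorbed at −1 (right choice), 1..n−2 =
    interior states, last = absorbed at +1 (left choice). Row-stochastic:
    ``p_next = p @ K``.
    """

    def __init__(self, sigma: float, settings: LikelihoodSettings):
        self.sigma = float(sigma)
        self.settings = settings
        n = settings.n_states
        self.states = np.linspace(-1.0, 1.0, n)
        self.interior = self.states[1:-1]
        self.dx = 2.0 / (n - 1)
        self.size = n  # interior + two absorbing states
        self._kernels: dict[float, np.ndarray] = {}
        self._powers: dict[float, list[np.ndarray]] = {}
        p0 = np.zeros(self.size)
        p0[(n - 1) // 2] = 1.0  # all mass at RDV = 0
        self.p0 = p0

    def kernel(self, mu: float) -> np.ndarray:
        key = round(float(mu), 12)
        K = self._kernels.get(key)
        if K is None:
            K = self._build(key)
            self._kernels[key] = K
        return K

    def _build(self, mu: float) -> np.ndarray:
        x = self.interior
        sig = self.sigma
        a_up = norm.sf((1.0 - x - mu) / sig)  # mass at/over +1 (exact hits absorb)
        a_dn = norm.cdf((-1.0 - x - mu) / sig)
        z = (x[None, :] - x[:, None] - mu) / sig
        w = norm.pdf(z) * (self.dx / sig)
        interior_target = 1.0 - a_up - a_dn
        row = w.sum(axis=1)
        K = np.zeros((self.size, self.size))
        K[0, 0] = 1.0
        K[-1, -1] = 1.0
        ok = row > 1e-300
        scale = np.where(ok, interior_target / np.where(ok, row, 1.0), 0.0)
        K[1:-1, 1:-1] = w * scale[:, None]
        # Degenerate rows (sigma far below the state spacing): put the
        # surviving mass on the state nearest the deterministic landing point.
        bad = ~ok & (interior_target > 0)
        if bad.any():
            land = np.clip(x[bad] + mu, x[0], x[-1])
            idx = np.rint((land - x[0]) / self.dx).astype(int)
            for i, j, m in zip(np.nonzero(bad)[0], idx, interior_target[bad]):
                K[1 + i, 1 + j] = m
        K[1:-1, 0] = a_dn
        K[1:-1, -1] = a_up
        return K

    def _power(self, mu: float, k: int) -> np.ndarray:
        """K^(2**k) for the kernel with drift mu."""
        key = round(float(mu), 12)
        chain = self._powers.setdefault(key, [self.kernel(key)])
        while len(chain) <= k:
            chain.append(chain[-1] @ chain[-1])
        return chain[k]

    def propagate(self, p: np.ndarray, mu: float, n_bins: int) -> np.ndarray:
        """Advance the mass vector by ``n_bins`` steps of the same regime."""
        k = 0
        n = int(n_bins)
        while n:
            if n & 1:
                p = p @ self._power(mu, k)
            n >>= 1
            k += 1
        return p


def trial_regime_bins(trial: Trial) -> list[tuple[str, int]]:
    """Compress a cleaned trial into (gaze regime, n 10 ms bins) runs.

    Event durations are floored to the 10 ms grid. The runs are adjusted to
    cover exactly ``rt // 10`` bins: a shortfall extends the final event, an
    overhang truncates from the end (mismatches beyond 20 ms are logged).
    """
    if not any(e.is_item for e in trial.events):
        raise ValueError("trial has no item fixations; clean it first")
    runs: list[tuple[str, int]] = []
    for e in trial.events:
        regime = {"left": "left_fixation", "right": "right_fixation", "blank": "none"}[e.location]
        n_bins = e.duration // DT_MS
        if n_bins <= 0:
            continue
        if runs and runs[-1][0] == regime:
            runs[-1] = (regime, runs[-1][1] + n_bins)
        else:
            runs.append((regime, n_bins))
    total = sum(n for _, n in runs)
    rt_bins = trial.rt // DT_MS
    if abs(total - rt_bins) * DT_MS > 20:
        logger.debug(
            "trial %s/%s: event time %d bins vs RT %d bins; adjusting final event",
            trial.subject_id, trial.trial_index, total, rt_bins,
        )
    if total < rt_bins:
        regime, n = runs[-1]
        runs[-1] = (regime, n + (rt_bins - total))
    elif total > rt_bins:
        excess = total - rt_bins
        while excess > 0 and runs:
            regime, n = runs.pop()
            cut = min(n, excess)
            excess -= cut
            if n - cut > 0:
                runs.append((regime, n - cut))
    return runs


def _mu_of(params: ModelParams, r_left: int, r_right: int, regime: str) -> float:
    return drift(params, r_left, r_right, regime)


def _trial_loglik_runs(
    engine: PropagationEngine,
    params: ModelParams,
    r_left: int,
    r_right: int,
    runs: Sequence[tuple[str, int]],
    choice: str,
    settings: LikelihoodSettings,
) -> float:
    total_bins = sum(n for _, n in runs)
    if total_bins < 1:
        return math.log(settings.floor_prob)
    if total_bins * DT_MS > settings.rt_cap_ms:
        logger.warning("RT %d ms beyond cap %d ms; floor probability", total_bins * DT_MS, settings.rt_cap_ms)
        return math.log(settings.floor_prob)
    side = engine.size - 1 if choice == "left" else 0
    p = engine.p0
    remaining = total_bins - 1
    final_mu = _mu_of(params, r_left, r_right, runs[-1][0])
    for regime, n in runs:
        m = min(n, remaining)
        if m > 0:
            p = engine.propagate(p, _mu_of(params, r_left, r_right, regime), m)
            remaining -= m
    p_final = p @ engine.kernel(final_mu)
    lik = p_final[side] - p[side]
    return math.log(max(lik, settings.floor_prob))


def trial_loglik(
    params: ModelParams, trial: Trial, settings: LikelihoodSettings | None = None
) -> float:
    """log P(choice, RT | fixations, r_left, r_right, params) for one trial."""
    settings = settings or LikelihoodSettings()
    engine = PropagationEngine(params.sigma, settings)
    runs = trial_regime_bins(trial)
    return _trial_loglik_runs(
        engine, params, trial.r_left, trial.r_right, runs, trial.choice, settings
    )


@dataclass
class _Prepared:
    r_left: int
    r_right: int
    runs: list[tuple[str, int]]
    choice: str


def _prepare(trials: Sequence[Trial]) -> list[_Prepared]:
    return [_Prepared(t.r_left, t.r_right, trial_regime_bins(t), t.choice) for t in trials]


def _dataset_loglik_prepared(
    params: ModelParams, prepared: Sequence[_Prepared], settings: LikelihoodSettings
) -> float:
    engine = PropagationEngine(params.sigma, settings)
    terms = [
        _trial_loglik_runs(engine, params, p.r_left, p.r_right, p.runs, p.choice, settings)
        for p in prepared
    ]
    return math.fsum(sorted(terms))  # compensated + order-canonical: permutation-invariant


def dataset_loglik(
    params: ModelParams, trials: Sequence[Trial], settings: LikelihoodSettings | None = None
) -> float:
    """Sum of trial log-likelihoods (order-invariant to the bit)."""
    settings = settings or LikelihoodSettings()
    return _dataset_loglik_prepared(params, _prepare(trials), settings)


def absorption_profile(
    params: ModelParams,
    r_left: int,
    r_right: int,
    runs: Sequence[tuple[str, int]],
    settings: LikelihoodSettings | None = None,
) -> tuple[np.ndarray, float]:
    """Step-by-step absorbed-mass histogram for a fixed fixation schedule.

    Returns ``(profile, survivor)`` where ``profile[t, 0]`` is the mass
    absorbed at −1 (right choice) during step t, ``profile[t, 1]`` the mass
    absorbed at +1 (left choice), and ``survivor`` the unabsorbed mass at
    the end of the schedule. Used as the deterministic side of the
    propagation-vs-Monte-Carlo cross-check.
    """
    settings = settings or LikelihoodSettings()
    engine = PropagationEngine(params.sigma, settings)
    p = engine.p0
    out = []
    for regime, n in runs:
        K = engine.kernel(_mu_of(params, r_left, r_right, regime))
        for _ in range(n):
            p_next = p @ K
            out.append((p_next[0] - p[0], p_next[-1] - p[-1]))
            p = p_next
    return np.asarray(out), float(p[1:-1].sum())


# ---------------------------------------------------------------------------
# Iterative grid MLE


def _grid_points(values: dict[str, Sequence[float]]) -> list[tuple[float, float, float]]:
    return [
        (d, th, sg)
        for d in sorted(values["d"])
        for th in sorted(values["theta"])
        for sg in sorted(values["sigma"])
    ]


def _refine(center: float, step: float, low: float | None, high: float | None) -> list[float]:
    pts = {center - step / 2.0, center, center + step / 2.0}
    out = set()
    for p in pts:
        q = p
        if low is not None and q < low:
            logger.debug("grid point %g clipped to %g", q, low)
            q = low
        if high is not None and q > high:
            logger.debug("grid point %g clipped to %g", q, high)
            q = high
        out.add(q)
    return sorted(out)


def grid_mle(
    trials: Sequence[Trial],
    settings: LikelihoodSettings | None = None,
    omega1: dict[str, Sequence[float]] | None = None,
    improvement_tol: float = 0.01,
    max_refinements: int = 20,
    fix_theta: float | None = None,
) -> FitResult:
    """Iterative grid-refinement maximum-likelihood fit of (d, θ, σ).

    Step 1 evaluates the dataset log-likelihood on the coarse grid Ω₁
    (default: d ∈ {0.001, 0.005, 0.01}, θ ∈ {0.1, 0.5, 0.9},
    σ ∈ {0.01, 0.05, 0.1}). Each later step builds the cross product of
    {x − Δ/2, x, x + Δ/2} around the incumbent, where Δ is the previous
    step size (so step sizes halve), and stops once the relative
    improvement in the best log-likelihood drops below ``improvement_tol``.
    Ties in the argmax break to the lexicographically smallest (d, θ, σ).
    θ points are clipped to [0, 1]; d and σ are floored at a small ε.
    """
    if not trials:
        raise ValueError("no trials to fit")
    settings = settings or LikelihoodSettings()
    omega = {k: list(v) for k, v in (omega1 or OMEGA1).items()}
    if fix_theta is not None:
        omega["theta"] = [float(fix_theta)]

    # Step size of an (possibly uneven) grid: half its span; fixed params 0.
    steps = {k: (max(v) - min(v)) / 2.0 if len(v) > 1 else 0.0 for k, v in omega.items()}

    prepared = _prepare(trials)
    cache: dict[tuple[float, float, float], float] = {}

    def evaluate(point: tuple[float, float, float]) -> float:
        key = tuple(round(x, 12) for x in point)
        if key not in cache:
            params = ModelParams(d=point[0], theta=point[1], sigma=point[2])
            cache[key] = _dataset_loglik_prepared(params, prepared, settings)
        return cache[key]

    trace: list[GridStep] = []
    converged = False
    best_point: tuple[float, float, float] | None = None
    best_ll = -math.inf

    for step_index in range(1, max_refinements + 1):
        grid = _grid_points(omega)
        lls = [evaluate(pt) for pt in grid]
        ll_max = max(lls)
        candidates = sorted(pt for pt, ll in zip(grid, lls) if ll == ll_max)
        step_best = candidates[0]

        prev_ll = best_ll
        if ll_max >= best_ll:
            best_ll, best_point = ll_max, step_best
        trace.append(GridStep(step_index, grid, step_best, ll_max))

        if step_index == 1:
            # An infinite tolerance is satisfied by any improvement, so no
            # refinement can help: return the Ω₁ argmax directly.
            if math.isinf(improvement_tol):
                converged = True
                break
        else:
            improvement = best_ll - prev_ll
            if improvement / abs(prev_ll) < improvement_tol:
                converged = True
                break

        d0, th0, sg0 = best_point
        steps = {k: s / 2.0 if step_index > 1 else s for k, s in steps.items()}
        omega = {
            "d": _refine(d0, steps["d"], _PARAM_EPS, None) if steps["d"] else [d0],
            "theta": _refine(th0, steps["theta"], 0.0, 1.0) if steps["theta"] else [th0],
            "sigma": _refine(sg0, steps["sigma"], _PARAM_EPS, None) if steps["sigma"] else [sg0],
        }

    d, th, sg = best_point  # type: ignore[misc]
    final_steps = {k: s / 2.0 ** max(len(trace) - 1, 0) for k, s in
                   {k: (max(v) - min(v)) / 2.0 if len(v) > 1 else 0.0
                    for k, v in (omega1 or OMEGA1).items()}.items()}
    if fix_theta is not None:
        final_steps["theta"] = 0.0
    return FitResult(
        params=ModelParams(d=d, theta=th, sigma=sg),
        log_likelihood=best_ll,
        trace=trace,
        converged=converged,
        n_steps=len(trace),
        final_step_sizes=final_steps,
    )


def fit_ddm(
    trials: Sequence[Trial],
    settings: LikelihoodSettings | None = None,
    omega1: dict[str, Sequence[float]] | None = None,
    improvement_tol: float = 0.01,
    max_refinements: int = 20,
) -> FitResult:
    """Grid MLE with θ pinned to 1 — the best-fitting standard DDM."""
    return grid_mle(
        trials,
        settings=settings,
        omega1=omega1,
        improvement_tol=improvement_tol,
        max_refinements=max_refinements,
        fix_theta=1.0,
    )
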