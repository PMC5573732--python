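"""Behavioural summaries and goodness-of-fit statistics.

All analyses operate on the shared ``Trial`` representation, so observed
and simulated datasets can be summarised identically and overlaid.

The key derived quantities are

* Δr = r_left − r_right, the signed relative-proximity difference;
* choice ease = |Δr|, the proximity gap between the correct and incorrect
  option (equidistant trials have ease 0 and either choice counts correct);
* net fixation time = total left-fixation ms − total right-fixation ms;
* corrected choice probability = the trial's choice indicator minus the
  dataset's mean choice rate at the same Δr, isolating gaze effects from
  stimulus effects.

Binned curves report pooled per-bin means with normal-approximation 95%
confidence intervals. Pooled logistic/least-squares fits stand in for the
mixed-effects regressions used on real multi-subject data; with the
descriptive role the slopes play here, per-subject random effects are out
of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency, pearsonr

from .preprocessing import Trial

__all__ = [
    "CurveSummary",
    "BiasReport",
    "psychometrics",
    "fixation_property_curves",
    "corrected_choice_probability",
    "bias_report",
    "efron_r2",
    "wls_fit_test",
    "last_fixation_stats",
]

logger = logging.getLogger(__name__)


@dataclass
class CurveSummary:
    """Per-bin mean of a dependent variable with pooled 95% CIs."""

    name: str
    x: np.ndarray
    y_mean: np.ndarray
    y_ci95: np.ndarray
    n: np.ndarray
    slope: float | None = None
    slope_p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "y_mean": self.y_mean, "y_ci95": self.y_ci95, "n": self.n}
        )


def _binned_curve(name: str, x: np.ndarray, y: np.ndarray, bins: Sequence[float] | None = None) -> CurveSummary:
    """Mean ± 95% CI of y in each distinct (or supplied) x bin; empty bins omitted."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if bins is None:
        centers = np.unique(x)
        labels = x
    else:
        edges = np.asarray(bins, dtype=float)
        idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
        centers = (edges[:-1] + edges[1:]) / 2.0
        labels = centers[idx]
        centers = np.unique(labels)
    xs, means, cis, ns = [], [], [], []
    for c in centers:
        sel = labels == c
        m = int(sel.sum())
        if m == 0:
            continue
        vals = y[sel]
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / math.sqrt(m)) if m > 1 else 0.0
        xs.append(c)
        means.append(mean)
        cis.append(1.96 * se)
        ns.append(m)
    return CurveSummary(name, np.array(xs), np.array(means), np.array(cis), np.array(ns, dtype=int))


def _frame(trials: Sequence[Trial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        fix = t.item_fixations
        rows.append(
            {
                "dr": t.r_left - t.r_right,
                "ease": abs(t.r_left - t.r_right),
                "choice_left": 1.0 if t.choice == "left" else 0.0,
                "rt": t.rt,
                "n_fix": len(fix),
                "net": t.net_fixation_time(),
                "first_side": fix[0].location if fix else "",
                "first_dur": fix[0].duration if fix else np.nan,
                "last_side": fix[-1].location if fix else "",
            }
        )
    return pd.DataFrame(rows)


def psychometrics(trials: Sequence[Trial]) -> dict[str, CurveSummary]:
    """Choice, RT, and fixation-count curves.

    Returns the psychometric choice curve P(choose left) over Δr, plus mean
    RT and mean fixation count over choice ease, each with a pooled summary
    fit (logistic for choice, least squares otherwise) reported alongside.
    """
    df = _frame(trials)
    if df["dr"].nunique() < 2:
        raise ValueError("need at least 2 distinct relative-proximity differences")

    choice = _binned_curve("p_choose_left_vs_dr", df["dr"].values, df["choice_left"].values)
    logit = sm.Logit(df["choice_left"], sm.add_constant(df["dr"].astype(float))).fit(disp=0)
    choice.slope = float(logit.params.iloc[1])
    choice.slope_p = float(logit.pvalues.iloc[1])

    rt = _binned_curve("rt_vs_ease", df["ease"].values, df["rt"].values)
    nfix = _binned_curve("n_fix_vs_ease", df["ease"].values, df["n_fix"].values)
    for curve, col in ((rt, "rt"), (nfix, "n_fix")):
        ols = sm.OLS(df[col].astype(float), sm.add_constant(df["ease"].astype(float))).fit()
        curve.slope = float(ols.params.iloc[1])
        curve.slope_p = float(ols.pvalues.iloc[1])
    return {"choice": choice, "rt": rt, "n_fixations": nfix}


def fixation_property_curves(trials: Sequence[Trial]) -> dict[str, CurveSummary]:
    """First/middle fixation duration vs r_fixated, Δr, and choice ease.

    Last fixations are excluded throughout: their duration is endogenous
    (truncated by the barrier crossing).
    """
    rows = []
    for t in trials:
        positions = [i for i, e in enumerate(t.events) if e.is_item]
        for ordinal, pos in enumerate(positions[:-1]):  # excludes each trial's last fixation
            e = t.events[pos]
            r_fix = t.r_left if e.location == "left" else t.r_right
            r_unfix = t.r_right if e.location == "left" else t.r_left
            rows.append(
                {
                    "cls": "first" if ordinal == 0 else "middle",
                    "dur": e.duration,
                    "r_fix": r_fix,
                    "dr": r_fix - r_unfix,
                    "ease": abs(t.r_left - t.r_right),
                }
            )
    df = pd.DataFrame(rows)
    out: dict[str, CurveSummary] = {}
    for cls in ("first", "middle"):
        sub = df[df["cls"] == cls]
        if sub.empty:
            continue
        for xcol, tag in (("r_fix", "r_fixated"), ("dr", "dr"), ("ease", "ease")):
            curve = _binned_curve(f"{cls}_duration_vs_{tag}", sub[xcol].values, sub["dur"].values)
            ols = sm.OLS(sub["dur"].astype(float), sm.add_constant(sub[xcol].astype(float))).fit()
            curve.slope = float(ols.params.iloc[1])
            curve.slope_p = float(ols.pvalues.iloc[1])
            out[curve.name] = curve
    return out


def _corrected_indicator(df: pd.DataFrame, indicator: str, by: str) -> pd.Series:
    """indicator minus its mean within each `by` cell (cells of size 1 give 0)."""
    cell_mean = df.groupby(by)[indicator].transform("mean")
    single = df.groupby(by)[indicator].transform("size") == 1
    if single.any():
        logger.debug("%d single-trial %s cells: corrected value 0 by construction", int(single.sum()), by)
    return df[indicator] - cell_mean


def corrected_choice_probability(
    trials: Sequence[Trial],
    conditioning: str = "net_time",
    bin_ms: int = 200,
) -> CurveSummary:
    """Corrected choice probability vs a gaze-time conditioning variable.

    ``net_time``: corrected P(choose left) — choice indicator minus the
    dataset's mean P(left) at the trial's Δr — binned by net fixation time.
    ``first_duration``: corrected P(choose first-seen item) binned by first
    fixation duration. The pooled trial-level regression slope is attached.
    """
    df = _frame(trials)
    if conditioning == "net_time":
        df = df[df["first_side"] != ""]
        df["corr"] = _corrected_indicator(df, "choice_left", "dr")
        x = df["net"].values.astype(float)
        name = "corrected_p_left_vs_net_time"
    elif conditioning == "first_duration":
        df = df[df["first_side"] != ""].copy()
        df["chose_first"] = (
            ((df["first_side"] == "left") & (df["choice_left"] == 1))
            | ((df["first_side"] == "right") & (df["choice_left"] == 0))
        ).astype(float)
        # the first-seen item's proximity advantage is side-relative
        df["dr_first"] = np.where(df["first_side"] == "left", df["dr"], -df["dr"])
        df["corr"] = _corrected_indicator(df, "chose_first", "dr_first")
        x = df["first_dur"].values.astype(float)
        name = "corrected_p_first_vs_first_duration"
    else:
        raise ValueError("conditioning must be 'net_time' or 'first_duration'")

    y = df["corr"].values.astype(float)
    lo = math.floor(x.min() / bin_ms) * bin_ms
    hi = math.ceil(x.max() / bin_ms) * bin_ms + bin_ms
    curve = _binned_curve(name, x, y, bins=np.arange(lo, hi + 1, bin_ms))
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    curve.slope = float(ols.params[1])
    curve.slope_p = float(ols.pvalues[1])
    return curve


@dataclass
class BiasReport:
    last_fixation_bias_curve: CurveSummary
    time_advantage_curve: CurveSummary
    corrected_net_time_curve: CurveSummary
    first_fixation_bias_curve: CurveSummary
    p_choose_last_at_dr0: float | None
    n_dr0: int


def bias_report(trials: Sequence[Trial], bin_ms: int = 200) -> BiasReport:
    """The gaze-driven choice-bias measures for one dataset."""
    rows = []
    for t in trials:
        fix = t.item_fixations
        if not fix:
            continue
        last = fix[-1].location
        dr_last = (t.r_left - t.r_right) if last == "left" else (t.r_right - t.r_left)
        rows.append(
            {
                "dr_last": dr_last,
                "chose_last": 1.0 if t.choice == last else 0.0,
                "net": t.net_fixation_time(),
                "choice_left": 1.0 if t.choice == "left" else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    last_curve = _binned_curve("p_choose_last_vs_dr", df["dr_last"].values, df["chose_last"].values)
    lo = math.floor(df["net"].min() / bin_ms) * bin_ms
    hi = math.ceil(df["net"].max() / bin_ms) * bin_ms + bin_ms
    adv_curve = _binned_curve(
        "p_left_vs_net_time", df["net"].values.astype(float), df["choice_left"].values,
        bins=np.arange(lo, hi + 1, bin_ms),
    )
    at0 = df[df["dr_last"] == 0]
    return BiasReport(
        last_fixation_bias_curve=last_curve,
        time_advantage_curve=adv_curve,
        corrected_net_time_curve=corrected_choice_probability(trials, "net_time", bin_ms),
        first_fixation_bias_curve=corrected_choice_probability(trials, "first_duration", bin_ms),
        p_choose_last_at_dr0=float(at0["chose_last"].mean()) if len(at0) else None,
        n_dr0=len(at0),
    )


def last_fixation_stats(trials: Sequence[Trial]) -> dict[str, float]:
    """Mean durations of last vs middle (incl. second) vs first fixations."""
    first, middle, last = [], [], []
    for t in trials:
        fix = t.item_fixations
        if len(fix) < 2:
            continue
        first.append(fix[0].duration)
        last.append(fix[-1].duration)
        middle.extend(e.duration for e in fix[1:-1])
    return {
        "mean_first_ms": float(np.mean(first)) if first else math.nan,
        "mean_middle_ms": float(np.mean(middle)) if middle else math.nan,
        "mean_last_ms": float(np.mean(last)) if last else math.nan,
    }


def efron_r2(predicted: Sequence[float], actual: Sequence[float]) -> float:
    """Squared Pearson correlation between predicted and actual values."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(p) == 0 or np.ptp(a) == 0:
        raise ValueError("efron_r2 undefined for a constant vector")
    r, _ = pearsonr(p, a)
    return float(r * r)


@dataclass
class WLSResult:
    const: float
    slope: float
    const_p: float
    slope_p: float


def wls_fit_test(
    subject_means: pd.DataFrame,
    model_means: dict[float, float] | pd.Series,
    subject_variances: pd.DataFrame | None = None,
    max_weight: float = 1e6,
) -> WLSResult:
    """Weighted least-squares test of model-vs-data pattern discrepancy.

    ``subject_means`` has columns ``subject``, ``x``, ``mean`` (and
    optionally ``var``). The dependent variable is each subject's bin mean
    minus the model's mean for that bin; weights are inverse variances
    (zero variances are capped at ``max_weight``). Non-significant
    coefficients indicate a good fit.
    """
    df = subject_means.copy()
    model = pd.Series(model_means)
    df["y"] = df["mean"].values - model.reindex(df["x"]).values
    if "var" in df.columns:
        var = df["var"].astype(float).values
    elif subject_variances is not None:
        var = subject_variances["var"].astype(float).values
    else:
        raise ValueError("per-subject variances required (column 'var')")
    with np.errstate(divide="ignore"):
        w = np.where(var > 0, 1.0 / np.where(var > 0, var, 1.0), max_weight)
    if (var <= 0).any():
        logger.warning("%d zero-variance bins: weight capped at %g", int((var <= 0).sum()), max_weight)
    w = np.minimum(w, max_weight)
    X = sm.add_constant(df["x"].astype(float))
    fit = sm.WLS(df["y"].astype(float), X, weights=w).fit()

    def _p(coef: float, p: float) -> float:
        # an exact model match has zero residual variance: the discrepancy
        # is identically zero, which counts as maximal non-significance
        if math.isnan(p):
            return 1.0 if abs(coef) < 1e-12 else 0.0
        return float(p)

    return WLSResult(
        const=float(fit.params.iloc[0]),
        slope=float(fit.params.iloc[1]),
        const_p=_p(float(fit.params.iloc[0]), float(fit.pvalues.iloc[0])),
        slope_p=_p(float(fit.params.iloc[1]), float(fit.pvalues.iloc[1])),
    )


def contingency_chi2(table: np.ndarray | Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson χ² (no continuity correction) for an r×c count table."""
    chi2, p, _, _ = chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)
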