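"""State-space likelihood: conservation, symmetry, and the grid MLE."""

from __future__ import annotations

import math

import numpy as np
import pytest

from addm.likelihood import (
    OMEGA1,
    LikelihoodSettings,
    absorption_profile,
    dataset_loglik,
    fit_ddm,
    grid_mle,
    trial_loglik,
)
from addm.model import ModelParams
from addm.preprocessing import RawEvent, Trial

PARAMS = ModelParams(d=0.0041, theta=0.36, sigma=0.063)


def _trial(events, choice, rt, dl=-5, dr=10, idx=0):
    return Trial(
        subject_id="s00", trial_index=idx, delta_left=dl, delta_right=dr,
        events=events, choice=choice, rt=rt,
    )


class TestTrialLikelihood:
    def test_mass_conservation(self):
        runs = [("none", 30), ("left_fixation", 60), ("none", 10), ("right_fixation", 500)]
        profile, survivor = absorption_profile(PARAMS, 2, 1, runs, LikelihoodSettings(n_states=101))
        total = profile.sum() + survivor
        assert abs(total - 1.0) < 1e-6
        # survivor mass is monotone non-increasing by construction
        assert (profile >= -1e-15).all()

    def test_mirror_trial_identical_loglik(self):
        events = [RawEvent("blank", 200), RawEvent("left", 400), RawEvent("blank", 100),
                  RawEvent("right", 700)]
        t = _trial(events, "right", 1400, dl=-5, dr=10)
        mirrored = [RawEvent({"left": "right", "right": "left", "blank": "blank"}[e.location], e.duration)
                    for e in events]
        m = _trial(mirrored, "left", 1400, dl=10, dr=-5)
        assert trial_loglik(PARAMS, t) == pytest.approx(trial_loglik(PARAMS, m), rel=1e-9)

    def test_no_item_fixation_errors(self):
        t = _trial([RawEvent("blank", 400)], "left", 400)
        with pytest.raises(ValueError):
            trial_loglik(PARAMS, t)

    def test_grid_resolution_convergence(self, cleaned_reference):
        for t in cleaned_reference[:10]:
            a = trial_loglik(PARAMS, t, LikelihoodSettings(n_states=101))
            b = trial_loglik(PARAMS, t, LikelihoodSettings(n_states=201))
            assert abs(a - b) < 0.01 * abs(b)


class TestDatasetLikelihood:
    def test_single_trial_equals_trial_loglik(self, cleaned_reference):
        t = cleaned_reference[0]
        assert dataset_loglik(PARAMS, [t]) == pytest.approx(trial_loglik(PARAMS, t))

    def test_duplication_doubles(self, cleaned_reference):
        sub = cleaned_reference[:5]
        assert dataset_loglik(PARAMS, sub + sub) == pytest.approx(2 * dataset_loglik(PARAMS, sub))

    def test_permutation_bit_identical(self, cleaned_reference):
        sub = list(cleaned_reference[:20])
        ll = dataset_loglik(PARAMS, sub)
        rng = np.random.default_rng(0)
        for _ in range(3):
            rng.shuffle(sub)
            assert dataset_loglik(PARAMS, sub) == ll


class TestGridMLE:
    SETTINGS = LikelihoodSettings(n_states=51)

    def test_infinite_tolerance_returns_omega1_argmax(self, cleaned_reference):
        sub = cleaned_reference[:100]
        fit = grid_mle(sub, settings=self.SETTINGS, improvement_tol=math.inf)
        assert fit.n_steps == 1
        assert fit.converged
        grid = fit.trace[0].grid
        lls = [dataset_loglik(ModelParams(*pt), sub, self.SETTINGS) for pt in grid]
        assert fit.log_likelihood == pytest.approx(max(lls))

    def test_trace_monotone_and_step1_is_omega1(self, cleaned_reference):
        fit = grid_mle(cleaned_reference[:150], settings=self.SETTINGS, max_refinements=4,
                       improvement_tol=1e-9)
        lls = [s.best_loglik for s in fit.trace]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))
        expected = {(d, th, sg) for d in OMEGA1["d"] for th in OMEGA1["theta"] for sg in OMEGA1["sigma"]}
        assert set(fit.trace[0].grid) == expected

    def test_refined_grid_halves_step_and_contains_incumbent(self, cleaned_reference):
        fit = grid_mle(cleaned_reference[:150], settings=self.SETTINGS, max_refinements=2,
                       improvement_tol=1e-9)
        assert len(fit.trace) >= 2
        best1 = fit.trace[0].best_params
        grid2 = fit.trace[1].grid
        assert best1 in grid2
        ds = sorted({pt[0] for pt in grid2})
        step1_d = (max(OMEGA1["d"]) - min(OMEGA1["d"])) / 2
        assert ds[1] - ds[0] == pytest.approx(step1_d / 2)

    def test_theta_grid_clipped_to_unit_interval(self, cleaned_reference):
        fit = grid_mle(cleaned_reference[:60], settings=self.SETTINGS, max_refinements=3,
                       improvement_tol=1e-9)
        for s in fit.trace:
            assert all(0 <= pt[1] <= 1 for pt in s.grid)

    def test_fit_ddm_pins_theta(self, cleaned_reference):
        fit = fit_ddm(cleaned_reference[:100], settings=self.SETTINGS, max_refinements=2,
                      improvement_tol=1e-9)
        for s in fit.trace:
            assert all(pt[1] == 1.0 for pt in s.grid)
        assert fit.params.theta == 1.0

    def test_addm_beats_ddm_on_attention_biased_data(self, cleaned_reference):
        # data generated at θ=0.36: with enough trials the free-θ fit finds
        # the attentional discount and beats the θ=1 restriction
        full = grid_mle(cleaned_reference, settings=self.SETTINGS)
        constrained = fit_ddm(cleaned_reference, settings=self.SETTINGS)
        assert full.log_likelihood > constrained.log_likelihood
        assert full.params.theta < 1.0

    def test_ddm_matches_addm_on_ddm_data(self, ddm_dataset):
        sub = ddm_dataset[:300]
        full = grid_mle(sub, settings=self.SETTINGS)
        constrained = fit_ddm(sub, settings=self.SETTINGS)
        # on θ=1 data the free fit gains at most one improvement tolerance
        assert full.log_likelihood >= constrained.log_likelihood - 1e-9
        assert (full.log_likelihood - constrained.log_likelihood) <= 0.01 * abs(constrained.log_likelihood)
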