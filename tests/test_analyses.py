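"""Behavioural summaries, corrected probabilities, goodness-of-fit stats."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from addm.analyses import (
    bias_report,
    contingency_chi2,
    corrected_choice_probability,
    efron_r2,
    fixation_property_curves,
    last_fixation_stats,
    psychometrics,
    wls_fit_test,
)
from addm.preprocessing import RawEvent, Trial


def _trial(idx, dl, dr, choice, events=None, rt=None):
    events = events or [RawEvent("left", 300), RawEvent("right", 300)]
    return Trial(
        subject_id="s00", trial_index=idx, delta_left=dl, delta_right=dr,
        events=events, choice=choice, rt=rt or sum(e.duration for e in events),
    )


def _mirror(t: Trial, idx: int) -> Trial:
    swap = {"left": "right", "right": "left", "blank": "blank"}
    return Trial(
        subject_id=t.subject_id, trial_index=idx, delta_left=t.delta_right,
        delta_right=t.delta_left, events=[RawEvent(swap[e.location], e.duration) for e in t.events],
        choice=swap[t.choice], rt=t.rt,
    )


class TestPsychometrics:
    def test_deterministic_chooser_step_curve(self):
        trials = []
        i = 0
        for dl, dr in [(0, 15), (0, 10), (15, 0), (10, 0)] * 10:
            rl, rr = 3 - abs(dl) // 5, 3 - abs(dr) // 5
            trials.append(_trial(i, dl, dr, "left" if rl > rr else "right"))
            i += 1
        curves = psychometrics(trials)
        c = curves["choice"]
        assert set(np.sign(c.x)) <= {-1.0, 1.0}
        for x, y in zip(c.x, c.y_mean):
            assert y == (1.0 if x > 0 else 0.0)

    def test_monotone_choice_curve_on_simulated_data(self, cleaned_reference):
        c = psychometrics(cleaned_reference)["choice"]
        # allow small sampling wiggles: check rank correlation is perfect-ish
        assert c.slope > 0
        assert np.all(np.diff(c.x) > 0)
        assert c.y_mean[-1] > 0.9 and c.y_mean[0] < 0.1

    def test_antisymmetry_on_mirrored_data(self, cleaned_reference):
        base = cleaned_reference[:200]
        mirrored = [_mirror(t, 10_000 + k) for k, t in enumerate(base)]
        c = psychometrics(list(base) + mirrored)["choice"]
        curve = dict(zip(c.x, c.y_mean))
        for x in c.x:
            assert curve[x] + curve[-x] == pytest.approx(1.0)

    def test_rt_and_fixation_count_decrease_with_ease(self, cleaned_reference):
        curves = psychometrics(cleaned_reference)
        assert curves["rt"].slope < 0
        assert curves["n_fixations"].slope < 0

    def test_requires_two_x_values(self):
        trials = [_trial(i, 0, 15, "left") for i in range(5)]
        with pytest.raises(ValueError):
            psychometrics(trials)


class TestFixationCurves:
    def test_slope_recovery_from_generator(self):
        # duration mean linear in r_fixated only: the binned first-fixation
        # slope recovers it (up to mild truncation-survival attenuation —
        # long draws are more likely to end as excluded last fixations)
        from addm.preprocessing import clean_dataset
        from addm.synthetic import SyntheticConfig, generate_trials

        config = SyntheticConfig(slope_dr_ms=0.0, n_subjects=3, trials_per_subject=336, master_seed=7)
        cleaned, _ = clean_dataset(generate_trials(config))
        curves = fixation_property_curves(cleaned)
        got = curves["first_duration_vs_r_fixated"]
        assert got.slope == pytest.approx(config.slope_r_ms, abs=12)
        assert got.slope > 0 and got.slope_p < 0.01

    def test_constant_duration_generator_flat(self):
        trials = []
        i = 0
        for dl, dr in [(0, 15), (15, 0), (5, -10), (-10, 5)] * 20:
            evs = [RawEvent("left", 300), RawEvent("right", 300), RawEvent("left", 300)]
            trials.append(_trial(i, dl, dr, "left", events=evs))
            i += 1
        curves = fixation_property_curves(trials)
        assert curves["first_duration_vs_r_fixated"].slope == pytest.approx(0.0, abs=1e-9)

    def test_last_shorter_than_middle_on_addm_data(self, cleaned_reference):
        stats = last_fixation_stats(cleaned_reference)
        assert stats["mean_last_ms"] < stats["mean_middle_ms"]


class TestCorrectedChoiceProbability:
    def test_choice_driven_by_dr_only_corrects_to_zero(self):
        trials = []
        i = 0
        for dl, dr in [(0, 15), (0, 10), (15, 0), (10, 0)] * 15:
            rl, rr = 3 - abs(dl) // 5, 3 - abs(dr) // 5
            trials.append(_trial(i, dl, dr, "left" if rl > rr else "right"))
            i += 1
        curve = corrected_choice_probability(trials, "net_time")
        assert np.allclose(curve.y_mean, 0.0, atol=1e-12)

    def test_attention_effect_survives_correction(self, cleaned_reference):
        curve = corrected_choice_probability(cleaned_reference, "net_time")
        assert curve.slope > 0
        assert curve.slope_p < 0.01

    def test_values_bounded(self, cleaned_reference):
        for conditioning in ("net_time", "first_duration"):
            curve = corrected_choice_probability(cleaned_reference, conditioning)
            assert np.all(curve.y_mean >= -1.0) and np.all(curve.y_mean <= 1.0)


class TestEfronR2:
    def test_hand_computed_case(self):
        assert efron_r2([0.2, 0.4, 0.6, 0.8], [0, 0, 1, 1]) == pytest.approx(0.8)

    def test_perfect_prediction(self):
        assert efron_r2([0, 1, 0, 1], [0, 1, 0, 1]) == pytest.approx(1.0)

    def test_independent_prediction_near_zero(self):
        rng = np.random.default_rng(0)
        p = rng.random(5000)
        a = rng.integers(0, 2, 5000)
        assert efron_r2(p, a) < 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            efron_r2([0.5, 0.5, 0.5], [0, 1, 0])


class TestWLS:
    def _subject_means(self, offset=0.0, slope=0.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(8):
            for x in range(4):
                rows.append(
                    {"subject": s, "x": float(x),
                     "mean": 10.0 + x + offset + slope * x + noise * rng.standard_normal(),
                     "var": 1.0}
                )
        return pd.DataFrame(rows)

    _model = {0.0: 10.0, 1.0: 11.0, 2.0: 12.0, 3.0: 13.0}

    def test_exact_match_gives_null_coefficients(self):
        res = wls_fit_test(self._subject_means(), self._model)
        assert res.const == pytest.approx(0.0, abs=1e-10)
        assert res.slope == pytest.approx(0.0, abs=1e-10)
        assert res.const_p > 0.9 and res.slope_p > 0.9

    def test_systematic_discrepancy_detected(self):
        res = wls_fit_test(self._subject_means(slope=0.5, noise=0.05), self._model)
        assert res.slope_p < 0.001

    def test_weight_scale_invariance(self):
        df = self._subject_means(offset=0.3, noise=0.2)
        res1 = wls_fit_test(df, self._model)
        df2 = df.copy()
        df2["var"] = df2["var"] * 2.0
        res2 = wls_fit_test(df2, self._model)
        assert res1.const == pytest.approx(res2.const)
        assert res1.slope == pytest.approx(res2.slope)


def test_chi2_hand_computed():
    chi2, p = contingency_chi2([[60, 40], [40, 60]])
    assert chi2 == pytest.approx(8.0)
    assert p < 0.01


def test_bias_report_on_reference_data(cleaned_reference):
    rep = bias_report(cleaned_reference)
    assert rep.p_choose_last_at_dr0 is not None and rep.n_dr0 > 30
    assert rep.p_choose_last_at_dr0 > 0.5
    assert -1 <= rep.corrected_net_time_curve.y_mean.min() <= rep.corrected_net_time_curve.y_mean.max() <= 1
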