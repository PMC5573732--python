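"""Proximity coding, fixation-stream cleaning, and dataset I/O."""

from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from addm.preprocessing import (
    VALID_DELTAS,
    RawEvent,
    Trial,
    clean_trial,
    read_dataset,
    relative_proximity,
    write_dataset,
)


class TestRelativeProximity:
    @pytest.mark.parametrize(
        "delta,expected",
        [(0, 3), (-15, 0), (15, 0), (-10, 1), (10, 1), (-5, 2), (5, 2)],
    )
    def test_values(self, delta, expected):
        assert relative_proximity(delta) == expected

    @pytest.mark.parametrize("delta", [20, -20, 3, 7, 1_000])
    def test_domain_error(self, delta):
        with pytest.raises(ValueError):
            relative_proximity(delta)

    @given(st.sampled_from(VALID_DELTAS))
    def test_even_and_onto(self, delta):
        assert relative_proximity(delta) == relative_proximity(-delta)
        assert relative_proximity(delta) in {0, 1, 2, 3}


class TestCleanTrial:
    def test_blank_absorbed_between_same_side(self):
        res = clean_trial([RawEvent("left", 300), RawEvent("blank", 40), RawEvent("left", 200)], rt=1000)
        assert res.keep
        assert res.events == [RawEvent("left", 540)]

    def test_majority_blank_discarded(self):
        res = clean_trial([RawEvent("blank", 600), RawEvent("left", 300)], rt=1000)
        assert not res.keep

    def test_blank_between_sides_is_transition(self):
        evs = [RawEvent("left", 300), RawEvent("blank", 100), RawEvent("right", 300)]
        res = clean_trial(evs, rt=800)
        assert res.keep
        assert res.events == evs  # transition kept in place

    def test_leading_blank_is_latency_and_trailing_dropped(self):
        res = clean_trial(
            [RawEvent("blank", 200), RawEvent("left", 300), RawEvent("blank", 150)], rt=1000
        )
        assert res.keep
        assert res.events == [RawEvent("blank", 200), RawEvent("left", 300)]

    def test_cascaded_absorption(self):
        # absorbing the inner blank creates new same-side adjacency
        res = clean_trial(
            [RawEvent("left", 100), RawEvent("blank", 20), RawEvent("left", 100),
             RawEvent("blank", 30), RawEvent("left", 100)],
            rt=1000,
        )
        assert res.events == [RawEvent("left", 350)]

    def test_no_item_fixations_discarded(self):
        res = clean_trial([RawEvent("blank", 100)], rt=1000)
        assert not res.keep

    _events = st.lists(
        st.builds(
            RawEvent,
            location=st.sampled_from(["left", "right", "blank"]),
            duration=st.integers(min_value=10, max_value=800),
        ),
        min_size=1,
        max_size=12,
    )

    @given(_events)
    def test_never_gains_time_and_preserves_item_time_up_to_absorption(self, events):
        rt = 20_000  # large so the 50% rule never triggers here
        res = clean_trial(events, rt)
        assert sum(e.duration for e in res.events) <= sum(e.duration for e in events)
        if res.keep:
            item_in = sum(e.duration for e in events if e.is_item)
            blank_in = sum(e.duration for e in events if not e.is_item)
            item_out = sum(e.duration for e in res.events if e.is_item)
            # item time only grows, and only by absorbed blank time
            assert item_in <= item_out <= item_in + blank_in


def _toy_trials():
    return [
        Trial(
            subject_id="s00", trial_index=0, delta_left=-10, delta_right=15,
            events=[RawEvent("blank", 200), RawEvent("left", 300), RawEvent("right", 410)],
            choice="right", rt=910,
        ),
        Trial(
            subject_id="s00", trial_index=1, delta_left=0, delta_right=5,
            events=[RawEvent("left", 500)], choice="left", rt=500,
            bias_target="left", timed_out=True,
        ),
    ]


class TestDatasetIO:
    def test_round_trip(self, tmp_path):
        trials = _toy_trials()
        write_dataset(trials, tmp_path / "t.csv", tmp_path / "f.csv")
        back = read_dataset(tmp_path / "t.csv", tmp_path / "f.csv")
        assert back == trials

    def test_empty_round_trip(self, tmp_path):
        write_dataset([], tmp_path / "t.csv", tmp_path / "f.csv")
        assert read_dataset(tmp_path / "t.csv", tmp_path / "f.csv") == []

    def test_malformed_duration_names_row(self, tmp_path):
        write_dataset(_toy_trials(), tmp_path / "t.csv", tmp_path / "f.csv")
        text = (tmp_path / "f.csv").read_text().replace("410", "abc")
        (tmp_path / "f.csv").write_text(text)
        with pytest.raises(ValueError, match="row 2"):
            read_dataset(tmp_path / "t.csv", tmp_path / "f.csv")

    def test_unknown_enum_rejected(self, tmp_path):
        write_dataset(_toy_trials(), tmp_path / "t.csv", tmp_path / "f.csv")
        text = (tmp_path / "t.csv").read_text().replace("right", "up")
        (tmp_path / "t.csv").write_text(text)
        with pytest.raises(ValueError):
            read_dataset(tmp_path / "t.csv", tmp_path / "f.csv")

    @given(st.integers(0, 2**31 - 1))
    def test_random_dataset_round_trips(self, seed):
        # cheap structural property via the synthetic generator at tiny n
        import numpy as np

        from addm.synthetic import SyntheticConfig, generate_trials

        config = SyntheticConfig(n_subjects=1, trials_per_subject=3, master_seed=seed % 1000)
        trials = generate_trials(config)
        import tempfile, pathlib

        with tempfile.TemporaryDirectory() as d:
            p = pathlib.Path(d)
            write_dataset(trials, p / "t.csv", p / "f.csv")
            assert read_dataset(p / "t.csv", p / "f.csv") == trials
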