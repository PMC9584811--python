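"""Titration schedules, branching, indifference derivation, anomaly items."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tempodisc.instrument import (
    CountryAnchor,
    IncompletePathError,
    InvalidConfigError,
    StateError,
    TERMINAL_PATTERNS,
    TitrationState,
    build_anomaly_items,
    build_titration_schedule,
    derive_indifference,
    enumerate_paths,
    next_item,
    next_multiplier,
    path_items,
    walk_instrument,
)


class TestSchedule:
    def test_small_gain_values_for_500_base(self, us_anchor):
        s = build_titration_schedule(us_anchor, "small_gain")
        assert s.immediate_amount == 500
        assert s.ascending == (550, 600, 750)
        assert s.descending == (510, 505)

    def test_large_gain_scales_by_multiplier(self, us_anchor):
        s = build_titration_schedule(us_anchor, "large_gain")
        assert s.immediate_amount == 5000
        assert s.ascending[0] == 5500

    def test_multiplier_arithmetic_for_other_anchor(self):
        s = build_titration_schedule(CountryAnchor("XX", "XXD", 1000.0), "small_gain")
        assert s.ascending == (1100, 1200, 1500)

    def test_loss_set_mirrors_gain_values_as_payments(self, us_anchor):
        s = build_titration_schedule(us_anchor, "loss")
        assert s.sign == "loss"
        assert s.ascending == (550, 600, 750)

    def test_non_positive_anchor_rejected(self):
        with pytest.raises(InvalidConfigError):
            CountryAnchor("XX", "XXD", 0.0)

    def test_non_baseline_set_rejected(self, us_anchor):
        with pytest.raises(InvalidConfigError):
            build_titration_schedule(us_anchor, "present_bias")


class TestBranching:
    def test_impatient_answer_escalates_to_120_percent(self, us_anchor):
        state = TitrationState(build_titration_schedule(us_anchor, "small_gain"))
        first = next_item(state)
        assert first.delayed_amount == 550
        second = next_item(state, "I")
        assert second.delayed_amount == 600

    def test_patient_answer_descends_to_102_percent(self, us_anchor):
        state = TitrationState(build_titration_schedule(us_anchor, "small_gain"))
        next_item(state)
        second = next_item(state, "D")
        assert second.delayed_amount == 510

    def test_reversal_at_second_item_terminates(self, us_anchor):
        state = TitrationState(build_titration_schedule(us_anchor, "small_gain"))
        next_item(state)
        next_item(state, "D")
        assert next_item(state, "I") is None
        with pytest.raises(StateError):
            next_item(state, "I")

    def test_schedule_exhausts_after_three_same_direction_answers(self):
        assert next_multiplier("small_gain", "III") is None
        assert next_multiplier("small_gain", "II") == 1.50
        assert next_multiplier("small_gain", "DD") == 1.01

    def test_loss_branching_is_mirrored(self):
        # delaying a payment escalates; paying now descends
        assert next_multiplier("loss", "D") == 1.20
        assert next_multiplier("loss", "I") == 1.02

    @pytest.mark.parametrize("pattern", TERMINAL_PATTERNS)
    def test_branching_determinism(self, us_anchor, pattern):
        def run():
            state = TitrationState(build_titration_schedule(us_anchor, "small_gain"))
            seen = []
            while not state.terminal:
                seen.append(state.current_item().delayed_amount)
                state.record(pattern[len(seen) - 1])
            return seen

        assert run() == run()


class TestIndifference:
    @pytest.mark.parametrize(
        "pattern, value, censored",
        [
            ("DDD", 505, False),
            ("DDI", 510, False),
            ("DI", 550, False),
            ("ID", 600, False),
            ("IID", 750, False),
            ("III", 750, True),
        ],
    )
    def test_smallest_accepted_delayed_value(self, us_anchor, pattern, value, censored):
        schedule = build_titration_schedule(us_anchor, "small_gain")
        assert derive_indifference(pattern, schedule) == (value, censored)

    def test_incomplete_set_rejected(self, us_anchor):
        schedule = build_titration_schedule(us_anchor, "small_gain")
        with pytest.raises(IncompletePathError):
            derive_indifference("II", schedule)

    def test_later_switch_on_ascending_branch_never_lowers_indifference(self, us_anchor):
        schedule = build_titration_schedule(us_anchor, "small_gain")
        values = [
            derive_indifference(p, schedule)[0] for p in ("ID", "IID", "III")
        ]
        assert values == sorted(values)


class TestAnomalyItems:
    def test_printed_us_example(self, us_anchor):
        items = build_anomaly_items(600, us_anchor)
        pb = items["present_bias"]
        assert (pb.immediate_amount, pb.immediate_time) == (500, 12)
        assert (pb.delayed_amount, pb.delayed_time) == (600, 24)
        sub = items["subadditivity"]
        assert (sub.immediate_amount, sub.immediate_time) == (500, 0)
        assert (sub.delayed_amount, sub.delayed_time) == (700, 24)
        assert items["delay_framing"].delayed_amount == 600  # premium 100
        assert items["delay_framing"].framing == "delay"
        assert items["speedup_framing"].framing == "speedup"

    def test_premium_50_gives_subadditivity_600(self, us_anchor):
        items = build_anomaly_items(550, us_anchor)
        assert items["subadditivity"].delayed_amount == 600
        assert items["delay_framing"].delayed_amount == 550

    def test_censored_indifference_extends_additively(self, us_anchor):
        items = build_anomaly_items(750, us_anchor)
        assert items["subadditivity"].delayed_amount == 1000

    def test_indifference_below_base_rejected(self, us_anchor):
        with pytest.raises(ValueError):
            build_anomaly_items(400, us_anchor)


class TestEnumeration:
    def test_each_staircase_has_six_terminal_patterns(self):
        assert len(TERMINAL_PATTERNS) == 6
        # brute force over the branching tree
        found = set()
        stack = [""]
        while stack:
            resp = stack.pop()
            if next_multiplier("small_gain", resp) is None:
                found.add(resp)
            else:
                stack.extend([resp + "I", resp + "D"])
        assert found == set(TERMINAL_PATTERNS)

    def test_total_paths_and_item_count_bounds(self, us_anchor):
        paths = list(enumerate_paths(us_anchor))
        assert len(paths) == 6**3 * 2**4 == 3456
        counts = [p.n_items for p in paths]
        assert min(counts) == 10
        assert max(counts) == 13
        assert set(counts) == {10, 11, 12, 13}

    def test_anomaly_items_come_after_all_baseline_sets(self, us_anchor):
        path = next(iter(enumerate_paths(us_anchor)))
        log = path_items(path, us_anchor)
        kinds = [item.set_id for item, _ in log]
        first_anomaly = kinds.index("present_bias")
        assert all(k in ("small_gain", "loss", "large_gain") for k in kinds[:first_anomaly])
        assert kinds[first_anomaly:] == [
            "present_bias", "subadditivity", "delay_framing", "speedup_framing"
        ]


class TestScaleEquivariance:
    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(
        c=st.floats(min_value=0.01, max_value=1000, allow_nan=False),
        pattern=st.sampled_from(TERMINAL_PATTERNS),
    )
    def test_amounts_scale_linearly_before_rounding(self, c, pattern):
        identity = lambda x: x
        a1 = CountryAnchor("A1", "X", 500.0)
        a2 = CountryAnchor("A2", "X", 500.0 * c)
        s1 = build_titration_schedule(a1, "small_gain", rounder=identity)
        s2 = build_titration_schedule(a2, "small_gain", rounder=identity)
        np.testing.assert_allclose(np.array(s2.ascending), c * np.array(s1.ascending))
        np.testing.assert_allclose(np.array(s2.descending), c * np.array(s1.descending))
        v1, _ = derive_indifference(pattern, s1, rounder=identity)
        v2, _ = derive_indifference(pattern, s2, rounder=identity)
        np.testing.assert_allclose(v2, c * v1)
        i1 = build_anomaly_items(v1, a1, rounder=identity)
        i2 = build_anomaly_items(v2, a2, rounder=identity)
        for name in i1:
            np.testing.assert_allclose(
                i2[name].delayed_amount, c * i1[name].delayed_amount, rtol=1e-12
            )


def test_walk_instrument_reproduces_fixed_choice_sequence(us_anchor):
    chooser = lambda item: "I" if item.set_id == "small_gain" else "D"
    path = walk_instrument(us_anchor, chooser, participant_id="p1")
    assert path.choices_small_gain == "III"
    assert path.indifference_censored
    assert path.choices_loss == "DDD"
    assert path.n_items == 13
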