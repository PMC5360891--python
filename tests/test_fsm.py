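"""Finite-state machine: input encoding, transitions, events, bookkeeping."""

import pytest
from hypothesis import given, settings, strategies as st

from copdwatch.fsm import (
    FsmInput,
    FsmValidationError,
    State,
    classify_symptom_change,
    detect_medication_event,
    encode_input,
    extract_exacerbation_events,
    run_fsm,
    step,
    transition_summary,
)
from conftest import make_session

N, T, E = State.NORMAL, State.TRANSITIONAL, State.EXACERBATION

# Independently hand-transcribed transition table: patients stay NORMAL
# unless symptoms worsen (medication then decides TRANSITIONAL vs
# EXACERBATION); improvement returns to NORMAL from anywhere; in
# TRANSITIONAL a medication event without improvement escalates; the
# EXACERBATION state is only left via improvement.
TRUTH_TABLE = {
    (N, 0, "00"): N, (N, 1, "00"): N,
    (N, 0, "11"): N, (N, 1, "11"): N,
    (N, 0, "10"): T, (N, 1, "10"): E,
    (T, 0, "00"): T, (T, 1, "00"): E,
    (T, 0, "10"): T, (T, 1, "10"): E,
    (T, 0, "11"): N, (T, 1, "11"): N,
    (E, 0, "00"): E, (E, 1, "00"): E,
    (E, 0, "10"): E, (E, 1, "10"): E,
    (E, 0, "11"): N, (E, 1, "11"): N,
}


class TestStep:
    def test_matches_hand_transcribed_truth_table_on_all_18_pairs(self):
        for (state, bit, code), expected in TRUTH_TABLE.items():
            assert step(state, FsmInput(bit, code)) is expected

    def test_no_path_into_transitional_from_exacerbation(self):
        for bit in (0, 1):
            for code in ("00", "10", "11"):
                assert step(E, FsmInput(bit, code)) is not T

    def test_illegal_symptom_code_rejected(self):
        with pytest.raises(FsmValidationError, match="01"):
            FsmInput(0, "01")
        with pytest.raises(FsmValidationError):
            FsmInput(2, "00")


class TestSymptomChange:
    @pytest.mark.parametrize(
        "worse, expected",
        [
            (("breathlessness", "cold_sore_throat"), "worse"),  # one major suffices
            (("cold_sore_throat", "run_down"), "no_change"),  # no major among the two
            (("breathlessness",), "no_change"),  # a single symptom is never significant
            (("chest_tightness", "sputum_volume", "run_down"), "worse"),
        ],
    )
    def test_worsening_rule(self, worse, expected):
        assert classify_symptom_change(make_session(0.0, worse=worse)) == expected

    def test_all_improved_is_improvement(self):
        s = make_session(0.0, improved=tuple(s for s in make_session(0.0).symptoms))
        assert classify_symptom_change(s) == "improve"

    def test_improvement_counts_resolved_worsening_vs_previous_session(self):
        prev = make_session(0.0, worse=("breathlessness", "run_down"))
        cur = make_session(1.0)  # both back to no_change
        assert classify_symptom_change(cur, prev) == "improve"
        # without the previous session there is nothing to improve on
        assert classify_symptom_change(cur) == "no_change"

    def test_simultaneous_worse_and_improve_resolves_to_worse(self):
        s = make_session(
            0.0,
            worse=("breathlessness", "run_down"),
            improved=("chest_tightness", "sputum_volume"),
        )
        assert classify_symptom_change(s) == "worse"

    def test_missing_answer_rejected(self):
        s = make_session(0.0)
        s.symptoms = {k: v for k, v in s.symptoms.items() if k != "run_down"}
        with pytest.raises(FsmValidationError, match="run_down"):
            classify_symptom_change(s)


class TestMedicationEvent:
    def test_starting_steroids_is_a_rising_edge(self):
        h = [make_session(0.0), make_session(1.0, steroids=True)]
        assert detect_medication_event(h) == 1
        # continuation is not a new event
        h.append(make_session(2.0, steroids=True))
        assert detect_medication_event(h) == 0

    def test_flag_on_first_ever_session_counts_as_start(self):
        assert detect_medication_event([make_session(0.0, antibiotics=True)]) == 1

    def test_new_course_after_seven_day_gap(self):
        h = [make_session(0.0, antibiotics=True), make_session(8.0, antibiotics=True)]
        assert detect_medication_event(h) == 1

    def test_isolated_reliever_session_fails_48h_rule(self):
        h = [make_session(0.0), make_session(1.0, reliever_increased=True)]
        assert detect_medication_event(h) == 0

    def test_reliever_run_spanning_48h_fires(self):
        h = [
            make_session(0.0, reliever_increased=True),
            make_session(1.0, reliever_increased=True),
            make_session(2.1, reliever_increased=True),
        ]
        assert detect_medication_event(h) == 1
        assert detect_medication_event(h[:2]) == 0  # span 1.0 d only

    def test_non_reliever_session_breaks_the_run(self):
        h = [
            make_session(0.0, reliever_increased=True),
            make_session(1.0, reliever_increased=False),
            make_session(2.1, reliever_increased=True),
        ]
        assert detect_medication_event(h) == 0

    def test_gap_longer_than_bridge_breaks_the_run(self):
        h = [
            make_session(0.0, reliever_increased=True),
            make_session(2.5, reliever_increased=True),
        ]
        # 2.5-day gap exceeds the 2-day bridge, so the run restarts at t=2.5
        assert detect_medication_event(h) == 0


class TestEncodeInput:
    def test_worse_without_meds(self):
        s = make_session(0.0, worse=("breathlessness", "run_down"))
        assert encode_input(s, [s]) == FsmInput(0, "10")

    def test_improve_with_steroid_start(self):
        prev = make_session(0.0)
        s = make_session(
            1.0, improved=("breathlessness", "chest_tightness"), steroids=True
        )
        assert encode_input(s, [prev, s]) == FsmInput(1, "11")

    def test_quiet_session(self):
        s = make_session(0.0)
        assert encode_input(s, [s]) == FsmInput(0, "00")

    def test_hcp_contact_sets_event_bit(self):
        s = make_session(0.0, worse=("breathlessness", "run_down"), hcp_contact=True)
        assert encode_input(s, [s]) == FsmInput(1, "10")


class TestRunFsm:
    def test_empty_input_stays_in_initial_normal(self):
        tl = run_fsm([])
        assert tl.entries == [] and tl.final_state is N

    def test_canonical_three_step_trajectory(self):
        # inputs (0,10), (1,00), (0,11) -> TRANSITIONAL, EXACERBATION, NORMAL
        sessions = [
            make_session(0.0, worse=("breathlessness", "run_down")),
            # one persisting complaint is not significant either way; the
            # steroid start makes this (1,00)
            make_session(1.0, worse=("breathlessness",), steroids=True),
            make_session(2.0, improved=("breathlessness", "chest_tightness")),
        ]
        tl = run_fsm(sessions)
        assert [e.fsm_input.as_bits() for e in tl.entries] == ["010", "100", "011"]
        assert tl.states() == [T, E, N]

    def test_unsorted_sessions_rejected(self):
        with pytest.raises(FsmValidationError, match="sorted"):
            run_fsm([make_session(1.0), make_session(0.5)])

    def test_mixed_patients_rejected(self):
        with pytest.raises(FsmValidationError, match="single patient"):
            run_fsm([make_session(0.0, patient_id="A"), make_session(1.0, patient_id="B")])


def _exacerbating_sessions(enter_t, exit_t, patient_id="P0"):
    return [
        make_session(enter_t, worse=("breathlessness", "chest_tightness"),
                     antibiotics=True, patient_id=patient_id),
        make_session(exit_t, improved=("breathlessness", "chest_tightness"),
                     patient_id=patient_id),
    ]


class TestEvents:
    def test_no_exacerbation_no_events(self):
        tl = run_fsm([make_session(0.0), make_session(1.0)])
        assert extract_exacerbation_events(tl) == []

    def test_length_is_ceiling_of_span_with_minimum_one_day(self):
        tl = run_fsm(_exacerbating_sessions(10.2, 14.5))
        (ev,) = extract_exacerbation_events(tl)
        assert (ev.start_t, ev.end_t, ev.length_days, ev.open) == (10.2, 14.5, 5, False)

        tl_short = run_fsm(_exacerbating_sessions(3.0, 3.4))
        assert extract_exacerbation_events(tl_short)[0].length_days == 1

    def test_open_event_when_monitoring_ends_in_exacerbation(self):
        sessions = _exacerbating_sessions(5.0, 9.0)[:1] + [make_session(8.0, worse=("breathlessness",), antibiotics=True)]
        tl = run_fsm(sessions)
        (ev,) = extract_exacerbation_events(tl)
        assert ev.open and ev.end_t is None and ev.length_days == 3

    def test_two_maximal_runs_give_two_disjoint_events(self):
        sessions = _exacerbating_sessions(1.0, 4.0) + _exacerbating_sessions(20.0, 23.0)
        tl = run_fsm(sessions)
        e1, e2 = extract_exacerbation_events(tl)
        assert e1.end_t <= e2.start_t


class TestTransitionSummary:
    def test_patient_ending_normal_balances_exits_and_entries(self):
        tl = run_fsm(_exacerbating_sessions(1.0, 4.0))
        counts = transition_summary([tl])
        assert counts.exits(N) == counts.entries(N) == 1
        assert counts.n_final_non_normal == 0

    def test_cohort_imbalance_equals_non_normal_finishers(self):
        tls = []
        for i in range(3):  # each ends in EXACERBATION
            s = make_session(0.0, worse=("breathlessness", "run_down"),
                             antibiotics=True, patient_id=f"P{i}")
            tls.append(run_fsm([s]))
        counts = transition_summary(tls)
        assert counts.exits(N) - counts.entries(N) == 3 == counts.n_final_non_normal

    def test_empty_cohort_all_zero(self):
        counts = transition_summary([])
        assert counts.n_patients == 0
        assert all(v == 0 for v in counts.transitions.values())


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.sampled_from([0, 1]), st.sampled_from(["00", "10", "11"])),
        max_size=40,
    )
)
def test_state_conservation_for_arbitrary_input_sequences(seq):
    """exits(s) - entries(s) is +1/-1/0 depending on start/end state, for
    every state, on any legal input sequence."""
    state = N
    visits = []
    for bit, code in seq:
        state = step(state, FsmInput(bit, code))
        visits.append(state)
    for s in State:
        exits = entries = 0
        prev = N
        for cur in visits:
            exits += prev == s and cur != s
            entries += prev != s and cur == s
            prev = cur
        expected = int(prev == s) - int(N == s)
        assert entries - exits == expected
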