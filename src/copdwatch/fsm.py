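"""Finite-state machine over symptom-diary sessions.

A telemonitored COPD patient completes self-monitoring "sessions": six
categorical symptom answers (improved / no change / worse, each relative to
what is usual for that patient), medication flags (increased reliever use,
antibiotics, oral steroids), an optional health-care-professional (HCP)
contact flag, and pulse-oximeter vitals.  Each session is encoded as a 3-bit
input — one medication-event bit and a 2-bit symptom code — that drives a
deterministic three-state machine:

    NORMAL -> TRANSITIONAL   symptoms worsen without a medication event
    NORMAL -> EXACERBATION   symptoms worsen with a medication event
    TRANSITIONAL -> EXACERBATION   a medication event while symptoms have
                                   not improved
    any state -> NORMAL      symptoms improve

An *exacerbation* is thus operationalised as a significant symptom increase
(at least two symptoms worse, one of them major) coinciding with a
medication event (starting antibiotics/steroids, or increased reliever use
sustained for at least 48 hours) or an HCP contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "MAJOR_SYMPTOMS",
    "MINOR_SYMPTOMS",
    "SYMPTOM_KEYS",
    "State",
    "FsmInput",
    "DiarySession",
    "TimelineEntry",
    "StateTimeline",
    "ExacerbationEvent",
    "TransitionCounts",
    "classify_symptom_change",
    "detect_medication_event",
    "encode_input",
    "step",
    "run_fsm",
    "extract_exacerbation_events",
    "transition_summary",
]

#: Major symptoms: a "significant" change needs at least one of these.
MAJOR_SYMPTOMS = ("chest_tightness", "breathlessness", "sputum_volume", "sputum_purulence")
#: Minor symptoms.
MINOR_SYMPTOMS = ("cold_sore_throat", "run_down")
SYMPTOM_KEYS = MAJOR_SYMPTOMS + MINOR_SYMPTOMS

ANSWER_VALUES = ("improved", "no_change", "worse")

#: Legal 2-bit symptom codes.  "01" is not a valid code.
SYMPTOM_CODES = ("00", "10", "11")
CODE_NO_CHANGE, CODE_WORSE, CODE_IMPROVE = "00", "10", "11"


class State(str, Enum):
    """Patient condition state."""

    NORMAL = "NORMAL"
    TRANSITIONAL = "TRANSITIONAL"
    EXACERBATION = "EXACERBATION"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class FsmValidationError(ValueError):
    """Raised for malformed sessions or illegal machine inputs."""


@dataclass(frozen=True)
class FsmInput:
    """3-bit machine input: medication-event bit + 2-bit symptom code."""

    event_bit: int
    symptom_code: str

    def __post_init__(self) -> None:
        if self.event_bit not in (0, 1):
            raise FsmValidationError(f"event_bit must be 0 or 1, got {self.event_bit!r}")
        if self.symptom_code not in SYMPTOM_CODES:
            raise FsmValidationError(
                f"illegal symptom code {self.symptom_code!r}; legal codes are {SYMPTOM_CODES}"
            )

    def as_bits(self) -> str:
        return f"{self.event_bit}{self.symptom_code}"


@dataclass
class DiarySession:
    """One self-monitoring session.

    ``t`` is the session time in fractional days since the patient's first
    session.  ``symptoms`` maps each of the six symptom keys to one of
    ``improved`` / ``no_change`` / ``worse``.  ``resp_rate`` is filled in by
    the respiratory-rate stage (it is not reported by the oximeter).
    """

    patient_id: str
    t: float
    symptoms: Mapping[str, str]
    reliever_increased: bool = False
    antibiotics: bool = False
    steroids: bool = False
    hcp_contact: bool = False
    spo2: Optional[float] = None
    pulse_rate: Optional[float] = None
    resp_rate: Optional[float] = None
    timestamp: Optional[str] = None

    def validate(self) -> None:
        if self.t < 0:
            raise FsmValidationError(f"session time must be non-negative, got {self.t}")
        missing = [k for k in SYMPTOM_KEYS if k not in self.symptoms]
        if missing:
            raise FsmValidationError(f"session at t={self.t} missing symptom answers: {missing}")
        bad = {k: v for k, v in self.symptoms.items() if v not in ANSWER_VALUES}
        if bad:
            raise FsmValidationError(f"invalid symptom answers {bad}; allowed: {ANSWER_VALUES}")


# ---------------------------------------------------------------------------
# Input encoding
# ---------------------------------------------------------------------------

def classify_symptom_change(
    current: DiarySession, previous: Optional[DiarySession] = None
) -> str:
    """Classify a session's symptoms as ``worse``, ``improve`` or ``no_change``.

    Worsening: at least two answers are "worse", at least one of them for a
    major symptom.  Improvement mirrors that definition against the previous
    diary session: an answer counts toward improvement if it is "improved",
    or if the same symptom was "worse" at the previous session and is
    "no_change" now.  If both thresholds are met simultaneously, worsening
    wins (conservative toward detecting deterioration).
    """
    current.validate()
    worse = [k for k in SYMPTOM_KEYS if current.symptoms[k] == "worse"]
    if len(worse) >= 2 and any(k in MAJOR_SYMPTOMS for k in worse):
        return "worse"

    better = [k for k in SYMPTOM_KEYS if current.symptoms[k] == "improved"]
    if previous is not None:
        better += [
            k
            for k in SYMPTOM_KEYS
            if current.symptoms[k] == "no_change" and previous.symptoms.get(k) == "worse"
        ]
    if len(better) >= 2 and any(k in MAJOR_SYMPTOMS for k in better):
        return "improve"
    return "no_change"


def detect_medication_event(
    history: Sequence[DiarySession],
    *,
    reliever_min_span_days: float = 2.0,
    reliever_bridge_days: float = 2.0,
    new_course_gap_days: float = 7.0,
) -> int:
    """Return 1 iff a medication event holds at the last session of ``history``.

    A medication event is (a) *starting* oral steroids and/or antibiotics —
    a rising edge of either flag relative to the immediately preceding
    session, with a gap of ``new_course_gap_days`` or more since a flagged
    session treated as a new course — or (b) increased reliever-inhaler use
    sustained for at least 48 hours: a contiguous run of sessions with the
    reliever flag set whose time span reaches ``reliever_min_span_days``.
    Consecutive run members may be at most ``reliever_bridge_days`` apart.
    """
    if not history:
        return 0
    cur = history[-1]
    prev = history[-2] if len(history) >= 2 else None

    for flag in ("antibiotics", "steroids"):
        if getattr(cur, flag):
            if prev is None or not getattr(prev, flag):
                return 1
            if cur.t - prev.t >= new_course_gap_days:
                return 1

    if cur.reliever_increased:
        run_start = cur.t
        later = cur
        for s in reversed(history[:-1]):
            if not s.reliever_increased or (later.t - s.t) > reliever_bridge_days:
                break
            run_start = s.t
            later = s
        if cur.t - run_start >= reliever_min_span_days:
            return 1
    return 0


def encode_input(session: DiarySession, history: Sequence[DiarySession]) -> FsmInput:
    """Encode a session as a 3-bit FSM input.

    ``history`` is the patient's session sequence up to and including
    ``session`` (used for the previous-session symptom comparison and the
    48-hour reliever rule).  The event bit is set by a medication event or
    an HCP contact.
    """
    if not history or history[-1] is not session:
        history = list(history) + [session]
    prev = history[-2] if len(history) >= 2 else None
    change = classify_symptom_change(session, prev)
    code = {"no_change": CODE_NO_CHANGE, "worse": CODE_WORSE, "improve": CODE_IMPROVE}[change]
    event = detect_medication_event(history) or int(bool(session.hcp_contact))
    return FsmInput(event_bit=int(bool(event)), symptom_code=code)


# ---------------------------------------------------------------------------
# Transition function
# ---------------------------------------------------------------------------

def _build_transition_table() -> dict[tuple[State, int, str], State]:
    t: dict[tuple[State, int, str], State] = {}
    for e in (0, 1):
        # Improvement returns to NORMAL from every state, regardless of the
        # medication bit.
        for s in State:
            t[(s, e, CODE_IMPROVE)] = State.NORMAL
        # Patients stay in NORMAL unless symptoms worsen.
        t[(State.NORMAL, e, CODE_NO_CHANGE)] = State.NORMAL
        # EXACERBATION is only left via improvement.
        t[(State.EXACERBATION, e, CODE_NO_CHANGE)] = State.EXACERBATION
        t[(State.EXACERBATION, e, CODE_WORSE)] = State.EXACERBATION
    # Worsening from NORMAL: medication event decides the destination.
    t[(State.NORMAL, 0, CODE_WORSE)] = State.TRANSITIONAL
    t[(State.NORMAL, 1, CODE_WORSE)] = State.EXACERBATION
    # In TRANSITIONAL, a medication event (symptoms not improving) escalates.
    t[(State.TRANSITIONAL, 0, CODE_NO_CHANGE)] = State.TRANSITIONAL
    t[(State.TRANSITIONAL, 0, CODE_WORSE)] = State.TRANSITIONAL
    t[(State.TRANSITIONAL, 1, CODE_NO_CHANGE)] = State.EXACERBATION
    t[(State.TRANSITIONAL, 1, CODE_WORSE)] = State.EXACERBATION
    return t


TRANSITIONS = _build_transition_table()


def step(state: State, fsm_input: FsmInput) -> State:
    """Pure transition function over {3 states} x {6 legal inputs}."""
    if fsm_input.symptom_code not in SYMPTOM_CODES:
        raise FsmValidationError(f"illegal symptom code {fsm_input.symptom_code!r}")
    return TRANSITIONS[(State(state), fsm_input.event_bit, fsm_input.symptom_code)]


# ---------------------------------------------------------------------------
# Timelines and events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimelineEntry:
    t: float
    state: State
    fsm_input: FsmInput


@dataclass
class StateTimeline:
    """Per-patient state trajectory; patients start in NORMAL."""

    patient_id: str
    entries: list[TimelineEntry] = field(default_factory=list)
    initial_state: State = State.NORMAL

    @property
    def final_state(self) -> State:
        return self.entries[-1].state if self.entries else self.initial_state

    def states(self) -> list[State]:
        return [e.state for e in self.entries]


def run_fsm(sessions: Sequence[DiarySession]) -> StateTimeline:
    """Run the machine over one patient's time-ordered sessions."""
    if not sessions:
        return StateTimeline(patient_id="", entries=[])
    pid = sessions[0].patient_id
    prev_t = -math.inf
    for s in sessions:
        if s.patient_id != pid:
            raise FsmValidationError(
                f"run_fsm expects a single patient; got {pid!r} and {s.patient_id!r}"
            )
        if s.t <= prev_t:
            raise FsmValidationError(
                f"sessions must be sorted with strictly increasing t "
                f"(t={s.t} after t={prev_t} for patient {pid!r})"
            )
        prev_t = s.t

    state = State.NORMAL
    entries: list[TimelineEntry] = []
    for i, s in enumerate(sessions):
        inp = encode_input(s, sessions[: i + 1])
        state = step(state, inp)
        entries.append(TimelineEntry(t=s.t, state=state, fsm_input=inp))
    return StateTimeline(patient_id=pid, entries=entries)


@dataclass(frozen=True)
class ExacerbationEvent:
    """A maximal run of sessions in the EXACERBATION state.

    ``end_t`` is the time of the session that exits back to NORMAL, or None
    if monitoring ended while still in EXACERBATION (an *open* event).
    ``length_days`` is the day span rounded up, with a minimum of 1 day.
    """

    start_t: float
    end_t: Optional[float]
    length_days: int
    open: bool = False


def _event_length(start_t: float, end_t: float) -> int:
    return max(1, math.ceil(end_t - start_t))


def extract_exacerbation_events(timeline: StateTimeline) -> list[ExacerbationEvent]:
    """One event per maximal EXACERBATION run in the timeline."""
    events: list[ExacerbationEvent] = []
    prev = timeline.initial_state
    start: Optional[float] = None
    for e in timeline.entries:
        if e.state == State.EXACERBATION and prev != State.EXACERBATION:
            start = e.t
        elif e.state != State.EXACERBATION and prev == State.EXACERBATION:
            assert start is not None
            events.append(
                ExacerbationEvent(start_t=start, end_t=e.t, length_days=_event_length(start, e.t))
            )
            start = None
        prev = e.state
    if start is not None:  # study ended in EXACERBATION
        last_t = timeline.entries[-1].t
        events.append(
            ExacerbationEvent(
                start_t=start, end_t=None, length_days=_event_length(start, last_t), open=True
            )
        )
    return events


@dataclass
class TransitionCounts:
    """Aggregated transition and occupancy counts across patients.

    ``transitions`` counts ordered (from, to) pairs over consecutive session
    states, including the step from the assumed initial NORMAL state to the
    first session's state; self-pairs (no state change) are included.
    ``session_counts`` counts sessions by their (post-input) state.
    """

    transitions: dict[tuple[State, State], int] = field(default_factory=dict)
    session_counts: dict[State, int] = field(default_factory=dict)
    n_patients: int = 0
    n_final_non_normal: int = 0

    def exits(self, state: State) -> int:
        return sum(n for (a, b), n in self.transitions.items() if a == state and b != state)

    def entries(self, state: State) -> int:
        return sum(n for (a, b), n in self.transitions.items() if b == state and a != state)


def transition_summary(timelines: Iterable[StateTimeline]) -> TransitionCounts:
    """Aggregate transitions and verify per-patient conservation.

    For a patient starting in NORMAL, exits(NORMAL) − entries(NORMAL) is 1
    if the patient finishes outside NORMAL and 0 otherwise; the aggregate
    difference therefore equals the number of non-NORMAL finishers.
    """
    out = TransitionCounts(
        transitions={(a, b): 0 for a in State for b in State},
        session_counts={s: 0 for s in State},
    )
    for tl in timelines:
        out.n_patients += 1
        prev = tl.initial_state
        exits_n = entries_n = 0
        for e in tl.entries:
            out.transitions[(prev, e.state)] += 1
            out.session_counts[e.state] += 1
            if prev == State.NORMAL and e.state != State.NORMAL:
                exits_n += 1
            if prev != State.NORMAL and e.state == State.NORMAL:
                entries_n += 1
            prev = e.state
        ends_off_normal = tl.final_state != State.NORMAL
        out.n_final_non_normal += int(ends_off_normal)
        if exits_n - entries_n != int(ends_off_normal):  # pragma: no cover - invariant
            raise AssertionError(
                f"conservation violated for patient {tl.patient_id!r}: "
                f"exits={exits_n}, entries={entries_n}, final={tl.final_state}"
            )
    return out
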