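"""Shared fixtures: session builders and a session-scoped synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from copdwatch.fsm import (
    DiarySession,
    FsmInput,
    State,
    StateTimeline,
    SYMPTOM_KEYS,
    TimelineEntry,
    extract_exacerbation_events,
    run_fsm,
)
from copdwatch.simulate import CohortConfig, generate_cohort


def make_session(
    t: float,
    worse=(),
    improved=(),
    patient_id: str = "P0",
    **kwargs,
) -> DiarySession:
    """A diary session with the named symptoms worse/improved and the rest
    unchanged; flags and vitals via keyword arguments."""
    symptoms = {k: "no_change" for k in SYMPTOM_KEYS}
    for k in worse:
        symptoms[k] = "worse"
    for k in improved:
        symptoms[k] = "improved"
    return DiarySession(patient_id=patient_id, t=t, symptoms=symptoms, **kwargs)


def make_timeline(states: list[tuple[float, State]], patient_id: str = "P0") -> StateTimeline:
    """A timeline with the given (t, state) entries and dummy inputs."""
    dummy = FsmInput(0, "00")
    return StateTimeline(
        patient_id=patient_id,
        entries=[TimelineEntry(t=t, state=s, fsm_input=dummy) for t, s in states],
    )


@pytest.fixture(scope="session")
def big_cohort():
    """100 patients monitored for a year (shared; do not mutate)."""
    return generate_cohort(CohortConfig(n_patients=100, duration_days=365, seed=11))


@pytest.fixture(scope="session")
def big_cohort_fsm(big_cohort):
    timelines = {pid: run_fsm(s) for pid, s in big_cohort.sessions.items()}
    events = {pid: extract_exacerbation_events(tl) for pid, tl in timelines.items()}
    return timelines, events


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
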