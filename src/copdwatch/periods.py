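"""Selection of independent 7-day stable and prodromal periods.

A *prodromal* period is the 7-day window immediately before an exacerbation
event, kept only if the patient was in the NORMAL or TRANSITIONAL state
throughout the window and completed at least two diary sessions in it.  A
*stable* period is a 7-day window lying entirely inside a NORMAL stretch,
separated by 7-day guard bands from the preceding and following
transitional/exacerbation states.  Guard bands are only applied against
non-NORMAL states: the enrollment date and the study end need no guard.

Between sessions, a patient's state is taken to be the state assigned at
the most recent session (a step function in time); before the first
session, patients are assumed NORMAL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

from .fsm import DiarySession, ExacerbationEvent, State, StateTimeline

__all__ = [
    "Period",
    "select_prodromal_periods",
    "select_stable_periods",
    "attach_vitals",
    "state_intervals",
]

logger = logging.getLogger(__name__)

WINDOW_DAYS = 7.0
GUARD_DAYS = 7.0
MIN_SESSIONS = 2


@dataclass
class Period:
    """A labeled 7-day window with its member sessions."""

    patient_id: str
    start_t: float
    end_t: float
    label: str  # "stable" or "prodromal"
    sessions: list[DiarySession]

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)


def state_intervals(
    timeline: StateTimeline, t_end: Optional[float] = None
) -> list[tuple[float, float, State]]:
    """Merge the timeline into maximal [a, b) intervals of constant state.

    The first interval starts at t=0 in the assumed initial NORMAL state;
    the last interval ends at ``t_end`` (default: the last session time).
    """
    if not timeline.entries:
        end = t_end if t_end is not None else 0.0
        return [(0.0, end, timeline.initial_state)] if end > 0 else []
    last_t = timeline.entries[-1].t
    end = max(t_end, last_t) if t_end is not None else last_t

    points = [(0.0, timeline.initial_state)] + [(e.t, e.state) for e in timeline.entries]
    merged: list[tuple[float, State]] = []
    for t, s in points:
        if not merged or merged[-1][1] != s:
            merged.append((t, s))
    out: list[tuple[float, float, State]] = []
    for i, (t, s) in enumerate(merged):
        b = merged[i + 1][0] if i + 1 < len(merged) else end
        if b > t:
            out.append((t, b, s))
    return out


def _state_at(timeline: StateTimeline, t: float) -> State:
    state = timeline.initial_state
    for e in timeline.entries:
        if e.t <= t:
            state = e.state
        else:
            break
    return state


def _sessions_in(sessions: Sequence[DiarySession], a: float, b: float) -> list[DiarySession]:
    return [s for s in sessions if a <= s.t < b]


def select_prodromal_periods(
    timeline: StateTimeline,
    events: Sequence[ExacerbationEvent],
    sessions: Sequence[DiarySession],
    *,
    window_days: float = WINDOW_DAYS,
    min_sessions: int = MIN_SESSIONS,
) -> list[Period]:
    """Extract the pre-onset window of each sufficiently isolated event.

    An event whose preceding ``window_days`` include any time in the
    EXACERBATION state (e.g. a previous event that ended within 7 days) is
    skipped, as is any window with fewer than ``min_sessions`` sessions.
    """
    states = {e.t: e.state for e in timeline.entries}
    out: list[Period] = []
    for ev in events:
        a, b = ev.start_t - window_days, ev.start_t
        if _state_at(timeline, a) == State.EXACERBATION:
            logger.debug(
                "prodromal window before t=%.2f rejected: prior exacerbation overlaps", b
            )
            continue
        members = _sessions_in(sessions, a, b)
        if any(states.get(s.t) == State.EXACERBATION for s in members):
            logger.debug("prodromal window before t=%.2f rejected: exacerbation session", b)
            continue
        if len(members) < min_sessions:
            logger.debug(
                "prodromal window before t=%.2f rejected: only %d session(s)", b, len(members)
            )
            continue
        out.append(
            Period(
                patient_id=timeline.patient_id,
                start_t=a,
                end_t=b,
                label="prodromal",
                sessions=members,
            )
        )
    return out


def select_stable_periods(
    timeline: StateTimeline,
    sessions: Sequence[DiarySession],
    *,
    window_days: float = WINDOW_DAYS,
    guard_days: float = GUARD_DAYS,
    min_sessions: int = MIN_SESSIONS,
    t_end: Optional[float] = None,
) -> list[Period]:
    """Tile guarded NORMAL stretches with non-overlapping 7-day windows.

    Each maximal NORMAL interval is trimmed by ``guard_days`` after its
    start (if it began by returning from a non-NORMAL state) and before its
    end (if it ended by leaving NORMAL); the remainder is tiled from the
    left with consecutive ``window_days`` windows, keeping those containing
    at least ``min_sessions`` sessions.
    """
    intervals = state_intervals(timeline, t_end=t_end)
    out: list[Period] = []
    for i, (a, b, s) in enumerate(intervals):
        if s != State.NORMAL:
            continue
        left = a + guard_days if i > 0 else a
        right = b - guard_days if i + 1 < len(intervals) else b
        w = left
        while w + window_days <= right:
            members = _sessions_in(sessions, w, w + window_days)
            if len(members) >= min_sessions:
                out.append(
                    Period(
                        patient_id=timeline.patient_id,
                        start_t=w,
                        end_t=w + window_days,
                        label="stable",
                        sessions=members,
                    )
                )
            w += window_days
    return out


def attach_vitals(
    period: Period,
    rr_estimates: Optional[Mapping[tuple[str, float], float]] = None,
    *,
    min_sessions: int = MIN_SESSIONS,
) -> Optional[Period]:
    """Attach respiratory-rate estimates and drop incomplete sessions.

    ``rr_estimates`` maps (patient_id, session time) to a respiratory rate
    in breaths/min; sessions whose ``resp_rate`` is already set keep it.
    Sessions missing any of SpO2, pulse rate or respiratory rate are
    dropped; returns None (period removed) if fewer than ``min_sessions``
    complete sessions remain.
    """
    kept: list[DiarySession] = []
    for s in period.sessions:
        rr = s.resp_rate
        if rr is None and rr_estimates is not None:
            rr = rr_estimates.get((s.patient_id, s.t))
        if s.spo2 is None or s.pulse_rate is None or rr is None:
            continue
        kept.append(replace(s, resp_rate=rr))
    if len(kept) < min_sessions:
        logger.info(
            "dropping %s period [%.2f, %.2f) for %s: %d complete session(s) < %d",
            period.label,
            period.start_t,
            period.end_t,
            period.patient_id,
            len(kept),
            min_sessions,
        )
        return None
    return replace(period, sessions=kept)
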