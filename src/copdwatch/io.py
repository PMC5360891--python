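"""File dialects: session/timeline/period/feature CSVs, ROC JSON, configs.

All tables are comma-separated UTF-8 with a header row.  Timestamps are
ISO-8601; on reading, each patient's session times are converted to
fractional days since that patient's first session, which is the time axis
used by every analysis stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from datetime import datetime
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .classify import RocSummary
from .fsm import (
    DiarySession,
    ExacerbationEvent,
    StateTimeline,
    SYMPTOM_KEYS,
    TransitionCounts,
)
from .periods import Period

__all__ = [
    "SESSION_COLUMNS",
    "read_sessions",
    "write_sessions",
    "write_timelines",
    "write_events",
    "write_periods",
    "write_rr_table",
    "read_rr_table",
    "write_roc_summary",
    "write_ppg_csv",
    "read_ppg_csv",
    "config_hash",
    "load_config",
    "dump_config",
]

PathLike = Union[str, Path]

FLAG_COLUMNS = ["reliever_increased", "antibiotics", "steroids", "hcp_contact"]
SESSION_COLUMNS = ["patient_id", "timestamp"] + list(SYMPTOM_KEYS) + FLAG_COLUMNS + [
    "spo2",
    "pulse_rate",
]


class SessionFileError(ValueError):
    """Malformed session file (missing columns, bad rows, duplicates)."""


def _parse_flag(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(int(v))


def read_sessions(path: PathLike) -> dict[str, list[DiarySession]]:
    """Read and validate a session CSV into per-patient, time-sorted streams.

    Malformed rows are reported with their line number (header = line 1).
    Duplicate (patient, timestamp) pairs are an error.
    """
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise SessionFileError(f"{path}: missing columns {missing}")

    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError):
        ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        raise SessionFileError(
            f"{path}: unparseable timestamp at line {int(bad[0]) + 2}: "
            f"{df['timestamp'].iloc[bad[0]]!r}"
        )
    df = df.assign(_ts=ts, _line=np.arange(2, len(df) + 2))

    dup = df.duplicated(subset=["patient_id", "_ts"], keep=False)
    if dup.any():
        lines = df.loc[dup, "_line"].tolist()
        raise SessionFileError(f"{path}: duplicate (patient, timestamp) rows at lines {lines}")

    out: dict[str, list[DiarySession]] = {}
    for pid, g in df.sort_values(["patient_id", "_ts"], kind="mergesort").groupby(
        "patient_id", sort=True
    ):
        t0 = g["_ts"].iloc[0]
        sessions = []
        for _, row in g.iterrows():
            t = (row["_ts"] - t0).total_seconds() / 86400.0
            s = DiarySession(
                patient_id=str(pid),
                t=t,
                symptoms={k: str(row[k]) for k in SYMPTOM_KEYS},
                reliever_increased=_parse_flag(row["reliever_increased"]),
                antibiotics=_parse_flag(row["antibiotics"]),
                steroids=_parse_flag(row["steroids"]),
                hcp_contact=_parse_flag(row["hcp_contact"]),
                spo2=None if pd.isna(row["spo2"]) else float(row["spo2"]),
                pulse_rate=None if pd.isna(row["pulse_rate"]) else float(row["pulse_rate"]),
                timestamp=row["_ts"].isoformat(),
            )
            try:
                s.validate()
            except ValueError as exc:
                raise SessionFileError(f"{path}: invalid row at line {row['_line']}: {exc}") from exc
            sessions.append(s)
        out[str(pid)] = sessions
    return out


def sessions_to_frame(cohort: Mapping[str, Sequence[DiarySession]]) -> pd.DataFrame:
    rows = []
    for pid in sorted(cohort):
        for s in cohort[pid]:
            row = {"patient_id": pid, "timestamp": s.timestamp}
            row.update({k: s.symptoms[k] for k in SYMPTOM_KEYS})
            for f in FLAG_COLUMNS:
                row[f] = int(bool(getattr(s, f)))
            row["spo2"] = s.spo2
            row["pulse_rate"] = s.pulse_rate
            rows.append(row)
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_sessions(cohort: Mapping[str, Sequence[DiarySession]], path: PathLike) -> None:
    sessions_to_frame(cohort).to_csv(path, index=False)


def write_timelines(timelines: Mapping[str, StateTimeline], path: PathLike) -> None:
    rows = [
        {
            "patient_id": pid,
            "t": e.t,
            "state": e.state.value,
            "event_bit": e.fsm_input.event_bit,
            "symptom_code": e.fsm_input.symptom_code,
        }
        for pid in sorted(timelines)
        for e in timelines[pid].entries
    ]
    pd.DataFrame(rows, columns=["patient_id", "t", "state", "event_bit", "symptom_code"]).to_csv(
        path, index=False
    )


def write_events(events: Mapping[str, Sequence[ExacerbationEvent]], path: PathLike) -> None:
    rows = [
        {
            "patient_id": pid,
            "start_t": ev.start_t,
            "end_t": "" if ev.end_t is None else ev.end_t,
            "length_days": ev.length_days,
            "open": int(ev.open),
        }
        for pid in sorted(events)
        for ev in events[pid]
    ]
    pd.DataFrame(rows, columns=["patient_id", "start_t", "end_t", "length_days", "open"]).to_csv(
        path, index=False
    )


def write_periods(periods: Sequence[Period], path: PathLike,
                  sessions_path: Optional[PathLike] = None) -> None:
    """Write a period table and, optionally, a long-format member-session table."""
    rows = [
        {
            "patient_id": p.patient_id,
            "label": p.label,
            "start_t": p.start_t,
            "end_t": p.end_t,
            "n_sessions": p.n_sessions,
        }
        for p in periods
    ]
    pd.DataFrame(rows, columns=["patient_id", "label", "start_t", "end_t", "n_sessions"]).to_csv(
        path, index=False
    )
    if sessions_path is not None:
        srows = [
            {
                "patient_id": p.patient_id,
                "label": p.label,
                "period_start_t": p.start_t,
                "t": s.t,
                "spo2": s.spo2,
                "pulse_rate": s.pulse_rate,
                "resp_rate": s.resp_rate,
            }
            for p in periods
            for s in p.sessions
        ]
        pd.DataFrame(
            srows,
            columns=["patient_id", "label", "period_start_t", "t", "spo2", "pulse_rate", "resp_rate"],
        ).to_csv(sessions_path, index=False)


def write_rr_table(rows: Sequence[Mapping], path: PathLike) -> None:
    pd.DataFrame(rows, columns=["patient_id", "t", "rr_brpm", "hr_bpm_used", "quality"]).to_csv(
        path, index=False
    )


def read_rr_table(path: PathLike) -> dict[tuple[str, float], float]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    ok = df["quality"].isin(["ok", "low_confidence"]) & df["rr_brpm"].notna()
    return {
        (str(r.patient_id), float(r.t)): float(r.rr_brpm)
        for r in df[ok].itertuples()
    }


def write_transition_summary(counts: TransitionCounts, path: PathLike) -> None:
    payload = {
        "n_patients": counts.n_patients,
        "n_final_non_normal": counts.n_final_non_normal,
        "session_counts": {s.value: n for s, n in counts.session_counts.items()},
        "transitions": {f"{a.value}->{b.value}": n for (a, b), n in counts.transitions.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_roc_summary(summary: RocSummary, path: PathLike) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2))


def write_ppg_csv(samples: np.ndarray, fs_hz: float, path: PathLike) -> None:
    """One sample per row, sampling rate recorded in the header comment row."""
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={fs_hz}\nsample\n")
        for v in np.asarray(samples, dtype=float):
            fh.write(f"{v:.8g}\n")


def read_ppg_csv(path: PathLike):
    from .ppg import PPGSegment

    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs_hz="):
            raise SessionFileError(f"{path}: missing '# fs_hz=' header")
        fs = float(header.split("=", 1)[1])
        fh.readline()  # column name
        samples = np.array([float(line) for line in fh if line.strip()])
    return PPGSegment(samples=samples, fs_hz=fs)


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, datetime):
        return obj.isoformat()
    return obj


def config_hash(config) -> str:
    """Stable short hash of a (dataclass or mapping) configuration."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def dump_config(config, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(_jsonable(config), sort_keys=True))


def load_config(path: PathLike) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
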