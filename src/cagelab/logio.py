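"""Readers and writers for the three CSV log schemas and the settings JSON.

All three logs are plain UTF-8, comma-separated CSV with a mandatory header
and one file per log type per colony:

* ``events.csv``  -- timestamp, subject_id, kind, detail (JSON string)
* ``trials.csv``  -- one row per trial, stimulus serialized as JSON
* ``antenna.csv`` -- timestamp, antenna_id, subject_id

Writers are bit-stable: the same sequence always produces byte-identical
files (fixed column order, shortest-round-trip float formatting, sorted JSON
keys), and ``read(write(x)) == x`` for valid inputs.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Any, Iterable, Sequence

from .records import (
    AntennaDetection,
    ConsistencyError,
    CorridorEvent,
    SchemaError,
    Session,
    TaskParameters,
    Trial,
    ValidationError,
)

EVENT_COLUMNS = ["timestamp", "subject_id", "kind", "detail"]
TRIAL_COLUMNS = [
    "subject_id",
    "session_ref",
    "index",
    "onset",
    "duration",
    "task",
    "difficulty",
    "stimulus",
    "choice",
    "outcome",
    "reward_ul",
    "forced_iti",
]
ANTENNA_COLUMNS = ["timestamp", "antenna_id", "subject_id"]


def _fmt(x: float) -> str:
    """Shortest decimal representation that round-trips the float exactly."""
    return repr(float(x))


def _check_header(header: Sequence[str] | None, expected: Sequence[str], path: Path) -> None:
    if header is None:
        raise SchemaError(f"{path}: empty file, expected header {expected}")
    if list(header) != list(expected):
        raise SchemaError(f"{path}: header {list(header)} does not match {list(expected)}")


def _warn_if_non_monotone(timestamps: Sequence[float], path: Path) -> None:
    for i in range(1, len(timestamps)):
        if timestamps[i] < timestamps[i - 1]:
            warnings.warn(
                f"{path}: timestamps are not non-decreasing at row {i + 1}",
                stacklevel=3,
            )
            return


# ---------------------------------------------------------------------------
# events.csv

def write_event_log(events: Iterable[CorridorEvent], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(EVENT_COLUMNS)
        for ev in events:
            writer.writerow(
                [
                    _fmt(ev.timestamp),
                    ev.subject_id or "",
                    ev.kind,
                    json.dumps(dict(ev.detail), sort_keys=True, separators=(",", ":")),
                ]
            )
    return path


def read_event_log(path: str | Path) -> list[CorridorEvent]:
    path = Path(path)
    events: list[CorridorEvent] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, EVENT_COLUMNS, path)
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(EVENT_COLUMNS):
                raise SchemaError(f"{path}: row {i} has {len(row)} fields")
            ts, subject, kind, detail = row
            try:
                events.append(
                    CorridorEvent(
                        timestamp=float(ts),
                        kind=kind,
                        subject_id=subject or None,
                        detail=json.loads(detail) if detail else {},
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise SchemaError(f"{path}: invalid row {i}: {exc}") from exc
    _warn_if_non_monotone([e.timestamp for e in events], path)
    return events


# ---------------------------------------------------------------------------
# trials.csv

def write_trial_log(trials: Iterable[Trial], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(TRIAL_COLUMNS)
        for tr in trials:
            writer.writerow(
                [
                    tr.subject_id,
                    tr.session_ref,
                    str(tr.index),
                    _fmt(tr.onset),
                    _fmt(tr.duration),
                    tr.task,
                    tr.difficulty,
                    json.dumps(tr.stimulus, sort_keys=True, separators=(",", ":")),
                    tr.choice or "",
                    tr.outcome,
                    _fmt(tr.reward_ul),
                    _fmt(tr.forced_iti),
                ]
            )
    return path


def read_trial_log(path: str | Path) -> list[Trial]:
    path = Path(path)
    trials: list[Trial] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, TRIAL_COLUMNS, path)
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(TRIAL_COLUMNS):
                raise SchemaError(f"{path}: row {i} has {len(row)} fields")
            try:
                trials.append(
                    Trial(
                        subject_id=row[0],
                        session_ref=row[1],
                        index=int(row[2]),
                        onset=float(row[3]),
                        duration=float(row[4]),
                        task=row[5],
                        difficulty=row[6],
                        stimulus=json.loads(row[7]) if row[7] else None,
                        choice=row[8] or None,
                        outcome=row[9],
                        reward_ul=float(row[10]),
                        forced_iti=float(row[11]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise SchemaError(f"{path}: invalid row {i}: {exc}") from exc
    _warn_if_non_monotone([t.onset for t in trials], path)
    return trials


# ---------------------------------------------------------------------------
# antenna.csv

def write_antenna_log(detections: Iterable[AntennaDetection], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(ANTENNA_COLUMNS)
        for d in detections:
            writer.writerow([_fmt(d.timestamp), str(d.antenna_id), d.subject_id])
    return path


def read_antenna_log(path: str | Path) -> list[AntennaDetection]:
    path = Path(path)
    out: list[AntennaDetection] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, ANTENNA_COLUMNS, path)
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(ANTENNA_COLUMNS):
                raise SchemaError(f"{path}: row {i} has {len(row)} fields")
            try:
                out.append(
                    AntennaDetection(
                        timestamp=float(row[0]),
                        antenna_id=int(row[1]),
                        subject_id=row[2],
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise SchemaError(f"{path}: invalid row {i}: {exc}") from exc
    _warn_if_non_monotone([d.timestamp for d in out], path)
    return out


# ---------------------------------------------------------------------------
# Session reconstruction

def sessions_from_events(events: Sequence[CorridorEvent]) -> list[Session]:
    """Pair ``session_start``/``session_end`` events into :class:`Session` records.

    Events must be time-ordered per subject.  ``door2_open`` events that occur
    while a session is running are attributed to that session as its
    ``door_open_time`` (the controller guarantees single occupancy).  A
    ``session_start`` left unmatched at the end of the log yields an open
    session (``open=True``) and a warning; a nested ``session_start`` for the
    same subject raises :class:`ConsistencyError`.
    """
    open_session: dict[str, dict[str, Any]] = {}
    sessions: list[Session] = []
    last_ts = 0.0
    for ev in events:
        last_ts = max(last_ts, ev.timestamp)
        if ev.kind == "session_start":
            sid = ev.subject_id
            if sid is None:
                raise ConsistencyError("session_start without subject_id")
            if sid in open_session:
                raise ConsistencyError(f"nested session_start for subject {sid}")
            open_session[sid] = {
                "start": ev.timestamp,
                "task": ev.detail.get("task", ""),
                "stage": int(ev.detail.get("stage", 0)),
                "door_open_time": None,
            }
        elif ev.kind == "door2_open" and len(open_session) == 1:
            rec = next(iter(open_session.values()))
            if rec["door_open_time"] is None:
                rec["door_open_time"] = ev.timestamp
        elif ev.kind == "session_end":
            sid = ev.subject_id
            rec = open_session.pop(sid, None) if sid else None
            if rec is None:
                raise ConsistencyError(
                    f"session_end without matching session_start for subject {sid}"
                )
            sessions.append(
                Session(
                    subject_id=sid,
                    start=rec["start"],
                    end=ev.timestamp,
                    task=rec["task"],
                    stage=rec["stage"],
                    door_open_time=rec["door_open_time"],
                    n_trials=int(ev.detail.get("n_trials", 0)),
                    water_ul=float(ev.detail.get("water_ul", 0.0)),
                )
            )
    for sid, rec in open_session.items():
        warnings.warn(f"open session for subject {sid} at end of log", stacklevel=2)
        sessions.append(
            Session(
                subject_id=sid,
                start=rec["start"],
                end=max(last_ts, rec["start"]),
                task=rec["task"],
                stage=rec["stage"],
                door_open_time=rec["door_open_time"],
                open=True,
            )
        )
    sessions.sort(key=lambda s: (s.start, s.subject_id))
    return sessions


# ---------------------------------------------------------------------------
# Per-subject settings JSON

_SETTINGS_KEYS = {"subject_id", "task", "stage", "params", "updated_at"}


def write_settings(params: TaskParameters, path: str | Path) -> Path:
    path = Path(path)
    payload: dict[str, Any] = {
        "subject_id": params.subject_id,
        "task": params.task,
        "stage": params.stage,
        "params": params.params,
        "updated_at": params.updated_at,
    }
    payload.update(params.extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_settings(path: str | Path) -> TaskParameters:
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: settings file must contain a JSON object")
    missing = {"subject_id", "task", "stage"} - payload.keys()
    if missing:
        raise SchemaError(f"{path}: missing keys {sorted(missing)}")
    extra = {k: v for k, v in payload.items() if k not in _SETTINGS_KEYS}
    return TaskParameters(
        subject_id=payload["subject_id"],
        task=payload["task"],
        stage=int(payload["stage"]),
        params=dict(payload.get("params", {})),
        updated_at=float(payload.get("updated_at", 0.0)),
        extra=extra,
    )
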