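"""Corridor access-control state machine.

The corridor connects the home cages to the operant box through two motorized
doors and a double identification stage (RFID + camera zone report).  The
controller admits exactly one animal at a time, enforces a refractory
interval between a subject's sessions and a minimum session duration during
which the exit door stays closed, and handles the exit/weighing sequence.

It is driven entirely by abstract stimuli so that a simulator (or a hardware
shim, out of scope here) can supply them::

    ("rfid_detect", subject_id)
    ("zone_report", {zone_id: "empty" | "single" | "multiple"})
    ("box_entry_detected", None)
    ("timer_tick", None)
    ("scale_reading", grams)
    ("box_empty_detected", None)

Every transition emits a deterministic command list: door commands, task
start/stop, and ``("LOG", CorridorEvent)`` entries that together form the
events.csv log.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping

import numpy as np

from .records import ConfigError, CorridorEvent, SubjectRecord, TaskParameters

# Phases
WAIT = "WAIT"
DETECTION = "DETECTION"
ACCESS_GRANTED = "ACCESS_GRANTED"
SESSION_RUNNING = "SESSION_RUNNING"
EXIT_PENDING = "EXIT_PENDING"

# Entry decisions
GRANTED = "granted"
DENIED_MULTI = "denied(multi_animal)"
DENIED_REFRACTORY = "denied(refractory)"
DENIED_UNKNOWN = "denied(unknown_subject)"

Stimulus = tuple[str, Any]
Command = tuple[str, Any]


@dataclass
class ControllerConfig:
    """Timing rules of the corridor.

    ``min_session_duration`` is either a fixed number of seconds or a
    ``(low, high)`` range from which each session's value is drawn uniformly
    with the controller's seeded RNG (the draw is logged on the
    ``session_start`` event).  ``restrictions_enabled=False`` disables both
    the refractory check and the minimum-duration door hold, nothing else.
    """

    refractory_interval: float = 14400.0
    min_session_duration: float | tuple[float, float] = 1800.0
    scale_settle_window: float = 2.0
    restrictions_enabled: bool = True
    seed: int = 0
    subjects: dict[str, SubjectRecord] | None = None
    settings: dict[str, TaskParameters] | None = None

    def __post_init__(self) -> None:
        if self.refractory_interval < 0:
            raise ConfigError("refractory_interval must be >= 0")
        if isinstance(self.min_session_duration, tuple):
            lo, hi = self.min_session_duration
            if not 0 <= lo <= hi:
                raise ConfigError("min_session_duration range must satisfy 0 <= low <= high")
        elif self.min_session_duration < 0:
            raise ConfigError("min_session_duration must be >= 0")


@dataclass
class ControllerState:
    phase: str = WAIT
    pending_subject: str | None = None
    pending_since: float | None = None
    current_subject: str | None = None
    session_started_at: float | None = None
    exit_door_deadline: float | None = None
    door_opened_at: float | None = None
    min_duration_draw: float | None = None
    last_session_end: dict[str, float] = field(default_factory=dict)
    scale_readings: list[float] = field(default_factory=list)
    scale_first_ts: float | None = None
    rng: np.random.Generator | None = None


def initial_state(config: ControllerConfig) -> ControllerState:
    return ControllerState(rng=np.random.default_rng(config.seed))


def _draw_min_duration(state: ControllerState, config: ControllerConfig) -> float:
    if not config.restrictions_enabled:
        return 0.0
    md = config.min_session_duration
    if isinstance(md, tuple):
        lo, hi = md
        assert state.rng is not None, "state must be created with initial_state()"
        return float(state.rng.uniform(lo, hi))
    return float(md)


def evaluate_entry(
    subject_id: str,
    now: float,
    zone_state: Mapping[str, str],
    state: ControllerState,
    config: ControllerConfig,
) -> str:
    """Decide whether ``subject_id`` may enter the box.

    A multi-animal zone report takes precedence: if any corridor zone reports
    multiple animals the attempt is denied without evaluating the refractory
    interval (so such attempts are never double-counted as refractory ones).
    """
    if config.subjects is not None and subject_id not in config.subjects:
        return DENIED_UNKNOWN
    if any(label == "multiple" for label in zone_state.values()):
        return DENIED_MULTI
    if config.restrictions_enabled:
        last_end = state.last_session_end.get(subject_id)
        if last_end is not None and now - last_end < config.refractory_interval:
            return DENIED_REFRACTORY
    return GRANTED


def _log(commands: list[Command], ev: CorridorEvent) -> None:
    commands.append(("LOG", ev))


def _warn(commands: list[Command], now: float, message: str) -> None:
    commands.append(("WARN", f"t={now:.3f}: {message}"))


def step(
    state: ControllerState,
    stimulus: Stimulus,
    now: float,
    config: ControllerConfig,
) -> tuple[ControllerState, list[Command]]:
    """Advance the state machine by one stimulus.

    Returns a new state (the input state is not mutated) and the ordered
    command list emitted by the transition.  A stimulus that is illegal for
    the current phase produces no transition and a ``("WARN", ...)`` command.
    """
    state = replace(
        state,
        last_session_end=dict(state.last_session_end),
        scale_readings=list(state.scale_readings),
    )
    kind, payload = stimulus
    commands: list[Command] = []

    if kind == "timer_tick":
        _handle_timer(state, now, config, commands)
        return state, commands

    if state.phase == WAIT:
        if kind == "rfid_detect":
            state.phase = DETECTION
            state.pending_subject = str(payload)
            state.pending_since = now
            _log(commands, CorridorEvent(now, "rfid_detect", str(payload)))
        else:
            _warn(commands, now, f"{kind} ignored in WAIT")

    elif state.phase == DETECTION:
        if kind == "rfid_detect":
            # Tie-break between near-simultaneous detections: first by
            # timestamp, then lexicographic subject id; logged either way.
            _log(commands, CorridorEvent(now, "rfid_detect", str(payload)))
            if now == state.pending_since and str(payload) < str(state.pending_subject):
                state.pending_subject = str(payload)
        elif kind == "zone_report":
            zones = dict(payload)
            subject = state.pending_subject
            assert subject is not None
            _log(commands, CorridorEvent(now, "zone_report", subject, {"zones": zones}))
            decision = evaluate_entry(subject, now, zones, state, config)
            if decision == GRANTED:
                state.phase = ACCESS_GRANTED
                state.current_subject = subject
                state.min_duration_draw = _draw_min_duration(state, config)
                commands.append(("CLOSE_DOOR1", None))
                commands.append(("OPEN_DOOR2", None))
                _log(commands, CorridorEvent(now, "door1_close"))
                _log(commands, CorridorEvent(now, "door2_open"))
                _log(commands, CorridorEvent(now, "entry_granted", subject))
            else:
                reason = decision[len("denied(") : -1]
                _log(
                    commands,
                    CorridorEvent(now, "entry_denied", subject, {"denial_reason": reason}),
                )
                state.phase = WAIT
            state.pending_subject = None
            state.pending_since = None
        else:
            _warn(commands, now, f"{kind} ignored in DETECTION")

    elif state.phase == ACCESS_GRANTED:
        if kind == "box_entry_detected":
            subject = state.current_subject
            assert subject is not None
            state.phase = SESSION_RUNNING
            state.session_started_at = now
            # Fixing the deadline as one sum here keeps the timer comparison
            # exact for callers that schedule a tick at start + min_duration.
            state.exit_door_deadline = now + (state.min_duration_draw or 0.0)
            commands.append(("CLOSE_DOOR2", None))
            _log(commands, CorridorEvent(now, "door2_close"))
            task, stage = _task_for(subject, config)
            detail = {"task": task, "stage": stage, "min_session_duration": state.min_duration_draw}
            commands.append(("START_TASK", {"subject_id": subject, "task": task, "stage": stage}))
            _log(commands, CorridorEvent(now, "session_start", subject, detail))
        else:
            _warn(commands, now, f"{kind} ignored in ACCESS_GRANTED")

    elif state.phase == SESSION_RUNNING:
        if kind == "scale_reading":
            if state.door_opened_at is None:
                _warn(commands, now, "scale_reading before exit door opened")
            else:
                state.phase = EXIT_PENDING
                state.scale_readings = [float(payload)]
                state.scale_first_ts = now
        else:
            _warn(commands, now, f"{kind} ignored in SESSION_RUNNING")

    elif state.phase == EXIT_PENDING:
        if kind == "scale_reading":
            state.scale_readings.append(float(payload))
            _maybe_finalize_exit(state, now, config, commands)
        elif kind == "box_entry_detected":
            # Re-entry after stepping on the scale but before door 1 opens:
            # behavior unspecified upstream; warn and hold the phase.
            _warn(commands, now, "box re-entry while exit pending; staying in EXIT_PENDING")
        elif kind == "box_empty_detected":
            _maybe_finalize_exit(state, now, config, commands, force=True)
        else:
            _warn(commands, now, f"{kind} ignored in EXIT_PENDING")

    return state, commands


def _handle_timer(
    state: ControllerState, now: float, config: ControllerConfig, commands: list[Command]
) -> None:
    if state.phase == SESSION_RUNNING:
        assert state.session_started_at is not None
        deadline = state.exit_door_deadline
        if deadline is None:
            deadline = state.session_started_at + (state.min_duration_draw or 0.0)
        if state.door_opened_at is None and now >= deadline:
            state.door_opened_at = now
            commands.append(("OPEN_DOOR2", None))
            _log(commands, CorridorEvent(now, "door2_open"))
    elif state.phase == EXIT_PENDING:
        _maybe_finalize_exit(state, now, config, commands)


def _maybe_finalize_exit(
    state: ControllerState,
    now: float,
    config: ControllerConfig,
    commands: list[Command],
    force: bool = False,
) -> None:
    assert state.scale_first_ts is not None
    if not force and now - state.scale_first_ts < config.scale_settle_window:
        return
    subject = state.current_subject
    assert subject is not None
    # Stability estimator: median of all readings within the settle window.
    weight = float(statistics.median(state.scale_readings))
    commands.append(("OPEN_DOOR1", None))
    commands.append(("CLOSE_DOOR2", None))
    commands.append(("STOP_TASK", {"subject_id": subject}))
    _log(commands, CorridorEvent(now, "weight_reading", subject, {"weight": weight}))
    _log(commands, CorridorEvent(now, "session_end", subject, {"weight": weight}))
    _log(commands, CorridorEvent(now, "door1_open"))
    _log(commands, CorridorEvent(now, "door2_close"))
    _log(commands, CorridorEvent(now, "box_exit", subject))
    state.last_session_end[subject] = now
    state.phase = WAIT
    state.current_subject = None
    state.session_started_at = None
    state.exit_door_deadline = None
    state.door_opened_at = None
    state.min_duration_draw = None
    state.scale_readings = []
    state.scale_first_ts = None


def _task_for(subject: str, config: ControllerConfig) -> tuple[str, int]:
    if config.settings is not None and subject in config.settings:
        tp = config.settings[subject]
        return tp.task, tp.stage
    if config.subjects is not None and subject in config.subjects:
        return config.subjects[subject].task, 0
    return "", 0


@dataclass
class RunResult:
    state: ControllerState
    events: list[CorridorEvent]
    warnings: list[str]
    commands: list[tuple[float, Command]]


def run(
    event_stream: Iterable[tuple[float, Stimulus]], config: ControllerConfig
) -> RunResult:
    """Fold :func:`step` over a time-ordered ``(time, stimulus)`` stream.

    Deterministic given the stream and config (including the seeded
    minimum-duration draws).  The emitted log satisfies the controller
    invariants: single occupancy, refractory spacing, door exclusivity and
    minimum session duration.
    """
    state = initial_state(config)
    events: list[CorridorEvent] = []
    warns: list[str] = []
    issued: list[tuple[float, Command]] = []
    for now, stimulus in event_stream:
        state, commands = step(state, stimulus, now, config)
        for cmd in commands:
            if cmd[0] == "LOG":
                events.append(cmd[1])
            elif cmd[0] == "WARN":
                warns.append(cmd[1])
            else:
                issued.append((now, cmd))
    return RunResult(state=state, events=events, warnings=warns, commands=issued)
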