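"""Domain records shared across the package.

All timestamps are epoch seconds (float, UTC); intervals are half-open
``[start, end)``.  Records validate their invariants at construction time so
that every log a component emits or parses is structurally sound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping


class CagelabError(Exception):
    """Base class for all package errors."""


class ValidationError(CagelabError, ValueError):
    """A record violates one of its invariants."""


class SchemaError(CagelabError, ValueError):
    """A file does not match the declared CSV/JSON schema."""


class ConsistencyError(CagelabError, ValueError):
    """A log is internally inconsistent (e.g. nested sessions)."""


class ConfigError(CagelabError, ValueError):
    """A configuration value or rule set is invalid."""


#: Corridor event vocabulary.  ``entry_denied`` events carry a
#: ``denial_reason`` in their detail; ``weight_reading`` carries ``weight``.
EVENT_KINDS = frozenset(
    {
        "rfid_detect",
        "zone_report",
        "entry_granted",
        "entry_denied",
        "door1_open",
        "door1_close",
        "door2_open",
        "door2_close",
        "session_start",
        "session_end",
        "weight_reading",
        "box_exit",
    }
)

DENIAL_REASONS = frozenset({"multi_animal", "refractory", "unknown_subject"})

TRIAL_OUTCOMES = frozenset({"correct", "incorrect", "omission"})

#: Tasks for which a correct trial may go unrewarded (probabilistic reward).
PROBABILISTIC_REWARD_TASKS = frozenset({"2ab"})


@dataclass(frozen=True)
class SubjectRecord:
    """Identity and baseline data for one animal in the colony."""

    subject_id: str
    rfid_tag: str
    baseline_weight: float
    task: str
    active: bool = True

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty")
        if self.baseline_weight <= 0:
            raise ValidationError(
                f"baseline_weight must be > 0, got {self.baseline_weight}"
            )


@dataclass(frozen=True)
class CorridorEvent:
    """One timestamped corridor happening (detection, door command, decision)."""

    timestamp: float
    kind: str
    subject_id: str | None = None
    detail: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.kind == "entry_denied":
            reason = self.detail.get("denial_reason")
            if reason not in DENIAL_REASONS:
                raise ValidationError(
                    "entry_denied events must carry a denial_reason in "
                    f"{sorted(DENIAL_REASONS)}, got {reason!r}"
                )
        if self.kind == "weight_reading":
            weight = self.detail.get("weight")
            if not isinstance(weight, (int, float)) or weight <= 0:
                raise ValidationError(
                    f"weight_reading events must carry a positive weight, got {weight!r}"
                )


@dataclass(frozen=True)
class Session:
    """One stay of one subject in the operant box.

    ``door_open_time`` marks the end of the minimum session duration (the exit
    door opening).  Open sessions (``session_start`` without a matching
    ``session_end`` at the end of a log) carry ``open=True`` and ``end`` equal
    to the last known timestamp; analytics exclude them explicitly.
    """

    subject_id: str
    start: float
    end: float
    task: str = ""
    stage: int = 0
    door_open_time: float | None = None
    n_trials: int = 0
    water_ul: float = 0.0
    open: bool = False

    def __post_init__(self) -> None:
        if self.stage < 0:
            raise ValidationError(f"stage must be >= 0, got {self.stage}")
        if self.n_trials < 0 or self.water_ul < 0:
            raise ValidationError("n_trials and water_ul must be >= 0")
        if not self.open:
            if not self.start < self.end:
                raise ValidationError(
                    f"session start {self.start} must precede end {self.end}"
                )
            if self.door_open_time is not None and not (
                self.start <= self.door_open_time <= self.end
            ):
                raise ValidationError("door_open_time must lie within the session")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Trial:
    """One task trial with outcome and derived bookkeeping.

    ``forced_iti`` is the imposed inter-trial interval of the bandit task
    (0 elsewhere); engagement analysis subtracts it from ``duration``.
    """

    subject_id: str
    session_ref: str
    index: int
    onset: float
    duration: float
    task: str
    difficulty: str
    stimulus: Any
    choice: str | None
    outcome: str
    reward_ul: float
    forced_iti: float = 0.0

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError(f"trial index must be >= 1, got {self.index}")
        if self.duration <= 0:
            raise ValidationError(f"trial duration must be > 0, got {self.duration}")
        if self.outcome not in TRIAL_OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.reward_ul < 0:
            raise ValidationError("reward_ul must be >= 0")
        if self.forced_iti < 0:
            raise ValidationError("forced_iti must be >= 0")
        if self.task not in PROBABILISTIC_REWARD_TASKS:
            # Reward iff correct -- except under probabilistic reward schedules,
            # where correct choices can go unrewarded and vice versa.
            if (self.outcome == "correct") != (self.reward_ul > 0):
                raise ValidationError(
                    f"task {self.task!r}: reward_ul > 0 must hold iff outcome is "
                    f"correct (outcome={self.outcome}, reward_ul={self.reward_ul})"
                )

    @property
    def effective_duration(self) -> float:
        """Trial duration with the forced inter-trial interval removed."""
        return self.duration - self.forced_iti


@dataclass(frozen=True)
class AntennaDetection:
    """One raw RFID ping from a home-cage tube antenna."""

    timestamp: float
    antenna_id: int
    subject_id: str

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty")


@dataclass
class TaskParameters:
    """A subject's current task assignment and stage-specific settings.

    ``params`` carries named settings (difficulty mix, reward volume, response
    window, ...); ``extra`` preserves unknown top-level keys across JSON
    round-trips.
    """

    subject_id: str
    task: str
    stage: int
    params: dict[str, Any] = field(default_factory=dict)
    updated_at: float = 0.0
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage < 0:
            raise ValidationError(f"stage must be >= 0, got {self.stage}")
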