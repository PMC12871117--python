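"""Session summaries and the stage-progression rule engine.

After each session the system summarizes performance and applies an ordered
set of declarative rules (thresholds over the last *k* summaries) to decide
whether the subject is promoted, demoted, held, or has a single parameter
overridden.  Criteria are user-set a priori; this module ships a rule
language plus documented defaults rather than hard-coded criteria.  Stage
changes are limited to +-1 per session so trajectories stay auditable.
"""

from __future__ import annotations

import csv
import operator
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Sequence

from .records import ConfigError, TaskParameters, Trial

_OPS = {">=": operator.ge, ">": operator.gt, "<=": operator.le, "<": operator.lt, "==": operator.eq}
_SUMMARY_FIELDS = {"accuracy", "n_valid", "n_total", "water_ul", "mean_trial_duration"}


@dataclass(frozen=True)
class SessionSummary:
    """Per-session performance digest.

    ``accuracy`` is the fraction of correct trials over valid trials (trials
    with a response inside the window); it is ``None`` -- not 0 -- when the
    session has no valid trials, and the ``no_valid_trials`` flag is set.
    """

    subject_id: str
    session_ref: str
    accuracy: float | None
    n_valid: int
    n_total: int
    water_ul: float
    mean_trial_duration: float | None
    flags: tuple[str, ...] = ()


def summarize_session(trials: Sequence[Trial]) -> SessionSummary:
    if not trials:
        return SessionSummary("", "", None, 0, 0, 0.0, None, flags=("empty",))
    subjects = {t.subject_id for t in trials}
    refs = {t.session_ref for t in trials}
    if len(subjects) > 1 or len(refs) > 1:
        raise ConfigError("summarize_session expects trials from a single session")
    n_total = len(trials)
    valid = [t for t in trials if t.outcome != "omission"]
    n_valid = len(valid)
    water = sum(t.reward_ul for t in trials)
    mean_dur = sum(t.duration for t in trials) / n_total
    if n_valid == 0:
        return SessionSummary(
            trials[0].subject_id, trials[0].session_ref, None, 0, n_total, water,
            mean_dur, flags=("no_valid_trials",),
        )
    accuracy = sum(1 for t in valid if t.outcome == "correct") / n_valid
    return SessionSummary(
        trials[0].subject_id, trials[0].session_ref, accuracy, n_valid, n_total,
        water, mean_dur,
    )


@dataclass(frozen=True)
class RuleCondition:
    """``field op value``, evaluated on every summary in the rule's window."""

    field: str
    op: str
    value: float

    def __post_init__(self) -> None:
        if self.field not in _SUMMARY_FIELDS:
            raise ConfigError(f"unknown summary field {self.field!r}")
        if self.op not in _OPS:
            raise ConfigError(f"unknown comparison {self.op!r}")

    def holds(self, summary: SessionSummary) -> bool:
        val = getattr(summary, self.field)
        if val is None:
            return False
        return _OPS[self.op](val, self.value)


@dataclass(frozen=True)
class ProgressionRule:
    """Fires when all conditions hold on each of the last ``window`` summaries."""

    rule_id: str
    window: int
    conditions: tuple[RuleCondition, ...]
    action: str  # promote | demote | hold | set_param
    priority: int
    param_key: str | None = None
    param_value: Any = None

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ConfigError("rule window must be >= 1")
        if self.action not in {"promote", "demote", "hold", "set_param"}:
            raise ConfigError(f"unknown action {self.action!r}")
        if self.action == "set_param" and not self.param_key:
            raise ConfigError("set_param rules need a param_key")

    def fires(self, history: Sequence[SessionSummary]) -> bool:
        if len(history) < self.window:
            return False
        recent = history[-self.window :]
        return all(cond.holds(s) for s in recent for cond in self.conditions)


def load_rules(config_section: Sequence[dict[str, Any]]) -> list[ProgressionRule]:
    """Parse and validate a declarative rule list; returns rules ordered by
    descending priority.  An empty section yields a hold-only default."""
    if not config_section:
        return [ProgressionRule("hold_default", 1, (), "hold", 0)]
    rules: list[ProgressionRule] = []
    for i, raw in enumerate(config_section):
        try:
            conds = tuple(
                RuleCondition(c["field"], c["op"], float(c["value"]))
                for c in raw.get("conditions", [])
            )
            rules.append(
                ProgressionRule(
                    rule_id=str(raw.get("rule_id", f"rule_{i}")),
                    window=int(raw.get("window", 1)),
                    conditions=conds,
                    action=raw["action"],
                    priority=int(raw["priority"]),
                    param_key=raw.get("param_key"),
                    param_value=raw.get("param_value"),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"rule {i}: missing key {exc}") from exc
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ConfigError("progression rules must have unique priorities")
    return sorted(rules, key=lambda r: -r.priority)


def rules_to_config(rules: Sequence[ProgressionRule]) -> list[dict[str, Any]]:
    """Inverse of :func:`load_rules` (round-trips losslessly)."""
    out = []
    for r in rules:
        out.append(
            {
                "rule_id": r.rule_id,
                "window": r.window,
                "conditions": [
                    {"field": c.field, "op": c.op, "value": c.value} for c in r.conditions
                ],
                "action": r.action,
                "priority": r.priority,
                "param_key": r.param_key,
                "param_value": r.param_value,
            }
        )
    return out


def default_rules(demotion: bool = True) -> list[ProgressionRule]:
    """Default criteria: promote after two sessions at >= 70% accuracy with
    >= 60 valid trials each; optionally demote after three sessions below 40%."""
    section: list[dict[str, Any]] = [
        {
            "rule_id": "promote_default",
            "window": 2,
            "conditions": [
                {"field": "accuracy", "op": ">=", "value": 0.7},
                {"field": "n_valid", "op": ">=", "value": 60},
            ],
            "action": "promote",
            "priority": 2,
        }
    ]
    if demotion:
        section.append(
            {
                "rule_id": "demote_default",
                "window": 3,
                "conditions": [{"field": "accuracy", "op": "<", "value": 0.4}],
                "action": "demote",
                "priority": 1,
            }
        )
    return load_rules(section)


@dataclass(frozen=True)
class ProgressionDecision:
    timestamp: float
    subject_id: str
    rule_id: str
    old_stage: int
    new_stage: int


def apply_progression(
    params: TaskParameters,
    history: Sequence[SessionSummary],
    rules: Sequence[ProgressionRule],
    now: float | None = None,
) -> tuple[TaskParameters, ProgressionDecision]:
    """Fire the highest-priority rule whose predicate holds on the history.

    Exactly one action fires per update (``hold`` when nothing else does);
    the stage moves by at most one and never below zero.  Deterministic:
    replaying the same summaries through the same rules rebuilds the same
    parameter file.
    """
    now = float(now) if now is not None else 0.0
    fired: ProgressionRule | None = None
    for rule in sorted(rules, key=lambda r: -r.priority):
        if rule.fires(history):
            fired = rule
            break
    old_stage = params.stage
    new_stage = old_stage
    new_params = dict(params.params)
    rule_id = "hold"
    if fired is not None:
        rule_id = fired.rule_id
        if fired.action == "promote":
            max_stage = int(params.params.get("max_stage", 10**9))
            new_stage = min(old_stage + 1, max_stage)
        elif fired.action == "demote":
            new_stage = max(old_stage - 1, 0)
        elif fired.action == "set_param":
            new_params[str(fired.param_key)] = fired.param_value
    updated = replace(params, stage=new_stage, params=new_params, updated_at=now)
    decision = ProgressionDecision(now, params.subject_id, rule_id, old_stage, new_stage)
    return updated, decision


AUDIT_COLUMNS = ["timestamp", "subject_id", "rule_id", "old_stage", "new_stage"]


def append_audit(path: str | Path, decision: ProgressionDecision) -> Path:
    """Append one decision to the progression audit log (CSV)."""
    path = Path(path)
    new = not path.exists()
    with open(path, "a", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        if new:
            writer.writerow(AUDIT_COLUMNS)
        writer.writerow(
            [
                repr(decision.timestamp),
                decision.subject_id,
                decision.rule_id,
                decision.old_stage,
                decision.new_stage,
            ]
        )
    return path
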