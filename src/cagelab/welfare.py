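"""Twice-daily per-subject welfare reports and threshold alarms.

At each light-cycle transition (08:00 and 20:00) the system summarizes the
preceding 12 h window per subject -- corridor/antenna detection counts,
session count, water intake and mean body weight -- and raises an alarm for
any subject strictly below a configured threshold.  The weight alarm fires
when the window's mean weight drops below 80% of the subject's baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .circadian import DEFAULT_LIGHTS_ON_EPOCH, HALF_DAY_S, is_transition
from .records import AntennaDetection, ConfigError, CorridorEvent, SubjectRecord

WEIGHT_BASELINE_FRACTION = 0.80

REPORT_COLUMNS = [
    "subject_id",
    "detection_count",
    "session_count",
    "water_ul",
    "mean_weight",
]


@dataclass(frozen=True)
class Alarm:
    subject_id: str
    metric: str
    value: float
    threshold: float


@dataclass
class WelfareReport:
    window_start: float
    window_end: float
    table: pd.DataFrame
    alarms: list[Alarm] = field(default_factory=list)


def build_report(
    events: Sequence[CorridorEvent],
    antenna: Sequence[AntennaDetection],
    subjects: dict[str, SubjectRecord],
    window_end: float,
    window_s: float = HALF_DAY_S,
    lights_on_epoch: float = DEFAULT_LIGHTS_ON_EPOCH,
) -> WelfareReport:
    """Summarize one report window ending at a light-cycle transition.

    Every subject in the colony appears in the table, with zeros if it
    produced no events in the window.
    """
    if not is_transition(window_end, lights_on_epoch):
        raise ConfigError(
            f"report window must end at a light-cycle transition, got {window_end}"
        )
    start = window_end - window_s
    rows = []
    for sid in sorted(subjects):
        win_events = [
            e for e in events if e.subject_id == sid and start <= e.timestamp < window_end
        ]
        detections = sum(1 for e in win_events if e.kind == "rfid_detect")
        detections += sum(
            1 for d in antenna if d.subject_id == sid and start <= d.timestamp < window_end
        )
        session_count = sum(1 for e in win_events if e.kind == "session_start")
        water = sum(
            float(e.detail.get("water_ul", 0.0))
            for e in win_events
            if e.kind == "session_end"
        )
        weights = [
            float(e.detail["weight"]) for e in win_events if e.kind == "weight_reading"
        ]
        rows.append(
            {
                "subject_id": sid,
                "detection_count": detections,
                "session_count": session_count,
                "water_ul": water,
                "mean_weight": (sum(weights) / len(weights)) if weights else float("nan"),
            }
        )
    return WelfareReport(
        window_start=start,
        window_end=window_end,
        table=pd.DataFrame(rows, columns=REPORT_COLUMNS),
    )


def check_alarms(
    report: WelfareReport,
    thresholds: dict[str, float],
    baselines: dict[str, float] | None = None,
) -> list[Alarm]:
    """Evaluate alarms: one per (subject, metric) strictly below threshold.

    ``thresholds`` maps metric names (``detection_count``, ``session_count``,
    ``water_ul``) to minimum acceptable values.  If ``check_weight`` is
    requested via a ``"weight"`` key (any value), the weight alarm uses
    ``mean_weight < 0.80 * baseline`` and requires a baseline per subject.
    """
    alarms: list[Alarm] = []
    known = {"detection_count", "session_count", "water_ul", "weight"}
    unknown = set(thresholds) - known
    if unknown:
        raise ConfigError(f"unknown alarm metrics {sorted(unknown)}")
    for _, row in report.table.iterrows():
        sid = str(row.subject_id)
        for metric in ("detection_count", "session_count", "water_ul"):
            if metric in thresholds and float(row[metric]) < thresholds[metric]:
                alarms.append(Alarm(sid, metric, float(row[metric]), thresholds[metric]))
        if "weight" in thresholds:
            if baselines is None or sid not in baselines:
                raise ConfigError(f"missing baseline weight for subject {sid}")
            cut = WEIGHT_BASELINE_FRACTION * baselines[sid]
            mean_weight = float(row.mean_weight)
            if mean_weight == mean_weight and mean_weight < cut:  # NaN-safe
                alarms.append(Alarm(sid, "weight", mean_weight, cut))
    report.alarms = alarms
    return alarms


def write_report(report: WelfareReport, csv_path: str | Path, text_path: str | Path | None = None) -> Path:
    """Write the report table as CSV (and optionally a human-readable text)."""
    csv_path = Path(csv_path)
    report.table.to_csv(csv_path, index=False)
    if text_path is not None:
        lines = [
            f"Welfare report for window [{report.window_start:.0f}, {report.window_end:.0f})",
            report.table.to_string(index=False),
        ]
        if report.alarms:
            lines.append("ALARMS:")
            lines.extend(
                f"  {a.subject_id}: {a.metric} = {a.value:.2f} < {a.threshold:.2f}"
                for a in report.alarms
            )
        else:
            lines.append("No alarms.")
        Path(text_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return csv_path
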