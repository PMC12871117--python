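"""Behavioral analytics over the corridor, trial and antenna logs.

Covers box-usage metrics (daily occupancy, Lorenz/Gini inequality, attempt
classification, inter-session intervals), engagement (per-subject sigma-cut
trial labels, session time budgets, psychometric tables, trial-index
curves), and home-cage analyses (cage-interval inference from antenna
pairs, cage-change circadian profiles, task vs no-task activity, and
peri-session cage occupancy).

Conventions: all intervals are half-open ``[start, end)``; analysis days are
24 h windows aligned to lights-on (08:00); accuracy denominators exclude
omissions; open sessions are excluded with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .circadian import DEFAULT_LIGHTS_ON_EPOCH, is_night
from .homecage import HomeCageTopology
from .records import (
    AntennaDetection,
    ConfigError,
    ConsistencyError,
    CorridorEvent,
    Session,
    Trial,
    ValidationError,
)

CHANCE_LEVEL = {"3afc": 1.0 / 3.0, "2afc": 0.5, "2ab": 0.5}


# ---------------------------------------------------------------------------
# Occupancy and inequality


@dataclass(frozen=True)
class OccupancyRecord:
    window_start: float
    occupied_seconds: float
    window_seconds: float = 86400.0

    @property
    def percentage(self) -> float:
        return 100.0 * self.occupied_seconds / self.window_seconds


def _closed(sessions: Iterable[Session]) -> list[Session]:
    closed = [s for s in sessions if not s.open]
    n_open = sum(1 for s in sessions if s.open)
    if n_open:
        warnings.warn(f"excluding {n_open} open session(s) from analysis", stacklevel=3)
    return closed


def daily_occupancy(
    sessions: Sequence[Session],
    day_boundaries: Sequence[tuple[float, float]],
) -> list[OccupancyRecord]:
    """Fraction of each 24 h window during which the box was occupied.

    The controller guarantees single occupancy, so the union of session
    intervals equals their summed overlap with the window.
    """
    closed = _closed(sessions)
    out = []
    for start, end in day_boundaries:
        occupied = sum(
            max(0.0, min(s.end, end) - max(s.start, start)) for s in closed
        )
        out.append(OccupancyRecord(start, occupied, end - start))
    return out


@dataclass(frozen=True)
class LorenzResult:
    """Lorenz construction over sorted occupancy shares.

    ``points`` holds (p, L(p)) for p = 0, 1/n, ..., 1 including the origin;
    G = 1 - 2 * trapezoid(L), which is exactly 0 for uniform shares and
    (n-1)/n when a single subject holds everything.
    """

    shares: tuple[float, ...]
    points: tuple[tuple[float, float], ...]
    gini: float


def gini(occupancy_by_subject: Sequence[float]) -> LorenzResult:
    x = np.asarray(occupancy_by_subject, dtype=float)
    if x.size == 0 or np.any(x < 0):
        raise ValidationError("need a non-empty vector of non-negative shares")
    total = x.sum()
    if total == 0:
        raise ValidationError("all-zero occupancy: Gini undefined")
    xs = np.sort(x)
    n = xs.size
    L = np.concatenate([[0.0], np.cumsum(xs) / total])
    p = np.arange(n + 1) / n
    integral = float(np.trapezoid(L, p))
    g = 1.0 - 2.0 * integral
    return LorenzResult(
        shares=tuple(xs.tolist()),
        points=tuple(zip(p.tolist(), L.tolist())),
        gini=float(g),
    )


def gini_mean_abs_difference(x: Sequence[float]) -> float:
    """Brute-force Gini via pairwise differences: sum|xi - xj| / (2 n^2 mean).

    Equals the Lorenz-trapezoid value exactly under this package's
    convention (n+1 Lorenz points including the origin); kept as an
    independent cross-check.
    """
    arr = np.asarray(x, dtype=float)
    n = arr.size
    mean = arr.mean()
    if mean == 0:
        raise ValidationError("all-zero occupancy: Gini undefined")
    diffs = np.abs(arr[:, None] - arr[None, :]).sum()
    return float(diffs / (2.0 * n * n * mean))


# ---------------------------------------------------------------------------
# Attempts and inter-session intervals


def classify_attempts(
    events: Sequence[CorridorEvent],
    day_boundaries: Sequence[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Tally granted / multi-animal / refractory attempts per subject per day.

    A denial that coincides with the refractory interval but was triggered by
    multiple animals counts as multi-animal only (the refractory check is
    skipped once multiple animals are detected).  The ``ratio`` column is
    failed attempts per successful entrance (NaN when nothing was granted
    but failures exist; 0.0 when there are no denials).
    """
    rows = []
    for ev in events:
        if ev.kind == "entry_granted":
            rows.append((ev.timestamp, ev.subject_id, "granted"))
        elif ev.kind == "entry_denied":
            reason = ev.detail.get("denial_reason")
            if reason is None:
                raise ConsistencyError("entry_denied without denial_reason")
            rows.append((ev.timestamp, ev.subject_id, reason))
    df = pd.DataFrame(rows, columns=["timestamp", "subject_id", "kind"])
    if day_boundaries is None:
        if df.empty:
            day_boundaries = []
        else:
            t0 = float(df.timestamp.min())
            n = int(np.ceil((float(df.timestamp.max()) - t0) / 86400.0)) or 1
            day_boundaries = [(t0 + 86400.0 * i, t0 + 86400.0 * (i + 1)) for i in range(n)]
    out = []
    for subject in sorted(df.subject_id.dropna().unique()) if not df.empty else []:
        sub = df[df.subject_id == subject]
        for start, end in day_boundaries:
            w = sub[(sub.timestamp >= start) & (sub.timestamp < end)]
            counts = w.kind.value_counts()
            granted = int(counts.get("granted", 0))
            multi = int(counts.get("multi_animal", 0))
            refractory = int(counts.get("refractory", 0))
            failed = multi + refractory
            if failed == 0:
                ratio = 0.0
            elif granted == 0:
                ratio = float("nan")
            else:
                ratio = failed / granted
            out.append(
                {
                    "subject_id": subject,
                    "window_start": start,
                    "granted": granted,
                    "multi_animal": multi,
                    "refractory": refractory,
                    "ratio": ratio,
                }
            )
    return pd.DataFrame(
        out,
        columns=["subject_id", "window_start", "granted", "multi_animal", "refractory", "ratio"],
    )


def inter_session_intervals(
    sessions: Sequence[Session], endpoints: str = "end_to_start"
) -> pd.DataFrame:
    """Per-subject intervals between consecutive sessions.

    ``endpoints="end_to_start"`` measures previous session end to next
    session start (matching the refractory semantics); ``"start_to_start"``
    measures between entrances.  Subjects with fewer than two sessions
    contribute no intervals.
    """
    if endpoints not in {"end_to_start", "start_to_start"}:
        raise ConfigError(f"unknown endpoints convention {endpoints!r}")
    closed = _closed(sessions)
    rows = []
    by_subject: dict[str, list[Session]] = {}
    for s in closed:
        by_subject.setdefault(s.subject_id, []).append(s)
    for subject, ss in sorted(by_subject.items()):
        ss = sorted(ss, key=lambda s: s.start)
        for prev, nxt in zip(ss, ss[1:]):
            ref = prev.end if endpoints == "end_to_start" else prev.start
            rows.append({"subject_id": subject, "isi_s": nxt.start - ref})
    return pd.DataFrame(rows, columns=["subject_id", "isi_s"])


def isi_summary(isis: pd.DataFrame) -> dict[str, float]:
    """Pooled median and 95.5th percentile of the ISI distribution, in hours."""
    if isis.empty:
        return {"median_h": float("nan"), "p955_h": float("nan"), "min_h": float("nan")}
    hours = isis.isi_s.to_numpy() / 3600.0
    return {
        "median_h": float(np.median(hours)),
        "p955_h": float(np.percentile(hours, 95.5)),
        "min_h": float(hours.min()),
    }


# ---------------------------------------------------------------------------
# Engagement


@dataclass(frozen=True)
class EngagementModel:
    """Per-subject sigma-cut thresholds over effective trial durations.

    Trials faster than ``mean - 0.5 sd`` are highly engaged, slower than
    ``mean + 2 sd`` disengaged, medium in between; for most analyses highly
    and medium engaged collapse to "engaged".  The population sd (ddof=0) of
    all of the subject's trials in the task is used.
    """

    subject_id: str
    mean_duration: float
    sd_duration: float
    n_trials: int
    unstable: bool = False

    @property
    def cut_high_engaged(self) -> float:
        return self.mean_duration - 0.5 * self.sd_duration

    @property
    def cut_disengaged(self) -> float:
        return self.mean_duration + 2.0 * self.sd_duration


MIN_TRIALS_FOR_MODEL = 10


def label_engagement(
    trials: Sequence[Trial],
) -> tuple[pd.DataFrame, dict[str, EngagementModel]]:
    """Label each trial highly/medium engaged or disengaged.

    The forced inter-trial interval of the bandit task is removed from the
    duration before the moments are computed.  Subjects with fewer than 10
    trials get a model flagged unstable (labels still computed).
    """
    df = trials_frame(trials)
    models: dict[str, EngagementModel] = {}
    labels = np.empty(len(df), dtype=object)
    engaged = np.zeros(len(df), dtype=bool)
    for subject, grp in df.groupby("subject_id"):
        dur = grp["effective_duration"].to_numpy()
        mean = float(dur.mean())
        sd = float(dur.std(ddof=0))
        model = EngagementModel(
            subject_id=str(subject),
            mean_duration=mean,
            sd_duration=sd,
            n_trials=len(dur),
            unstable=len(dur) < MIN_TRIALS_FOR_MODEL,
        )
        models[str(subject)] = model
        idx = grp.index.to_numpy()
        lab = np.where(
            dur > model.cut_disengaged,
            "disengaged",
            np.where(dur < model.cut_high_engaged, "highly_engaged", "medium_engaged"),
        )
        labels[idx] = lab
        engaged[idx] = lab != "disengaged"
    df["engagement"] = labels
    df["engaged"] = engaged
    return df, models


def trials_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    """Tidy DataFrame view of a trial list (positional index)."""
    return pd.DataFrame(
        {
            "subject_id": [t.subject_id for t in trials],
            "session_ref": [t.session_ref for t in trials],
            "index": [t.index for t in trials],
            "onset": [t.onset for t in trials],
            "duration": [t.duration for t in trials],
            "forced_iti": [t.forced_iti for t in trials],
            "effective_duration": [t.effective_duration for t in trials],
            "task": [t.task for t in trials],
            "difficulty": [t.difficulty for t in trials],
            "outcome": [t.outcome for t in trials],
            "reward_ul": [t.reward_ul for t in trials],
        }
    )


def session_time_budget(
    session: Session, labeled_trials: pd.DataFrame
) -> dict[str, float]:
    """Partition a session's in-box time into four fractions summing to 1.

    ``first_trial`` is the latency to complete the first trial after entry;
    ``engaged``/``disengaged`` aggregate the remaining trials (inter-trial
    gaps count as disengaged time); ``exit_latency`` is the tail after the
    last trial.  The exit is fast when it occurs within a minute of the door
    opening.
    """
    if session.open:
        raise ValidationError("cannot budget an open session")
    tr = labeled_trials[labeled_trials.session_ref == _session_ref(session, labeled_trials)]
    total = session.duration
    if tr.empty:
        return {
            "first_trial": 0.0,
            "engaged": 0.0,
            "disengaged": 1.0,
            "exit_latency": 0.0,
            "fast_exit": _fast_exit(session),
        }
    tr = tr.sort_values("index")
    first_end = float(tr.iloc[0].onset + tr.iloc[0].duration)
    first = first_end - session.start
    rest = tr.iloc[1:]
    engaged_t = float(rest.loc[rest.engaged, "duration"].sum())
    disengaged_t = float(rest.loc[~rest.engaged, "duration"].sum())
    last_end = float((tr.onset + tr.duration).max())
    gaps = max(0.0, (last_end - first_end) - float(rest.duration.sum()))
    disengaged_t += gaps
    exit_latency = max(0.0, session.end - last_end)
    # Numerical guard: trials must fit inside the session.
    parts = np.array([first, engaged_t, disengaged_t, exit_latency])
    return {
        "first_trial": float(parts[0] / total),
        "engaged": float(parts[1] / total),
        "disengaged": float(parts[2] / total),
        "exit_latency": float(parts[3] / total),
        "fast_exit": _fast_exit(session),
    }


def _fast_exit(session: Session) -> bool | None:
    if session.door_open_time is None:
        return None
    return (session.end - session.door_open_time) < 60.0


def _session_ref(session: Session, labeled: pd.DataFrame) -> str:
    refs = labeled.loc[
        (labeled.subject_id == session.subject_id)
        & (labeled.onset >= session.start)
        & (labeled.onset < session.end),
        "session_ref",
    ].unique()
    return refs[0] if len(refs) else "__none__"


def accuracy_by_difficulty(labeled_trials: pd.DataFrame) -> pd.DataFrame:
    """Psychometric table: accuracy per subject x difficulty x engagement.

    Omissions are excluded from denominators; empty cells are absent rather
    than zero.  Chance level is 1/3 for the three-alternative task and 1/2
    otherwise.
    """
    valid = labeled_trials[labeled_trials.outcome != "omission"]
    rows = []
    group_cols = ["subject_id", "task", "difficulty", "engaged"]
    for (subject, task, difficulty, engaged), grp in valid.groupby(group_cols):
        rows.append(
            {
                "subject_id": subject,
                "task": task,
                "difficulty": difficulty,
                "engaged": engaged,
                "n": len(grp),
                "accuracy": float((grp.outcome == "correct").mean()),
                "chance": CHANCE_LEVEL.get(task, 0.5),
            }
        )
    return pd.DataFrame(
        rows, columns=["subject_id", "task", "difficulty", "engaged", "n", "accuracy", "chance"]
    )


WARMUP_TRIALS_3AFC = 12
BIN_SIZE = {"3afc": 10, "2afc": 30, "2ab": 30}


def engagement_by_trial_index(labeled_trials: pd.DataFrame, task: str) -> pd.DataFrame:
    """Engaged fraction vs trial index, controlled for session length.

    Only sessions with at least the median trial count contribute, and only
    indices up to that median, so every point is supported by the same
    session set.  The first 12 trials of the three-alternative task are
    excluded as warm-up.  Indices are binned (10 trials for 3afc, 30
    otherwise).
    """
    df = labeled_trials[labeled_trials.task == task]
    if df.empty:
        return pd.DataFrame(columns=["bin_start", "n", "engaged_fraction"])
    counts = df.groupby("session_ref")["index"].max()
    median_n = float(np.median(counts.to_numpy()))
    keep = counts[counts >= median_n].index
    df = df[df.session_ref.isin(keep) & (df["index"] <= median_n)]
    if task == "3afc":
        df = df[df["index"] > WARMUP_TRIALS_3AFC]
    size = BIN_SIZE.get(task, 30)
    start = WARMUP_TRIALS_3AFC + 1 if task == "3afc" else 1
    bins = ((df["index"] - start) // size) * size + start
    rows = []
    for b, grp in df.groupby(bins):
        rows.append(
            {"bin_start": int(b), "n": len(grp), "engaged_fraction": float(grp.engaged.mean())}
        )
    return pd.DataFrame(rows, columns=["bin_start", "n", "engaged_fraction"]).sort_values(
        "bin_start", ignore_index=True
    )


# ---------------------------------------------------------------------------
# Home-cage inference


@dataclass(frozen=True)
class CageInterval:
    subject_id: str
    cage: str
    start: float
    end: float


def infer_cage_intervals(
    antenna_log: Sequence[AntennaDetection], topology: HomeCageTopology
) -> list[CageInterval]:
    """Infer per-subject cage residency from consecutive antenna pairs.

    When the two antennas of one tube fire consecutively for a subject, the
    subject is inside the destination cage from the second detection until
    its next assignment.  Isolated detections assign nothing; dropout never
    invents crossings.
    """
    ids = topology.antenna_ids
    for d in antenna_log:
        if d.antenna_id not in ids:
            raise ConfigError(f"antenna {d.antenna_id} not in declared topology")
    intervals: list[CageInterval] = []
    by_subject: dict[str, list[AntennaDetection]] = {}
    for d in sorted(antenna_log, key=lambda d: d.timestamp):
        by_subject.setdefault(d.subject_id, []).append(d)
    for subject, ds in sorted(by_subject.items()):
        current_cage: str | None = None
        since: float | None = None
        prev: AntennaDetection | None = None
        for d in ds:
            if prev is not None:
                dest = topology.destination_of(prev.antenna_id, d.antenna_id)
                if dest is not None:
                    if current_cage is not None and since is not None and d.timestamp > since:
                        intervals.append(CageInterval(subject, current_cage, since, d.timestamp))
                    current_cage = dest
                    since = d.timestamp
                    prev = None
                    continue
            prev = d
        if (
            current_cage is not None
            and since is not None
            and ds
            and ds[-1].timestamp > since
        ):
            intervals.append(CageInterval(subject, current_cage, since, ds[-1].timestamp))
    return intervals


def cage_changes(
    antenna_log: Sequence[AntennaDetection],
    topology: HomeCageTopology,
    max_pair_gap_s: float = 60.0,
    lights_on_epoch: float = DEFAULT_LIGHTS_ON_EPOCH,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract cage-change events and their circadian profile.

    A change is a consistent antenna pair of one tube fired by the same
    subject within a minute.  The profile reports the median changes per
    hour by clock hour, split day/night (lights on 08:00, 12 h cycle).
    """
    changes = []
    by_subject: dict[str, list[AntennaDetection]] = {}
    for d in sorted(antenna_log, key=lambda d: d.timestamp):
        by_subject.setdefault(d.subject_id, []).append(d)
    for subject, ds in sorted(by_subject.items()):
        prev: AntennaDetection | None = None
        for d in ds:
            if prev is not None:
                dest = topology.destination_of(prev.antenna_id, d.antenna_id)
                if dest is not None and (d.timestamp - prev.timestamp) < max_pair_gap_s:
                    changes.append(
                        {"subject_id": subject, "timestamp": d.timestamp, "cage": dest}
                    )
                    prev = None
                    continue
            prev = d
    changes_df = pd.DataFrame(changes, columns=["subject_id", "timestamp", "cage"])
    if changes_df.empty:
        profile = pd.DataFrame(columns=["clock_hour", "night", "median_changes_per_h"])
        return changes_df, profile
    ts = changes_df.timestamp.to_numpy()
    rel = ts - lights_on_epoch
    day_idx = np.floor(rel / 86400.0).astype(int)
    hour = ((np.floor(rel / 3600.0).astype(int) % 24) + 8) % 24
    tmp = changes_df.assign(day=day_idx, clock_hour=hour)
    per_hour = (
        tmp.groupby(["subject_id", "day", "clock_hour"]).size().rename("changes").reset_index()
    )
    profile = (
        per_hour.groupby("clock_hour")["changes"]
        .median()
        .rename("median_changes_per_h")
        .reset_index()
    )
    profile["night"] = (profile.clock_hour < 8) | (profile.clock_hour >= 20)
    return changes_df, profile[["clock_hour", "night", "median_changes_per_h"]]


def task_vs_notask_activity(
    changes: pd.DataFrame,
    sessions: Sequence[Session],
    condition_labels: Sequence[tuple[float, float, str]],
) -> pd.DataFrame:
    """Compare cage-change rates between task and no-task conditions.

    ``condition_labels`` are non-overlapping ``(start, end, condition)``
    ranges.  Periods a subject spends inside the operant box are removed
    from that subject's denominator in every condition (changes are
    impossible while in the box), so the rates are per hour of home-cage
    time, scaled to changes per day.
    """
    labels = sorted(condition_labels)
    for (s1, e1, _), (s2, e2, _) in zip(labels, labels[1:]):
        if s2 < e1:
            raise ConfigError("condition labels overlap")
    closed = _closed(sessions)
    subjects = sorted(
        set(changes.subject_id.unique()).union(s.subject_id for s in closed)
    )
    rows = []
    for subject in subjects:
        in_box = [(s.start, s.end) for s in closed if s.subject_id == subject]
        sub_changes = changes[changes.subject_id == subject]
        for start, end, condition in labels:
            boxed = sum(
                max(0.0, min(be, end) - max(bs, start)) for bs, be in in_box
            )
            exposed = (end - start) - boxed
            n = int(
                ((sub_changes.timestamp >= start) & (sub_changes.timestamp < end)).sum()
            )
            rate = (n / exposed * 86400.0) if exposed > 0 else float("nan")
            rows.append(
                {
                    "subject_id": subject,
                    "condition": condition,
                    "n_changes": n,
                    "exposed_s": exposed,
                    "changes_per_day": rate,
                }
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "condition", "n_changes", "exposed_s", "changes_per_day"]
    )


def peri_session_occupancy(
    cage_intervals: Sequence[CageInterval],
    sessions: Sequence[Session],
    window_s: float = 300.0,
) -> pd.DataFrame:
    """Cage-occupancy fractions in the 5 minutes before entry and after exit.

    Fractions over the four cages sum to at most 1 per window (the remainder
    is corridor/unassigned time).  Windows truncated at the log boundary are
    renormalized to the covered span and flagged.
    """
    closed = _closed(sessions)
    if not cage_intervals:
        return pd.DataFrame(
            columns=["subject_id", "phase", "cage", "fraction", "truncated"]
        )
    log_start = min(ci.start for ci in cage_intervals)
    log_end = max(ci.end for ci in cage_intervals)
    cages = sorted({ci.cage for ci in cage_intervals})
    acc: dict[tuple[str, str, str], list[float]] = {}
    truncated_flags: dict[tuple[str, str], bool] = {}
    for s in closed:
        for phase, w_start, w_end in (
            ("before", s.start - window_s, s.start),
            ("after", s.end, s.end + window_s),
        ):
            lo = max(w_start, log_start)
            hi = min(w_end, log_end)
            span = hi - lo
            if span <= 0:
                continue
            truncated = span < window_s - 1e-9
            truncated_flags[(s.subject_id, phase)] = (
                truncated_flags.get((s.subject_id, phase), False) or truncated
            )
            for cage in cages:
                t_in = sum(
                    max(0.0, min(ci.end, hi) - max(ci.start, lo))
                    for ci in cage_intervals
                    if ci.subject_id == s.subject_id and ci.cage == cage
                )
                acc.setdefault((s.subject_id, phase, cage), []).append(t_in / span)
    rows = []
    for (subject, phase, cage), fracs in sorted(acc.items()):
        rows.append(
            {
                "subject_id": subject,
                "phase": phase,
                "cage": cage,
                "fraction": float(np.mean(fracs)),
                "truncated": truncated_flags.get((subject, phase), False),
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "phase", "cage", "fraction", "truncated"])


# ---------------------------------------------------------------------------
# Convenience


def sessions_per_day(sessions: Sequence[Session], days: float) -> pd.DataFrame:
    closed = _closed(sessions)
    counts: dict[str, int] = {}
    for s in closed:
        counts[s.subject_id] = counts.get(s.subject_id, 0) + 1
    return pd.DataFrame(
        [
            {"subject_id": k, "sessions_per_day": v / days}
            for k, v in sorted(counts.items())
        ],
        columns=["subject_id", "sessions_per_day"],
    )


def night_day_attempt_ratio(
    events: Sequence[CorridorEvent], lights_on_epoch: float = DEFAULT_LIGHTS_ON_EPOCH
) -> float:
    """Ratio of night to day corridor-entry attempt rates (granted + denied)."""
    ts = np.array(
        [e.timestamp for e in events if e.kind in ("entry_granted", "entry_denied")]
    )
    if ts.size == 0:
        return float("nan")
    night = is_night(ts, lights_on_epoch)
    n_night = int(night.sum())
    n_day = int((~night).sum())
    if n_day == 0:
        return float("inf")
    return n_night / n_day
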