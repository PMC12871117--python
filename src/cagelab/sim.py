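"""Discrete-event colony simulator.

A group of agents lives in the home cages, attempts corridor entries with a
circadian- and motivation-modulated hazard, trains in the operant box through
the *real* access controller (the simulator supplies corridor stimuli and
never bypasses it), and moves among four home cages emitting antenna
detections.  One run yields the three logs of a real colony -- events.csv,
trials.csv, antenna.csv -- plus a manifest of the generative ground truth,
fully reproducible from the seed.

The generative structure mirrors the phenomena an automated home-cage
training system records: sessions regularized by a refractory interval
(~2.5/day, shifted-exponential inter-session intervals), engagement epochs
broken by pauses, psychometric accuracy by difficulty, mostly-fast exits
once the door opens, and nest-biased light-phase residence.
"""

from __future__ import annotations

import dataclasses
import heapq
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import tasks as tk
from .circadian import DEFAULT_LIGHTS_ON_EPOCH, is_night
from .controller import (
    ControllerConfig,
    RunResult,
    initial_state,
    step,
)
from .homecage import HomeCageTopology, default_topology
from .logio import (
    sessions_from_events,
    write_antenna_log,
    write_event_log,
    write_trial_log,
)
from .records import (
    AntennaDetection,
    ConfigError,
    CorridorEvent,
    Session,
    SubjectRecord,
    TaskParameters,
    Trial,
)

# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class TaskBehavior:
    """Generative per-task behavior of a simulated observer."""

    accuracy: dict[str, float]
    trial_duration_median_s: float
    trial_duration_sigma: float = 0.45
    omission_p: float = 0.0
    disengage_p: float = 0.03
    pause_median_s: float = 90.0
    pause_sigma: float = 0.8
    first_trial_median_s: float = 45.0
    first_trial_sigma: float = 0.5
    modality: str = "visual"  # 2AFC only
    difficulties: tuple[str, ...] = ()
    iti_gap_s: float = 0.0


def default_task_behaviors() -> dict[str, TaskBehavior]:
    return {
        "3afc": TaskBehavior(
            accuracy={"easy": 0.85, "medium": 0.75, "hard": 0.65, "extreme": 0.55},
            trial_duration_median_s=19.1,
            omission_p=0.02,
            difficulties=("easy", "medium", "hard", "extreme"),
        ),
        "2afc": TaskBehavior(
            accuracy={"easy": 0.90, "medium": 0.75, "hard": 0.60},
            trial_duration_median_s=4.1,
            difficulties=("easy", "medium", "hard"),
            iti_gap_s=tk.ITI_2AFC_S,
        ),
        "2ab": TaskBehavior(
            accuracy={"easy": 0.80, "medium": 0.70, "hard": 0.62, "extreme": 0.55},
            trial_duration_median_s=1.65,
            difficulties=("easy", "medium", "hard", "extreme"),
        ),
    }


@dataclass(frozen=True)
class ExitBehavior:
    """Exit once the door-open cue sounds: mostly immediate, sometimes a long
    pause independent of the door-opening time (a missed cue)."""

    fast_exit_prob: float = 0.65
    fast_latency_range_s: tuple[float, float] = (5.0, 55.0)
    slow_pause_median_s: float = 480.0
    slow_pause_sigma: float = 0.8


@dataclass(frozen=True)
class HomeCageBehavior:
    """Continuous-time random walk over the cage graph.

    Rates are cage-leave rates per hour; the nest is stickier during the
    light phase (nest_light_stay_factor divides the leave rate), which
    produces the nest-dwell bias of resting animals.
    """

    move_rate_day_per_h: float = 0.55
    move_rate_night_per_h: float = 1.3
    nest_light_stay_factor: float = 2.5
    traversal_s: tuple[float, float] = (2.0, 8.0)


@dataclass(frozen=True)
class SimConfig:
    """All generative parameters of a synthetic colony."""

    n_agents: int = 10
    days: float = 7.0
    seed: int = 0
    task: str = "2afc"
    t0: float = DEFAULT_LIGHTS_ON_EPOCH  # a lights-on instant
    attempt_rate_day_per_h: float = 1.0
    attempt_rate_night_per_h: float = 1.5
    motivation_floor: float = 0.2
    refractory_s: float = 14400.0
    min_session_s: float | tuple[float, float] = (300.0, 3600.0)
    scale_settle_s: float = 2.0
    restrictions_enabled: bool = True
    coincidence_window_s: float = 2.0
    entry_latency_s: float = 3.0
    behaviors: dict[str, TaskBehavior] = field(default_factory=default_task_behaviors)
    exit: ExitBehavior = field(default_factory=ExitBehavior)
    homecage: HomeCageBehavior = field(default_factory=HomeCageBehavior)
    topology: HomeCageTopology = field(default_factory=default_topology)
    baseline_weight_g: float = 25.0

    def __post_init__(self) -> None:
        if self.n_agents < 1 or self.days <= 0:
            raise ConfigError("need n_agents >= 1 and days > 0")
        if self.task not in self.behaviors:
            raise ConfigError(f"no behavior profile for task {self.task!r}")
        for p in (self.motivation_floor, self.exit.fast_exit_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if min(self.attempt_rate_day_per_h, self.attempt_rate_night_per_h) <= 0:
            raise ConfigError("attempt rates must be > 0")


@dataclass
class AgentState:
    agent_id: str
    location: str = "nest"
    last_session_end: float | None = None
    suppressed_until: float = -math.inf  # in corridor/box: no antenna pings
    traversal_until: float = -math.inf  # mid-tube: cannot attempt or move yet
    bandit_block: tk.BanditBlock | None = None
    bandit_trial_in_block: int = 0
    n_sessions: int = 0


# ---------------------------------------------------------------------------
# Hazard


def attempt_hazard(agent: AgentState, t: float, config: SimConfig) -> float:
    """Corridor-entry attempt rate (attempts/hour) for one agent at time t.

    The base day/night rate is modulated multiplicatively by motivation,
    which is 0 immediately after a session (hazard at its floor) and
    recovers linearly over one refractory interval.
    """
    base = (
        config.attempt_rate_night_per_h
        if bool(is_night(t, config.t0))
        else config.attempt_rate_day_per_h
    )
    if agent.last_session_end is None:
        motivation = 1.0
    else:
        motivation = min(1.0, max(0.0, (t - agent.last_session_end) / max(config.refractory_s, 1.0)))
    floor = config.motivation_floor
    return base * (floor + (1.0 - floor) * motivation)


# ---------------------------------------------------------------------------
# Session-level generation


@dataclass
class SessionSim:
    trials: list[Trial]
    leave_time: float
    fast_exit: bool
    water_ul: float


def simulate_session(
    agent: AgentState,
    task_params: TaskParameters,
    start: float,
    door_open_time: float,
    config: SimConfig,
    rng: np.random.Generator,
    session_ref: str,
) -> SessionSim:
    """Generate one session's trial stream and the exit time.

    Trials are produced by the task engines with the configured
    per-difficulty accuracies; with probability ``disengage_p`` per trial a
    pause drawn from the pause distribution inflates that trial's duration.
    On the door-open cue the agent exits within a minute with probability
    ``fast_exit_prob``, otherwise after a long pause independent of the
    door-opening time.
    """
    task = task_params.task
    beh = config.behaviors[task]
    if rng.random() < config.exit.fast_exit_prob:
        lo, hi = config.exit.fast_latency_range_s
        latency = float(rng.uniform(lo, hi))
        fast = True
    else:
        latency = float(
            rng.lognormal(math.log(config.exit.slow_pause_median_s), config.exit.slow_pause_sigma)
        )
        fast = False
    leave_time = door_open_time + latency

    trials: list[Trial] = []
    t = start
    water = 0.0
    index = 1
    while True:
        if index == 1:
            duration = float(
                rng.lognormal(math.log(beh.first_trial_median_s), beh.first_trial_sigma)
            )
        else:
            duration = float(
                rng.lognormal(math.log(beh.trial_duration_median_s), beh.trial_duration_sigma)
            )
        if rng.random() < beh.disengage_p:
            duration += float(rng.lognormal(math.log(beh.pause_median_s), beh.pause_sigma))
        trial = _make_trial(agent, task, beh, task_params, t, duration, index, rng, session_ref)
        if trial.onset + trial.duration > leave_time:
            break
        trials.append(trial)
        water += trial.reward_ul
        t = trial.onset + trial.duration + beh.iti_gap_s
        index += 1
    return SessionSim(trials=trials, leave_time=leave_time, fast_exit=fast, water_ul=water)


def _make_trial(
    agent: AgentState,
    task: str,
    beh: TaskBehavior,
    task_params: TaskParameters,
    onset: float,
    duration: float,
    index: int,
    rng: np.random.Generator,
    session_ref: str,
) -> Trial:
    subject = agent.agent_id
    if task == "3afc":
        mix = task_params.params.get(
            "difficulty_mix", {d: 1.0 / len(beh.difficulties) for d in beh.difficulties}
        )
        plan = tk.generate_trial_3afc(
            {"difficulty_mix": mix, "species": task_params.params.get("species", "mouse")}, rng
        )
        if rng.random() < beh.omission_p:
            touched = None
        elif rng.random() < beh.accuracy[plan.difficulty]:
            touched = plan.position
        else:
            others = [p for p in tk.POSITIONS_3AFC if p != plan.position]
            touched = others[rng.integers(0, 2)]
        res = tk.evaluate_response_3afc(plan, touched)
        return Trial(
            subject_id=subject,
            session_ref=session_ref,
            index=index,
            onset=onset,
            duration=duration,
            task=task,
            difficulty=plan.difficulty,
            stimulus={"position": plan.position, "delay_s": plan.delay_s},
            choice=res.choice,
            outcome=res.outcome,
            reward_ul=res.reward_ul,
        )
    if task == "2afc":
        difficulty = beh.difficulties[rng.integers(0, len(beh.difficulties))]
        side = tk.SIDES[rng.integers(0, 2)]
        plan = tk.plan_2afc(beh.modality, side, difficulty, rng)
        trace = tk.sample_response_trace_2afc(plan, beh.accuracy[difficulty], rng, start=onset)
        res = tk.run_trial_2afc(plan, trace)
        assert res.completed and res.outcome is not None
        return Trial(
            subject_id=subject,
            session_ref=session_ref,
            index=index,
            onset=onset,
            duration=duration,
            task=task,
            difficulty=difficulty,
            stimulus={
                "modality": plan.modality,
                "correct_side": side,
                "evidence": plan.evidence,
                "n_restarts": res.n_restarts,
                "fixation_s": res.fixation_s,
            },
            choice=res.choice,
            outcome=res.outcome,
            reward_ul=res.reward_ul,
        )
    if task == "2ab":
        if agent.bandit_block is None or agent.bandit_trial_in_block >= agent.bandit_block.length:
            difficulty = beh.difficulties[rng.integers(0, len(beh.difficulties))]
            agent.bandit_block = tk.next_block_2ab(agent.bandit_block, difficulty, rng)
            agent.bandit_trial_in_block = 0
        block = agent.bandit_block
        diff_label = _bandit_difficulty_label(block.p_high)
        if rng.random() < beh.accuracy[diff_label]:
            choice = block.high_side
        else:
            choice = "L" if block.high_side == "R" else "R"
        res = tk.run_trial_2ab(block, choice, rng)
        agent.bandit_trial_in_block += 1
        return Trial(
            subject_id=subject,
            session_ref=session_ref,
            index=index,
            onset=onset,
            duration=duration + res.forced_iti,
            task=task,
            difficulty=diff_label,
            stimulus={"high_side": block.high_side, "p_high": block.p_high},
            choice=res.choice,
            outcome=res.outcome,
            reward_ul=res.reward_ul,
            forced_iti=res.forced_iti,
        )
    raise ConfigError(f"unknown task {task!r}")


def _bandit_difficulty_label(p_high: float) -> str:
    for name, p in tk.BANDIT_P_HIGH.items():
        if math.isclose(p_high, p):
            return name
    return "extreme"


# ---------------------------------------------------------------------------
# Main simulation


@dataclass
class SimResult:
    events: list[CorridorEvent]
    trials: list[Trial]
    antenna: list[AntennaDetection]
    sessions: list[Session]
    manifest: dict[str, Any]
    controller: RunResult | None = None


def simulate(config: SimConfig, out_dir: str | Path | None = None) -> SimResult:
    """Run the colony for ``config.days`` days and return the three logs.

    The simulator feeds stimuli to the access controller and collects the
    corridor events it emits, so every emitted log satisfies the controller
    invariants (single occupancy, refractory spacing, minimum duration).
    """
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(4)
    rng_tasks = np.random.default_rng(child[0])
    rng_colony = np.random.default_rng(child[1])
    agent_rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(child[2].entropy).spawn(config.n_agents + 1)[1:]]
    rng_home = np.random.default_rng(child[3])

    agents = [AgentState(agent_id=f"m{i + 1:02d}") for i in range(config.n_agents)]
    subjects = {
        a.agent_id: SubjectRecord(
            subject_id=a.agent_id,
            rfid_tag=f"tag-{i + 1:04d}",
            baseline_weight=float(config.baseline_weight_g + rng_colony.normal(0.0, 1.5)),
            task=config.task,
        )
        for i, a in enumerate(agents)
    }
    settings = {
        sid: TaskParameters(subject_id=sid, task=config.task, stage=1, updated_at=config.t0)
        for sid in subjects
    }
    ctrl_cfg = ControllerConfig(
        refractory_interval=config.refractory_s,
        min_session_duration=config.min_session_s,
        scale_settle_window=config.scale_settle_s,
        restrictions_enabled=config.restrictions_enabled,
        seed=int(np.random.default_rng(child[1]).integers(0, 2**31 - 1)),
        subjects=subjects,
        settings=settings,
    )
    state = initial_state(ctrl_cfg)

    events: list[CorridorEvent] = []
    warns: list[str] = []
    trials: list[Trial] = []
    antenna: list[AntennaDetection] = []

    def feed(stimulus: tuple[str, Any], now: float) -> None:
        nonlocal state
        state, commands = step(state, stimulus, now, ctrl_cfg)
        for cmd in commands:
            if cmd[0] == "LOG":
                events.append(cmd[1])
            elif cmd[0] == "WARN":
                warns.append(cmd[1])

    t_end = config.t0 + config.days * 86400.0
    heap: list[tuple[float, int, str, int]] = []
    seq = 0

    def push(t: float, kind: str, agent_idx: int) -> None:
        nonlocal seq
        heapq.heappush(heap, (t, seq, kind, agent_idx))
        seq += 1

    # Poisson candidate streams are thinned against the per-agent hazard.
    rate_max = max(config.attempt_rate_day_per_h, config.attempt_rate_night_per_h) / 3600.0
    for i, agent in enumerate(agents):
        push(config.t0 + float(agent_rngs[i].exponential(1.0 / rate_max)), "attempt", i)
        push(config.t0 + _dwell_draw(agent, config.t0, config, rng_home), "move", i)

    # Agents linger in the corridor for a handful of seconds per attempt;
    # overlapping presences are what the camera reports as "multiple".
    corridor: dict[int, float] = {}  # agent index -> in corridor until
    eval_pending = False
    box_busy_until = -math.inf
    session_counter = 0
    n_multi = 0
    n_refractory = 0
    n_fast_exit = 0

    while heap:
        t, _, kind, idx = heapq.heappop(heap)
        if t >= t_end:
            break
        agent = agents[idx]

        if kind == "attempt":
            rng = agent_rngs[idx]
            push(t + float(rng.exponential(1.0 / rate_max)), "attempt", idx)
            rate = attempt_hazard(agent, t, config) / 3600.0
            if rng.random() >= rate / rate_max:
                continue  # thinned out
            if t < box_busy_until:
                continue  # box occupied: door 1 closed, no attempt possible
            if t < agent.traversal_until:
                continue  # still inside a tube; its far ping is in flight
            for j in [j for j, until in corridor.items() if until <= t]:
                del corridor[j]
            if idx in corridor:
                continue
            if agent.location != "task_access":
                _force_walk(agent, "task_access", t, config, antenna, rng_home)
            corridor[idx] = t + float(rng.uniform(5.0, 25.0))
            agent.suppressed_until = max(agent.suppressed_until, corridor[idx])
            feed(("rfid_detect", agent.agent_id), t)
            if not eval_pending:
                eval_pending = True
                push(t + config.coincidence_window_s, "zone_eval", idx)

        elif kind == "zone_eval":
            eval_pending = False
            for j in [j for j, until in corridor.items() if until <= t]:
                del corridor[j]
            label = "multiple" if len(corridor) >= 2 else "single"
            feed(("zone_report", {"door_gap": label}), t)
            granted = events and events[-1].kind == "entry_granted"
            if granted:
                entered = events[-1].subject_id
                assert entered is not None
                e_idx = next(i for i in corridor if agents[i].agent_id == entered)
                corridor.clear()
                session_counter += 1
                result = _run_box_session(
                    agents[e_idx],
                    t + config.entry_latency_s,
                    config,
                    ctrl_cfg,
                    settings[entered],
                    rng_tasks,
                    feed,
                    lambda: state,
                    f"S{session_counter:05d}",
                    subjects[entered].baseline_weight,
                )
                trials.extend(result.trials)
                if result.fast_exit:
                    n_fast_exit += 1
                session_end_t = result.leave_time + config.scale_settle_s
                agents[e_idx].last_session_end = session_end_t
                agents[e_idx].n_sessions += 1
                agents[e_idx].location = "task_access"
                agents[e_idx].suppressed_until = session_end_t
                box_busy_until = session_end_t + 1.0
                # Patch the session_end event with the session totals.
                for j in range(len(events) - 1, -1, -1):
                    if events[j].kind == "session_end":
                        detail = dict(events[j].detail)
                        detail["n_trials"] = len(result.trials)
                        detail["water_ul"] = result.water_ul
                        events[j] = dataclasses.replace(events[j], detail=detail)
                        break
            else:
                reason = events[-1].detail.get("denial_reason") if events else None
                if reason == "multi_animal":
                    n_multi += 1
                elif reason == "refractory":
                    n_refractory += 1
                corridor.clear()

        elif kind == "move":
            if t < agent.suppressed_until or t < agent.traversal_until or idx in corridor:
                resume = max(agent.suppressed_until, agent.traversal_until, t)
                push(resume + _dwell_draw(agent, resume, config, rng_home), "move", idx)
                continue
            nbrs = config.topology.neighbors(agent.location)
            target = nbrs[int(rng_home.integers(0, len(nbrs)))]
            _emit_traversal(agent, target, t, config, antenna, rng_home)
            push(t + _dwell_draw(agent, t, config, rng_home), "move", idx)

    antenna.sort(key=lambda d: (d.timestamp, d.subject_id, d.antenna_id))
    sessions = sessions_from_events(events)
    n_sessions = sum(1 for s in sessions if not s.open)
    manifest = {
        "seed": config.seed,
        "n_agents": config.n_agents,
        "days": config.days,
        "task": config.task,
        "t0": config.t0,
        "refractory_s": config.refractory_s,
        "min_session_s": list(config.min_session_s)
        if isinstance(config.min_session_s, tuple)
        else config.min_session_s,
        "attempt_rate_day_per_h": config.attempt_rate_day_per_h,
        "attempt_rate_night_per_h": config.attempt_rate_night_per_h,
        "accuracy": config.behaviors[config.task].accuracy,
        "disengage_p": config.behaviors[config.task].disengage_p,
        "fast_exit_prob": config.exit.fast_exit_prob,
        "pause_family": "lognormal",
        "attempt_family": "thinned-poisson",
        "realized": {
            "n_sessions": n_sessions,
            "n_trials": len(trials),
            "n_multi_animal_denials": n_multi,
            "n_refractory_denials": n_refractory,
            "fast_exit_fraction": (n_fast_exit / n_sessions) if n_sessions else None,
        },
    }
    result = SimResult(
        events=events, trials=trials, antenna=antenna, sessions=sessions, manifest=manifest
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_event_log(events, out / "events.csv")
        write_trial_log(trials, out / "trials.csv")
        write_antenna_log(antenna, out / "antenna.csv")
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result


def _run_box_session(
    agent: AgentState,
    entry_time: float,
    config: SimConfig,
    ctrl_cfg: ControllerConfig,
    task_params: TaskParameters,
    rng: np.random.Generator,
    feed,
    get_state,
    session_ref: str,
    baseline_weight: float,
) -> SessionSim:
    """Drive the controller through one full box stay (atomic in sim time)."""
    feed(("box_entry_detected", None), entry_time)
    min_dur = get_state().min_duration_draw or 0.0
    door_open_t = entry_time + min_dur
    sim = simulate_session(agent, task_params, entry_time, door_open_t, config, rng, session_ref)
    feed(("timer_tick", None), door_open_t)
    weight = baseline_weight + float(rng.normal(0.0, 0.3))
    feed(("scale_reading", weight), sim.leave_time)
    feed(("scale_reading", weight + float(rng.normal(0.0, 0.05))), sim.leave_time + 1.0)
    feed(("timer_tick", None), sim.leave_time + config.scale_settle_s)
    return sim


def _dwell_draw(agent: AgentState, t: float, config: SimConfig, rng: np.random.Generator) -> float:
    hc = config.homecage
    night = bool(is_night(t, config.t0))
    rate = hc.move_rate_night_per_h if night else hc.move_rate_day_per_h
    if agent.location == "nest" and not night:
        rate /= hc.nest_light_stay_factor
    return float(rng.exponential(3600.0 / rate))


def _emit_traversal(
    agent: AgentState,
    target: str,
    t: float,
    config: SimConfig,
    antenna: list[AntennaDetection],
    rng: np.random.Generator,
) -> None:
    a_near, a_far = config.topology.antenna_pair(agent.location, target)
    lo, hi = config.homecage.traversal_s
    dt = float(rng.uniform(lo, hi))
    antenna.append(AntennaDetection(t, a_near, agent.agent_id))
    antenna.append(AntennaDetection(t + dt, a_far, agent.agent_id))
    agent.location = target
    agent.traversal_until = t + dt


def _force_walk(
    agent: AgentState,
    target: str,
    t: float,
    config: SimConfig,
    antenna: list[AntennaDetection],
    rng: np.random.Generator,
) -> None:
    """Walk the agent to ``target`` just before time ``t`` (tube pings emitted)."""
    path = config.topology.path(agent.location, target)
    hops = len(path) - 1
    t_hop = t - 12.0 * hops
    for nxt in path[1:]:
        _emit_traversal(agent, nxt, t_hop, config, antenna, rng)
        t_hop += 12.0
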