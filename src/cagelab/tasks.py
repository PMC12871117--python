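"""Trial engines for the three operant paradigms.

* ``3afc``  -- visuospatial delayed-response three-alternative choice: a
  stimulus appears at one of three touchscreen positions and disappears after
  a difficulty-dependent mnemonic delay; the animal reports the remembered
  position. Correct touches earn a 10 ul sucrose reward.
* ``2afc``  -- evidence discrimination (visual luminance-ratio or auditory
  tone-cloud version): after a >= 500 ms center fixation the animal picks the
  side with stronger evidence; correct choices earn 2 ul. Fixation breaks
  restart the trial.
* ``2ab``   -- probabilistic two-armed bandit: sides pay 3 ul with
  complementary probabilities that reverse across 25-55 trial blocks; a trial
  is *correct* when the animal picks the high-probability side, whether or
  not the reward draw pays out.

All engines are pure functions of (parameters, response, rng state); audio
stimuli are symbolic schedules, never waveforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import ConfigError, ValidationError

POSITIONS_3AFC = ("L", "C", "R")
SIDES = ("L", "R")

#: Nominal mnemonic delay (s) per difficulty; the stimulus-offset rule is
#: tied to corridor position sensors that are not modeled here.
DELAYS_3AFC = {
    "mouse": {"easy": 0.0, "medium": 2.0, "hard": 2.3, "extreme": 3.3},
    "rat": {"easy": 0.0, "medium": 0.8, "hard": 1.5, "extreme": 2.6},
}

#: Visual 2AFC luminance ratios between the brighter and dimmer port.
LUMINANCE_RATIOS_2AFC = {"easy": 5.0, "medium": 2.5, "hard": 1.25}
#: Auditory 2AFC stimulus evidence (fraction of tones from the target octave).
AUDITORY_EVIDENCE_2AFC = {"easy": 0.98, "medium": 0.82, "hard": 0.66}

#: Bandit reward probability of the high side per difficulty; the extreme
#: level is drawn per block from {0.6, 0.55}.
BANDIT_P_HIGH = {"easy": 0.9, "medium": 0.8, "hard": 0.7}
BANDIT_P_EXTREME = (0.6, 0.55)

FIXATION_REQUIRED_S = 0.5
REWARD_UL = {"3afc": 10.0, "2afc": 2.0, "2ab": 3.0}
ITI_2AFC_S = 1.0
BANDIT_ITI_MEAN_S = 5.0
BANDIT_ITI_MAX_S = 30.0
BANDIT_BLOCK_RANGE = (25, 55)
DEFAULT_RESPONSE_WINDOW_3AFC_S = 60.0

TONE_RATE_HZ = 100.0
TONE_DURATION_S = 0.030
OCTAVE_BANDS_HZ = {"low": (5000.0, 10000.0), "high": (20000.0, 40000.0)}


# ---------------------------------------------------------------------------
# 3AFC


@dataclass(frozen=True)
class TrialPlan3AFC:
    position: str
    difficulty: str
    delay_s: float
    response_window: float = DEFAULT_RESPONSE_WINDOW_3AFC_S
    species: str = "mouse"


def generate_trial_3afc(
    stage_params: dict, rng: np.random.Generator
) -> TrialPlan3AFC:
    """Draw one trial plan: position uniform over L/C/R, difficulty from the
    stage's mix (a dict of weights summing to 1)."""
    mix = stage_params.get("difficulty_mix", {"easy": 1.0})
    names = sorted(mix)
    weights = np.array([mix[k] for k in names], dtype=float)
    if np.any(weights < 0):
        raise ConfigError("difficulty mix weights must be non-negative")
    if not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise ConfigError(f"difficulty mix must sum to 1, got {weights.sum()}")
    species = stage_params.get("species", "mouse")
    delays = DELAYS_3AFC[species]
    unknown = set(names) - set(delays)
    if unknown:
        raise ConfigError(f"unknown 3AFC difficulties {sorted(unknown)}")
    position = POSITIONS_3AFC[rng.integers(0, 3)]
    difficulty = names[rng.choice(len(names), p=weights)]
    return TrialPlan3AFC(
        position=position,
        difficulty=difficulty,
        delay_s=delays[difficulty],
        response_window=float(stage_params.get("response_window", DEFAULT_RESPONSE_WINDOW_3AFC_S)),
        species=species,
    )


@dataclass(frozen=True)
class Outcome3AFC:
    outcome: str  # correct | incorrect | omission
    choice: str | None
    reward_ul: float
    feedback: str  # tone_15khz | tone_4khz_house_light | house_light


def evaluate_response_3afc(
    plan: TrialPlan3AFC, touched: str | None, rt: float | None = None
) -> Outcome3AFC:
    """Score a touch (or its absence) against the planned position.

    A touch at the stimulus position is correct (10 ul, 15 kHz cue); any
    other touch is incorrect (4 kHz cue + house light, no reward); no touch
    within the response window is an omission (house light, no reward).
    """
    if touched is not None and touched not in POSITIONS_3AFC:
        raise ValidationError(f"unknown touch position {touched!r}")
    timed_out = touched is None or (rt is not None and rt > plan.response_window)
    if timed_out:
        return Outcome3AFC("omission", None, 0.0, "house_light")
    if touched == plan.position:
        return Outcome3AFC("correct", touched, REWARD_UL["3afc"], "tone_15khz")
    return Outcome3AFC("incorrect", touched, 0.0, "tone_4khz_house_light")


# ---------------------------------------------------------------------------
# 2AFC


@dataclass(frozen=True)
class TrialPlan2AFC:
    modality: str  # visual | auditory
    correct_side: str
    difficulty: str
    evidence: float  # luminance ratio (visual) or tone-cloud evidence (auditory)
    amplitude_db: float | None = None
    fixation_required: float = FIXATION_REQUIRED_S

    def __post_init__(self) -> None:
        if self.correct_side not in SIDES:
            raise ValidationError("correct_side must be L or R")
        if self.modality == "visual" and self.difficulty in LUMINANCE_RATIOS_2AFC:
            expected = LUMINANCE_RATIOS_2AFC[self.difficulty]
            if not math.isclose(self.evidence, expected):
                raise ValidationError(
                    f"visual {self.difficulty} ratio must be {expected}, got {self.evidence}"
                )
        if self.modality == "auditory" and self.difficulty in AUDITORY_EVIDENCE_2AFC:
            expected = AUDITORY_EVIDENCE_2AFC[self.difficulty]
            if not math.isclose(self.evidence, expected):
                raise ValidationError(
                    f"auditory {self.difficulty} evidence must be {expected}, got {self.evidence}"
                )


def plan_2afc(
    modality: str, correct_side: str, difficulty: str, rng: np.random.Generator | None = None
) -> TrialPlan2AFC:
    """Build a plan with the canonical evidence level for the difficulty."""
    if modality == "visual":
        evidence = LUMINANCE_RATIOS_2AFC[difficulty]
        amp = None
    elif modality == "auditory":
        evidence = AUDITORY_EVIDENCE_2AFC[difficulty]
        amp = float(rng.uniform(60.0, 80.0)) if rng is not None else 70.0
    else:
        raise ConfigError(f"unknown modality {modality!r}")
    return TrialPlan2AFC(modality, correct_side, difficulty, evidence, amp)


@dataclass(frozen=True)
class Result2AFC:
    """Outcome of running one response trace through the 2AFC engine."""

    completed: bool
    n_restarts: int
    fixation_s: float | None
    choice: str | None
    outcome: str | None
    reward_ul: float
    duration: float


def run_trial_2afc(plan: TrialPlan2AFC, response_trace: Sequence[tuple[float, str, str]]) -> Result2AFC:
    """Score a timestamped port in/out trace against the plan.

    ``response_trace`` rows are ``(t, port, "in" | "out")`` with port in
    {"C", "L", "R"}.  Center fixations shorter than the required 500 ms
    restart the trial (counted, no trial emitted); after the first valid
    fixation the first side poke is the choice.  If the trace ends before a
    valid fixation + side poke, the result is not completed.
    """
    times = [t for t, _, _ in response_trace]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValidationError("response trace must be time-ordered")
    n_restarts = 0
    fixation: float | None = None
    fix_start: float | None = None
    fixated = False
    for t, port, edge in response_trace:
        if not fixated:
            if port == "C" and edge == "in":
                fix_start = t
            elif port == "C" and edge == "out" and fix_start is not None:
                held = t - fix_start
                if held >= plan.fixation_required:
                    fixated = True
                    fixation = held
                else:
                    n_restarts += 1
                    fix_start = None
        else:
            if port in SIDES and edge == "in":
                outcome = "correct" if port == plan.correct_side else "incorrect"
                reward = REWARD_UL["2afc"] if outcome == "correct" else 0.0
                duration = t - times[0] if times else 0.0
                return Result2AFC(True, n_restarts, fixation, port, outcome, reward, duration)
    duration = (times[-1] - times[0]) if len(times) > 1 else 0.0
    return Result2AFC(False, n_restarts, fixation if fixated else None, None, None, 0.0, duration)


def sample_response_trace_2afc(
    plan: TrialPlan2AFC,
    p_correct: float,
    rng: np.random.Generator,
    restart_prob: float = 0.2,
    start: float = 0.0,
) -> list[tuple[float, str, str]]:
    """Generate a plausible port in/out trace for a simulated observer.

    With probability ``restart_prob`` (per attempt) the fixation is broken
    early (drawn uniform on [0.1, 0.5) s); held fixations draw uniform on
    [0.5, 0.8] s.  The side choice matches ``plan.correct_side`` with
    probability ``p_correct``.
    """
    trace: list[tuple[float, str, str]] = []
    t = start
    while rng.random() < restart_prob:
        t += float(rng.uniform(0.2, 1.0))
        trace.append((t, "C", "in"))
        t += float(rng.uniform(0.1, FIXATION_REQUIRED_S - 1e-3))
        trace.append((t, "C", "out"))
    t += float(rng.uniform(0.2, 1.0))
    trace.append((t, "C", "in"))
    t += float(rng.uniform(FIXATION_REQUIRED_S, 0.8))
    trace.append((t, "C", "out"))
    if rng.random() < p_correct:
        side = plan.correct_side
    else:
        side = "L" if plan.correct_side == "R" else "R"
    t += float(rng.uniform(0.2, 1.0))
    trace.append((t, side, "in"))
    t += float(rng.uniform(0.1, 0.5))
    trace.append((t, side, "out"))
    return trace


# ---------------------------------------------------------------------------
# Tone clouds (auditory 2AFC stimulus)


@dataclass(frozen=True)
class ToneCloud:
    """A symbolic 100 Hz stream of 30 ms pure tones.

    Each tone's octave is drawn Bernoulli(evidence) toward the target octave;
    its frequency is drawn uniformly from that octave's 6 log-spaced values.
    """

    onsets_s: tuple[float, ...]
    frequencies_hz: tuple[float, ...]
    target_octave: str
    evidence: float
    tone_duration_s: float = TONE_DURATION_S
    amplitude_db: float | None = None


def octave_frequencies(octave: str, n: int = 6) -> np.ndarray:
    lo, hi = OCTAVE_BANDS_HZ[octave]
    return np.geomspace(lo, hi, n)


def sample_tone_cloud(
    evidence: float,
    target_octave: str,
    duration: float,
    rng: np.random.Generator,
    amplitude_db: float | None = None,
) -> ToneCloud:
    if not 0.0 <= evidence <= 1.0:
        raise ConfigError("evidence must be in [0, 1]")
    if target_octave not in OCTAVE_BANDS_HZ:
        raise ConfigError(f"unknown octave {target_octave!r}")
    n = int(round(duration * TONE_RATE_HZ))
    onsets = np.arange(n) / TONE_RATE_HZ
    other = "high" if target_octave == "low" else "low"
    toward_target = rng.random(n) < evidence
    freqs = np.empty(n)
    for octave, sel in ((target_octave, toward_target), (other, ~toward_target)):
        k = int(sel.sum())
        if k:
            bank = octave_frequencies(octave)
            freqs[sel] = bank[rng.integers(0, len(bank), size=k)]
    return ToneCloud(
        onsets_s=tuple(onsets.tolist()),
        frequencies_hz=tuple(freqs.tolist()),
        target_octave=target_octave,
        evidence=evidence,
        amplitude_db=amplitude_db,
    )


def target_fraction(cloud: ToneCloud) -> float:
    lo, hi = OCTAVE_BANDS_HZ[cloud.target_octave]
    freqs = np.asarray(cloud.frequencies_hz)
    return float(np.mean((freqs >= lo) & (freqs <= hi))) if freqs.size else float("nan")


# ---------------------------------------------------------------------------
# Two-armed bandit


@dataclass(frozen=True)
class BanditBlock:
    high_side: str
    p_high: float
    length: int

    def __post_init__(self) -> None:
        if self.high_side not in SIDES:
            raise ValidationError("high_side must be L or R")
        if not BANDIT_BLOCK_RANGE[0] <= self.length <= BANDIT_BLOCK_RANGE[1]:
            raise ValidationError(
                f"block length must be in {BANDIT_BLOCK_RANGE}, got {self.length}"
            )
        if not 0.5 <= self.p_high <= 1.0:
            raise ValidationError("p_high must be in [0.5, 1]")

    @property
    def p_low(self) -> float:
        return 1.0 - self.p_high

    def p_reward(self, side: str) -> float:
        return self.p_high if side == self.high_side else self.p_low


def next_block_2ab(
    prev_block: BanditBlock | None, difficulty: str, rng: np.random.Generator
) -> BanditBlock:
    """Start a new block: the high side reverses, the length is uniform on
    [25, 55], and p_high follows the difficulty (extreme: drawn from
    {0.6, 0.55})."""
    if prev_block is None:
        high_side = SIDES[rng.integers(0, 2)]
    else:
        high_side = "L" if prev_block.high_side == "R" else "R"
    if difficulty == "extreme":
        p_high = float(BANDIT_P_EXTREME[rng.integers(0, len(BANDIT_P_EXTREME))])
    elif difficulty in BANDIT_P_HIGH:
        p_high = BANDIT_P_HIGH[difficulty]
    else:
        raise ConfigError(f"unknown bandit difficulty {difficulty!r}")
    length = int(rng.integers(BANDIT_BLOCK_RANGE[0], BANDIT_BLOCK_RANGE[1] + 1))
    return BanditBlock(high_side=high_side, p_high=p_high, length=length)


@dataclass(frozen=True)
class Result2AB:
    choice: str
    outcome: str  # correct iff choice == high_side, regardless of payout
    rewarded: bool
    reward_ul: float
    forced_iti: float


def sample_forced_iti(rng: np.random.Generator) -> float:
    """Exponential(mean 5 s) inter-trial interval, rejected beyond 30 s."""
    while True:
        iti = float(rng.exponential(BANDIT_ITI_MEAN_S))
        if iti <= BANDIT_ITI_MAX_S:
            return iti


def run_trial_2ab(block: BanditBlock, choice: str, rng: np.random.Generator) -> Result2AB:
    if choice not in SIDES:
        raise ValidationError("choice must be L or R")
    rewarded = bool(rng.random() < block.p_reward(choice))
    outcome = "correct" if choice == block.high_side else "incorrect"
    return Result2AB(
        choice=choice,
        outcome=outcome,
        rewarded=rewarded,
        reward_ul=REWARD_UL["2ab"] if rewarded else 0.0,
        forced_iti=sample_forced_iti(rng),
    )
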