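# Methods and modeling notes

This document records what `cagelab` models, the default parameters and
their units, what the colony generator does and does not emulate, and the
numerical choices that matter for reproducibility.

## 1. Access controller (`cagelab.controller`)

A finite-state machine over the corridor and box:
`WAIT → DETECTION → ACCESS_GRANTED → SESSION_RUNNING → EXIT_PENDING → WAIT`.

Entry policy, evaluated in order when an identified animal stands at the
inner door with the corridor zone report available:

1. **Unknown subject** — RFID tag not registered → denied.
2. **Multiple animals** — the vision zone report is not `single` → denied.
   (The refractory check is skipped in this case; denial reasons are
   therefore mutually exclusive and multi-animal takes precedence.)
3. **Refractory** — the subject's previous session ended less than
   `refractory_interval` ago → denied.

Defaults (all times in seconds): `refractory_interval = 14400` (4 h);
`min_session_duration = 1800`, or a `(low, high)` tuple from which each
session's minimum stay is drawn uniformly; `scale_settle_window = 2.0`.

The controller emits an exact event-kind sequence for a granted session:
`rfid_detect, zone_report, door1_close, door2_open, entry_granted,
door2_close, session_start, door2_open, weight_reading, session_end,
door1_open, door2_close, box_exit`. The exit weight is the median of the
scale readings collected during the settle window.

**Numerical choice — exit-door deadline.** The door-opening test is
`now >= deadline` against a deadline *frozen once* at session start as
`session_started_at + min_duration_draw`. Testing
`now - start >= min_duration` instead can fail by one ulp when a caller
schedules a tick at exactly `start + min_duration`, because
`(a + d) - a != d` in floating point. Freezing the sum makes the comparison
exact for any caller that derives its tick time from the same addition.

## 2. Vision (`cagelab.vision`)

Occupancy is decided per region of interest by thresholding dark pixels:
counts below `t_single` → `empty`, in `[t_single, t_multi)` → `single`,
at or above `t_multi` → `multiple`. Defaults: three equal ROIs across a
640×480 frame, `t_single = 1200` px, `t_multi = 2040` px (0.3× and 1.7× of
a nominal animal silhouette). A connected-component counter (8-connectivity)
and a centroid tracker serve as oracles in tests; synthetic frames with
ground-truth blob lists are generated in-process, so no image fixtures are
stored. Classification of a frame takes well under the 33 ms frame budget.

## 3. Task engines (`cagelab.tasks`)

- **3AFC** (visual, three ports L/C/R): stimulus delays per species
  (mouse: 0, 2.0, 2.3, 3.3 s; rat: 0, 0.8, 1.5, 2.6 s). Feedback: 15 kHz
  tone on correct, 4 kHz tone plus house light on incorrect, house light on
  omission. Reward 10 µl.
- **2AFC** (visual or auditory): the animal must hold the center port for
  `FIXATION_REQUIRED_S = 0.5` s; a shorter hold restarts the trial (counted,
  not scored). Visual luminance ratios 5 / 2.5 / 1.25; auditory tone-cloud
  evidence 0.98 / 0.82 / 0.66 at 100 Hz. Reward 2 µl, 1 s inter-trial gap.
- **2AB bandit**: block lengths uniform on [25, 55]; the high-probability
  side alternates between blocks; p(reward | high side) ∈ {0.9, 0.8, 0.7}
  (standard) or {0.6, 0.55} (extreme). A trial is *correct* when the animal
  chooses the high side, independent of the stochastic payout. Reward 3 µl.
  Forced inter-trial intervals are exponential with mean 5 s, truncated at
  30 s by rejection (truncated mean ≈ 4.926 s); the forced portion is
  excluded from engagement-relevant trial durations.

## 4. Progression (`cagelab.progression`)

Stage changes fire from windows of recent session summaries (accuracy over
valid, i.e. non-omitted, trials; valid-trial counts). Rules carry unique
priorities; the highest-priority firing rule acts, moving the stage by ±1
within [0, max_stage] or setting a parameter. Defaults: promote when
accuracy ≥ 0.7 and ≥ 60 valid trials over the last 2 sessions; demote when
accuracy < 0.4 over the last 3. Every decision is appended to a CSV audit
trail, and replaying the same summaries reproduces the same trajectory.

## 5. Colony simulator (`cagelab.sim`)

A discrete-event generator over continuous time. Crucially, it does **not**
mimic the controller's outputs — it synthesizes hardware inputs (RFID
detections, zone reports, timer ticks, scale readings) and feeds them to the
*real* controller, so granted/denied decisions, door events and session
records come from the code under test.

Modeled:

- **Attempt process.** Per-agent thinned Poisson attempts with rate
  `base × (floor + (1 − floor) × min(1, Δt/refractory))`, where Δt is time
  since the agent's last session end; night rate is 1.5× the day rate
  (lights on 08:00, 12 h cycle). Defaults: 1.0 attempt/h (day),
  motivation floor 0.2.
- **Corridor coincidence.** Other agents linger in the corridor for
  U(5, 25) s; a second animal within the 2 s evaluation window produces a
  `multiple` zone report and a multi-animal denial.
- **Sessions.** Minimum stay drawn from U(300, 3600) s by the controller;
  with probability 0.65 the agent leaves within U(5, 55) s of the exit door
  opening ("fast exit"), otherwise after a lognormal dwell (median 480 s).
  Trials are produced by the real task engines with per-difficulty
  generative accuracies (2AFC: 0.90/0.75/0.60) and a small per-trial
  disengagement probability.
- **Home cage.** A chain topology nest–food–enrichment–task_access with
  paired antennas per tube ((1,2), (3,4), (5,6)); traversals emit ordered
  ping pairs. While an agent is mid-tube it can neither attempt nor start
  another move (see ledgered traversal fix), so antenna pings never occur
  while their subject is logged inside the box.

Not modeled: body-weight dynamics (weights are noise around a baseline),
learning (accuracies are stationary per difficulty), social structure beyond
corridor coincidence, water-intake physiology, illness.

All randomness flows from one `numpy` `default_rng(seed)`; log writing uses
`repr(float)` so CSV round-trips are bit-exact and same-seed runs are
byte-identical. A run's manifest records the configuration and realized
marginals (sessions, trials, denials by reason, fast-exit fraction).

Realized marginals for the documented run (10 agents, 7 days, seed 1):
213 sessions (3.0 per agent-day), daily occupancy 72–83%, minimum ISI
4.01 h, fast-exit fraction 0.653, 135 refractory and 2 multi-animal
denials, 51,758 trials. These fall inside a-priori plausibility bands and
were *not* tuned against any test threshold.

## 6. Analytics (`cagelab.analytics`)

- **Occupancy**: per-window occupied seconds and percentage; single
  occupancy (guaranteed by the controller) makes the union of sessions equal
  their sum.
- **Gini**: Lorenz-curve construction over n+1 points including the origin,
  integrated with the trapezoid rule; `G = 1 − 2∫L`. An independent
  mean-absolute-difference implementation
  (`Σ|xi − xj| / (2 n² x̄)`) is kept as an oracle; the two agree to 1e-9 on
  random vectors. Uniform inputs give exactly 0 because the trapezoid
  integral of the diagonal is exactly 1/2 in floating point for these sums.
- **ISIs**: consecutive-session intervals per subject; `end_to_start`
  (default; what the refractory rule constrains) or `start_to_start`.
- **Engagement**: per-subject sigma cuts on *effective* trial durations
  (forced bandit ITIs subtracted): `highly_engaged` below mean − 0.5 σ,
  `disengaged` above mean + 2 σ (population σ, ddof = 0); subjects with
  fewer than 10 trials are labeled unstable.
- **Session time budget**: first-trial latency / engaged / disengaged /
  exit-latency fractions summing to 1; a fast exit is an exit within 60 s of
  the door opening.
- **Psychometrics**: accuracy by difficulty over non-omitted trials with the
  appropriate chance level (1/3 for 3AFC, 1/2 otherwise); engagement by
  trial position controls for session length by using median-length sessions
  and skips the 12-trial warm-up for 3AFC.
- **Home cage**: residency intervals are inferred only from consistent
  same-tube antenna pairs — dropout never invents a crossing; cage changes
  are pairs within 60 s; circadian profiles split night/day at the 08:00 and
  20:00 transitions; task vs no-task comparisons remove in-box time from the
  denominators; peri-session occupancy uses ±300 s windows, renormalizing
  and flagging windows truncated at the log boundary.

## 7. Welfare (`cagelab.welfare`)

Reports cover half-day windows ending exactly at a light transition
(enforced); they tabulate detections, sessions, water (µl) and mean weight
per subject, with explicit zero/NaN rows for absent subjects. Alarms fire on
values *strictly below* threshold; the weight alarm compares the window's
mean weight against `0.80 × baseline` and never fires on NaN (no readings is
a detection/session problem, not a weight measurement).

## 8. Open decisions and limitations

- The zone classifier uses fixed pixel-count thresholds; lighting drift or
  unusually large/small animals would require recalibration. The
  component-count oracle exists but is not the production path.
- Session pairing in `logio.sessions_from_events` attributes a stray
  `door2_open` to a subject only when exactly one session is open; logs
  corrupted beyond that raise `ConsistencyError` rather than guessing.
- The simulator's stationary accuracies mean progression dynamics are
  exercised on synthetic summaries, not on a closed learning loop.
- Gini is computed on non-negative inputs only; negative "occupancy" is
  rejected at validation.
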