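# cagelab

Hardware-free implementation of an automated home-cage operant training
system for rodents: a corridor access controller, vision-based occupancy
checks, self-paced task engines, adaptive training progression, a
discrete-event colony simulator that drives the real controller, and the
analytics needed to audit usage, learning, home-cage activity and welfare.

## The system being modeled

A colony of RFID-tagged animals lives in interconnected home cages. A single
operant box is reachable through a corridor gated by two doors. Animals train
themselves, around the clock, without handling:

- An animal entering the corridor is identified by RFID; an overhead camera
  confirms that exactly one animal is present before the inner door opens.
- Access is denied if another animal is in the box, if multiple animals are
  in the corridor, or if the animal finished a session less than the
  **refractory interval** (default 4 h) ago.
- Once inside, the animal runs self-paced trials (three-alternative visual
  discrimination, two-alternative forced choice with a 500 ms center-port
  fixation requirement, or a two-armed bandit with 25–55-trial blocks) and
  earns its daily water in the box.
- The exit door opens only after a minimum stay; the animal is weighed on a
  scale at the exit; sessions, trials and antenna crossings are logged.
- Training stages advance automatically from session-summary rules; a
  twice-daily report checks detections, sessions, water intake and weight
  against welfare thresholds.

`cagelab` implements the control logic, task logic and analytics of such a
system against plain data structures and logs, and replaces the animals and
hardware with a stochastic colony simulator, so every contract can be tested
end to end in software.

## Package layout

| Module | Contents |
| --- | --- |
| `cagelab.records` | Validated domain records (events, trials, sessions, subjects) |
| `cagelab.logio` | Bit-stable CSV/JSON log reading and writing; session pairing |
| `cagelab.controller` | The corridor/door state machine and its entry policy |
| `cagelab.vision` | Pixel-threshold occupancy classifier and synthetic frames |
| `cagelab.tasks` | 3AFC, 2AFC (fixation, restarts) and 2AB bandit engines |
| `cagelab.progression` | Rule-based stage promotion/demotion with audit trail |
| `cagelab.sim` | Discrete-event colony generator driving the real controller |
| `cagelab.analytics` | Occupancy, Gini fairness, ISIs, engagement, psychometrics, home-cage inference |
| `cagelab.welfare` | Twice-daily reports and threshold alarms |
| `cagelab.cli` | `cagelab simulate / analyze / report` |

## Worked example

```python
from cagelab.sim import SimConfig, simulate
from cagelab.analytics import daily_occupancy, gini, inter_session_intervals, isi_summary, sessions_per_day
from cagelab.circadian import day_windows

config = SimConfig(n_agents=10, days=7.0, seed=1)
result = simulate(config)
windows = day_windows(config.t0, 7)

occ = daily_occupancy(result.sessions, windows)
print([round(r.percentage, 1) for r in occ])
# [81.1, 81.0, 81.6, 72.4, 79.0, 83.1, 76.8]  -> 133.2 box-hours that week

print(round(gini(sessions_per_day(result.sessions, 7.0).sessions_per_day).gini, 3))
# 0.069  (near-equal access across the 10 animals)

print(isi_summary(inter_session_intervals(result.sessions)))
# median 5.92 h, 95.5th percentile 14.15 h, minimum 4.01 h  (>= 4 h refractory)
```

The same run yields 213 sessions (3.0 per animal per day), 51,758 trials,
and a 65.3% fast-exit fraction — animals leaving within a minute of the exit
door opening. The scripts in `examples/` walk through simulation, usage and
fairness, engagement and psychometrics, and home-cage/welfare analysis.

From the command line:

```sh
cagelab simulate --seed 1 --out run/         # writes events/trials/antenna CSVs + manifest
cagelab analyze gini --data run/ --out out/  # and: occupancy, attempts, isi, engagement, ...
cagelab report --data run/ --at <epoch-of-light-transition> --out out/
```

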