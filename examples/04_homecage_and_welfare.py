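"""Home-cage activity from antenna pings, and a twice-daily welfare report.

Run:
    python examples/04_homecage_and_welfare.py
"""

from __future__ import annotations

from cagelab.analytics import (
    cage_changes,
    infer_cage_intervals,
    night_day_attempt_ratio,
    peri_session_occupancy,
)
from cagelab.circadian import HALF_DAY_S
from cagelab.homecage import default_topology
from cagelab.records import SubjectRecord
from cagelab.sim import SimConfig, simulate
from cagelab.welfare import build_report, check_alarms

config = SimConfig(n_agents=10, days=7.0, seed=1)
result = simulate(config)
topo = default_topology()

# Reconstruct where each animal was from raw antenna pings.
intervals = infer_cage_intervals(result.antenna, topo)
print(f"inferred {len(intervals)} cage-residency intervals")

# Cage changes and their circadian profile (animals are nocturnal).
changes, profile = cage_changes(result.antenna, topo)
night = profile[profile.night].median_changes_per_h.mean()
day = profile[~profile.night].median_changes_per_h.mean()
print(f"cage changes/h: night {night:.2f} vs day {day:.2f}")
print(f"night/day corridor-attempt ratio: "
      f"{night_day_attempt_ratio(result.events):.2f}")

# Which cage do animals come from / return to around a session?
peri = peri_session_occupancy(intervals, result.sessions)
top = (peri.groupby(["phase", "cage"]).fraction.mean()
           .groupby(level=0).idxmax())
print("most occupied cage before entry / after exit:", dict(top))

# Twice-daily welfare report at the first lights-off transition.
subjects = {
    f"m{i:02d}": SubjectRecord(f"m{i:02d}", rfid_tag=f"m{i:02d}",
                               baseline_weight=config.baseline_weight_g,
                               task=config.task)
    for i in range(1, config.n_agents + 1)
}
report = build_report(result.events, result.antenna, subjects,
                      window_end=config.t0 + HALF_DAY_S)
print(report.table.to_string(index=False))
alarms = check_alarms(
    report,
    {"detection_count": 1.0, "session_count": 1.0, "water_ul": 20.0,
     "weight": 1.0},
    baselines={s: config.baseline_weight_g for s in subjects},
)
print(f"alarms in first half-day window: {len(alarms)}")
for a in alarms:
    print(f"  {a.subject_id}: {a.metric} = {a.value} < {a.threshold}")
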