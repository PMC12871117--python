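"""Box usage: daily occupancy, access fairness (Gini), attempts and ISIs.

Run after the simulation example, or standalone (it simulates in memory):
    python examples/02_occupancy_and_fairness.py
"""

from __future__ import annotations

from cagelab.analytics import (
    classify_attempts,
    daily_occupancy,
    gini,
    inter_session_intervals,
    isi_summary,
    sessions_per_day,
)
from cagelab.circadian import day_windows
from cagelab.sim import SimConfig, simulate

config = SimConfig(n_agents=10, days=7.0, seed=1)
result = simulate(config)
windows = day_windows(config.t0, int(config.days))

# How busy is the single operant box, day by day?
occ = daily_occupancy(result.sessions, windows)
print("daily occupancy (%):", [round(r.percentage, 1) for r in occ])
weekly_hours = sum(r.occupied_seconds for r in occ) / 3600.0
print(f"weekly training hours delivered by one box: {weekly_hours:.1f}")

# Is access shared fairly across animals?
per_subject = sessions_per_day(result.sessions, config.days)
g = gini(per_subject.sessions_per_day)
print(f"Gini of per-animal session counts: {g.gini:.3f} (0 = perfectly even)")

# How often are entry attempts rejected, per successful entrance?
attempts = classify_attempts(result.events, windows)
print(f"failed attempts per entrance (mean over subject-days): "
      f"{attempts.ratio.mean():.2f}")

# How long do animals wait between sessions?
isis = inter_session_intervals(result.sessions)
summary = isi_summary(isis)
print(f"ISI hours: median {summary['median_h']:.2f}, "
      f"95.5th pct {summary['p955_h']:.2f}, min {summary['min_h']:.2f} "
      f"(refractory floor: {config.refractory_s / 3600:.0f} h)")
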