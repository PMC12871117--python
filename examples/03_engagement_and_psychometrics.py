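"""Within-session behavior: engagement labels, time budgets, psychometrics.

Run:
    python examples/03_engagement_and_psychometrics.py
"""

from __future__ import annotations

from cagelab.analytics import (
    accuracy_by_difficulty,
    engagement_by_trial_index,
    label_engagement,
    session_time_budget,
)
from cagelab.sim import SimConfig, simulate

config = SimConfig(n_agents=10, days=7.0, seed=1)
result = simulate(config)

# Per-trial engagement from each animal's own response-time distribution.
labeled, models = label_engagement(result.trials)
fractions = labeled.engagement.value_counts(normalize=True)
print("engagement fractions:")
print(fractions.round(3).to_string())

# Where does in-box time go?  Average the four-way budget over sessions.
closed = [s for s in result.sessions if not s.open]
budgets = [session_time_budget(s, labeled) for s in closed]
for key in ("first_trial", "engaged", "disengaged", "exit_latency"):
    mean = sum(b[key] for b in budgets) / len(budgets)
    print(f"mean fraction of session in {key}: {mean:.3f}")
fast = sum(b["fast_exit"] for b in budgets) / len(budgets)
print(f"fast-exit fraction (left within 60 s of door opening): {fast:.3f}")

# Accuracy should fall monotonically with stimulus difficulty.
psy = accuracy_by_difficulty(labeled)
print(psy.to_string(index=False))

# Engagement by trial position, controlling for session length.
profile = engagement_by_trial_index(labeled, config.task)
print(profile.head(5).to_string(index=False))
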