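"""Light-cycle bookkeeping shared by the simulator, analytics and reports.

The colony lives under a 12 h light / 12 h dark cycle with lights on at
08:00.  Analysis days are 24 h windows aligned to lights-on, so daily counts
and day/night splits share boundaries, and welfare report windows end at the
two light-cycle transitions (08:00 and 20:00).
"""

from __future__ import annotations

import numpy as np

#: 2024-01-01T08:00:00Z -- an arbitrary lights-on instant used as the default
#: time origin for simulated colonies.
DEFAULT_LIGHTS_ON_EPOCH = 1704096000.0

DAY_S = 86400.0
HALF_DAY_S = 43200.0


def phase_seconds(ts, lights_on_epoch: float = DEFAULT_LIGHTS_ON_EPOCH):
    """Seconds since the most recent lights-on boundary (vectorized)."""
    return np.asarray(ts, dtype=float) - lights_on_epoch - (
        np.floor((np.asarray(ts, dtype=float) - lights_on_epoch) / DAY_S) * DAY_S
    )


def is_night(ts, lights_on_epoch: float = DEFAULT_LIGHTS_ON_EPOCH):
    """True during the dark phase (20:00-08:00 under the default cycle)."""
    return phase_seconds(ts, lights_on_epoch) >= HALF_DAY_S


def clock_hour(ts, lights_on_epoch: float = DEFAULT_LIGHTS_ON_EPOCH, lights_on_hour: int = 8):
    """Local clock hour in [0, 24)."""
    return (phase_seconds(ts, lights_on_epoch) / 3600.0 + lights_on_hour) % 24.0


def day_windows(t0: float, n_days: int, window_s: float = DAY_S) -> list[tuple[float, float]]:
    """Consecutive [start, end) analysis windows beginning at ``t0``."""
    return [(t0 + i * window_s, t0 + (i + 1) * window_s) for i in range(n_days)]


def is_transition(ts: float, lights_on_epoch: float = DEFAULT_LIGHTS_ON_EPOCH, tol: float = 1.0) -> bool:
    """Whether ``ts`` falls on a light-cycle transition (08:00 or 20:00)."""
    ph = float(phase_seconds(ts, lights_on_epoch))
    return min(ph % HALF_DAY_S, HALF_DAY_S - (ph % HALF_DAY_S)) <= tol
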