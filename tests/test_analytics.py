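"""Behavioral analytics: inequality, attempts, engagement, home-cage inference.

The Gini test cross-checks the Lorenz-trapezoid implementation against an
independent mean-absolute-difference formula; the cage-inference test replays
a scripted ground-truth walk through the detector.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cagelab.analytics import (
    CageInterval,
    accuracy_by_difficulty,
    cage_changes,
    classify_attempts,
    daily_occupancy,
    engagement_by_trial_index,
    gini,
    gini_mean_abs_difference,
    infer_cage_intervals,
    inter_session_intervals,
    isi_summary,
    label_engagement,
    night_day_attempt_ratio,
    peri_session_occupancy,
    session_time_budget,
    sessions_per_day,
    task_vs_notask_activity,
)
from cagelab.homecage import default_topology
from cagelab.records import (
    AntennaDetection,
    ConfigError,
    ConsistencyError,
    CorridorEvent,
    Session,
    Trial,
    ValidationError,
)


# ---------------------------------------------------------------------------
# Occupancy


class TestOccupancy:
    def test_session_durations_sum_to_occupied_seconds(self):
        sessions = [
            Session("m01", 100.0, 700.0),
            Session("m02", 1000.0, 1600.0),
        ]
        (rec,) = daily_occupancy(sessions, [(0.0, 86400.0)])
        assert rec.occupied_seconds == pytest.approx(1200.0)
        assert rec.percentage == pytest.approx(100.0 * 1200.0 / 86400.0)

    def test_sessions_clipped_to_window(self):
        sessions = [Session("m01", -100.0, 100.0)]
        (rec,) = daily_occupancy(sessions, [(0.0, 86400.0)])
        assert rec.occupied_seconds == pytest.approx(100.0)

    def test_open_sessions_excluded_with_warning(self):
        sessions = [Session("m01", 0.0, 50.0, open=True)]
        with pytest.warns(UserWarning, match="open session"):
            (rec,) = daily_occupancy(sessions, [(0.0, 86400.0)])
        assert rec.occupied_seconds == 0.0

    def test_colony_occupancy_never_exceeds_100(self, colony, colony_days):
        for rec in daily_occupancy(colony.sessions, colony_days):
            assert 0.0 <= rec.percentage <= 100.0


# ---------------------------------------------------------------------------
# Gini / Lorenz


class TestGini:
    def test_uniform_occupancy_is_exactly_zero(self):
        assert gini([3.5] * 10).gini == 0.0

    def test_single_owner_anchor(self):
        # One subject holds everything: G = (n-1)/n under this convention.
        res = gini([0.0, 0.0, 0.0, 12.0])
        assert res.gini == pytest.approx(0.75, abs=1e-12)

    def test_two_subject_example(self):
        assert gini([1.0, 3.0]).gini == pytest.approx(0.25, abs=1e-12)

    def test_scale_invariance(self):
        a = gini([1.0, 2.0, 5.0, 9.0]).gini
        b = gini([10.0, 20.0, 50.0, 90.0]).gini
        assert a == pytest.approx(b, abs=1e-12)

    def test_transfer_to_richer_increases_gini(self):
        base = [2.0, 4.0, 6.0, 8.0]
        poorer_to_richer = [1.0, 4.0, 6.0, 9.0]
        assert gini(poorer_to_richer).gini > gini(base).gini

    def test_lorenz_points_include_origin(self):
        res = gini([1.0, 1.0])
        assert res.points[0] == (0.0, 0.0)
        assert res.points[-1] == (1.0, 1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            gini([])
        with pytest.raises(ValidationError):
            gini([0.0, 0.0])
        with pytest.raises(ValidationError):
            gini([-1.0, 2.0])

    def test_trapezoid_equals_mean_abs_difference_on_1000_random_vectors(self):
        """The Lorenz-trapezoid Gini and the pairwise-difference formula are
        the same statistic under this convention; verified to 1e-9 without an
        n/(n-1) correction."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(1, 13))
            x = rng.uniform(0.0, 10.0, size=n)
            if x.sum() == 0:
                continue
            assert gini(x).gini == pytest.approx(
                gini_mean_abs_difference(x), abs=1e-9
            )


# ---------------------------------------------------------------------------
# Attempts


def _denied(t, sid, reason):
    return CorridorEvent(t, "entry_denied", sid, {"denial_reason": reason})


class TestAttempts:
    def test_counts_and_ratio(self):
        events = [
            CorridorEvent(100.0, "entry_granted", "m01"),
            _denied(200.0, "m01", "refractory"),
            _denied(300.0, "m01", "refractory"),
            _denied(400.0, "m01", "multi_animal"),
        ]
        df = classify_attempts(events, [(0.0, 86400.0)])
        row = df.iloc[0]
        assert row.granted == 1
        assert row.refractory == 2 and row.multi_animal == 1
        assert row.ratio == pytest.approx(3.0)

    def test_no_failures_ratio_zero(self):
        events = [CorridorEvent(100.0, "entry_granted", "m01")]
        df = classify_attempts(events, [(0.0, 86400.0)])
        assert df.iloc[0].ratio == 0.0

    def test_failures_without_grant_ratio_nan(self):
        events = [_denied(100.0, "m01", "refractory")]
        df = classify_attempts(events, [(0.0, 86400.0)])
        assert np.isnan(df.iloc[0].ratio)

    def test_denial_without_reason_raises(self):
        ev = CorridorEvent.__new__(CorridorEvent)
        object.__setattr__(ev, "timestamp", 0.0)
        object.__setattr__(ev, "kind", "entry_denied")
        object.__setattr__(ev, "subject_id", "m01")
        object.__setattr__(ev, "detail", {})
        with pytest.raises(ConsistencyError):
            classify_attempts([ev])

    def test_colony_attempt_table_consistent_with_manifest(self, colony, colony_days):
        df = classify_attempts(colony.events, colony_days)
        r = colony.manifest["realized"]
        assert int(df.multi_animal.sum()) == r["n_multi_animal_denials"]
        assert int(df.refractory.sum()) == r["n_refractory_denials"]
        assert int(df.granted.sum()) == r["n_sessions"]


# ---------------------------------------------------------------------------
# ISI


class TestISI:
    def test_end_to_start_semantics(self):
        sessions = [
            Session("m01", 0.0, 600.0),
            Session("m01", 15000.0, 15600.0),
        ]
        df = inter_session_intervals(sessions)
        assert df.iloc[0].isi_s == pytest.approx(14400.0)

    def test_start_to_start_alternative(self):
        sessions = [
            Session("m01", 0.0, 600.0),
            Session("m01", 15000.0, 15600.0),
        ]
        df = inter_session_intervals(sessions, endpoints="start_to_start")
        assert df.iloc[0].isi_s == pytest.approx(15000.0)

    def test_unknown_endpoints_rejected(self):
        with pytest.raises(ConfigError):
            inter_session_intervals([], endpoints="middle_to_middle")

    def test_single_session_contributes_nothing(self):
        df = inter_session_intervals([Session("m01", 0.0, 10.0)])
        assert df.empty
        assert np.isnan(isi_summary(df)["median_h"])

    def test_summary_units_are_hours(self):
        sessions = [Session("m01", 0.0, 600.0), Session("m01", 7800.0, 8000.0)]
        s = isi_summary(inter_session_intervals(sessions))
        assert s["median_h"] == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# Engagement


def _dur_trial(sid, i, dur, task="3afc", iti=0.0):
    outcome = "correct"
    reward = {"3afc": 10.0, "2afc": 2.0, "2ab": 3.0}[task]
    return Trial(sid, f"{sid}-s1", i, 1000.0 + 200.0 * i, dur, task, "easy",
                 None, "L", outcome, reward, forced_iti=iti)


class TestEngagement:
    def test_sigma_cut_moment_arithmetic(self):
        """Ten 10 s trials and one 100 s trial: mean 18.18, population sd
        25.87, so the disengaged cut falls at 69.9 s and only the 100 s trial
        is disengaged."""
        durations = [10.0] * 10 + [100.0]
        trials = [_dur_trial("m01", i + 1, d) for i, d in enumerate(durations)]
        labeled, models = label_engagement(trials)
        m = models["m01"]
        assert m.mean_duration == pytest.approx(np.mean(durations))
        assert m.sd_duration == pytest.approx(np.std(durations))  # ddof=0
        assert m.cut_disengaged == pytest.approx(69.92, abs=0.01)
        # cut_high = 18.18 - 12.94 = 5.25 s: the 10 s trials sit in the medium
        # band; only the 100 s trial crosses the disengaged cut.
        assert m.cut_high_engaged == pytest.approx(5.245, abs=0.01)
        assert list(labeled.engagement[:10]) == ["medium_engaged"] * 10
        assert labeled.engaged[:10].all()
        assert labeled.engagement.iloc[10] == "disengaged"

    def test_forced_iti_removed_before_moments(self):
        # Same effective durations => same labels, whatever the forced ITI.
        plain = [_dur_trial("m01", i + 1, 10.0) for i in range(10)] + [
            _dur_trial("m01", 11, 100.0)
        ]
        shifted = [
            _dur_trial("m01", i + 1, 10.0 + 20.0, task="2ab", iti=20.0)
            for i in range(10)
        ] + [_dur_trial("m01", 11, 120.0, task="2ab", iti=20.0)]
        la, _ = label_engagement(plain)
        lb, _ = label_engagement(shifted)
        assert list(la.engagement) == list(lb.engagement)

    def test_small_sample_flagged_unstable(self):
        trials = [_dur_trial("m01", i + 1, 10.0 + i) for i in range(5)]
        _, models = label_engagement(trials)
        assert models["m01"].unstable

    def test_disengaged_fraction_bounded_on_colony(self, colony, colony_config):
        """Sigma-cut property: on simulated data the disengaged fraction stays
        near the pause-injection rate (2 sigma one-sided tail + injected
        pauses)."""
        labeled, _ = label_engagement(colony.trials)
        frac = float((labeled.engagement == "disengaged").mean())
        inject = colony_config.behaviors[colony_config.task].disengage_p
        assert frac <= inject + 0.025


class TestTimeBudget:
    def test_four_fractions_sum_to_one(self):
        session = Session("m01", 1000.0, 2000.0, door_open_time=1900.0)
        trials = [
            Trial("m01", "s1", 1, 1040.0, 30.0, "2afc", "easy", None, "L",
                  "correct", 2.0),
            Trial("m01", "s1", 2, 1080.0, 20.0, "2afc", "easy", None, "L",
                  "correct", 2.0),
            Trial("m01", "s1", 3, 1200.0, 40.0, "2afc", "easy", None, "R",
                  "incorrect", 0.0),
        ]
        labeled, _ = label_engagement(trials)
        budget = session_time_budget(session, labeled)
        total = (budget["first_trial"] + budget["engaged"]
                 + budget["disengaged"] + budget["exit_latency"])
        assert total == pytest.approx(1.0, abs=1e-9)
        # First-trial latency: entry 1000 to first completion 1070.
        assert budget["first_trial"] == pytest.approx(70.0 / 1000.0)
        # Exit latency: last trial ends 1240, session ends 2000.
        assert budget["exit_latency"] == pytest.approx(760.0 / 1000.0)

    def test_fast_exit_flag_uses_door_open_time(self):
        fast = Session("m01", 0.0, 650.0, door_open_time=600.0)
        slow = Session("m01", 0.0, 700.0, door_open_time=600.0)
        empty = pd.DataFrame(
            columns=["subject_id", "session_ref", "index", "onset", "duration",
                     "forced_iti", "effective_duration", "task", "difficulty",
                     "outcome", "reward_ul", "engagement", "engaged"]
        )
        assert session_time_budget(fast, empty)["fast_exit"] is True
        assert session_time_budget(slow, empty)["fast_exit"] is False

    def test_open_session_rejected(self):
        with pytest.raises(ValidationError):
            session_time_budget(Session("m01", 0.0, 0.0, open=True), pd.DataFrame())

    def test_colony_budgets_conserve(self, colony):
        labeled, _ = label_engagement(colony.trials)
        closed = [s for s in colony.sessions if not s.open][:40]
        for s in closed:
            b = session_time_budget(s, labeled)
            total = b["first_trial"] + b["engaged"] + b["disengaged"] + b["exit_latency"]
            assert total == pytest.approx(1.0, abs=1e-9)


class TestPsychometrics:
    def test_accuracy_excludes_omissions(self):
        trials = [
            _dur_trial("m01", 1, 10.0),
            _dur_trial("m01", 2, 10.0),
            Trial("m01", "m01-s1", 3, 1600.0, 10.0, "3afc", "easy", None, None,
                  "omission", 0.0),
        ]
        labeled, _ = label_engagement(trials)
        table = accuracy_by_difficulty(labeled)
        assert table.n.sum() == 2  # omission dropped from denominator
        assert (table.accuracy == 1.0).all()
        assert np.allclose(table.chance, 1.0 / 3.0)

    def test_colony_accuracy_orders_by_difficulty(self, colony, colony_config):
        """Recovered accuracies preserve the generative easy > medium > hard
        ordering when pooled over subjects."""
        labeled, _ = label_engagement(colony.trials)
        valid = labeled[(labeled.outcome != "omission") & labeled.engaged]
        acc = valid.groupby("difficulty").apply(
            lambda g: (g.outcome == "correct").mean(), include_groups=False
        )
        assert acc["easy"] > acc["medium"] > acc["hard"]

    def test_trial_index_curve_respects_median_control(self):
        # Two sessions of 60 trials, one of 10: median is 60, the short
        # session is dropped and bins end at index 60.
        trials = []
        for ref, n in (("a", 60), ("b", 60), ("c", 10)):
            for i in range(1, n + 1):
                trials.append(
                    Trial("m01", ref, i, 1000.0 + 20.0 * i, 10.0, "2afc", "easy",
                          None, "L", "correct", 2.0)
                )
        labeled, _ = label_engagement(trials)
        curve = engagement_by_trial_index(labeled, "2afc")
        assert curve.bin_start.min() == 1
        assert curve.bin_start.max() <= 60
        assert curve.n.sum() == 120  # only the two long sessions contribute

    def test_trial_index_curve_3afc_warmup_excluded(self):
        trials = [
            Trial("m01", "a", i, 1000.0 + 25.0 * i, 10.0, "3afc", "easy", None,
                  "L", "correct", 10.0)
            for i in range(1, 41)
        ]
        labeled, _ = label_engagement(trials)
        curve = engagement_by_trial_index(labeled, "3afc")
        assert curve.bin_start.min() == 13  # first 12 trials are warm-up


# ---------------------------------------------------------------------------
# Home-cage inference


class TestCageInference:
    def _walk_pings(self, hops, t0=0.0, gap=100.0, dt=4.0, sid="m01"):
        """Scripted ground-truth walk: hops is a list of (near, far, dest)."""
        topo = default_topology()
        pings, truth = [], []
        t = t0
        for src, dst in hops:
            a, b = topo.antenna_pair(src, dst)
            pings.append(AntennaDetection(t, a, sid))
            pings.append(AntennaDetection(t + dt, b, sid))
            truth.append((dst, t + dt))
            t += gap
        return pings, truth

    def test_lossless_pings_recover_ground_truth(self):
        pings, truth = self._walk_pings(
            [("nest", "food"), ("food", "enrichment"), ("enrichment", "food"),
             ("food", "nest")]
        )
        intervals = infer_cage_intervals(pings, default_topology())
        assert [iv.cage for iv in intervals] == [c for c, _ in truth][:-1] + []
        # Each residency runs from its arrival ping to the next arrival.
        for iv, (cage, arrived), (_, left) in zip(intervals, truth, truth[1:]):
            assert iv.cage == cage
            assert iv.start == pytest.approx(arrived)
            assert iv.end == pytest.approx(left)

    def test_dropout_never_invents_crossings(self):
        rng = np.random.default_rng(6)
        pings, _ = self._walk_pings(
            [("nest", "food"), ("food", "enrichment"), ("enrichment", "task_access"),
             ("task_access", "enrichment"), ("enrichment", "food"), ("food", "nest")]
        )
        full = infer_cage_intervals(pings, default_topology())
        full_cages = {(iv.cage, round(iv.start, 3)) for iv in full}
        kept = [p for p in pings if rng.random() > 0.10]
        degraded = infer_cage_intervals(kept, default_topology())
        for iv in degraded:
            assert (iv.cage, round(iv.start, 3)) in full_cages

    def test_isolated_ping_assigns_nothing(self):
        pings = [AntennaDetection(0.0, 1, "m01")]
        assert infer_cage_intervals(pings, default_topology()) == []

    def test_unknown_antenna_rejected(self):
        with pytest.raises(ConfigError):
            infer_cage_intervals(
                [AntennaDetection(0.0, 99, "m01")], default_topology()
            )

    def test_colony_inference_consistent_with_chain(self, colony):
        """On simulated lossless logs, consecutive inferred cages are always
        neighbors in the declared chain."""
        topo = default_topology()
        intervals = infer_cage_intervals(colony.antenna, topo)
        by_subject: dict[str, list[CageInterval]] = {}
        for iv in intervals:
            by_subject.setdefault(iv.subject_id, []).append(iv)
        for ivs in by_subject.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if a.end == b.start:  # contiguous residency change
                    assert b.cage in topo.neighbors(a.cage) or b.cage == a.cage


class TestCageChanges:
    def test_pair_within_minute_counts(self):
        pings = [AntennaDetection(0.0, 1, "m01"), AntennaDetection(4.0, 2, "m01")]
        changes, _ = cage_changes(pings, default_topology())
        assert len(changes) == 1
        assert changes.iloc[0].cage == "food"

    def test_pair_90_seconds_apart_is_no_change(self):
        pings = [AntennaDetection(0.0, 1, "m01"), AntennaDetection(90.0, 2, "m01")]
        changes, _ = cage_changes(pings, default_topology())
        assert changes.empty

    def test_night_profile_exceeds_day_on_colony(self, colony):
        _, profile = cage_changes(colony.antenna, default_topology())
        night = profile[profile.night].median_changes_per_h.mean()
        day = profile[~profile.night].median_changes_per_h.mean()
        assert night > day

    def test_task_vs_notask_denominator_excludes_box_time(self):
        # 10 changes in 24 h with 6 h in the box: rate is per 18 h, scaled /day.
        changes = pd.DataFrame(
            {"subject_id": ["m01"] * 10,
             "timestamp": np.linspace(1000.0, 80000.0, 10),
             "cage": ["food"] * 10}
        )
        sessions = [Session("m01", 10.0, 10.0 + 6 * 3600.0)]
        out = task_vs_notask_activity(changes, sessions, [(0.0, 86400.0, "task")])
        row = out.iloc[0]
        assert row.exposed_s == pytest.approx(86400.0 - 6 * 3600.0)
        assert row.changes_per_day == pytest.approx(10 / (18 * 3600.0) * 86400.0)

    def test_overlapping_labels_rejected(self):
        changes = pd.DataFrame(columns=["subject_id", "timestamp", "cage"])
        with pytest.raises(ConfigError):
            task_vs_notask_activity(
                changes, [], [(0.0, 10.0, "a"), (5.0, 15.0, "b")]
            )


class TestPeriSession:
    def test_full_window_fractions(self):
        intervals = [CageInterval("m01", "nest", 0.0, 10_000.0)]
        sessions = [Session("m01", 1000.0, 2000.0)]
        out = peri_session_occupancy(intervals, sessions)
        before_nest = out[(out.phase == "before") & (out.cage == "nest")]
        assert before_nest.fraction.iloc[0] == pytest.approx(1.0)
        assert not before_nest.truncated.iloc[0]

    def test_fractions_sum_at_most_one(self, colony):
        intervals = infer_cage_intervals(colony.antenna, default_topology())
        out = peri_session_occupancy(intervals, colony.sessions)
        sums = out.groupby(["subject_id", "phase"]).fraction.sum()
        assert (sums <= 1.0 + 1e-9).all()

    def test_truncated_window_flagged(self):
        intervals = [CageInterval("m01", "nest", 0.0, 5000.0)]
        # Pre-entry window [ -200, 100 ) starts before the log: truncated.
        sessions = [Session("m01", 100.0, 600.0)]
        out = peri_session_occupancy(intervals, sessions)
        before = out[out.phase == "before"]
        assert before.truncated.all()


# ---------------------------------------------------------------------------
# Convenience metrics


def test_sessions_per_day(colony, colony_config):
    df = sessions_per_day(colony.sessions, colony_config.days)
    assert len(df) == colony_config.n_agents
    total = df.sessions_per_day.sum() * colony_config.days
    assert total == colony.manifest["realized"]["n_sessions"]


def test_night_day_attempt_ratio_on_colony(colony):
    """Night attempt pressure exceeds day pressure by construction."""
    assert night_day_attempt_ratio(colony.events) > 1.0


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=12))
def test_gini_always_in_unit_interval(xs):
    g = gini(xs).gini
    assert -1e-12 <= g <= 1.0
    assert g == pytest.approx(gini_mean_abs_difference(xs), abs=1e-9)
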