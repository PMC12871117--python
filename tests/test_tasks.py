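"""Trial engines: 3AFC scoring, 2AFC fixation contract, tone clouds, bandit.

Statistical checks (position uniformity, tone-cloud fraction, ITI truncation)
use fixed seeds and tolerances derived from the sampling distributions.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cagelab.records import ConfigError, ValidationError
from cagelab.tasks import (
    AUDITORY_EVIDENCE_2AFC,
    BANDIT_BLOCK_RANGE,
    BANDIT_ITI_MAX_S,
    BANDIT_P_EXTREME,
    BANDIT_P_HIGH,
    DELAYS_3AFC,
    FIXATION_REQUIRED_S,
    LUMINANCE_RATIOS_2AFC,
    REWARD_UL,
    BanditBlock,
    evaluate_response_3afc,
    generate_trial_3afc,
    next_block_2ab,
    octave_frequencies,
    plan_2afc,
    run_trial_2ab,
    run_trial_2afc,
    sample_forced_iti,
    sample_response_trace_2afc,
    sample_tone_cloud,
    target_fraction,
    TrialPlan3AFC,
)


# ---------------------------------------------------------------------------
# 3AFC


class Test3AFC:
    def test_correct_touch_rewarded_with_high_tone(self):
        plan = TrialPlan3AFC("C", "easy", 0.0)
        out = evaluate_response_3afc(plan, "C", rt=3.0)
        assert out.outcome == "correct"
        assert out.reward_ul == REWARD_UL["3afc"] == 10.0
        assert out.feedback == "tone_15khz"

    def test_incorrect_touch_unrewarded_with_low_tone_and_light(self):
        plan = TrialPlan3AFC("C", "easy", 0.0)
        out = evaluate_response_3afc(plan, "L", rt=3.0)
        assert out.outcome == "incorrect" and out.reward_ul == 0.0
        assert out.feedback == "tone_4khz_house_light"

    def test_no_touch_is_omission(self):
        plan = TrialPlan3AFC("C", "easy", 0.0)
        out = evaluate_response_3afc(plan, None)
        assert out.outcome == "omission" and out.choice is None
        assert out.feedback == "house_light"

    def test_late_touch_is_omission(self):
        plan = TrialPlan3AFC("C", "easy", 0.0, response_window=60.0)
        assert evaluate_response_3afc(plan, "C", rt=61.0).outcome == "omission"

    def test_unknown_position_rejected(self):
        plan = TrialPlan3AFC("C", "easy", 0.0)
        with pytest.raises(ValidationError):
            evaluate_response_3afc(plan, "X")

    def test_species_delay_ladders(self):
        assert DELAYS_3AFC["mouse"]["easy"] == 0.0
        assert DELAYS_3AFC["mouse"]["extreme"] == 3.3
        assert DELAYS_3AFC["rat"]["hard"] == 1.5

    def test_generate_uses_stage_delay(self):
        rng = np.random.default_rng(0)
        plan = generate_trial_3afc({"difficulty_mix": {"hard": 1.0}}, rng)
        assert plan.difficulty == "hard" and plan.delay_s == 2.3

    def test_generate_rejects_bad_mix(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ConfigError):
            generate_trial_3afc({"difficulty_mix": {"easy": 0.7}}, rng)
        with pytest.raises(ConfigError):
            generate_trial_3afc({"difficulty_mix": {"warp": 1.0}}, rng)

    def test_position_uniformity_chi_square(self):
        """3000 draws over L/C/R pass a chi-square uniformity test."""
        rng = np.random.default_rng(11)
        params = {"difficulty_mix": {"easy": 1.0}}
        counts = {"L": 0, "C": 0, "R": 0}
        n = 3000
        for _ in range(n):
            counts[generate_trial_3afc(params, rng).position] += 1
        _, p = stats.chisquare(list(counts.values()))
        assert p > 1e-4  # seeded; fails only on an implementation bug


# ---------------------------------------------------------------------------
# 2AFC


class Test2AFC:
    def test_canonical_levels(self):
        assert LUMINANCE_RATIOS_2AFC == {"easy": 5.0, "medium": 2.5, "hard": 1.25}
        assert AUDITORY_EVIDENCE_2AFC == {"easy": 0.98, "medium": 0.82, "hard": 0.66}

    def test_plan_validates_evidence_against_difficulty(self):
        from cagelab.tasks import TrialPlan2AFC

        with pytest.raises(ValidationError):
            TrialPlan2AFC("visual", "L", "easy", evidence=3.0)
        with pytest.raises(ValidationError):
            TrialPlan2AFC("auditory", "L", "hard", evidence=0.9)
        TrialPlan2AFC("visual", "L", "easy", evidence=5.0)

    def test_short_fixation_restarts_then_completes(self):
        plan = plan_2afc("visual", "L", "easy")
        trace = [
            (0.0, "C", "in"), (0.3, "C", "out"),      # 300 ms: restart
            (1.0, "C", "in"), (1.7, "C", "out"),      # 700 ms: valid
            (2.0, "L", "in"),
        ]
        res = run_trial_2afc(plan, trace)
        assert res.completed and res.n_restarts == 1
        assert res.fixation_s == pytest.approx(0.7)
        assert res.outcome == "correct" and res.reward_ul == 2.0

    def test_exact_threshold_fixation_completes(self):
        plan = plan_2afc("visual", "R", "medium")
        trace = [(0.0, "C", "in"), (0.5, "C", "out"), (1.0, "L", "in")]
        res = run_trial_2afc(plan, trace)
        assert res.completed and res.fixation_s == pytest.approx(0.5)
        assert res.outcome == "incorrect" and res.reward_ul == 0.0

    def test_trace_without_valid_fixation_incomplete(self):
        plan = plan_2afc("visual", "L", "easy")
        trace = [(0.0, "C", "in"), (0.2, "C", "out"), (1.0, "L", "in")]
        res = run_trial_2afc(plan, trace)
        assert not res.completed and res.choice is None

    def test_unordered_trace_rejected(self):
        plan = plan_2afc("visual", "L", "easy")
        with pytest.raises(ValidationError):
            run_trial_2afc(plan, [(1.0, "C", "in"), (0.5, "C", "out")])

    def test_completed_trials_never_fixate_below_threshold(self):
        """Contract: across many sampled traces, every completed trial holds
        fixation >= 500 ms."""
        rng = np.random.default_rng(21)
        plan = plan_2afc("visual", "L", "easy")
        fixations = []
        for _ in range(400):
            trace = sample_response_trace_2afc(plan, 0.8, rng, restart_prob=0.4)
            res = run_trial_2afc(plan, trace)
            if res.completed:
                fixations.append(res.fixation_s)
        assert fixations, "sampler produced no completed trials"
        assert min(fixations) >= FIXATION_REQUIRED_S

    def test_sampled_choice_accuracy_recovers_p_correct(self):
        rng = np.random.default_rng(5)
        plan = plan_2afc("visual", "L", "easy")
        outcomes = []
        for _ in range(2000):
            res = run_trial_2afc(plan, sample_response_trace_2afc(plan, 0.75, rng))
            outcomes.append(res.outcome == "correct")
        # Binomial sd at n=2000 is ~1 pp; allow 3 sd.
        assert np.mean(outcomes) == pytest.approx(0.75, abs=0.03)


# ---------------------------------------------------------------------------
# Tone clouds


class TestToneCloud:
    def test_tone_schedule_geometry(self):
        rng = np.random.default_rng(0)
        cloud = sample_tone_cloud(0.82, "low", duration=0.5, rng=rng)
        assert len(cloud.onsets_s) == 50  # 100 Hz for 0.5 s
        assert cloud.onsets_s[1] - cloud.onsets_s[0] == pytest.approx(0.01)
        assert cloud.tone_duration_s == 0.030

    def test_frequencies_drawn_from_octave_banks(self):
        rng = np.random.default_rng(0)
        cloud = sample_tone_cloud(0.5, "high", duration=1.0, rng=rng)
        banks = set(octave_frequencies("low")) | set(octave_frequencies("high"))
        assert set(cloud.frequencies_hz) <= banks

    def test_octave_bank_is_six_log_spaced(self):
        f = octave_frequencies("low")
        assert len(f) == 6
        assert f[0] == pytest.approx(5000.0) and f[-1] == pytest.approx(10000.0)
        ratios = f[1:] / f[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_target_fraction_matches_evidence(self):
        rng = np.random.default_rng(9)
        cloud = sample_tone_cloud(0.82, "low", duration=10.0, rng=rng)  # 1000 tones
        # Bernoulli sd at n=1000 is ~1.2 pp; allow 4 sd.
        assert target_fraction(cloud) == pytest.approx(0.82, abs=0.05)

    def test_extreme_evidence_levels(self):
        rng = np.random.default_rng(0)
        assert target_fraction(sample_tone_cloud(1.0, "low", 1.0, rng)) == 1.0
        assert target_fraction(sample_tone_cloud(0.0, "low", 1.0, rng)) == 0.0

    def test_evidence_bounds(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ConfigError):
            sample_tone_cloud(1.2, "low", 1.0, rng)
        with pytest.raises(ConfigError):
            sample_tone_cloud(0.5, "mid", 1.0, rng)


# ---------------------------------------------------------------------------
# Bandit


class TestBandit:
    def test_block_validation(self):
        with pytest.raises(ValidationError):
            BanditBlock("L", 0.9, 24)
        with pytest.raises(ValidationError):
            BanditBlock("L", 0.9, 56)
        with pytest.raises(ValidationError):
            BanditBlock("L", 0.4, 30)

    def test_block_probabilities_complementary(self):
        b = BanditBlock("L", 0.8, 30)
        assert b.p_reward("L") == 0.8 and b.p_reward("R") == pytest.approx(0.2)

    def test_reversal_flips_high_side(self):
        rng = np.random.default_rng(0)
        b1 = next_block_2ab(None, "easy", rng)
        b2 = next_block_2ab(b1, "easy", rng)
        assert b2.high_side != b1.high_side
        assert b1.p_high == BANDIT_P_HIGH["easy"]

    def test_extreme_difficulty_draws_from_pair(self):
        rng = np.random.default_rng(0)
        seen = {next_block_2ab(None, "extreme", rng).p_high for _ in range(200)}
        assert seen == set(BANDIT_P_EXTREME)

    def test_block_lengths_within_bounds_10000_blocks(self):
        rng = np.random.default_rng(17)
        lengths = [next_block_2ab(None, "medium", rng).length for _ in range(10_000)]
        lo, hi = BANDIT_BLOCK_RANGE
        assert min(lengths) >= lo and max(lengths) <= hi
        # Both endpoints should actually occur in 10k draws.
        assert lo in lengths and hi in lengths

    def test_correct_means_high_side_even_if_unrewarded(self):
        rng = np.random.default_rng(2)
        block = BanditBlock("L", 0.7, 30)
        results = [run_trial_2ab(block, "L", rng) for _ in range(300)]
        assert all(r.outcome == "correct" for r in results)
        assert any(not r.rewarded for r in results)  # p_high < 1
        rewarded = [r for r in results if r.rewarded]
        assert all(r.reward_ul == 3.0 for r in rewarded)

    def test_low_side_rewarded_sometimes_but_incorrect(self):
        rng = np.random.default_rng(3)
        block = BanditBlock("L", 0.7, 30)
        results = [run_trial_2ab(block, "R", rng) for _ in range(300)]
        assert all(r.outcome == "incorrect" for r in results)
        assert any(r.rewarded for r in results)  # p_low = 0.3

    def test_forced_iti_truncated_exponential(self):
        rng = np.random.default_rng(4)
        itis = np.array([sample_forced_iti(rng) for _ in range(5000)])
        assert itis.max() <= BANDIT_ITI_MAX_S
        assert itis.min() >= 0.0
        # Mean of Exp(5) truncated at 30 is 5 - 30/(e^6 - 1) ~ 4.926.
        expected = 5.0 - 30.0 / (np.exp(6.0) - 1.0)
        assert itis.mean() == pytest.approx(expected, abs=0.2)

    def test_invalid_choice_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError):
            run_trial_2ab(BanditBlock("L", 0.8, 30), "C", rng)


@settings(max_examples=50, deadline=None)
@given(seed=st.integers(0, 2**20), difficulty=st.sampled_from(["easy", "medium", "hard", "extreme"]))
def test_block_generation_always_valid(seed, difficulty):
    rng = np.random.default_rng(seed)
    prev = None
    for _ in range(5):
        b = next_block_2ab(prev, difficulty, rng)  # validates in __post_init__
        assert 0.5 <= b.p_high <= 1.0
        prev = b
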