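"""Unit and property tests for the adaptive task engine."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from birdwatch.engine import (BlockRecord, ConfigurationError,
                              DegenerateBlockError, EngineConfig, EngineState,
                              Trial, block_dprime, block_score,
                              classify_response, generate_block_trials,
                              play_block, update_difficulty)


def _record_for(state, config, passed, duration=120.0):
    """Minimal consistent block record for driving update_difficulty."""
    dp = 3.5 if passed else 0.0
    return BlockRecord(
        block_index=1, n=state.n_contexts,
        dprime_threshold=state.dprime_threshold(config), maxrt=state.maxrt,
        hit=40, cr=40, miss=0, fa=0, dprime=dp, score=0.0, passed=passed,
        duration_seconds=duration, cumulative_hours=0.0)


class TestTrialGeneration:
    def test_single_context_has_no_switches(self, config):
        state = EngineState(n_contexts=1)
        trials = generate_block_trials(state, config, np.random.default_rng(0))
        assert len(trials) == config.block_length
        assert all(t.context_id == 1 for t in trials)
        assert not any(t.is_switch for t in trials)

    def test_every_trial_has_defined_match_status(self, config):
        state = EngineState(n_contexts=4)
        trials = generate_block_trials(state, config, np.random.default_rng(1))
        # context preview seeding means even each context's first trial is scored
        assert all(isinstance(t.is_match, bool) for t in trials)
        assert {t.context_id for t in trials} <= {1, 2, 3, 4}

    def test_match_trials_repeat_last_stimulus_in_context(self, config):
        state = EngineState(n_contexts=3)
        trials = generate_block_trials(state, config, np.random.default_rng(5))
        last = {}
        for t in trials:
            if t.context_id in last:
                assert t.is_match == (t.stimulus_id == last[t.context_id])
            last[t.context_id] = t.stimulus_id

    def test_deterministic_under_fixed_seed(self, config):
        state = EngineState(n_contexts=4)
        a = generate_block_trials(state, config, np.random.default_rng(42))
        b = generate_block_trials(state, config, np.random.default_rng(42))
        assert a == b

    def test_match_count_matches_binomial_mean(self, config):
        # mean per-block match count within 3 SE of block_length * match_rate
        state = EngineState(n_contexts=6)
        rng = np.random.default_rng(7)
        n_blocks = 2000
        counts = [sum(t.is_match for t in
                      generate_block_trials(state, config, rng))
                  for _ in range(n_blocks)]
        expected = config.block_length * config.match_rate
        se = np.sqrt(config.block_length * 0.25 / n_blocks)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_invalid_context_count_rejected(self, config):
        with pytest.raises(ConfigurationError):
            generate_block_trials(EngineState(n_contexts=7), config,
                                  np.random.default_rng(0))


class TestClassifyResponse:
    @pytest.mark.parametrize("is_match,response,category", [
        (True, "match", "hit"),
        (True, "nonmatch", "miss"),
        (False, "nonmatch", "correct_rejection"),
        (False, "match", "false_alarm"),
    ])
    def test_signal_detection_mapping(self, is_match, response, category):
        trial = Trial(1, 1, 0, is_match, False, not is_match)
        assert classify_response(trial, response, 1.2, 5.0).category == category

    @pytest.mark.parametrize("is_match", [True, False])
    def test_timeout_is_always_a_miss(self, is_match):
        trial = Trial(1, 1, 0, is_match, False, not is_match)
        result = classify_response(trial, "timeout", None, 5.0)
        assert result.category == "miss"
        assert result.rt is None

    def test_rt_beyond_window_is_contract_violation(self):
        trial = Trial(1, 1, 0, True, False, False)
        with pytest.raises(ValueError):
            classify_response(trial, "match", 5.3, 5.0)


class TestDprime:
    def test_equal_rates_give_zero(self):
        assert block_dprime(20, 20, 20, 20) == pytest.approx(0.0, abs=1e-12)

    def test_moderate_counts_match_inverse_normal_oracle(self):
        # Phi^-1(0.875) - Phi^-1(0.125)
        assert block_dprime(35, 5, 5, 35) == pytest.approx(2.3006987607520157,
                                                           abs=1e-9)

    def test_perfect_block_gets_half_count_correction(self):
        # rates 0 and 1 replaced by 1/(2*40) and 1 - 1/(2*40)
        assert block_dprime(40, 0, 0, 40) == pytest.approx(4.482805455209892,
                                                           abs=1e-9)

    def test_degenerate_class_raises(self):
        with pytest.raises(DegenerateBlockError):
            block_dprime(0, 0, 20, 20)

    @given(h=st.integers(0, 80), m=st.integers(0, 80),
           f=st.integers(0, 80), c=st.integers(0, 80))
    def test_antisymmetry(self, h, m, f, c):
        if h + m == 0 or f + c == 0:
            return
        assert block_dprime(h, m, f, c) == pytest.approx(
            -block_dprime(f, c, h, m), abs=1e-12)


class TestScore:
    def test_pure_penalty(self):
        assert block_score(0, 0, 40, 40, 0.0, 7.0) == -4000.0

    def test_zero_dprime_case(self):
        assert block_score(20, 20, 20, 20, 0.0, 5.0) == 2000.0

    def test_perfect_block(self):
        dp = block_dprime(40, 0, 0, 40)
        assert block_score(40, 40, 0, 0, dp, 5.0) == pytest.approx(
            8000.0 + 1000.0 * dp * 2.0)


class TestDifficultyProgression:
    def test_pass_at_six_contexts_raises_threshold_and_unlocks(self, config):
        state = EngineState(n_contexts=6, threshold_epoch=0, maxrt=5.0)
        new, events = update_difficulty(state, _record_for(state, config, True),
                                        config)
        assert (new.n_contexts, new.threshold_epoch) == (1, 1)
        assert new.dprime_threshold(config) == pytest.approx(0.8)
        assert "unlock" in events

    def test_three_consecutive_failures_relax_maxrt(self, config):
        state = EngineState(n_contexts=3, consecutive_failures=2, maxrt=5.0)
        new, events = update_difficulty(state, _record_for(state, config, False),
                                        config)
        assert new.maxrt == pytest.approx(5.5)
        assert new.consecutive_failures == 0
        assert "maxrt_relief" in events

    def test_pass_resets_failure_counter(self, config):
        state = EngineState(n_contexts=2, consecutive_failures=2)
        new, _ = update_difficulty(state, _record_for(state, config, True),
                                   config)
        assert new.consecutive_failures == 0

    def test_milestone_decrement_applies_before_relief_increment(self, config):
        # one 10% milestone (2 h) crossed on the same block as a 3rd failure:
        # decrement then increment leaves MaxRT unchanged at the start value
        state = EngineState(n_contexts=1, consecutive_failures=2, maxrt=5.0,
                            elapsed_seconds=7100.0)
        rec = _record_for(state, config, False, duration=200.0)
        new, events = update_difficulty(state, rec, config)
        assert events.index("maxrt_decrement") < events.index("maxrt_relief")
        assert new.maxrt == pytest.approx(5.0)

    def test_terminal_pass_caps_threshold_and_freezes(self, config):
        state = EngineState(n_contexts=6, threshold_epoch=11)
        new, events = update_difficulty(state, _record_for(state, config, True),
                                        config)
        assert new.terminal
        assert new.dprime_threshold(config) == pytest.approx(3.0)
        assert "terminal" in events
        after, _ = update_difficulty(new, _record_for(new, config, True), config)
        assert (after.n_contexts, after.threshold_epoch) == (6, 12)

    def test_always_passing_agent_visits_72_states_in_lex_order(self, config):
        cfg = EngineConfig(expected_total_hours=1e9)  # no milestones
        state = EngineState(maxrt=cfg.maxrt_start)
        visited = []
        while not state.terminal:
            visited.append((state.threshold_epoch, state.n_contexts))
            state, _ = update_difficulty(state, _record_for(state, cfg, True),
                                         cfg)
        assert visited == [(e, n) for e in range(12) for n in range(1, 7)]
        assert len(set(visited)) == 72

    def test_mismatched_record_rejected(self, config):
        state = EngineState(n_contexts=2)
        rec = _record_for(EngineState(n_contexts=5), config, True)
        with pytest.raises(ValueError):
            update_difficulty(state, rec, config)


@given(passes=st.lists(st.booleans(), min_size=1, max_size=400),
       duration=st.floats(30.0, 400.0))
def test_maxrt_bounded_and_stepped_for_any_outcome_stream(passes, duration):
    """MaxRT stays in [1, 6] and moves only in 0.5 steps for any agent."""
    config = EngineConfig()
    state = EngineState(maxrt=config.maxrt_start)
    for passed in passes:
        prev = state.maxrt
        state, _ = update_difficulty(
            state, _record_for(state, config, passed, duration), config)
        assert config.maxrt_min - 1e-9 <= state.maxrt <= config.maxrt_max + 1e-9
        assert abs((state.maxrt - prev) / config.maxrt_step
                   - round((state.maxrt - prev) / config.maxrt_step)) < 1e-9


def test_count_conservation_and_block_determinism(config):
    """hit+cr+miss+fa equals the block length; same seed -> same record."""
    rng = np.random.default_rng(3)

    def noisy(trial, state):
        r = rng.random()
        if r < 0.05:
            return "timeout", None
        return ("match" if r < 0.5 else "nonmatch"), 1.0

    state = EngineState(n_contexts=3)
    for _ in range(200):
        rec = play_block(state, config, noisy, rng)
        assert rec.hit + rec.cr + rec.miss + rec.fa == config.block_length

    def fixed(trial, state):
        return ("match" if trial.is_match else "nonmatch"), 1.0

    a = play_block(state, config, fixed, np.random.default_rng(11))
    b = play_block(state, config, fixed, np.random.default_rng(11))
    assert a == b


def test_config_validation():
    with pytest.raises(ConfigurationError):
        EngineConfig(match_rate=0.0)
    with pytest.raises(ConfigurationError):
        EngineConfig(maxrt_start=0.5)
    with pytest.raises(ConfigurationError):
        EngineConfig(dprime_start=3.5)
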