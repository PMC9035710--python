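"""Task-engine behaviour: block balance, run-length constraint, learning
criterion, stability-phase reversal rule, points accounting, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import revlearn as rl
from revlearn.task import (CORRECT, INCORRECT, AlwaysCorrectAgent,
                           AlwaysMissAgent, FixedChoiceAgent, ScriptedAgent,
                           TaskConfigError, TaskState, build_outcome_block,
                           _max_run)


def _wins(block):
    return sum(block)


class TestOutcomeBlocks:
    @pytest.mark.parametrize(
        "role,expected_wins", [(CORRECT, 16), (INCORRECT, 4)]
    )
    def test_block_balance(self, role, expected_wins, task_config, rng):
        for _ in range(20):
            block = build_outcome_block(role, task_config, rng)
            assert len(block) == task_config.block_len
            assert _wins(block) == expected_wins

    def test_run_length_within_and_across_blocks(self, task_config, rng):
        tail = []
        stream = []
        for _ in range(30):
            block = build_outcome_block(CORRECT, task_config, rng, prev_tail=tail)
            stream += block
            tail = stream[-task_config.max_run:]
        assert _max_run(stream) <= task_config.max_run

    def test_unsatisfiable_split_is_config_error(self):
        # 16 wins cannot be packed into runs of <= 3 with only 4 losses
        with pytest.raises(TaskConfigError):
            rl.TaskConfig(max_run=3)

    def test_non_integer_block_split_rejected(self):
        with pytest.raises(TaskConfigError):
            rl.TaskConfig(p_win_correct=0.75, block_len=10)


class TestCriterion:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ([True] * 5 + [False], True),  # 5 of the previous 6
            ([True, False, True, False, True, True], False),  # only 4 of 6
            ([True] * 5, True),  # evaluable from trial 5
            ([True] * 4, False),  # too early
            ([False] + [True] * 5, True),
            ([False, False, True, True, True, True, True], True),  # window slides
        ],
    )
    def test_examples(self, flags, expected, task_config):
        assert rl.check_criterion(flags, task_config) is expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), max_size=30))
    def test_matches_bruteforce_rule(self, flags):
        config = rl.TaskConfig()
        t = len(flags)
        expected = (
            t >= config.criterion_hits
            and sum(flags[-min(config.criterion_window, t):]) >= config.criterion_hits
        )
        assert rl.check_criterion(flags, config) == expected


class TestReversalProbability:
    @pytest.mark.parametrize("k,expected", [(0, 0.0), (3, 0.3), (10, 1.0), (12, 1.0)])
    def test_examples(self, k, expected, task_config):
        assert rl.reversal_probability(k, task_config) == pytest.approx(expected)

    def test_reversal_always_fires_at_saturated_k(self, task_config, rng):
        # brute force: sampled reversal must fire whenever k >= divisor
        for _ in range(100):
            assert rng.random() < rl.reversal_probability(12, task_config)


class TestStep:
    def test_miss_trial(self, task_config, rng):
        state = TaskState.new(task_config, rng)
        rec = rl.step(state, rl.MISS, task_config, rng)
        assert rec.outcome == "NONE"
        assert rec.points_delta == 0
        assert rec.cumulative_points == 0
        assert not rec.criterion_met

    def test_win_pays_win_points(self, task_config, rng):
        state = TaskState.new(task_config, rng)
        rec = None
        # choose the correct image until the queue delivers a win
        while rec is None or rec.outcome != "WIN":
            rec = rl.step(state, state.correct_image, task_config, rng)
        assert rec.points_delta == task_config.win_points

    def test_invalid_choice(self, task_config, rng):
        state = TaskState.new(task_config, rng)
        with pytest.raises(ValueError):
            rl.step(state, "C", task_config, rng)

    def test_determinism_same_seed(self, task_config, group_mean_params):
        runs = [
            rl.run_session(
                rl.RLAgent(group_mean_params),
                task_config,
                np.random.default_rng(99),
            )
            for _ in range(2)
        ]
        assert runs[0].trials == runs[1].trials


class TestSessionInvariants:
    def test_points_conservation(self, sim_session):
        cfg = sim_session.config
        wins = sum(1 for t in sim_session.trials if t.outcome == "WIN")
        losses = sum(1 for t in sim_session.trials if t.outcome == "LOSS")
        assert sim_session.trials[-1].cumulative_points == (
            cfg.win_points * wins + cfg.loss_points * losses
        )

    def test_reversals_only_under_criterion_and_images_swap(self, sim_session):
        trials = sim_session.trials
        for i, t in enumerate(trials):
            if t.reversed_after:
                assert t.criterion_met
                assert trials[i + 1].correct_image != t.correct_image
                assert trials[i + 1].learning_event == t.learning_event + 1

    def test_session_length(self, sim_session):
        assert len(sim_session) == sim_session.config.n_trials

    def test_realised_outcome_stream_balance_per_role(self, sim_session):
        """Completed 20-selection blocks of each role have the exact nominal
        win counts, and no role stream has a run longer than max_run."""
        cfg = sim_session.config
        streams = {CORRECT: [], INCORRECT: []}
        for t in sim_session.trials:
            if t.choice is None:
                continue
            role = CORRECT if t.choice == t.correct_image else INCORRECT
            streams[role].append(t.outcome == "WIN")
        for role, stream in streams.items():
            assert _max_run(stream) <= cfg.max_run
            p = cfg.p_win_correct if role == CORRECT else 1 - cfg.p_win_correct
            n_blocks = len(stream) // cfg.block_len
            for b in range(n_blocks):
                block = stream[b * cfg.block_len:(b + 1) * cfg.block_len]
                assert sum(block) == round(p * cfg.block_len)


class TestRunSession:
    def test_always_correct_reaches_criterion_at_trial_5(self, task_config, rng):
        session = rl.run_session(AlwaysCorrectAgent(), task_config, rng)
        first = next(t.trial_index for t in session.trials if t.criterion_met)
        assert first == 5

    def test_always_miss_scores_zero(self, task_config, rng):
        session = rl.run_session(AlwaysMissAgent(), task_config, rng)
        assert session.trials[-1].cumulative_points == 0
        assert all(t.outcome == "NONE" for t in session.trials)

    def test_fixed_choice_never_reverses(self, task_config, rng):
        # a subject stuck on one image reaches criterion only while that
        # image is correct; check the session is well formed regardless
        session = rl.run_session(FixedChoiceAgent("A"), task_config, rng)
        assert len(session) == task_config.n_trials

    def test_group_mean_agent_reverses(self, task_config, group_mean_params):
        """A group-mean dual-rate agent experiences at least one reversal in
        360 trials (smoke property over seeds)."""
        for seed in range(25):
            session = rl.run_session(
                rl.RLAgent(group_mean_params),
                task_config,
                np.random.default_rng(seed),
            )
            assert sum(t.reversed_after for t in session.trials) >= 1

    def test_scripted_misses_consume_no_outcome(self, task_config, rng):
        script = ["A", rl.MISS, "A", rl.MISS] * 90
        session = rl.run_session(ScriptedAgent(script), task_config, rng)
        n_outcomes = sum(1 for t in session.trials if t.outcome != "NONE")
        assert n_outcomes == 180
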