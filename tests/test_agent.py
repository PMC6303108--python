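"""TD updates, softmax choice, replay tagging/sampling, and MLE fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from replayplan.agent import (AgentParams, ContractError, EstimationError,
                              QTable, ReplayBuffer, TDAgent, fit_learning_rate,
                              offline_replay, softmax_choose,
                              softmax_probabilities, tag_experience, td_update)
from replayplan.task import STAGE1, make_block_config, run_block

PARAMS = AgentParams(alpha=0.7, lapse=0.0)


class TestTdUpdate:
    def test_single_terminal_update_from_zero(self):
        q = QTable()
        delta = td_update(q, "S2", "top", 10.0, None, None, PARAMS)
        assert delta == 10.0 and q[("S2", "top")] == 7.0

    def test_second_identical_update_follows_the_closed_form(self):
        q = QTable()
        td_update(q, "S2", "top", 10.0, None, None, PARAMS)
        delta = td_update(q, "S2", "top", 10.0, None, None, PARAMS)
        assert delta == pytest.approx(3.0)
        assert q[("S2", "top")] == pytest.approx(10.0 * (1 - 0.3 ** 2))  # 9.1

    def test_root_error_bootstraps_from_the_successor_value(self):
        q = QTable({("S2", "top"): 9.1})
        delta = td_update(q, STAGE1, "left", 0.0, "S2", "top", PARAMS)
        assert delta == pytest.approx(9.1)

    def test_nonterminal_successor_without_action_is_a_contract_error(self):
        with pytest.raises(ContractError):
            td_update(QTable(), STAGE1, "left", 0.0, "S2", None, PARAMS)

    @given(st.floats(0.05, 1.0), st.floats(1.0, 50.0), st.integers(1, 20))
    def test_repeated_terminal_updates_converge_by_the_closed_form(self, alpha, r, k):
        q = QTable()
        params = AgentParams(alpha=alpha, lapse=0.0)
        for _ in range(k):
            td_update(q, "S3", "bottom", r, None, None, params)
        assert q[("S3", "bottom")] == pytest.approx(
            r * (1 - (1 - alpha) ** k), abs=1e-9)

    def test_no_other_entry_is_modified(self):
        q = QTable()
        td_update(q, "S2", "top", 10.0, None, None, PARAMS)
        untouched = {k: v for k, v in q.as_dict().items() if k != ("S2", "top")}
        assert all(v == 0.0 for v in untouched.values())


class TestSoftmaxChoose:
    def test_equal_values_give_symmetric_choice(self, rng):
        q = QTable()
        picks = [softmax_choose(q, STAGE1, 3.0, rng) for _ in range(10_000)]
        p_left = picks.count("left") / len(picks)
        assert abs(p_left - 0.5) < 3 * 0.005

    def test_beta_zero_is_uniform_whatever_the_values(self, rng):
        q = QTable({("S2", "top"): 100.0})
        picks = [softmax_choose(q, "S2", 0.0, rng) for _ in range(10_000)]
        assert abs(picks.count("top") / len(picks) - 0.5) < 3 * 0.005

    def test_probability_follows_the_logistic_form(self, rng):
        q = QTable({(STAGE1, "left"): 10.0, (STAGE1, "right"): 0.0})
        expected = 1.0 / (1.0 + math.exp(-10.0))
        p = softmax_probabilities(q.values_at(STAGE1), beta=1.0)
        assert p[0] == pytest.approx(expected, abs=1e-12)
        picks = [softmax_choose(q, STAGE1, 1.0, rng) for _ in range(10_000)]
        assert abs(picks.count("left") / len(picks) - expected) < 0.01

    def test_lapse_mixes_toward_uniform(self):
        q = QTable({(STAGE1, "left"): 100.0})
        p = softmax_probabilities(q.values_at(STAGE1), beta=3.0, lapse=0.1)
        assert p[1] == pytest.approx(0.05, abs=1e-9)


class TestTagging:
    def test_priority_is_unsigned(self):
        buf = ReplayBuffer()
        tag_experience(buf, ("S2", "top", 12.0, None), delta=-4.0)
        assert buf.get("S2", "top").priority == 4.0

    def test_retagging_replaces_the_priority(self):
        buf = ReplayBuffer()
        tag_experience(buf, ("S2", "top", 12.0, None), delta=-4.0)
        tag_experience(buf, ("S2", "top", 11.0, None), delta=1.0)
        assert len(buf) == 1 and buf.get("S2", "top").priority == 1.0

    def test_tagging_raises_buffered_predecessor_priorities(self):
        buf = ReplayBuffer()
        tag_experience(buf, (STAGE1, "left", None, "S2"), delta=0.0)
        tag_experience(buf, ("S2", "top", 20.0, None), delta=-25.0)
        assert buf.get(STAGE1, "left").priority == 25.0

    def test_converged_noiseless_learning_leaves_negligible_priorities(self):
        # oracle: converged values make every online TD error vanish
        cfg = make_block_config("control", "noiseless", "face", seed=1,
                                n_learning_trials=400)
        agent = TDAgent(AgentParams(lapse=0.2, replay_mode="none"))
        run_block(cfg, agent, np.random.default_rng(1))
        assert max(it.priority for it in agent.buffer.items()) < 1e-6


class TestOfflineReplay:
    def test_mode_none_is_a_no_op(self, rng):
        q = QTable({("S2", "top"): 5.0})
        buf = ReplayBuffer()
        tag_experience(buf, ("S2", "top", 9.0, None), delta=4.0)
        q2, log = offline_replay(q, buf, AgentParams(replay_mode="none"), rng)
        assert q2.as_dict() == q.as_dict() and log == []

    def test_zero_priority_items_are_never_sampled_against_positive_ones(self, rng):
        buf = ReplayBuffer()
        tag_experience(buf, ("S2", "top", 9.0, None), delta=5.0, propagate=False)
        tag_experience(buf, ("S3", "top", 9.0, None), delta=0.0, propagate=False)
        params = AgentParams(replay_budget_k=100, background_replay_mass=0.0)
        _, log = offline_replay(QTable(), buf, params, rng)
        replayed = {(ev.s, ev.a) for ev in log if ev.s != "off-task"}
        assert ("S3", "top") not in replayed and len(log) > 0

    def test_empty_buffer_returns_unchanged_values_and_empty_log(self, rng):
        q = QTable({("S2", "top"): 3.0})
        q2, log = offline_replay(q, ReplayBuffer(),
                                 AgentParams(replay_budget_k=5), rng)
        assert q2.as_dict() == q.as_dict() and log == []

    def test_replaying_root_transitions_flips_the_root_policy(self, rng):
        # hand-run oracle: after relearning swaps the stage-II values,
        # replaying S1->S2 and S1->S3 propagates them to the root
        q = QTable({(STAGE1, "left"): 45.0, (STAGE1, "right"): 20.0,
                    ("S2", "top"): 20.0, ("S2", "bottom"): 5.0,
                    ("S3", "top"): 45.0, ("S3", "bottom"): 5.0})
        buf = ReplayBuffer()
        tag_experience(buf, (STAGE1, "left", None, "S2"), delta=25.0)
        tag_experience(buf, (STAGE1, "right", None, "S3"), delta=25.0)
        params = AgentParams(replay_budget_k=20, background_replay_mass=0.0)
        q, _ = offline_replay(q, buf, params, rng)
        assert q[(STAGE1, "right")] > q[(STAGE1, "left")]
        # fixed point of the replay update is the greedy successor value
        assert q[(STAGE1, "right")] == pytest.approx(45.0, abs=1.0)

    def test_background_mass_absorbs_draws_when_nothing_is_surprising(self, rng):
        buf = ReplayBuffer()
        tag_experience(buf, ("S2", "top", 9.0, None), delta=0.0)
        params = AgentParams(replay_budget_k=10, background_replay_mass=25.0)
        q, log = offline_replay(QTable(), buf, params, rng)
        assert all(ev.s == "off-task" for ev in log)


class TestFitLearningRate:
    @staticmethod
    def _simulate(alpha, n_blocks=12, seed=0):
        logs = []
        for i in range(n_blocks):
            cfg = make_block_config("revaluation" if i % 2 else "control",
                                    "noisy" if i % 4 > 1 else "noiseless",
                                    "face", seed=seed + i)
            agent = TDAgent(AgentParams(alpha=alpha, replay_mode="none"))
            logs.append(run_block(cfg, agent, np.random.default_rng(seed + 90 + i)))
        return logs

    def test_recovers_a_planted_learning_rate(self):
        logs = self._simulate(0.6)
        fit = fit_learning_rate(logs, beta=3.0, lapse=0.05)
        assert abs(fit.alpha - 0.6) <= 0.1 and fit.identifiable

    def test_random_choices_are_flagged_non_identifiable(self):
        # beta = 0 makes the likelihood independent of the value trajectory
        logs = []
        for i in range(4):
            cfg = make_block_config("control", "noiseless", "face", seed=i)
            agent = TDAgent(AgentParams(beta=0.0, replay_mode="none"))
            logs.append(run_block(cfg, agent, np.random.default_rng(i)))
        fit = fit_learning_rate(logs, beta=0.0)
        assert not fit.identifiable
        assert fit.alpha == fit.grid[0]  # tie-break toward the grid minimum
        assert fit.grid_log_likelihood.max() - fit.grid_log_likelihood.min() < 1e-9

    def test_accepts_dataframe_logs(self):
        logs = self._simulate(0.7, n_blocks=6)
        frames = [log.to_frame() for log in logs]
        fit_df = fit_learning_rate(frames, beta=3.0, lapse=0.05)
        fit_obj = fit_learning_rate(logs, beta=3.0, lapse=0.05)
        assert fit_df.alpha == fit_obj.alpha

    def test_forced_only_logs_raise(self):
        logs = self._simulate(0.7, n_blocks=1)
        frame = logs[0].to_frame()
        frame["forced"] = True
        with pytest.raises(EstimationError):
            fit_learning_rate([frame], beta=3.0)
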