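"""Reward function, policy biases, Q-learning plumbing and action selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncolattice.config import LearningParams, PolicyRule, default_config
from oncolattice.decision import (Experience, ExperienceWindow, TabularQ,
                                  _batch_bias, _batch_reward,
                                  admit_experience, policy_bias, q_update,
                                  reward_fn, select_action_test,
                                  select_action_train, total_reward,
                                  train_loop)


def rule(variable="x", threshold=0.0, gradient=1.0, direction=1,
         cell_types=("cancerous",), **kw):
    return PolicyRule(99, variable, threshold, gradient, direction,
                      cell_types, **kw)


class TestRewardFn:
    def test_zero_exactly_at_threshold(self):
        for grad in (0.5, 2.0, 10.0):
            assert reward_fn(5.0, rule(threshold=5.0, gradient=grad)) == 0.0

    def test_tanh_arithmetic(self):
        r = rule(threshold=5.0, gradient=2.0)
        assert reward_fn(7.0, r) == pytest.approx(math.tanh(1.0))
        assert reward_fn(7.0, r) == pytest.approx(0.76159, abs=1e-5)

    def test_direction_flips_sign(self):
        r_up = rule(threshold=1.0, direction=1)
        r_dn = rule(threshold=1.0, direction=-1)
        assert reward_fn(2.0, r_up) == -reward_fn(2.0, r_dn) > 0

    @given(x=st.floats(-1e6, 1e6), thr=st.floats(-100, 100),
           grad=st.floats(0.01, 100))
    @settings(max_examples=300, deadline=None)
    def test_bounded_and_sign_changes_at_threshold(self, x, thr, grad):
        r = rule(threshold=thr, gradient=grad)
        val = reward_fn(x, r)
        assert abs(val) <= 1.0
        if abs(x - thr) / grad < 18:  # inside float-representable tanh range
            assert abs(val) < 1.0
        if x > thr:
            assert val > 0.0
        elif x < thr:
            assert val < 0.0


class TestTotalReward:
    def test_all_at_thresholds_gives_zero(self):
        rules = [rule("a", 1.0), rule("b", 2.0)]
        assert total_reward({"a": 1.0, "b": 2.0}, rules, "cancerous") == 0.0

    def test_antisymmetric_pair_cancels(self):
        rules = [rule("a", 0.0, direction=1), rule("a", 0.0, direction=-1)]
        assert total_reward({"a": 0.7}, rules, "cancerous") == \
            pytest.approx(0.0, abs=1e-12)

    def test_mean_arithmetic(self):
        # choose states so the three terms are exactly 0.5, 0.1, -0.3
        rules = [rule("a"), rule("b"), rule("c")]
        state = {"a": math.atanh(0.5), "b": math.atanh(0.1),
                 "c": math.atanh(-0.3)}
        assert total_reward(state, rules, "cancerous") == pytest.approx(0.1)

    def test_only_applicable_rules_enter(self):
        rules = [rule("a", cell_types=("cancerous",)),
                 rule("b", cell_types=("healthy",))]
        val = total_reward({"a": 2.0, "b": 2.0}, rules, "cancerous")
        assert val == pytest.approx(math.tanh(2.0))


class TestPolicyBias:
    def setup_method(self):
        self.cfg = default_config()

    def _tissue_state(self, **over):
        base = {"oxygen": 0.5, "glucose": 0.5, "division_counter": 0.0,
                "prolif_delay": 0.0, "hypoxia_counter": 0.0, "plcg": 0.0,
                "plcg_excess": 0.0, "n_healthy_nb": 5.0,
                "n_cancerous_nb": 5.0, "n_neighbors": 10.0,
                "tnf_alpha": 0.0, "is_cancerous": 1.0}
        base.update(over)
        return base

    def test_migration_impossible_with_two_or_fewer_neighbors(self):
        st_few = self._tissue_state(n_neighbors=2.0)
        w = policy_bias(st_few, self.cfg.policies, "cancerous")
        assert w["migration"] == 0.0
        st_many = self._tissue_state(n_neighbors=3.0)
        w2 = policy_bias(st_many, self.cfg.policies, "cancerous")
        assert w2["migration"] > 0.0

    def test_intermediate_glucose_favors_quiescence_for_healthy(self):
        # the glucose policy alone: between the dead and active thresholds a
        # healthy cell leans toward quiescence
        a = self.cfg.agents
        glucose_rules = [r for r in self.cfg.policies if r.rule_id == 2]
        mid = (a.glucose_dead + a.glucose_active) / 2
        st_mid = self._tissue_state(glucose=mid, is_cancerous=0.0)
        w = policy_bias(st_mid, glucose_rules, "healthy")
        assert w["quiescence"] == max(w.values())

    def test_tip_maturity_gates_branching(self):
        psi = self.cfg.agents.tip_maturity_psi
        vegf_ok = self.cfg.agents.vegf_sprout_threshold * 3
        young = {"vegf": vegf_ok, "tip_age": 0.0, "is_tip": 1.0}
        old = {"vegf": vegf_ok, "tip_age": psi * 2, "is_tip": 1.0}
        wy = policy_bias(young, self.cfg.policies, "tip")
        wo = policy_bias(old, self.cfg.policies, "tip")
        assert wy["branch"] < wy["expansion"]
        assert wo["branch"] > wo["expansion"]

    def test_vegf_hard_gate_silences_vessel_growth(self):
        quiet = {"vegf": 0.0, "tip_age": 50.0, "is_tip": 0.0}
        w = policy_bias(quiet, self.cfg.policies, "stalk")
        assert w["sprout"] == 0.0 and w["branch"] == 0.0
        assert w["quiescence"] > 0.0

    def test_batch_bias_matches_scalar(self):
        rng = np.random.default_rng(3)
        states = [self._tissue_state(
            oxygen=rng.random(), glucose=rng.random(),
            n_neighbors=float(rng.integers(0, 20)),
            hypoxia_counter=float(rng.integers(0, 80)),
            tnf_alpha=rng.random(), is_cancerous=float(rng.integers(0, 2)))
            for _ in range(40)]
        for s in states:
            s["n_healthy_nb"] = s["n_neighbors"]
            s["n_cancerous_nb"] = 0.0
        ctypes = np.array(["cancerous" if s["is_cancerous"] else "healthy"
                           for s in states])
        varr = {k: np.array([s[k] for s in states]) for k in states[0]}
        W = _batch_bias(varr, ctypes, self.cfg.policies, "tissue",
                        self.cfg.agents.bias_strength)
        from oncolattice.decision import TISSUE_ACTIONS
        for i, s in enumerate(states):
            ref = policy_bias(s, self.cfg.policies, ctypes[i],
                              self.cfg.agents.bias_strength)
            for j, a in enumerate(TISSUE_ACTIONS):
                if a in ref:
                    assert W[i, j] == pytest.approx(ref[a], rel=1e-9), (i, a)
                else:
                    assert W[i, j] == 0.0

    def test_batch_reward_matches_scalar(self):
        rng = np.random.default_rng(4)
        states = [self._tissue_state(oxygen=rng.random(),
                                     glucose=rng.random(),
                                     tnf_alpha=rng.random())
                  for _ in range(25)]
        ctypes = np.array(["cancerous"] * 25)
        varr = {k: np.array([s[k] for s in states]) for k in states[0]}
        r = _batch_reward(varr, ctypes, self.cfg.policies)
        for i, s in enumerate(states):
            assert r[i] == pytest.approx(
                total_reward(s, self.cfg.policies, "cancerous"), rel=1e-9)


class TestQUpdate:
    def test_zero_learning_rate_is_identity(self):
        assert q_update(0.37, 5.0, 9.0, 0.0, 0.9) == 0.37

    def test_full_replacement_with_no_discount(self):
        assert q_update(0.37, 0.8, 9.0, 1.0, 0.0) == 0.8

    def test_direct_substitution(self):
        assert q_update(0.5, 1.0, 0.8, 0.1, 0.9) == pytest.approx(0.622)


class TestActionSelection:
    def test_equal_q_samples_uniformly(self, rng):
        counts = {"a": 0, "b": 0, "c": 0}
        for _ in range(10_000):
            counts[select_action_train({"a": 1., "b": 1., "c": 1.}, rng)] += 1
        for v in counts.values():
            assert abs(v / 10_000 - 1 / 3) < 4 * math.sqrt((1 / 3) * (2 / 3) / 1e4)

    def test_nonnegative_q_is_plain_proportional(self, rng):
        # Q = {3, 1} -> selection probabilities 0.75 / 0.25
        wins = sum(select_action_train({"hi": 3.0, "lo": 1.0}, rng) == "hi"
                   for _ in range(10_000))
        assert abs(wins / 10_000 - 0.75) < 4 * math.sqrt(0.75 * 0.25 / 1e4)

    def test_negative_q_yields_valid_distribution(self, rng):
        # after the shift-plus-floor, weights are {0.05, 0.85}
        seen = {select_action_train({"a": -0.9, "b": -0.1}, rng)
                for _ in range(500)}
        assert seen == {"a", "b"}  # both stay reachable

    def test_single_action_always_chosen(self, rng):
        assert select_action_train({"only": -0.4}, rng) == "only"

    def test_greedy_picks_argmax(self, rng):
        assert select_action_test({"a": 0.2, "b": 0.9, "c": 0.1}, rng) == "b"

    def test_greedy_is_shift_invariant(self, rng):
        q = {"a": 0.2, "b": 0.9, "c": 0.1}
        shifted = {k: v + 13.5 for k, v in q.items()}
        assert select_action_test(q, rng) == select_action_test(shifted, rng)

    def test_tie_break_reproducible_per_seed(self):
        q = {"a": 0.5, "b": 0.5}
        picks1 = [select_action_test(q, np.random.default_rng(k))
                  for k in range(50)]
        picks2 = [select_action_test(q, np.random.default_rng(k))
                  for k in range(50)]
        assert picks1 == picks2
        assert set(picks1) == {"a", "b"}


class TestExperienceWindow:
    def _exp(self, r, step=0):
        return Experience(np.zeros(3), "quiescence", 0.5, r, step)

    def test_reward_at_threshold_not_admitted(self):
        w = ExperienceWindow(5)
        admit_experience(self._exp(0.3), 0.3, w)
        assert len(w) == 0

    def test_reward_above_threshold_admitted(self):
        w = ExperienceWindow(5)
        admit_experience(self._exp(0.3 + 1e-9), 0.3, w)
        assert len(w) == 1

    def test_fifo_eviction_at_capacity(self):
        w = ExperienceWindow(3)
        for i in range(4):
            admit_experience(self._exp(1.0, step=i), 0.0, w)
        assert len(w) == 3
        assert [e.step for e in w] == [1, 2, 3]


class ChainMDP:
    """Deterministic 3-state chain: s0 -> s1 -> s2 -> s0.

    'advance' moves along the chain; 'stay' remains.  Rewards depend only
    on (state, action), so Q-learning converges exactly.
    """

    rewards = {(0, "advance"): 0.0, (1, "advance"): 0.0, (2, "advance"): 1.0,
               (0, "stay"): 0.1, (1, "stay"): -0.2, (2, "stay"): 0.0}

    def reset(self, rng):
        return 0

    def actions(self, state):
        return ["advance", "stay"]

    def step(self, state, action, rng):
        nxt = (state + 1) % 3 if action == "advance" else state
        return nxt, self.rewards[(state, action)]

    def value_iteration(self, gamma, sweeps=2000):
        Q = {(s, a): 0.0 for s in range(3) for a in self.actions(0)}
        for _ in range(sweeps):
            Q = {(s, a): self.rewards[(s, a)] + gamma * max(
                Q[((s + 1) % 3 if a == "advance" else s, b)]
                for b in self.actions(0))
                for s in range(3) for a in self.actions(0)}
        return Q


class TestLearningLoop:
    def test_toy_mdp_recovers_value_iteration_optimum(self):
        env = ChainMDP()
        params = LearningParams(eta=0.5, gamma_disc=0.8, theta=-10.0,
                                window=10_000)
        qf = TabularQ()
        rng = np.random.default_rng(0)
        train_loop(env, qf, params, rng, n_steps=6000)
        qstar = env.value_iteration(0.8)
        for key, v in qstar.items():
            assert abs(qf.table[key] - v) <= 1e-2, key
        for s in range(3):
            greedy = max(env.actions(s), key=lambda a: qf.table[(s, a)])
            optimal = max(env.actions(s), key=lambda a: qstar[(s, a)])
            assert greedy == optimal

    def test_trace_is_reproducible_under_fixed_seed(self):
        env = ChainMDP()
        params = LearningParams(theta=-10.0, window=100)
        t1 = train_loop(env, TabularQ(), params, np.random.default_rng(5), 200)
        t2 = train_loop(env, TabularQ(), params, np.random.default_rng(5), 200)
        assert t1 == t2

    def test_zero_steps_is_a_no_op(self):
        env = ChainMDP()
        qf = TabularQ()
        trace = train_loop(env, qf, LearningParams(), np.random.default_rng(0), 0)
        assert trace == []
        assert qf.table == {}
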