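"""The gather/look/choose agent: inference, policies, learning, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gazetrade as gz
from gazetrade.agent import ExhaustionError

from conftest import make_combined_trial
from oracles import enumerate_trial_outcomes, posterior_oracle


def fresh_state(trial, v_color=None, config=None):
    state = gz.BeliefState(config=config or gz.TaskConfig())
    if v_color:
        state.v_color_learned.update(v_color)
    state.begin_trial(trial)
    return state


class TestCsPosterior:
    @pytest.mark.parametrize("up,down,expected", [
        (0, 0, (1 / 3, 1 / 3, 1 / 3)),
        (1, 0, (1 / 6, 1 / 3, 1 / 2)),
        (0, 1, (1 / 2, 1 / 3, 1 / 6)),
    ])
    def test_worked_examples(self, up, down, expected):
        post = gz.cs_posterior(up, down, (3, 6, 9), 12)
        assert np.allclose(post, expected, atol=1e-12)

    @given(up=st.integers(0, 12), down=st.integers(0, 12))
    @settings(max_examples=60, deadline=None)
    def test_normalized_and_matches_oracle(self, up, down):
        if up + down > 12:
            return
        post = gz.cs_posterior(up, down, (3, 6, 9), 12)
        assert post.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(post, posterior_oracle(up, down), atol=1e-12)

    def test_mode_on_truth_after_full_census(self):
        # the binomial likelihood concentrates on the true level but never
        # fully: a census of a 3-up ring leaves ~0.83 on 3 (the with-
        # replacement model cannot rule out neighbouring levels entirely)
        for i, truth in enumerate((3, 6, 9)):
            post = gz.cs_posterior(truth, 12 - truth, (3, 6, 9), 12)
            assert np.argmax(post) == i
            assert post[i] >= 0.7

    def test_empty_levels_rejected(self):
        with pytest.raises(gz.ConfigurationError):
            gz.cs_posterior(0, 0, (), 12)


class TestCsValue:
    def test_worked_examples(self):
        uniform = np.ones(3) / 3
        assert gz.cs_value(uniform, "combined") == pytest.approx(0.5)
        assert gz.cs_value(np.array([0, 0, 1.0]), "cs_only") == pytest.approx(1.0)
        post = np.array([1 / 6, 1 / 3, 1 / 2])
        assert gz.cs_value(post, "combined") == pytest.approx(
            post @ np.array([0.25, 0.5, 0.75]), abs=1e-12)

    def test_unnormalized_rejected(self):
        with pytest.raises(gz.DataError):
            gz.cs_value(np.array([0.5, 0.5, 0.5]), "combined")


class TestEffectiveColorValue:
    def test_instant_retrieval(self):
        assert gz.effective_color_value(0.8, 1, 0.0) == pytest.approx(0.8)

    def test_partial_retrieval(self):
        assert gz.effective_color_value(0.8, 2, 0.5) == pytest.approx(0.6)

    def test_second_fixation_retrieval_fraction(self):
        # tau_color ~ 0.2324 retrieves ~94.6% of the value by t = 2
        assert gz.effective_color_value(1.0, 2, 0.2324) == pytest.approx(
            0.946, abs=5e-4)


class TestPolicies:
    def test_zero_params_give_half(self):
        trial = make_combined_trial()
        params = gz.AgentParams()
        state = fresh_state(trial)
        assert gz.p_continue_gathering(state, params) == pytest.approx(0.5,
                                                                       abs=1e-12)
        assert gz.p_look_right(state, params) == pytest.approx(0.5, abs=1e-12)
        assert gz.p_choose_right(state, params) == pytest.approx(0.5, abs=1e-12)

    def test_gather_closed_forms(self):
        from scipy.special import expit
        trial = make_combined_trial()
        state = fresh_state(trial, v_color={0: 0.0, 1: 1.0})
        p = gz.AgentParams(alpha_gather=2.0)
        assert gz.p_continue_gathering(state, p) == pytest.approx(
            float(expit(2.0)), abs=1e-12)
        # tau_color = 0: the full learned difference (1.0) is retrieved at t=1
        p = gz.AgentParams(beta_dcolor=-1.0, tau_color=0.0)
        assert gz.p_continue_gathering(state, p) == pytest.approx(
            float(expit(-1.0)), abs=1e-12)

    def test_look_closed_forms(self):
        from scipy.special import expit
        trial = make_combined_trial()
        state = fresh_state(trial, v_color={0: 0.5, 1: 0.0})
        p = gz.AgentParams(beta_look_stay=1.0)
        state.last_side = "right"
        assert gz.p_look_right(state, p) == pytest.approx(float(expit(1.0)),
                                                          abs=1e-12)
        state.last_side = None
        p = gz.AgentParams(beta_look_color=2.0, tau_color=0.0)
        # dv_color = -0.5 -> logit = -1
        assert gz.p_look_right(state, p) == pytest.approx(float(expit(-1.0)),
                                                          abs=1e-12)

    def test_choose_cancellation(self):
        # beta_choose * (dV_Cs + omega * dV_color) = 3 * (0.25 - 0.25) = 0
        trial = make_combined_trial()
        state = fresh_state(trial, v_color={0: 0.5, 1: 0.0})
        state.observed_up["right"] = 3  # posterior pushed up on the right
        p = gz.AgentParams(beta_choose=3.0, omega_color=0.5, tau_color=0.0)
        dv_cs = state.dv_cs()
        dv_color = state.dv_color_effective(0.0)
        from scipy.special import expit
        expected = float(expit(3.0 * (dv_cs + 0.5 * dv_color)))
        assert gz.p_choose_right(state, p) == pytest.approx(expected, abs=1e-12)

    def test_extreme_inverse_temperature_saturates(self):
        trial = make_combined_trial()
        state = fresh_state(trial)
        state.observed_up["right"] = 6
        p = gz.AgentParams(beta_choose=1e4)
        assert gz.p_choose_right(state, p) > 1 - 1e-6

    @given(st.floats(-20, 20), st.floats(-20, 20), st.floats(-20, 20),
           st.floats(-20, 20), st.floats(0, 1))
    @settings(max_examples=40, deadline=None)
    def test_outputs_are_probabilities(self, a, b, c, d, tau):
        trial = make_combined_trial()
        state = fresh_state(trial, v_color={0: 0.2, 1: 0.9})
        params = gz.AgentParams(alpha_gather=a, beta_dCs=b, beta_dcolor=c,
                                beta_time=d, tau=tau, beta_choose=abs(b))
        for f in (gz.p_continue_gathering, gz.p_look_right):
            assert 0.0 <= f(state, params) <= 1.0
        assert 0.0 <= gz.p_choose_right(state, params) <= 1.0

    def test_larger_color_gap_never_raises_gathering(self):
        trial = make_combined_trial()
        params = gz.AgentParams(beta_dcolor=-2.0, tau_color=0.0)
        last = 1.0
        for gap in (0.0, 0.25, 0.5, 0.75, 1.0):
            state = fresh_state(trial, v_color={0: 0.0, 1: gap})
            p = gz.p_continue_gathering(state, params)
            assert p <= last + 1e-12
            last = p

    def test_color_blind_parameters_ignore_color(self):
        # omega_color = 0 and zero color weights: color-only choices at 0.5
        left = gz.Stimulus(side="left", color_id=0, p_color=0.0)
        right = gz.Stimulus(side="right", color_id=1, p_color=1.0)
        trial = gz.Trial(block=0, trial=0, trial_type="color_only",
                         left=left, right=right)
        state = fresh_state(trial, v_color={0: 0.0, 1: 1.0})
        params = gz.AgentParams(omega_color=0.0, beta_choose=5.0)
        assert gz.p_choose_right(state, params) == pytest.approx(0.5, abs=1e-12)


class TestTdUpdate:
    def test_first_outcome_learning_rate(self):
        trial = make_combined_trial(p_color_right=1.0, up_right=6)
        state = fresh_state(trial)
        for i in range(12):  # full census of the right ring
            state.apply_fixation("right", i)
        params = gz.AgentParams(epsilon=0.5)
        v_cs = state.cs_side_value("right")
        assert v_cs == pytest.approx(0.5, abs=1e-9)
        gz.td_update(state, trial.right, 1, params)
        # eta = 1/(0.5 + 0.5) = 1, delta = 1 - (0.5 + 0) = 0.5
        assert state.v_color_learned[1] == pytest.approx(0.5, abs=1e-9)

    def test_zero_prediction_error_leaves_value(self):
        trial = make_combined_trial()
        state = fresh_state(trial, v_color={1: 0.25})
        for i in range(12):
            state.apply_fixation("right", i)
        v_cs = state.cs_side_value("right")
        state.v_color_learned[1] = 1.0 - v_cs
        gz.td_update(state, trial.right, 1, gz.AgentParams())
        assert state.v_color_learned[1] == pytest.approx(1.0 - v_cs, abs=1e-12)

    def test_colorless_choice_is_noop(self):
        left = gz.Stimulus(side="left", up_count=3,
                           orientations=tuple(i < 3 for i in range(12)))
        right = gz.Stimulus(side="right", up_count=9,
                            orientations=tuple(i < 9 for i in range(12)))
        trial = gz.Trial(block=0, trial=0, trial_type="cs_only",
                         left=left, right=right)
        state = fresh_state(trial, v_color={0: 0.3})
        gz.td_update(state, trial.left, 1, gz.AgentParams())
        assert state.v_color_learned == {0: 0.3}
        assert state.n_color_outcomes == {}

    def test_stochastic_convergence_to_reward_rate(self):
        # color-only-like updates (V_Cs = 0) converge to p = 0.5
        left = gz.Stimulus(side="left", color_id=0, p_color=0.5)
        right = gz.Stimulus(side="right", color_id=1, p_color=0.5)
        trial = gz.Trial(block=0, trial=0, trial_type="color_only",
                         left=left, right=right)
        rng = np.random.default_rng(3)
        state = fresh_state(trial)
        params = gz.AgentParams(epsilon=1.0)
        for _ in range(1000):
            state.begin_trial(trial)
            gz.td_update(state, trial.left, gz.draw_reward(0.5, rng), params)
        assert abs(state.v_color_learned[0] - 0.5) < 0.05


class TestSelectC:
    def test_forced_final_index(self):
        trial = make_combined_trial()
        state = fresh_state(trial)
        for i in range(11):
            state.apply_fixation("left", i)
        idx = gz.select_c_to_fixate(state, "left", np.random.default_rng(0))
        assert idx == 11
        with pytest.raises(ExhaustionError):
            gz.select_c_to_fixate(state, "left", np.random.default_rng(0))

    def test_uniform_over_unfixated(self):
        trial = make_combined_trial()
        rng = np.random.default_rng(1)
        counts = np.zeros(12)
        n = 10_000
        for _ in range(n):
            state = fresh_state(trial)
            counts[gz.select_c_to_fixate(state, "left", rng)] += 1
        se = np.sqrt((1 / 12) * (11 / 12) / n)
        assert np.all(np.abs(counts / n - 1 / 12) < 3 * se)

    def test_counter_contract(self):
        trial = make_combined_trial(up_left=3)
        state = fresh_state(trial)
        state.apply_fixation("left", 0)  # orientation True (index < 3)
        assert state.observed_up["left"] == 1
        assert state.observed_down["left"] == 0
        state.apply_fixation("left", 5)  # orientation False
        assert state.observed_down["left"] == 1


class TestSimulation:
    def test_degenerate_policy_chooses_immediately(self):
        trial = make_combined_trial()
        state = gz.BeliefState()
        params = gz.AgentParams(alpha_gather=-50.0)
        rec = gz.simulate_trial(trial, state, params, np.random.default_rng(0))
        assert rec.n_fixations == 0
        assert rec.rt_proxy == 1

    def test_max_steps_cap(self):
        trial = make_combined_trial()
        params = gz.AgentParams(alpha_gather=50.0)
        state = gz.BeliefState()
        rec = gz.simulate_trial(trial, state, params,
                                np.random.default_rng(0), max_steps=7)
        assert rec.n_fixations == 7

    def test_reproducible_under_seed(self, default_schedule, demo_params):
        r1 = gz.simulate_participant(default_schedule, demo_params, seed=9)
        r2 = gz.simulate_participant(default_schedule, demo_params, seed=9)
        assert r1 == r2

    def test_color_only_trials_have_no_fixations(self, default_schedule,
                                                 demo_params):
        recs = gz.simulate_participant(default_schedule, demo_params, seed=2)
        for r in recs:
            if r.trial_type == "color_only":
                assert r.n_fixations == 0

    def test_negative_color_weight_reduces_fixations(self, default_schedule):
        base = dict(alpha_gather=2.0, beta_time=-3.0, tau=0.8,
                    beta_choose=5.0, omega_color=0.5, tau_color=0.2,
                    epsilon=1.0)
        with_color = gz.AgentParams(beta_dcolor=-3.0, **base)
        without = gz.AgentParams(beta_dcolor=0.0, **base)
        n_with = np.mean([r.n_fixations for r in gz.simulate_participant(
            default_schedule, with_color, seed=4) if r.trial_type == "combined"])
        n_without = np.mean([r.n_fixations for r in gz.simulate_participant(
            default_schedule, without, seed=4) if r.trial_type == "combined"])
        assert n_with < n_without

    def test_outcome_distribution_matches_enumeration(self, demo_params):
        """Brute-force oracle: chained policy probabilities sum to one and
        match simulated outcome frequencies (short trials)."""
        trial = make_combined_trial(p_color_left=0.0, p_color_right=1.0,
                                    up_left=3, up_right=9)
        v_color = {0: 0.1, 1: 0.6}
        params = gz.AgentParams(alpha_gather=0.5, beta_dCs=-0.5,
                                beta_dcolor=-1.0, beta_time=-1.0, tau=0.7,
                                alpha_look_right=0.2, beta_look_color=1.0,
                                beta_look_Cs=0.5, beta_look_stay=0.8,
                                beta_choose=3.0, omega_color=0.6,
                                tau_color=0.3, epsilon=1.0)
        enum = enumerate_trial_outcomes(params, "combined", 3, 9, 0.1, 0.6,
                                        max_steps=2)
        assert sum(enum.values()) == pytest.approx(1.0, abs=1e-12)

        n = 20_000
        rng = np.random.default_rng(8)
        freq = {}
        for _ in range(n):
            state = gz.BeliefState()
            state.v_color_learned.update(v_color)
            rec = gz.simulate_trial(trial, state, params, rng, max_steps=2)
            key = (rec.sides, rec.c_orientations, rec.choice)
            freq[key] = freq.get(key, 0) + 1
        for key, p in enum.items():
            if p * n < 10:
                continue
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freq.get(key, 0) / n - p) < 3.5 * se, key
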