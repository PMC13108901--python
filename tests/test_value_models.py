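"""Learning updates, choice policies, and agent simulation contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transrank.task_design import DEFAULT_PAIR_SET
from transrank.value_models import (
    AgentParams,
    BetaState,
    ValueState,
    beta_choice_prob,
    betaq_update,
    betasort_update,
    correct_ranking_values,
    distance_average_values,
    qlearning_update,
    simulate_agent,
    softmax_choice_prob,
)


class TestQLearning:
    def test_hand_evaluated_first_update(self):
        # D(6,1) = 5/7; alpha/2 * D = 0.25 * 5/7
        state = qlearning_update(ValueState.zeros(8), (6, 1), 0.5, 8)
        assert state.q[5] == pytest.approx(5 / 28)
        assert state.q[0] == pytest.approx(-5 / 28)
        assert np.all(state.q[[1, 2, 3, 4, 6, 7]] == 0)

    def test_fixed_point_when_difference_matches_distance(self):
        q = np.zeros(8)
        q[5], q[0] = 5 / 14, -5 / 14  # Qm - Qn = 5/7 = D(6,1)
        state = qlearning_update(ValueState(q.copy()), (6, 1), 0.7, 8)
        assert np.allclose(state.q, q)

    @given(
        st.lists(
            st.floats(-1, 1, allow_nan=False), min_size=8, max_size=8
        ),
        st.integers(1, 8),
        st.integers(1, 8),
        st.floats(0.01, 1.0),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_value_sum_conserved(self, qvals, m, n, alpha):
        if m == n:
            return
        before = ValueState(np.array(qvals))
        after = qlearning_update(before, (m, n), alpha, 8)
        assert after.q.sum() == pytest.approx(before.q.sum(), abs=1e-12)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qlearning_update(ValueState.zeros(8), (2, 1), 1.5, 8)


class TestSoftmax:
    def test_gamma_zero_is_chance(self):
        assert softmax_choice_prob(3.0, -2.0, 0.0) == 0.5

    def test_unit_difference_logistic_value(self):
        assert softmax_choice_prob(1.0, 0.0, 1.0) == pytest.approx(
            0.7310585786300049
        )

    def test_complementarity_and_monotonicity(self):
        ps = [softmax_choice_prob(d, 0.0, 2.0) for d in (-1, 0, 1, 5, 50)]
        assert all(a < b for a, b in zip(ps, ps[1:]))
        assert softmax_choice_prob(0.3, 0.1, 2.0) + softmax_choice_prob(
            0.1, 0.3, 2.0
        ) == pytest.approx(1.0)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            softmax_choice_prob(1.0, 0.0, -0.1)


class TestBetaQ:
    def test_hand_evaluated_uniform_start(self):
        # pair (4,1): D = 3/7, dV = 0 at the uniform start
        state = betaq_update(BetaState.uniform(8), (4, 1), 0.5, 8)
        assert state.u[3] == pytest.approx(1 + 3 / 7)
        assert state.l[3] == pytest.approx(1 - 0.5 * 3 / 7)
        assert state.u[0] == pytest.approx(1 - 0.5 * 3 / 7)
        assert state.l[0] == pytest.approx(1 + 3 / 7)

    def test_fixed_point_when_expectation_matches_distance(self):
        # choose shapes with Vm - Vn = D(5,2) = 3/7: Vm = 5/7, Vn = 2/7
        u = np.ones(8)
        l = np.ones(8)
        u[4], l[4] = 5.0, 2.0
        u[1], l[1] = 2.0, 5.0
        before = BetaState(u.copy(), l.copy())
        after = betaq_update(before, (5, 2), 0.5, 8)
        assert np.allclose(after.u, u) and np.allclose(after.l, l)

    def test_value_moves_up_when_distance_exceeds_expectation(self):
        for dv_scale in np.linspace(0.0, 0.9, 10):
            u = np.ones(8)
            l = np.ones(8)
            u[6] = 1 + dv_scale  # modest positive dV below D(7,1)=6/7
            before = BetaState(u, l)
            dv = before.v[6] - before.v[0]
            if dv >= 6 / 7:
                continue
            after = betaq_update(before, (7, 1), 0.5, 8)
            assert after.v[6] > before.v[6]

    def test_nonpositive_shapes_rejected(self):
        bad = BetaState(np.ones(8), np.ones(8))
        bad.u[0] = 0.0
        with pytest.raises(ValueError):
            betaq_update(bad, (3, 1), 0.5, 8)


class TestBetasort:
    def test_between_item_sharpens_in_place(self):
        u = np.ones(8)
        l = np.ones(8)
        u[7], l[7] = 3.0, 1.0  # Vm = 0.75
        u[0], l[0] = 1.0, 3.0  # Vn = 0.25
        state = betasort_update(BetaState(u, l), (8, 1), 0.5, 8)
        # item at position 2 had V = 0.5, strictly between
        assert state.u[1] == pytest.approx(1.5)
        assert state.l[1] == pytest.approx(1.5)
        assert state.v[1] == pytest.approx(0.5)

    def test_low_item_update_uses_alpha_on_lower_shape(self):
        # engineer dV(m,n) = 0.4 and an item below Vn
        u = np.ones(8)
        l = np.ones(8)
        u[6], l[6] = 7.0, 3.0    # Vm = 0.7
        u[3], l[3] = 3.0, 7.0    # Vn = 0.3
        u[0], l[0] = 1.0, 9.0    # Vo = 0.1 < Vn
        state = betasort_update(BetaState(u, l), (7, 4), 0.5, 8)
        assert state.u[0] == pytest.approx(1.0 + 0.4)
        assert state.l[0] == pytest.approx(9.0 + 0.2)

    def test_high_item_mirrors_with_alpha_on_upper_shape(self):
        u = np.ones(8)
        l = np.ones(8)
        u[6], l[6] = 7.0, 3.0    # Vm = 0.7
        u[3], l[3] = 3.0, 7.0    # Vn = 0.3
        u[7], l[7] = 9.0, 1.0    # Vo = 0.9 > Vm
        state = betasort_update(BetaState(u, l), (7, 4), 0.5, 8)
        assert state.u[7] == pytest.approx(9.0 + 0.2)
        assert state.l[7] == pytest.approx(1.0 + 0.4)

    def test_uniform_start_degenerates_to_betaq(self):
        # at the uniform start every non-presented item ties with Vn and Vm
        # (all V = 0.5), falling into the mean-preserving case; the presented
        # pair must match Beta-Q exactly
        pair, alpha = (6, 2), 0.4
        bq = betaq_update(BetaState.uniform(8), pair, alpha, 8)
        bs = betasort_update(BetaState.uniform(8), pair, alpha, 8)
        for idx in (5, 1):
            assert bs.u[idx] == pytest.approx(bq.u[idx])
            assert bs.l[idx] == pytest.approx(bq.l[idx])


class TestBetaChoice:
    def test_symmetric_parameters_give_half(self):
        state = BetaState(np.full(8, 2.0), np.full(8, 3.0))
        assert beta_choice_prob(state, 1, 2) == pytest.approx(0.5, abs=1e-9)

    def test_closed_form_beta21_vs_beta12(self):
        # P(X > Y), X~Beta(2,1), Y~Beta(1,2) = 5/6 by the closed-form integral
        state = BetaState(np.array([2.0, 1.0]), np.array([1.0, 2.0]))
        assert beta_choice_prob(state, 1, 2) == pytest.approx(5 / 6, abs=1e-8)

    def test_sampling_agrees_with_integral(self):
        state = BetaState(np.array([3.0, 1.5]), np.array([1.2, 2.5]))
        exact = beta_choice_prob(state, 1, 2)
        mc = beta_choice_prob(
            state, 1, 2, method="sampling", n_samples=200_000, seed=5
        )
        se = np.sqrt(exact * (1 - exact) / 200_000)
        assert abs(mc - exact) < 3 * se

    def test_invalid_sample_count_rejected(self):
        state = BetaState.uniform(2)
        with pytest.raises(ValueError):
            beta_choice_prob(state, 1, 2, method="sampling", n_samples=0)


class TestBaselines:
    def test_distance_average_worked_example(self, identity_rank):
        # rank-1 item sits in pairs (1,6) and (1,8): mean(-5, -7) = -6
        values = distance_average_values(DEFAULT_PAIR_SET, identity_rank)
        assert values.q[0] == pytest.approx(-6.0)
        # rank-8 item sits in pairs (5,8) and (1,8): mean(+3, +7) = +5
        assert values.q[7] == pytest.approx(5.0)

    def test_distance_average_antisymmetric_in_orientation(self, identity_rank):
        values = distance_average_values(DEFAULT_PAIR_SET, identity_rank)
        flipped_pairs = frozenset(
            (9 - b, 9 - a) for a, b in DEFAULT_PAIR_SET
        )
        from transrank.task_design import PairSet

        flipped = distance_average_values(PairSet(flipped_pairs), identity_rank)
        assert np.allclose(flipped.q, -values.q[::-1])

    def test_item_missing_from_pairs_rejected(self, identity_rank):
        from transrank.task_design import PairSet

        sparse = PairSet(frozenset({(1, 2)}))
        with pytest.raises(ValueError):
            distance_average_values(sparse, identity_rank)

    def test_correct_ranking_values_are_true_ranks(self, identity_rank):
        values = correct_ranking_values(identity_rank)
        assert np.array_equal(values.q, np.arange(1, 9))


class TestSimulateAgent:
    def test_oracle_agent_with_huge_gamma_is_perfect(
        self, identity_rank, default_learn, default_test
    ):
        params = AgentParams("correct_rank", gamma=1000.0)
        table = simulate_agent(params, identity_rank, default_learn,
                               default_test, seed=1)
        assert len(table) == 280
        assert table["is_correct"].all()

    @pytest.mark.parametrize("model", ["qlearning", "correct_rank"])
    def test_gamma_zero_is_chance(
        self, model, identity_rank, default_learn, default_test
    ):
        params = AgentParams(model, alpha=0.5, gamma=0.0)
        table = simulate_agent(params, identity_rank, default_learn,
                               default_test, seed=2)
        acc = table["is_correct"].mean()
        # binomial 3-sigma band around 0.5 at 280 trials
        assert abs(acc - 0.5) < 3 * 0.5 / np.sqrt(280)

    @pytest.mark.parametrize("model", ["qlearning", "betaq", "betasort"])
    def test_same_seed_reproduces_table(
        self, model, identity_rank, default_learn, default_test
    ):
        params = AgentParams(model, alpha=0.4, gamma=4.0)
        a = simulate_agent(params, identity_rank, default_learn, default_test,
                           seed=9)
        b = simulate_agent(params, identity_rank, default_learn, default_test,
                           seed=9)
        assert a.equals(b)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            AgentParams("mystery")


class TestGroupSignatures:
    """Simulated value-model cohorts reproduce both hallmark effects."""

    @pytest.mark.parametrize("model,kw", [
        ("qlearning", dict(alpha=0.4, gamma=5.0)),
        ("betaq", dict(alpha=0.5)),
        ("distance_avg", dict(gamma=1.0)),
    ])
    def test_distance_slope_positive_and_serial_u_shape(
        self, model, kw, identity_rank, default_learn, default_test
    ):
        from transrank.behavior_metrics import (
            distance_effect_slope,
            pair_accuracy,
            serial_position_curve,
        )

        params = AgentParams(model, **kw)
        slopes, ends, middles = [], [], []
        for s in range(12):
            table = simulate_agent(
                params, identity_rank, default_learn, default_test, seed=100 + s
            )
            pa = pair_accuracy(table, identity_rank)
            slopes.append(distance_effect_slope(pa))
            curve = serial_position_curve(pa)
            ends.append((curve[1] + curve[8]) / 2)
            middles.append((curve[4] + curve[5]) / 2)
        assert np.mean(slopes) > 0
        assert np.mean(ends) > np.mean(middles)
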