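"""Transition matrices, rewards, and the cohort accumulator.

The accumulator is cross-checked against an exhaustive path-enumeration
oracle written independently in this file (and against the one in
renalcea.synthetic), so the matrix recursion never validates itself.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from renalcea.config import ConfigError, ModelOptions
from renalcea.decision_tree import initial_distribution, strategy_split
from renalcea.markov import (
    N_STATES,
    NARRATIVE_STATE,
    State,
    accumulate,
    build_transition_matrices,
    build_transition_matrix,
    per_state_totals,
    reward_vectors,
    run_cohort,
    state_rewards,
    transition_cost_matrix,
)
from renalcea.sensitivity import sample_parameters
from renalcea.synthetic import gompertz_life_table


def benign_vec():
    vec = np.zeros(N_STATES)
    vec[State.BENIGN] = 1.0
    return vec


class TestTransitionMatrix:
    def test_rows_are_stochastic_every_cycle(self, params, life_table):
        for P in build_transition_matrices(params, life_table):
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_dead_is_absorbing(self, params, life_table):
        P = build_transition_matrix(params, life_table, 0)
        expected = np.zeros(N_STATES)
        expected[State.DEAD] = 1.0
        np.testing.assert_array_equal(P[State.DEAD], expected)

    def test_metastatic_row_matches_disease_mortality(self, params, life_table):
        P = build_transition_matrix(params, life_table, 0)
        assert P[State.METASTATIC_Y1, State.DEAD] == 0.335
        assert P[State.METASTATIC_Y1, State.METASTATIC_LATER] == pytest.approx(0.665)
        assert P[State.METASTATIC_LATER, State.DEAD] == 0.335

    def test_no_event_limit_is_identity_plus_tunnels(self, params):
        quiet = params.replace(
            p_non_r0=0, p_fn_metastasis=0, p_local_recurrence=0,
            p_post_resection_metastasis=0, p_death_metastatic=0,
            p_fn_detection=0, benign_mortality=0,
        )
        immortal = gompertz_life_table(0.0, 0.0)
        P = build_transition_matrix(quiet, immortal, 0)
        expected = np.eye(N_STATES)
        # deterministic year-1 -> later tunnel advances remain
        for y1, later in [
            (State.BENIGN_POSTFP_Y1, State.BENIGN_POSTFP_LATER),
            (State.RESECTED_Y1, State.RESECTED_LATER),
            (State.METASTATIC_Y1, State.METASTATIC_LATER),
        ]:
            expected[y1, y1] = 0.0
            expected[y1, later] = 1.0
        # recurrence surgery still resolves (success -> resected, else metastatic)
        expected[State.RECURRENCE, State.RECURRENCE] = 0.0
        expected[State.RECURRENCE, State.RESECTED_Y1] = quiet.p_recurrence_surgery_success
        expected[State.RECURRENCE, State.METASTATIC_Y1] = (
            1 - quiet.p_recurrence_surgery_success
        )
        np.testing.assert_allclose(P, expected, atol=1e-12)

    def test_mortality_tracks_age(self, params, life_table):
        p0 = build_transition_matrix(params, life_table, 0)
        p9 = build_transition_matrix(params, life_table, 9)
        assert p9[State.RESECTED_LATER, State.DEAD] > p0[State.RESECTED_LATER, State.DEAD]
        assert p0[State.UNDETECTED, State.DEAD] == life_table.q(63)

    def test_cycle_outside_horizon_rejected(self, params, life_table):
        with pytest.raises(ConfigError, match="cycle_index"):
            build_transition_matrix(params, life_table, 10)

    def test_short_life_table_is_coverage_error(self, params):
        short = gompertz_life_table(0.012, 0.09, (63, 68))
        with pytest.raises(ConfigError, match="ages 63-68"):
            build_transition_matrices(params, short)

    def test_every_state_maps_to_a_narrative_state(self):
        assert set(NARRATIVE_STATE) == set(State)
        assert len(set(NARRATIVE_STATE.values())) == 7

    @given(seed=st.integers(0, 10_000))
    def test_rows_stochastic_under_psa_draws(self, params, life_table, seed):
        draw = sample_parameters(params, np.random.default_rng(seed))
        for P in build_transition_matrices(draw, life_table):
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestStateRewards:
    @pytest.mark.parametrize(
        "state,cost,utility",
        [
            (State.BENIGN, 0.0, 1.0),
            (State.BENIGN_POSTFP_Y1, 0.0, 0.995),
            (State.BENIGN_POSTFP_LATER, 0.0, 1.0),
            (State.UNDETECTED, 0.0, 1.0),
            (State.RESECTED_Y1, 492.0, 0.97),
            (State.RESECTED_LATER, 246.0, 1.0),
            (State.RECURRENCE, 492.0, 0.97),
            (State.METASTATIC_Y1, 70_703.0, 0.66),
            (State.METASTATIC_LATER, 34_716.0, 0.66),
            (State.DEAD, 0.0, 0.0),
        ],
    )
    def test_annual_rewards(self, params, plain_options, state, cost, utility):
        assert state_rewards(params, state, plain_options) == (cost, utility)

    def test_monthly_composition_blends_first_year(self, params):
        composed = ModelOptions(compose_monthly_qol=True)
        _, utility = state_rewards(params, State.RESECTED_Y1, composed)
        assert utility == pytest.approx((11 * 0.97 + 0.7) / 12)
        _, fp_utility = state_rewards(params, State.BENIGN_POSTFP_Y1, composed)
        assert fp_utility == pytest.approx((11 * 0.995 + 0.7) / 12)

    def test_unknown_state_is_programming_error(self, params):
        with pytest.raises(ValueError, match="unknown state"):
            state_rewards(params, 42)

    def test_only_detection_transition_is_priced(self, params):
        C = transition_cost_matrix(params)
        assert C[State.UNDETECTED, State.RESECTED_Y1] == params.cost_timely_surgery
        assert np.count_nonzero(C) == 1


class TestRunCohort:
    def test_benign_cohort_matches_geometric_series(self, params, life_table):
        trace = run_cohort(benign_vec(), 0.0, params, life_table)
        closed_form = sum(1.03 ** -t for t in range(10))
        assert trace.total_qaly == pytest.approx(closed_form, abs=1e-12)
        assert trace.total_qaly == pytest.approx(8.7861, abs=5e-5)
        assert trace.total_cost == 0.0

    def test_dead_cohort_earns_entry_cost_only(self, params, life_table):
        vec = np.zeros(N_STATES)
        vec[State.DEAD] = 1.0
        trace = run_cohort(vec, 1234.0, params, life_table)
        assert trace.total_cost == 1234.0
        assert trace.total_qaly == 0.0

    def test_undiscounted_full_survival_gives_horizon_years(self, params):
        undiscounted = params.replace(discount_rate=0.0)
        immortal = gompertz_life_table(0.0, 0.0)
        trace = run_cohort(benign_vec(), 0.0, undiscounted, immortal)
        assert trace.total_qaly == pytest.approx(10.0, abs=1e-12)

    def test_discount_limit_recovers_undiscounted_sum(self, params, life_table):
        init = initial_distribution(strategy_split(params, "mri"))
        tiny = run_cohort(init, 0.0, params.replace(discount_rate=1e-12),
                          life_table)
        zero = run_cohort(init, 0.0, params.replace(discount_rate=0.0), life_table)
        assert tiny.total_qaly == pytest.approx(zero.total_qaly, rel=1e-9)
        assert tiny.total_cost == pytest.approx(zero.total_cost, rel=1e-9)

    def test_trace_invariants(self, params, life_table):
        init = initial_distribution(strategy_split(params, "mri_ai"))
        trace = run_cohort(init, 0.0, params, life_table)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
        dead = trace.occupancy[:, State.DEAD]
        assert np.all(np.diff(dead) >= -1e-15)
        ceiling = sum(1.03 ** -t for t in range(10))
        assert trace.total_qaly <= ceiling + 1e-12

    def test_raising_metastatic_mortality_lowers_qalys(self, params, life_table):
        init = initial_distribution(strategy_split(params, "mri"))
        base = run_cohort(init, 0.0, params, life_table)
        worse = run_cohort(
            init, 0.0, params.replace(p_death_metastatic=0.6), life_table
        )
        assert worse.total_qaly < base.total_qaly

    def test_raising_state_cost_raises_total_cost(self, params, life_table):
        init = initial_distribution(strategy_split(params, "mri"))
        base = run_cohort(init, 0.0, params, life_table)
        pricier = run_cohort(
            init, 0.0, params.replace(cost_metastatic_later=50_000.0), life_table
        )
        assert pricier.total_cost > base.total_cost

    def test_half_cycle_keeps_conservation_and_lowers_qalys(self, params, life_table):
        init = initial_distribution(strategy_split(params, "mri"))
        half = run_cohort(init, 0.0, params, life_table,
                          ModelOptions(half_cycle=True))
        full = run_cohort(init, 0.0, params, life_table)
        np.testing.assert_allclose(half.occupancy.sum(axis=1), 1.0, atol=1e-12)
        # trapezoid puts half weight on the (worse) final row
        assert half.total_qaly < full.total_qaly

    def test_invalid_initial_rejected(self, params, life_table):
        with pytest.raises(ConfigError, match="sum to 1"):
            run_cohort(0.5 * benign_vec(), 0.0, params, life_table)


class TestOracleEquivalence:
    """Matrix recursion vs exhaustive path enumeration."""

    @staticmethod
    def enumerate_totals(initial, matrices, costs, utils, rate, trans_costs):
        horizon = matrices.shape[0]
        n = matrices.shape[1]
        d = (1.0 + rate) ** -np.arange(horizon + 1)
        total_cost = total_qaly = 0.0
        for path in itertools.product(range(n), repeat=horizon + 1):
            prob = initial[path[0]]
            for t in range(horizon):
                prob *= matrices[t, path[t], path[t + 1]]
            if prob == 0.0:
                continue
            total_cost += prob * sum(d[t] * costs[path[t]] for t in range(horizon))
            total_qaly += prob * sum(d[t] * utils[path[t]] for t in range(horizon))
            total_cost += prob * sum(
                d[t + 1] * trans_costs[path[t], path[t + 1]]
                for t in range(horizon - 1)
            )
        return total_cost, total_qaly

    def test_full_model_three_cycles(self, params, life_table, plain_options):
        short = params.replace(horizon_cycles=3)
        matrices = build_transition_matrices(short, life_table)
        costs, utils = reward_vectors(short, plain_options)
        trans = transition_cost_matrix(short)
        init = initial_distribution(strategy_split(short, "mri"))
        oracle_cost, oracle_qaly = self.enumerate_totals(
            init, matrices, costs, utils, short.discount_rate, trans
        )
        _, dc, dq = accumulate(init, matrices, costs, utils,
                               short.discount_rate, trans)
        assert dc.sum() == pytest.approx(oracle_cost, abs=1e-10)
        assert dq.sum() == pytest.approx(oracle_qaly, abs=1e-10)

    def test_per_state_totals_equal_linear_combination(self, params, life_table):
        cost_vec, qaly_vec = per_state_totals(params, life_table)
        init = initial_distribution(strategy_split(params, "mri_ai"))
        trace = run_cohort(init, 0.0, params, life_table)
        assert init @ cost_vec == pytest.approx(trace.total_cost, abs=1e-9)
        assert init @ qaly_vec == pytest.approx(trace.total_qaly, abs=1e-12)
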