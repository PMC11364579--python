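"""Markov cohort engine for the renal-lesion model.

The narrative model has seven health states (benign correctly identified,
benign after unnecessary surgery, undetected malignancy, resected
malignancy, recurrence, metastatic disease, dead). Because first-year
costs and utilities differ from later years for the post-surgery and
metastatic states, the engine expands those states into year-1 /
later-year tunnel pairs, giving ten computational states. Annual
transition matrices are age-dependent through the life-table mortality of
patients carrying a localized tumor; benign patients die at the (zero by
default) benign background rate, and metastatic patients at the disease-
specific rate.

Competing risks within a cycle are resolved death-first: the annual death
probability is taken off the top, and the remaining probability mass is
split among disease events at their stated annual probabilities, the
residual going to the row's default destination.

The cohort recursion is exact for this model class; an exhaustive
path-enumeration oracle over small synthetic models (see
:mod:`renalcea.synthetic`) is used in the test suite to verify the
accumulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .config import ConfigError, LifeTable, ModelOptions, ParameterSet

__all__ = [
    "CohortTrace",
    "N_STATES",
    "State",
    "NARRATIVE_STATE",
    "accumulate",
    "build_transition_matrices",
    "build_transition_matrix",
    "per_state_totals",
    "reward_vectors",
    "run_cohort",
    "state_rewards",
    "transition_cost_matrix",
]


class State(IntEnum):
    """Expanded (tunnel-resolved) computational states."""

    BENIGN = 0
    BENIGN_POSTFP_Y1 = 1
    BENIGN_POSTFP_LATER = 2
    UNDETECTED = 3
    RESECTED_Y1 = 4
    RESECTED_LATER = 5
    RECURRENCE = 6
    METASTATIC_Y1 = 7
    METASTATIC_LATER = 8
    DEAD = 9


N_STATES = len(State)

# Mapping of each computational state to the narrative model state.
NARRATIVE_STATE: dict[State, str] = {
    State.BENIGN: "Benign, correctly identified",
    State.BENIGN_POSTFP_Y1: "Benign, identified as malignant",
    State.BENIGN_POSTFP_LATER: "Benign, identified as malignant",
    State.UNDETECTED: "Malignant lesion, identified as benign",
    State.RESECTED_Y1: "Malignant, correctly identified",
    State.RESECTED_LATER: "Malignant, correctly identified",
    State.RECURRENCE: "Recurrence",
    State.METASTATIC_Y1: "Metastasized/non-resectable",
    State.METASTATIC_LATER: "Metastasized/non-resectable",
    State.DEAD: "Dead",
}

_ROW_TOL = 1e-9


def build_transition_matrix(
    params: ParameterSet, life_table: LifeTable, cycle_index: int
) -> np.ndarray:
    """Row-stochastic annual transition matrix for one cycle.

    Mortality of patients with a localized tumor uses the life-table
    probability at age ``start_age + cycle_index``.
    """
    if not 0 <= cycle_index < params.horizon_cycles:
        raise ConfigError(
            f"cycle_index {cycle_index} outside horizon [0, {params.horizon_cycles})"
        )
    q = life_table.q(params.start_age + cycle_index)
    m = params.benign_mortality
    P = np.zeros((N_STATES, N_STATES))

    P[State.BENIGN, State.BENIGN] = 1.0 - m
    P[State.BENIGN, State.DEAD] = m

    P[State.BENIGN_POSTFP_Y1, State.BENIGN_POSTFP_LATER] = 1.0 - m
    P[State.BENIGN_POSTFP_Y1, State.DEAD] = m

    P[State.BENIGN_POSTFP_LATER, State.BENIGN_POSTFP_LATER] = 1.0 - m
    P[State.BENIGN_POSTFP_LATER, State.DEAD] = m

    # Undetected malignancy: metastasize, else be detected and resected.
    s = 1.0 - q
    P[State.UNDETECTED, State.DEAD] = q
    P[State.UNDETECTED, State.METASTATIC_Y1] = s * params.p_fn_metastasis
    rest = s * (1.0 - params.p_fn_metastasis)
    P[State.UNDETECTED, State.RESECTED_Y1] = rest * params.p_fn_detection
    P[State.UNDETECTED, State.UNDETECTED] = rest * (1.0 - params.p_fn_detection)

    # First post-resection year: residual tumor (non-R0) or local
    # recurrence both enter the recurrence pathway.
    p_rec_y1 = params.p_non_r0 + params.p_local_recurrence
    if p_rec_y1 + params.p_post_resection_metastasis > 1.0:
        raise ConfigError(
            "post-resection event probabilities exceed 1 "
            "(p_non_r0 + p_local_recurrence + p_post_resection_metastasis)"
        )
    P[State.RESECTED_Y1, State.DEAD] = q
    P[State.RESECTED_Y1, State.RECURRENCE] = s * p_rec_y1
    P[State.RESECTED_Y1, State.METASTATIC_Y1] = s * params.p_post_resection_metastasis
    P[State.RESECTED_Y1, State.RESECTED_LATER] = s * (
        1.0 - p_rec_y1 - params.p_post_resection_metastasis
    )

    P[State.RESECTED_LATER, State.DEAD] = q
    P[State.RESECTED_LATER, State.RECURRENCE] = s * params.p_local_recurrence
    P[State.RESECTED_LATER, State.METASTATIC_Y1] = (
        s * params.p_post_resection_metastasis
    )
    P[State.RESECTED_LATER, State.RESECTED_LATER] = s * (
        1.0 - params.p_local_recurrence - params.p_post_resection_metastasis
    )

    # Recurrence: repeat surgery succeeds or the disease becomes metastatic.
    P[State.RECURRENCE, State.DEAD] = q
    P[State.RECURRENCE, State.RESECTED_Y1] = s * params.p_recurrence_surgery_success
    P[State.RECURRENCE, State.METASTATIC_Y1] = s * (
        1.0 - params.p_recurrence_surgery_success
    )

    P[State.METASTATIC_Y1, State.DEAD] = params.p_death_metastatic
    P[State.METASTATIC_Y1, State.METASTATIC_LATER] = 1.0 - params.p_death_metastatic

    P[State.METASTATIC_LATER, State.DEAD] = params.p_death_metastatic
    P[State.METASTATIC_LATER, State.METASTATIC_LATER] = 1.0 - params.p_death_metastatic

    P[State.DEAD, State.DEAD] = 1.0

    rows = P.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > _ROW_TOL):
        bad = State(int(np.argmax(np.abs(rows - 1.0)))).name
        raise AssertionError(f"transition row for {bad} is off-stochastic")
    return P


def build_transition_matrices(
    params: ParameterSet, life_table: LifeTable
) -> np.ndarray:
    """All per-cycle matrices, shape (horizon, n_states, n_states)."""
    if not life_table.covers(params.start_age, params.horizon_cycles):
        raise ConfigError(
            f"life table covers ages {life_table.min_age}-{life_table.max_age}; "
            f"model needs {params.start_age}-"
            f"{params.start_age + params.horizon_cycles - 1}"
        )
    return np.stack(
        [
            build_transition_matrix(params, life_table, t)
            for t in range(params.horizon_cycles)
        ]
    )


def state_rewards(
    params: ParameterSet,
    state: State,
    options: ModelOptions = ModelOptions(),
) -> tuple[float, float]:
    """Annual (cost, utility) attributed to one cycle spent in ``state``.

    The recurrence state reuses the first-treatment-year rewards, since a
    repeat surgery with follow-up is what the state represents.
    """
    if options.compose_monthly_qol:
        # One month of post-operative QoL blended into the first year.
        u_res_y1 = (11.0 * params.u_resected_y1 + params.u_month_surgery) / 12.0
        u_fp_y1 = (11.0 * params.u_fp_y1 + params.u_month_surgery) / 12.0
    else:
        u_res_y1 = params.u_resected_y1
        u_fp_y1 = params.u_fp_y1
    table: dict[State, tuple[float, float]] = {
        State.BENIGN: (0.0, params.u_benign),
        State.BENIGN_POSTFP_Y1: (0.0, u_fp_y1),
        State.BENIGN_POSTFP_LATER: (0.0, params.u_benign),
        State.UNDETECTED: (0.0, params.u_unresected),
        State.RESECTED_Y1: (params.cost_localized_y1, u_res_y1),
        State.RESECTED_LATER: (params.cost_localized_later, params.u_resected_later),
        State.RECURRENCE: (params.cost_localized_y1, u_res_y1),
        State.METASTATIC_Y1: (params.cost_metastatic_y1, params.u_metastatic),
        State.METASTATIC_LATER: (params.cost_metastatic_later, params.u_metastatic),
        State.DEAD: (0.0, params.u_dead),
    }
    try:
        return table[State(state)]
    except (ValueError, KeyError):
        raise ValueError(f"unknown state {state!r}") from None


def reward_vectors(
    params: ParameterSet, options: ModelOptions = ModelOptions()
) -> tuple[np.ndarray, np.ndarray]:
    """Per-state annual cost and utility vectors."""
    pairs = [state_rewards(params, s, options) for s in State]
    costs = np.array([c for c, _ in pairs])
    utils = np.array([u for _, u in pairs])
    return costs, utils


def transition_cost_matrix(params: ParameterSet) -> np.ndarray:
    """One-time costs attached to transitions (charged on arrival).

    The only priced transition is the detection of an initially missed
    malignancy, which triggers the (delayed) therapeutic surgery.
    """
    C = np.zeros((N_STATES, N_STATES))
    C[State.UNDETECTED, State.RESECTED_Y1] = params.cost_timely_surgery
    return C


@dataclass
class CohortTrace:
    """Cohort evolution and discounted reward accumulation.

    occupancy has ``horizon + 1`` rows (cycle 0 through the state reached
    after the final transition). disc_cost / disc_qaly hold the discounted
    reward attributed to each cycle row; with the default cycle-start
    accrual, the final row accrues nothing.
    """

    occupancy: np.ndarray
    disc_cost: np.ndarray
    disc_qaly: np.ndarray
    entry_cost: float

    @property
    def total_cost(self) -> float:
        return self.entry_cost + float(self.disc_cost.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.disc_qaly.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[s.name.lower() for s in State])
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df["disc_cost"] = self.disc_cost
        df["disc_qaly"] = self.disc_qaly
        return df


def accumulate(
    initial: np.ndarray,
    matrices: np.ndarray,
    state_costs: np.ndarray,
    state_utils: np.ndarray,
    discount_rate: float,
    transition_costs: np.ndarray | None = None,
    half_cycle: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the cohort recursion for arbitrary inputs.

    ``initial`` may be a single occupancy vector (S,) or a stack (k, S);
    totals are then returned per row, which makes the accumulator reusable
    both for a strategy cohort and for per-starting-state totals (identity
    stack). Returns (occupancy over cycles, discounted cost per cycle,
    discounted QALY per cycle), each with a leading cycle axis of length
    ``horizon + 1``.

    Rewards accrue at cycle start with discount factor (1+r)^-t, t = 0 for
    the first cycle; the half-cycle option switches to the trapezoidal
    correction (half weight on the first and the final row). Transition
    costs are charged in full on arrival, discounted at the arrival cycle;
    arrivals produced by the final transition fall outside the accrual
    window and are not charged.
    """
    initial = np.atleast_2d(np.asarray(initial, dtype=float))
    horizon = matrices.shape[0]
    k, S = initial.shape
    occ = np.empty((horizon + 1, k, S))
    occ[0] = initial
    disc_cost = np.zeros((horizon + 1, k))
    disc_qaly = np.zeros((horizon + 1, k))
    d = (1.0 + discount_rate) ** -np.arange(horizon + 1)

    if half_cycle:
        weights = np.ones(horizon + 1)
        weights[0] = weights[-1] = 0.5
    else:
        weights = np.ones(horizon + 1)
        weights[-1] = 0.0

    event_cost = None
    if transition_costs is not None and np.any(transition_costs):
        event_cost = matrices * transition_costs[None, :, :]

    for t in range(horizon):
        disc_cost[t] += weights[t] * d[t] * (occ[t] @ state_costs)
        disc_qaly[t] += weights[t] * d[t] * (occ[t] @ state_utils)
        occ[t + 1] = occ[t] @ matrices[t]
        if event_cost is not None and t < horizon - 1:
            disc_cost[t + 1] += d[t + 1] * (occ[t] @ event_cost[t]).sum(axis=1)
    disc_cost[horizon] += weights[horizon] * d[horizon] * (occ[horizon] @ state_costs)
    disc_qaly[horizon] += weights[horizon] * d[horizon] * (occ[horizon] @ state_utils)
    return occ, disc_cost, disc_qaly


def run_cohort(
    initial: np.ndarray,
    entry_cost: float,
    params: ParameterSet,
    life_table: LifeTable,
    options: ModelOptions = ModelOptions(),
) -> CohortTrace:
    """Evolve a cohort over the model horizon and accumulate rewards.

    ``initial`` is the occupancy vector produced by the decision tree;
    ``entry_cost`` is the cohort-average one-time diagnostic/treatment cost
    incurred at t = 0 (undiscounted).
    """
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (N_STATES,):
        raise ConfigError(f"initial occupancy must have shape ({N_STATES},)")
    if abs(initial.sum() - 1.0) > 1e-9:
        raise ConfigError("initial occupancy must sum to 1")
    matrices = build_transition_matrices(params, life_table)
    costs, utils = reward_vectors(params, options)
    occ, dc, dq = accumulate(
        initial,
        matrices,
        costs,
        utils,
        params.discount_rate,
        transition_costs=transition_cost_matrix(params),
        half_cycle=options.half_cycle,
    )
    return CohortTrace(
        occupancy=occ[:, 0, :],
        disc_cost=dc[:, 0],
        disc_qaly=dq[:, 0],
        entry_cost=float(entry_cost),
    )


def per_state_totals(
    params: ParameterSet,
    life_table: LifeTable,
    options: ModelOptions = ModelOptions(),
) -> tuple[np.ndarray, np.ndarray]:
    """Discounted (cost, QALY) totals per unit cohort started in each state.

    Because reward accumulation is linear in the initial occupancy, any
    strategy's long-term totals are dot products of its initial
    distribution with these vectors. The probabilistic sensitivity
    analysis relies on this to evaluate both strategies from one pass.
    """
    matrices = build_transition_matrices(params, life_table)
    costs, utils = reward_vectors(params, options)
    _, dc, dq = accumulate(
        np.eye(N_STATES),
        matrices,
        costs,
        utils,
        params.discount_rate,
        transition_costs=transition_cost_matrix(params),
        half_cycle=options.half_cycle,
    )
    return dc.sum(axis=0), dq.sum(axis=0)
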