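"""Synthetic inputs for testing: life tables and small oracle models.

Life tables follow a Gompertz mortality law, which captures the
log-linear rise of old-age death probabilities well enough to stand in
for a period life table in any test that does not reproduce the published
numbers. Toy Markov models are small enough that discounted totals can be
computed by exhaustively enumerating every state path, giving an oracle
that is independent of the cohort-recursion engine.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .config import LifeTable

__all__ = ["ToyModel", "gompertz_life_table", "toy_model"]


def gompertz_life_table(
    a: float, b: float, age_range: tuple[int, int] = (63, 73)
) -> LifeTable:
    """Life table with Gompertz hazard a*exp(b*(age - start)).

    ``qx(age) = 1 - exp(-a * exp(b * (age - start)))``, clipped below 1.
    ``b = 0`` gives the constant-hazard (exponential) limit; ``a = 0`` an
    immortal cohort.
    """
    if a < 0.0:
        raise ValueError("baseline hazard 'a' must be >= 0")
    if b < 0.0:
        raise ValueError("log-slope 'b' must be >= 0")
    start, stop = age_range
    ages = np.arange(start, stop + 1)
    hazard = a * np.exp(b * (ages - start))
    qx = 1.0 - np.exp(-hazard)
    if np.any(qx >= 1.0):
        warnings.warn("Gompertz parameters drive qx to 1; clipping", stacklevel=2)
        qx = np.clip(qx, 0.0, 1.0 - 1e-12)
    return LifeTable(ages, qx)


@dataclass(frozen=True)
class ToyModel:
    """Small random cohort model with exhaustively enumerated totals."""

    matrices: np.ndarray            # (cycles, S, S), row-stochastic
    state_costs: np.ndarray
    state_utils: np.ndarray
    transition_costs: np.ndarray    # (S, S), charged on arrival
    initial: np.ndarray
    discount_rate: float
    oracle_cost: float
    oracle_qaly: float


def toy_model(
    n_states: int = 3,
    n_cycles: int = 3,
    seed: int = 0,
    discount_rate: float = 0.03,
    with_transition_costs: bool = True,
) -> ToyModel:
    """Random valid model plus oracle totals by path enumeration.

    Sizes are bounded (<= 4 states, <= 3 cycles) so that the number of
    paths stays tiny. The oracle sums, over every possible state path,
    the path probability times its discounted rewards, with rewards
    accruing at cycle start and transition costs charged on arrival (the
    final transition, which leads beyond the accrual window, is free) --
    the same reward conventions the engine implements, computed without
    any matrix recursion.
    """
    if not 1 <= n_states <= 4 or not 1 <= n_cycles <= 3:
        raise ValueError("toy models are limited to <= 4 states and <= 3 cycles")
    rng = np.random.default_rng(seed)
    matrices = rng.random((n_cycles, n_states, n_states))
    matrices /= matrices.sum(axis=2, keepdims=True)
    state_costs = rng.random(n_states) * 1000.0
    state_utils = rng.random(n_states)
    transition_costs = (
        rng.random((n_states, n_states)) * 500.0
        if with_transition_costs
        else np.zeros((n_states, n_states))
    )
    initial = rng.random(n_states)
    initial /= initial.sum()

    d = (1.0 + discount_rate) ** -np.arange(n_cycles + 1)
    total_cost = 0.0
    total_qaly = 0.0
    # A path visits one state per cycle row 0..n_cycles.
    for path in itertools.product(range(n_states), repeat=n_cycles + 1):
        prob = initial[path[0]]
        for t in range(n_cycles):
            prob *= matrices[t, path[t], path[t + 1]]
        if prob == 0.0:
            continue
        cost = sum(d[t] * state_costs[path[t]] for t in range(n_cycles))
        qaly = sum(d[t] * state_utils[path[t]] for t in range(n_cycles))
        cost += sum(
            d[t + 1] * transition_costs[path[t], path[t + 1]]
            for t in range(n_cycles - 1)
        )
        total_cost += prob * cost
        total_qaly += prob * qaly
    return ToyModel(
        matrices=matrices,
        state_costs=state_costs,
        state_utils=state_utils,
        transition_costs=transition_costs,
        initial=initial,
        discount_rate=discount_rate,
        oracle_cost=total_cost,
        oracle_qaly=total_qaly,
    )
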