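"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis reruns the full pipeline with one parameter at
a time moved to the ends of its range; a bisection search locates
parameter values where a property of the comparison (typically the sign
of the incremental cost) flips. The probabilistic analysis draws every
uncertain parameter from a method-of-moments beta (probabilities,
utilities) or gamma (costs) distribution around its base value, runs both
strategies on each joint draw, and summarizes the Monte Carlo sample as a
cost-effectiveness scatter and an acceptability curve (CEAC).

The source distributions' families are part of the model specification;
their dispersions are not, so a common coefficient of variation (default
0.2) is applied to every sampled parameter and can be overridden per
parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import (
    CEAResult,
    DEFAULT_WTP_GRID,
    StrategyOutcome,
    compare,
    evaluate_all,
)
from .config import (
    ConfigError,
    LifeTable,
    ModelOptions,
    PARAMETER_KINDS,
    ParameterSet,
)
from .decision_tree import entry_costs, initial_distribution, strategy_split
from .markov import per_state_totals

__all__ = [
    "CalibrationError",
    "DEFAULT_DSA_PARAMETERS",
    "PSAResult",
    "TornadoEntry",
    "calibrate_distribution",
    "default_dsa_ranges",
    "find_crossing",
    "one_way_dsa",
    "run_psa",
    "sample_parameters",
    "specificity_crossings",
]


class CalibrationError(ValueError):
    """Requested moments cannot be represented by the distribution family."""


# ---------------------------------------------------------------------------
# Distribution calibration and sampling


def calibrate_distribution(
    family: str, mean: float, cv: float, on_infeasible: str = "error"
) -> dict:
    """Method-of-moments parameters for a beta or gamma distribution.

    ``cv`` is the coefficient of variation, so the target standard
    deviation is ``cv * mean``. A zero cv (or a mean pinned at a boundary)
    degenerates to a point mass. A beta variance at or above the
    feasibility bound mean*(1-mean) either raises (``on_infeasible =
    'error'``) or is clipped just inside the bound with a warning
    (``'clip'``).
    """
    if cv < 0.0:
        raise CalibrationError("cv must be >= 0")
    if family == "beta":
        if not 0.0 <= mean <= 1.0:
            raise CalibrationError(f"beta mean must lie in [0, 1], got {mean}")
        if cv == 0.0 or mean in (0.0, 1.0):
            return {"family": "fixed", "value": mean}
        var = (cv * mean) ** 2
        bound = mean * (1.0 - mean)
        if var >= bound:
            if on_infeasible == "clip":
                warnings.warn(
                    f"beta(mean={mean}, cv={cv}) infeasible "
                    f"(sd^2 >= mean*(1-mean)); clipping variance",
                    stacklevel=2,
                )
                var = 0.95**2 * bound
            else:
                raise CalibrationError(
                    f"infeasible beta variance: sd^2 = {var:.6g} >= "
                    f"mean*(1-mean) = {bound:.6g}"
                )
        nu = bound / var - 1.0
        return {"family": "beta", "alpha": mean * nu, "beta": (1.0 - mean) * nu}
    if family == "gamma":
        if mean <= 0.0:
            raise CalibrationError(f"gamma mean must be > 0, got {mean}")
        if cv == 0.0:
            return {"family": "fixed", "value": mean}
        return {"family": "gamma", "shape": 1.0 / cv**2, "scale": mean * cv**2}
    raise CalibrationError(f"unknown family '{family}' (expected 'beta' or 'gamma')")


def _draw(dist: dict, rng: np.random.Generator) -> float:
    if dist["family"] == "fixed":
        return dist["value"]
    if dist["family"] == "beta":
        return float(rng.beta(dist["alpha"], dist["beta"]))
    return float(rng.gamma(dist["shape"], dist["scale"]))


def sample_parameters(
    params: ParameterSet,
    rng: np.random.Generator,
    cv: float = 0.2,
    cv_overrides: Mapping[str, float] | None = None,
) -> ParameterSet:
    """One joint PSA draw around the base-case parameter set.

    Probabilities and utilities are drawn beta, costs gamma; structural
    constants and boundary-pinned values stay fixed. Draws are
    independent across parameters.
    """
    cv_overrides = cv_overrides or {}
    overrides: dict[str, float] = {}
    for name in params.sampled_names():
        kind = PARAMETER_KINDS[name]
        family = "beta" if kind in ("probability", "utility") else "gamma"
        dist = calibrate_distribution(
            family, getattr(params, name), cv_overrides.get(name, cv),
            on_infeasible="clip",
        )
        overrides[name] = _draw(dist, rng)
    return params.replace(**overrides)


# ---------------------------------------------------------------------------
# Deterministic (one-way) sensitivity analysis

# Diagnostic accuracy and every cost actually charged by the model.
DEFAULT_DSA_PARAMETERS: tuple[str, ...] = (
    "prevalence",
    "mri_sens",
    "mri_spec",
    "ai_sens",
    "ai_spec",
    "cost_mri",
    "cost_timely_surgery",
    "cost_unnecessary_surgery",
    "cost_localized_y1",
    "cost_localized_later",
    "cost_metastatic_y1",
    "cost_metastatic_later",
)


def default_dsa_ranges(
    params: ParameterSet,
    names: Sequence[str] = DEFAULT_DSA_PARAMETERS,
    rel: float = 0.2,
) -> dict[str, tuple[float, float]]:
    """+/-``rel`` ranges around base values, clipped to [0, 1] for bounded kinds."""
    ranges = {}
    for name in names:
        base = getattr(params, name)
        low, high = base * (1.0 - rel), base * (1.0 + rel)
        if PARAMETER_KINDS[name] in ("probability", "utility"):
            low, high = max(low, 0.0), min(high, 1.0)
        ranges[name] = (low, high)
    return ranges


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of the tornado diagram."""

    parameter: str
    low: float
    high: float
    outcome_low: float
    outcome_high: float
    outcome_base: float

    @property
    def width(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def _outcome_value(result: CEAResult, outcome: str) -> float:
    if outcome == "nmb":
        return result.nmb
    if outcome == "icer":
        # signed delta-cost per delta-QALY; negative under dominance
        if result.delta_effect == 0.0:
            return float("nan")
        return result.delta_cost / result.delta_effect
    raise ConfigError(f"unknown outcome '{outcome}' (expected 'icer' or 'nmb')")


def one_way_dsa(
    params: ParameterSet,
    life_table: LifeTable,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    outcome: str = "icer",
    options: ModelOptions = ModelOptions(),
) -> list[TornadoEntry]:
    """One-way sensitivity analysis of the MRI+AI vs MRI comparison.

    For each parameter independently, the full pipeline is rerun at the
    low and high end of its range with everything else at base; entries
    come back sorted by bar width, widest first.
    """
    ranges = dict(ranges) if ranges is not None else default_dsa_ranges(params)
    base = _compare_at(params, life_table, options)
    base_value = _outcome_value(base, outcome)
    entries = []
    for name, (low, high) in ranges.items():
        if low > high:
            raise ConfigError(f"range for '{name}' has low > high ({low} > {high})")
        value_low = _outcome_value(
            _compare_at(params.replace(**{name: low}), life_table, options), outcome
        )
        value_high = _outcome_value(
            _compare_at(params.replace(**{name: high}), life_table, options), outcome
        )
        entries.append(
            TornadoEntry(name, low, high, value_low, value_high, base_value)
        )
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


def _compare_at(
    params: ParameterSet, life_table: LifeTable, options: ModelOptions
) -> CEAResult:
    arms = evaluate_all(params, life_table, options)
    return compare(arms["mri"], arms["mri_ai"], params.wtp)


def find_crossing(
    params: ParameterSet,
    life_table: LifeTable,
    parameter: str,
    predicate: Callable[[CEAResult], bool],
    bracket: tuple[float, float],
    tol: float = 1e-6,
    options: ModelOptions = ModelOptions(),
) -> float:
    """Bisect for the parameter value where ``predicate`` flips.

    The predicate maps the MRI+AI vs MRI comparison to a boolean and must
    differ at the two bracket ends.
    """
    lo, hi = bracket
    if lo > hi:
        raise ConfigError(f"bracket has low > high ({lo} > {hi})")

    def value(x: float) -> bool:
        return bool(predicate(_compare_at(params.replace(**{parameter: x}),
                                          life_table, options)))

    at_lo, at_hi = value(lo), value(hi)
    if at_lo == at_hi:
        raise ConfigError(
            f"predicate is identical at both ends of the bracket for "
            f"'{parameter}' ({lo}, {hi})"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if value(mid) == at_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def specificity_crossings(
    params: ParameterSet,
    life_table: LifeTable,
    options: ModelOptions = ModelOptions(),
    tol: float = 1e-6,
) -> dict[str, float]:
    """Specificity values at which the incremental cost changes sign.

    Returns the MRI specificity above which, and the MRI+AI specificity
    below which, the AI arm stops saving money (ICER turns positive).
    """
    positive_cost = lambda res: res.delta_cost > 0.0  # noqa: E731
    return {
        "mri_spec": find_crossing(
            params, life_table, "mri_spec", positive_cost,
            (params.mri_spec, min(params.mri_spec + 0.10, 1.0)), tol, options,
        ),
        "ai_spec": find_crossing(
            params, life_table, "ai_spec", positive_cost,
            (max(params.ai_spec - 0.11, 0.0), params.ai_spec), tol, options,
        ),
    }


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo sample of both strategies' outcomes under joint draws."""

    outcomes: np.ndarray          # (n, 4): mri cost, mri qaly, ai cost, ai qaly
    wtp_grid: np.ndarray
    ceac: np.ndarray              # fraction of draws where MRI+AI has higher NMB
    seed: int
    n_iterations: int
    cv: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.outcomes,
            columns=["mri_cost", "mri_qaly", "mri_ai_cost", "mri_ai_qaly"],
        )
        df.insert(0, "iteration", np.arange(len(df)))
        return df

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "p_ai_cost_effective": self.ceac})


def _ceac(outcomes: np.ndarray, wtp_grid: np.ndarray) -> np.ndarray:
    d_cost = outcomes[:, 2] - outcomes[:, 0]
    d_eff = outcomes[:, 3] - outcomes[:, 1]
    nmb = wtp_grid[:, None] * d_eff[None, :] - d_cost[None, :]
    return (nmb > 0.0).mean(axis=1)


def run_psa(
    params: ParameterSet,
    life_table: LifeTable,
    n_iterations: int = 30_000,
    seed: int = 0,
    cv: float = 0.2,
    cv_overrides: Mapping[str, float] | None = None,
    wtp_grid: np.ndarray | None = None,
    options: ModelOptions = ModelOptions(),
) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Each iteration draws one joint parameter set and evaluates both
    strategies on it (the arms share the draw, so their outcomes are
    correlated as in the underlying model). Reward accumulation is linear
    in the initial state occupancy, so each draw needs a single Markov
    pass; the two arms differ only in their entry costs and initial
    distribution.
    """
    if n_iterations < 1:
        raise ConfigError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    outcomes = np.empty((n_iterations, 4))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # repeated infeasible-beta clip notices
        for i in range(n_iterations):
            draw = sample_parameters(params, rng, cv, cv_overrides)
            cost_vec, qaly_vec = per_state_totals(draw, life_table, options)
            for j, strategy in enumerate(("mri", "mri_ai")):
                split = strategy_split(draw, strategy)
                costing = entry_costs(
                    split, draw, ai_arm=(strategy == "mri_ai"), options=options
                )
                init = initial_distribution(split)
                outcomes[i, 2 * j] = costing.expected_cost(split) + init @ cost_vec
                outcomes[i, 2 * j + 1] = init @ qaly_vec
    return PSAResult(
        outcomes=outcomes,
        wtp_grid=grid,
        ceac=_ceac(outcomes, grid),
        seed=seed,
        n_iterations=n_iterations,
        cv=cv,
    )


def psa_compare(result: PSAResult, wtp: float) -> CEAResult:
    """Mean-outcome comparison of the PSA sample at one WTP."""
    mean = result.outcomes.mean(axis=0)
    mri = StrategyOutcome("MRI", mean[0], mean[1])
    ai = StrategyOutcome("MRI+AI", mean[2], mean[3])
    return compare(mri, ai, wtp)
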