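"""Cost-effectiveness analysis of the two diagnostic strategies.

Runs the decision tree + Markov pipeline for the MRI and MRI+AI arms,
compares them (incremental cost, incremental effect, ICER or dominance,
net monetary benefit), and derives the maximum justifiable per-application
price of the AI algorithm as a function of the willingness-to-pay
threshold.

Because the AI surcharge is a one-time, undiscounted cost charged to every
patient in the AI arm, the arm's total cost is exactly linear in the
surcharge. The price at which the AI arm's ICER equals a given WTP
therefore has the closed form ``threshold(wtp) = dC0 + wtp * dE0`` where
dC0 is the base-case saving and dE0 the base-case QALY gain at zero
surcharge; at wtp = 0 this is the price up to which the AI arm stays
strictly dominant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import LifeTable, ModelOptions, ParameterSet
from .decision_tree import entry_costs, initial_distribution, strategy_split
from .markov import CohortTrace, run_cohort

__all__ = [
    "CEAResult",
    "StrategyOutcome",
    "ThresholdCurve",
    "ai_cost_threshold",
    "compare",
    "evaluate_all",
    "evaluate_strategy",
    "threshold_curve",
]

DEFAULT_WTP_GRID = np.arange(0, 200_001, 10_000, dtype=float)


@dataclass(frozen=True)
class StrategyOutcome:
    """Total discounted cost and effectiveness of one diagnostic strategy."""

    label: str
    cost: float
    effect: float
    trace: CohortTrace | None = field(default=None, compare=False, repr=False)


@dataclass(frozen=True)
class CEAResult:
    """Pairwise comparison of a comparator against a reference strategy."""

    reference: StrategyOutcome
    comparator: StrategyOutcome
    wtp: float
    delta_cost: float
    delta_effect: float
    icer: float | None
    status: str  # "dominant" | "dominated" | "equivalent" | "cost-minimization" | "icer"
    nmb: float

    @property
    def cost_effective(self) -> bool:
        """Is the comparator cost-effective at the stated WTP (NMB > 0)?"""
        return self.nmb > 0.0

    def summary_row(self) -> dict:
        return {
            "reference": self.reference.label,
            "comparator": self.comparator.label,
            "reference_cost": self.reference.cost,
            "reference_qaly": self.reference.effect,
            "comparator_cost": self.comparator.cost,
            "comparator_qaly": self.comparator.effect,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_effect,
            "icer": self.icer,
            "status": self.status,
            "wtp": self.wtp,
            "nmb": self.nmb,
        }


def evaluate_strategy(
    params: ParameterSet,
    life_table: LifeTable,
    strategy: str,
    options: ModelOptions = ModelOptions(),
) -> StrategyOutcome:
    """Run decision tree and Markov cohort for one arm ('mri' or 'mri_ai')."""
    split = strategy_split(params, strategy)
    costing = entry_costs(split, params, ai_arm=(strategy == "mri_ai"), options=options)
    trace = run_cohort(
        initial_distribution(split),
        costing.expected_cost(split),
        params,
        life_table,
        options,
    )
    return StrategyOutcome(
        label=split.strategy_label, cost=trace.total_cost, effect=trace.total_qaly,
        trace=trace,
    )


def evaluate_all(
    params: ParameterSet,
    life_table: LifeTable,
    options: ModelOptions = ModelOptions(),
) -> dict[str, StrategyOutcome]:
    """Both arms on the same parameter set."""
    return {
        s: evaluate_strategy(params, life_table, s, options)
        for s in ("mri", "mri_ai")
    }


def compare(
    reference: StrategyOutcome, comparator: StrategyOutcome, wtp: float
) -> CEAResult:
    """Incremental comparison: comparator minus reference.

    The ICER (delta cost per delta QALY) is reported only when the
    incremental effect is nonzero and neither strategy dominates;
    otherwise a dominance/equivalence/cost-minimization label is set.
    """
    d_cost = comparator.cost - reference.cost
    d_eff = comparator.effect - reference.effect
    nmb = wtp * d_eff - d_cost
    icer: float | None = None
    if d_cost < 0.0 and d_eff > 0.0:
        status = "dominant"
    elif d_cost > 0.0 and d_eff < 0.0:
        status = "dominated"
    elif d_eff == 0.0:
        status = "equivalent" if d_cost == 0.0 else "cost-minimization"
    else:
        status = "icer"
        icer = d_cost / d_eff
    return CEAResult(
        reference=reference,
        comparator=comparator,
        wtp=wtp,
        delta_cost=d_cost,
        delta_effect=d_eff,
        icer=icer,
        status=status,
        nmb=nmb,
    )


def ai_cost_threshold(base: CEAResult, wtp: float) -> float:
    """Maximum AI price per application at the given WTP.

    ``base`` must be the MRI vs MRI+AI comparison computed at zero AI
    surcharge. Returns the unique surcharge at which the AI arm's ICER
    equals ``wtp`` (for wtp = 0: the dominance threshold, i.e. the
    base-case saving).
    """
    saving = -base.delta_cost          # MRI cost minus MRI+AI cost at price 0
    gain = base.delta_effect
    if gain < 0.0 and wtp > 0.0:
        warnings.warn(
            "AI arm loses QALYs; price threshold above the dominance point "
            "is undefined and the dominance threshold is returned",
            stacklevel=2,
        )
        return saving
    return saving + wtp * gain


@dataclass(frozen=True)
class ThresholdCurve:
    """Maximum AI price per application over a WTP grid."""

    wtp: np.ndarray
    max_ai_cost: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "max_ai_cost": self.max_ai_cost})


def threshold_curve(
    base: CEAResult, wtp_grid: np.ndarray | None = None
) -> ThresholdCurve:
    """Evaluate the AI price threshold on a WTP grid ($0-200k by default)."""
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    values = np.array([ai_cost_threshold(base, w) for w in grid])
    return ThresholdCurve(wtp=grid, max_ai_cost=values)
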