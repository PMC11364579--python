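"""Diagnostic decision tree feeding the Markov model.

Each strategy (MRI reading alone, MRI with AI support) images every
patient once and classifies the lesion as benign or malignant. Prevalence
and the strategy's sensitivity/specificity split the cohort into true
positives (resected malignancy), false positives (unnecessary surgery of a
benign lesion), true negatives, and false negatives (missed malignancy).
Each branch carries a one-time entry cost and starts the cohort in the
matching Markov state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigError, ModelOptions, ParameterSet
from .markov import N_STATES, State

__all__ = [
    "DiagnosticSplit",
    "EntryCosting",
    "classify",
    "entry_costs",
    "initial_distribution",
    "strategy_split",
]

OUTCOMES = ("tp", "fp", "tn", "fn")


@dataclass(frozen=True)
class DiagnosticSplit:
    """Cohort fractions by diagnostic outcome for one strategy."""

    p_tp: float
    p_fp: float
    p_tn: float
    p_fn: float
    strategy_label: str = ""

    def __post_init__(self) -> None:
        probs = (self.p_tp, self.p_fp, self.p_tn, self.p_fn)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("diagnostic fractions must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ConfigError("diagnostic fractions must sum to 1")

    @property
    def prevalence(self) -> float:
        return self.p_tp + self.p_fn


@dataclass(frozen=True)
class EntryCosting:
    """One-time entry cost and first-cycle utility per diagnostic outcome.

    The utilities duplicate, for inspection, the first-cycle state rewards
    that the Markov engine applies to each entry state; only the costs are
    charged separately (at t = 0, undiscounted).
    """

    cost: dict[str, float]
    utility: dict[str, float]

    def expected_cost(self, split: DiagnosticSplit) -> float:
        """Cohort-average entry cost under the given split."""
        masses = {"tp": split.p_tp, "fp": split.p_fp, "tn": split.p_tn, "fn": split.p_fn}
        return sum(masses[o] * self.cost[o] for o in OUTCOMES)


def classify(prevalence: float, sens: float, spec: float, label: str = "") -> DiagnosticSplit:
    """Split a cohort by test outcome.

    TP = prevalence*sens, FN = prevalence*(1-sens), TN = (1-prevalence)*spec,
    FP = (1-prevalence)*(1-spec).
    """
    for name, value in (("prevalence", prevalence), ("sens", sens), ("spec", spec)):
        if not 0.0 <= value <= 1.0:
            raise ConfigError(f"'{name}' must lie in [0, 1], got {value!r}")
    return DiagnosticSplit(
        p_tp=prevalence * sens,
        p_fn=prevalence * (1.0 - sens),
        p_tn=(1.0 - prevalence) * spec,
        p_fp=(1.0 - prevalence) * (1.0 - spec),
        strategy_label=label,
    )


def strategy_split(params: ParameterSet, strategy: str) -> DiagnosticSplit:
    """Diagnostic split for 'mri' or 'mri_ai' at the configured accuracy."""
    if strategy == "mri":
        return classify(params.prevalence, params.mri_sens, params.mri_spec, "MRI")
    if strategy == "mri_ai":
        return classify(params.prevalence, params.ai_sens, params.ai_spec, "MRI+AI")
    raise ConfigError(f"unknown strategy '{strategy}' (expected 'mri' or 'mri_ai')")


def entry_costs(
    split: DiagnosticSplit,
    params: ParameterSet,
    ai_arm: bool = False,
    options: ModelOptions = ModelOptions(),
) -> EntryCosting:
    """One-time costs and first-cycle utilities per diagnostic outcome.

    Every patient is imaged (cost_mri); the AI surcharge applies to every
    application in the AI arm. True positives undergo timely surgery, false
    positives unnecessary surgery (plus biopsy if the fp_includes_biopsy
    switch is on); negatives incur no further action.
    """
    base = params.cost_mri + (params.cost_ai_per_use if ai_arm else 0.0)
    fp_extra = params.cost_unnecessary_surgery + (
        params.cost_biopsy if options.fp_includes_biopsy else 0.0
    )
    return EntryCosting(
        cost={
            "tp": base + params.cost_timely_surgery,
            "fp": base + fp_extra,
            "tn": base,
            "fn": base,
        },
        utility={
            "tp": params.u_resected_y1,
            "fp": params.u_fp_y1,
            "tn": params.u_benign,
            "fn": params.u_unresected,
        },
    )


def initial_distribution(split: DiagnosticSplit) -> np.ndarray:
    """Initial Markov occupancy implied by the diagnostic outcome.

    TP enter the first post-resection year, FP the first post-unnecessary-
    surgery year, TN stay benign, FN carry an undetected malignancy.
    """
    vec = np.zeros(N_STATES)
    vec[State.RESECTED_Y1] = split.p_tp
    vec[State.BENIGN_POSTFP_Y1] = split.p_fp
    vec[State.BENIGN] = split.p_tn
    vec[State.UNDETECTED] = split.p_fn
    return vec
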