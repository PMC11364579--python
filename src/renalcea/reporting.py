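"""Plain-text result writers (CSV/JSON) shared by the CLI.

Every file starts with a comment header naming the configuration hash and
the random seed of the run, so outputs diff cleanly and stay traceable to
their inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .cea import CEAResult, ThresholdCurve
from .config import ParameterSet
from .markov import CohortTrace
from .sensitivity import PSAResult, TornadoEntry

__all__ = [
    "write_ceac",
    "write_scatter",
    "write_summary",
    "write_threshold_curve",
    "write_tornado",
    "write_trace",
]


def _header(params: ParameterSet, seed: int | None) -> str:
    seed_part = "" if seed is None else f" seed={seed}"
    return f"# renalcea config={params.config_hash()}{seed_part}\n"


def _write_csv(
    df: pd.DataFrame, path: Path, params: ParameterSet, seed: int | None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(params, seed))
        df.to_csv(fh, index=False)


def write_summary(
    result: CEAResult,
    thresholds: dict[str, float],
    params: ParameterSet,
    out_dir: Path,
    seed: int | None = None,
) -> None:
    payload = {
        "config": params.config_hash(),
        "seed": seed,
        **result.summary_row(),
        "ai_cost_thresholds": thresholds,
    }
    (out_dir / "summary.json").write_text(json.dumps(payload, indent=2) + "\n")
    _write_csv(pd.DataFrame([result.summary_row()]), out_dir / "summary.csv",
               params, seed)


def write_trace(
    trace: CohortTrace, path: Path, params: ParameterSet, seed: int | None = None
) -> None:
    _write_csv(trace.to_frame(), path, params, seed)


def write_tornado(
    entries: list[TornadoEntry],
    path: Path,
    params: ParameterSet,
    seed: int | None = None,
) -> None:
    df = pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "outcome_low": [e.outcome_low for e in entries],
            "outcome_high": [e.outcome_high for e in entries],
            "outcome_base": [e.outcome_base for e in entries],
            "width": [e.width for e in entries],
        }
    )
    _write_csv(df, path, params, seed)


def write_scatter(
    psa: PSAResult, path: Path, params: ParameterSet
) -> None:
    _write_csv(psa.to_frame(), path, params, psa.seed)


def write_ceac(psa: PSAResult, path: Path, params: ParameterSet) -> None:
    _write_csv(psa.ceac_frame(), path, params, psa.seed)


def write_threshold_curve(
    curve: ThresholdCurve, path: Path, params: ParameterSet, seed: int | None = None
) -> None:
    _write_csv(curve.to_frame(), path, params, seed)
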