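"""Model configuration: the base-case parameter set and period life tables.

The parameter set collects every quantity the economic model needs: the
pre-test probability that an incidentally detected renal lesion is
malignant, the diagnostic accuracy of MRI reading with and without AI
support, one-time diagnostic and surgical costs, long-term annual costs and
utility weights per health state, and the annual transition probabilities
of the Markov model.  Defaults are the published base case for a US
healthcare-payer perspective; every value can be overridden from a flat
YAML configuration file.

Age-dependent background mortality for patients carrying a localized tumor
comes from a period life table (age -> annual death probability ``qx``); a
transcription of the 2017 US total-population table for ages 63-73 ships
with the package.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "LifeTable",
    "ModelOptions",
    "ParameterSet",
    "PARAMETER_KINDS",
    "bundled_life_table",
    "default_parameters",
    "load_config",
    "load_life_table",
    "write_config",
]


class ConfigError(ValueError):
    """A configuration value violates the model's schema or bounds."""


# Classification of every parameter. The kind determines validation bounds
# and the PSA sampling family: probabilities and utilities are beta
# distributed, costs gamma distributed, structural constants are never
# sampled.
PARAMETER_KINDS: dict[str, str] = {
    "prevalence": "probability",
    "start_age": "structural",
    "horizon_cycles": "structural",
    "discount_rate": "structural",
    "wtp": "structural",
    "mri_sens": "probability",
    "mri_spec": "probability",
    "ai_sens": "probability",
    "ai_spec": "probability",
    "cost_biopsy": "cost",
    "cost_mri": "cost",
    "cost_cect": "cost",
    "cost_timely_surgery": "cost",
    "cost_unnecessary_surgery": "cost",
    "cost_localized_y1": "cost",
    "cost_localized_later": "cost",
    "cost_metastatic_y1": "cost",
    "cost_metastatic_later": "cost",
    "cost_ai_per_use": "cost",
    "u_benign": "utility",
    "u_fp_y1": "utility",
    "u_resected_y1": "utility",
    "u_resected_later": "utility",
    "u_unresected": "utility",
    "u_metastatic": "utility",
    "u_dead": "utility",
    "u_month_biopsy": "utility",
    "u_month_surgery": "utility",
    "p_non_r0": "probability",
    "p_fn_metastasis": "probability",
    "p_local_recurrence": "probability",
    "p_post_resection_metastasis": "probability",
    "p_recurrence_surgery_success": "probability",
    "p_death_metastatic": "probability",
    "p_death_surgery": "probability",
    "p_fn_detection": "probability",
    "benign_mortality": "probability",
}


@dataclass(frozen=True)
class ParameterSet:
    """Complete input-parameter set of the economic model.

    Defaults are the published base case. Probabilities and utilities live
    in [0, 1]; costs are nonnegative USD. ``cost_ai_per_use`` is the
    per-application surcharge of the AI algorithm, zero in the base case
    and swept by the threshold analysis.
    """

    # Cohort and analytic frame
    prevalence: float = 0.19          # pre-test probability of malignancy
    start_age: int = 63               # age at the diagnostic procedure
    horizon_cycles: int = 10          # annual cycles
    discount_rate: float = 0.03
    wtp: float = 100_000.0            # willingness to pay, USD per QALY

    # Diagnostic test performance
    mri_sens: float = 0.80
    mri_spec: float = 0.35
    ai_sens: float = 0.92
    ai_spec: float = 0.41

    # One-time (acute) costs, USD
    cost_biopsy: float = 1535.0
    cost_mri: float = 453.0
    cost_cect: float = 246.0
    cost_timely_surgery: float = 7652.0
    cost_unnecessary_surgery: float = 4884.0

    # Long-term annual costs, USD per year
    cost_localized_y1: float = 492.0
    cost_localized_later: float = 246.0
    cost_metastatic_y1: float = 70_703.0
    cost_metastatic_later: float = 34_716.0

    cost_ai_per_use: float = 0.0

    # Utility weights (QoL) per year in state
    u_benign: float = 1.0
    u_fp_y1: float = 0.995            # first year after unnecessary workup
    u_resected_y1: float = 0.97       # first year incl. resection
    u_resected_later: float = 1.0
    u_unresected: float = 1.0         # undetected lesion, asymptomatic
    u_metastatic: float = 0.66
    u_dead: float = 0.0

    # One-month QoL weights, used only by the optional monthly-composition
    # mode (see ModelOptions.compose_monthly_qol)
    u_month_biopsy: float = 0.995
    u_month_surgery: float = 0.7

    # Annual transition probabilities
    p_non_r0: float = 0.057
    p_fn_metastasis: float = 0.01
    p_local_recurrence: float = 0.018
    p_post_resection_metastasis: float = 0.0018
    p_recurrence_surgery_success: float = 0.412
    p_death_metastatic: float = 0.335
    p_death_surgery: float = 0.0
    p_fn_detection: float = 1.0       # detection of an initially missed lesion
    benign_mortality: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            kind = PARAMETER_KINDS[f.name]
            value = getattr(self, f.name)
            if not np.isfinite(value):
                raise ConfigError(f"parameter '{f.name}' must be finite, got {value!r}")
            if kind in ("probability", "utility") and not 0.0 <= value <= 1.0:
                raise ConfigError(
                    f"parameter '{f.name}' must lie in [0, 1], got {value!r}"
                )
            if kind == "cost" and value < 0.0:
                raise ConfigError(
                    f"parameter '{f.name}' must be nonnegative, got {value!r}"
                )
        if self.discount_rate < 0.0:
            raise ConfigError("parameter 'discount_rate' must be >= 0")
        if self.horizon_cycles < 1:
            raise ConfigError("parameter 'horizon_cycles' must be >= 1")
        if self.wtp < 0.0:
            raise ConfigError("parameter 'wtp' must be >= 0")
        if self.start_age < 0 or self.start_age != int(self.start_age):
            raise ConfigError("parameter 'start_age' must be a nonnegative integer")

    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the given fields overridden (re-validated)."""
        unknown = set(overrides) - PARAMETER_KINDS.keys()
        if unknown:
            raise ConfigError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def sampled_names(self) -> list[str]:
        """Parameters subject to probabilistic sensitivity analysis.

        Structural constants (age, horizon, discount rate, WTP) are fixed.
        Degenerate values -- probabilities/utilities at exactly 0 or 1 and
        zero costs -- admit no beta/gamma uncertainty and stay fixed too.
        """
        names = []
        for name, kind in PARAMETER_KINDS.items():
            value = getattr(self, name)
            if kind == "structural":
                continue
            if kind in ("probability", "utility") and value in (0.0, 1.0):
                continue
            if kind == "cost" and value == 0.0:
                continue
            names.append(name)
        return names

    def config_hash(self) -> str:
        """Short digest of the resolved parameter values, for output headers."""
        payload = repr(sorted(self.to_dict().items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass(frozen=True)
class ModelOptions:
    """Structural switches of the model.

    fp_includes_biopsy
        Charge the biopsy fee in addition to unnecessary surgery to false
        positives at entry. On by default: the workup of a suspicious
        lesion prices a biopsy before surgery, which is also why the FP
        first-year utility is a post-biopsy weight. Turn off to charge
        surgery only.
    compose_monthly_qol
        Blend first-year utilities as 11/12 of the annual weight plus 1/12
        of the one-month post-surgery weight. On by default, since the
        one-month QoL weights are model inputs; turn off to treat the
        annual first-year weights as already inclusive of the procedure.
    half_cycle
        Apply the standard half-cycle (trapezoidal) correction to state
        rewards. Off by default: rewards accrue at cycle start.
    """

    fp_includes_biopsy: bool = True
    compose_monthly_qol: bool = True
    half_cycle: bool = False


class LifeTable:
    """Period life table: annual death probability ``qx`` by integer age."""

    def __init__(self, ages: np.ndarray, qx: np.ndarray):
        ages = np.asarray(ages, dtype=int)
        qx = np.asarray(qx, dtype=float)
        if ages.ndim != 1 or ages.shape != qx.shape or ages.size == 0:
            raise ConfigError("life table needs matching 1-D 'age' and 'qx' columns")
        order = np.argsort(ages)
        ages, qx = ages[order], qx[order]
        if np.any(np.diff(ages) != 1):
            missing = int(ages[np.flatnonzero(np.diff(ages) != 1)[0]] + 1)
            raise ConfigError(f"life table ages must be contiguous; gap at age {missing}")
        if np.any((qx < 0.0) | (qx > 1.0)):
            bad = int(ages[np.flatnonzero((qx < 0.0) | (qx > 1.0))[0]])
            raise ConfigError(f"life table qx out of [0, 1] at age {bad}")
        self.ages = ages
        self.qx = qx

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def q(self, age: int) -> float:
        """Annual probability of death at exact integer age."""
        if not self.min_age <= age <= self.max_age:
            raise ConfigError(
                f"life table covers ages {self.min_age}-{self.max_age}; "
                f"age {age} requested"
            )
        return float(self.qx[age - self.min_age])

    def covers(self, start_age: int, cycles: int) -> bool:
        return self.min_age <= start_age and start_age + cycles <= self.max_age + 1

    def __iter__(self) -> Iterator[tuple[int, float]]:
        return zip(self.ages.tolist(), self.qx.tolist())

    def __len__(self) -> int:
        return self.ages.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_parameters() -> ParameterSet:
    """The published base case (AI surcharge set to zero)."""
    return ParameterSet()


def load_life_table(path: str | Path) -> LifeTable:
    """Read a two-column ``age,qx`` CSV (header optional)."""
    try:
        df = pd.read_csv(path, comment="#")
    except FileNotFoundError:
        raise ConfigError(f"life table file not found: {path}") from None
    if df.columns.size < 2:
        raise ConfigError("life table must have two columns: age, qx")
    first = str(df.columns[0])
    try:  # headerless file: the first row parsed as column names
        float(first)
    except ValueError:
        pass
    else:
        df = pd.read_csv(path, header=None, comment="#")
    df = df.iloc[:, :2]
    df.columns = ["age", "qx"]
    return LifeTable(df["age"].to_numpy(), df["qx"].to_numpy())


def bundled_life_table() -> LifeTable:
    """The bundled 2017 US total-population table, ages 63-73."""
    ref = resources.files("renalcea.data").joinpath("us_life_table_2017.csv")
    with resources.as_file(ref) as path:
        return load_life_table(path)


def load_config(
    path: str | Path,
) -> tuple[ParameterSet, ModelOptions, LifeTable | None]:
    """Read a YAML configuration file.

    Schema: an optional flat ``parameters:`` map (keys are ParameterSet
    field names; missing keys fall back to the base case), an optional
    ``options:`` map of structural switches, and an optional ``life_table:``
    path (resolved relative to the config file).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file is not valid YAML: {exc}") from None
    if not isinstance(raw, Mapping):
        raise ConfigError("config file must be a mapping at top level")

    unknown_top = set(raw) - {"parameters", "options", "life_table"}
    if unknown_top:
        raise ConfigError(f"unknown top-level config key(s): {sorted(unknown_top)}")

    params_map = raw.get("parameters") or {}
    if not isinstance(params_map, Mapping):
        raise ConfigError("'parameters' must be a flat key/value map")
    for key, value in params_map.items():
        if key not in PARAMETER_KINDS:
            raise ConfigError(f"unknown parameter '{key}' in config")
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigError(f"parameter '{key}' must be numeric, got {value!r}")
    params = default_parameters().replace(**dict(params_map))

    options_map = raw.get("options") or {}
    if not isinstance(options_map, Mapping):
        raise ConfigError("'options' must be a key/value map")
    valid_options = {f.name for f in fields(ModelOptions)}
    for key, value in options_map.items():
        if key not in valid_options:
            raise ConfigError(f"unknown option '{key}' in config")
        if not isinstance(value, bool):
            raise ConfigError(f"option '{key}' must be boolean, got {value!r}")
    options = ModelOptions(**dict(options_map))

    life_table = None
    if raw.get("life_table"):
        lt_path = Path(raw["life_table"])
        if not lt_path.is_absolute():
            lt_path = path.parent / lt_path
        life_table = load_life_table(lt_path)
    return params, options, life_table


def write_config(
    params: ParameterSet,
    path: str | Path,
    options: ModelOptions | None = None,
    life_table_path: str | None = None,
) -> None:
    """Write the fully resolved configuration as YAML (round-trips load_config)."""
    doc: dict = {"parameters": params.to_dict()}
    if options is not None:
        doc["options"] = dataclasses.asdict(options)
    if life_table_path is not None:
        doc["life_table"] = life_table_path
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
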