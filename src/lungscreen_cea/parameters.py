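"""Model parameter set: validation, distribution fitting, and sampling.

Every model input is a :class:`ParameterSpec` carrying a deterministic base
value, a (lower, upper) range used by one-way sensitivity analysis, and a
distribution family used by probabilistic sensitivity analysis (PSA).
Beta and Gamma distributions are fitted by method of moments from the range,
interpreting (lower, upper) as a symmetric 95% interval, i.e.
``sd = (upper - lower) / 3.92``.  This reproduces the base value as the
distribution mean by construction.
"""
from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "Distribution",
    "ParameterSpec",
    "ParameterSpecSet",
    "ParameterDraw",
    "ParameterError",
    "MissingParameterError",
    "BoundsError",
    "SchemaError",
    "InfeasibleMomentsError",
    "DegenerateIntervalError",
    "REQUIRED_PARAMETERS",
    "load_parameter_specs",
    "fit_beta_from_ci",
    "fit_gamma_from_ci",
    "sample_parameters",
]

#: Width of a symmetric 95% normal interval in standard-deviation units.
Z95_WIDTH = 3.92


class ParameterError(ValueError):
    """Base class for parameter validation and fitting errors."""


class MissingParameterError(ParameterError):
    """A required parameter is absent from the configuration."""


class BoundsError(ParameterError):
    """lower <= base <= upper is violated, or a value is out of domain."""


class SchemaError(ParameterError):
    """The configuration document is malformed."""


class InfeasibleMomentsError(ParameterError):
    """The requested (mean, sd) pair admits no Beta distribution."""


class DegenerateIntervalError(ParameterError):
    """A zero-width interval: the parameter is a point mass."""


class Distribution(str, Enum):
    BETA = "beta"
    GAMMA = "gamma"
    UNIFORM = "uniform"
    NORMAL = "normal"
    FIXED = "fixed"


# kind controls domain validation: probabilities/utilities in [0, 1],
# rates/costs non-negative, ages positive.
REQUIRED_PARAMETERS: dict[str, str] = {
    "prevalence": "probability",
    "sensitivity": "probability",
    "specificity": "probability",
    "p_early_screened": "probability",
    "p_early_clinical": "probability",
    "mortality_rate_early": "rate",
    "mortality_rate_advanced": "rate",
    "utility_no_cancer": "utility",
    "utility_early": "utility",
    "utility_advanced": "utility",
    "cost_diagnostic": "cost",
    "cost_staging": "cost",
    "cost_liquid_biopsy": "cost",
    "cost_treatment_early": "cost",
    "cost_treatment_advanced": "cost",
    "cost_chemo_early": "cost",
    "sigtap_adjustment_factor": "factor",
    "initial_age": "years",
    "discount_rate": "rate",
}

_UNIT_INTERVAL_KINDS = frozenset({"probability", "utility"})
_NON_NEGATIVE_KINDS = frozenset({"rate", "cost", "factor", "years"})


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter with its deterministic value and uncertainty."""

    name: str
    base: float
    lower: float
    upper: float
    distribution: Distribution
    source: str = ""
    kind: str = "factor"

    def __post_init__(self) -> None:
        if not (self.lower <= self.base <= self.upper):
            raise BoundsError(
                f"{self.name}: require lower <= base <= upper, got "
                f"({self.lower}, {self.base}, {self.upper})"
            )
        self.validate_value(self.base)
        self.validate_value(self.lower)
        self.validate_value(self.upper)
        if self.distribution is Distribution.BETA and self.kind not in _UNIT_INTERVAL_KINDS:
            raise SchemaError(f"{self.name}: beta distribution requires a [0, 1] parameter")
        if self.distribution is Distribution.GAMMA and self.lower < 0:
            raise SchemaError(f"{self.name}: gamma distribution requires non-negative support")

    def validate_value(self, value: float) -> None:
        """Check a realized value against this parameter's domain."""
        if not np.isfinite(value):
            raise BoundsError(f"{self.name}: non-finite value {value}")
        if self.kind in _UNIT_INTERVAL_KINDS and not (0.0 <= value <= 1.0):
            raise BoundsError(f"{self.name}: {value} outside [0, 1]")
        if self.kind in _NON_NEGATIVE_KINDS and value < 0.0:
            raise BoundsError(f"{self.name}: {value} is negative")

    @property
    def sd(self) -> float:
        """Implied standard deviation under the 95%-interval reading."""
        return (self.upper - self.lower) / Z95_WIDTH


class ParameterDraw(Mapping):
    """One realized value per parameter (a frozen name -> float mapping)."""

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        self._values = dict(values)

    def __getitem__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise MissingParameterError(f"parameter '{name}' missing from draw") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def replace(self, **overrides: float) -> "ParameterDraw":
        values = dict(self._values)
        values.update(overrides)
        return ParameterDraw(values)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ParameterDraw({self._values!r})"


@dataclass
class ParameterSpecSet:
    """The complete, validated parameter configuration of the model."""

    specs: dict[str, ParameterSpec]
    cohort_size: int = 1000
    cycle_length_years: float = 1.0
    wtp_thresholds: tuple[float, float] = (7017.54, 21052.62)

    def __post_init__(self) -> None:
        missing = [name for name in REQUIRED_PARAMETERS if name not in self.specs]
        if missing:
            raise MissingParameterError(f"missing parameters: {', '.join(missing)}")
        if self.cohort_size <= 0:
            raise SchemaError("cohort_size must be a positive integer")

    def __getitem__(self, name: str) -> ParameterSpec:
        try:
            return self.specs[name]
        except KeyError:
            raise MissingParameterError(f"unknown parameter '{name}'") from None

    def __contains__(self, name: str) -> bool:
        return name in self.specs

    def names(self) -> list[str]:
        """Parameter names in the fixed sampling order."""
        extras = sorted(set(self.specs) - set(REQUIRED_PARAMETERS))
        return list(REQUIRED_PARAMETERS) + extras

    def base_draw(self) -> ParameterDraw:
        """Deterministic draw with every parameter at its base value."""
        return ParameterDraw({name: self.specs[name].base for name in self.names()})

    def with_spec(self, spec: ParameterSpec) -> "ParameterSpecSet":
        specs = dict(self.specs)
        specs[spec.name] = spec
        return replace(self, specs=specs)


def _coerce_float(record: Mapping, key: str, name: str) -> float:
    try:
        return float(record[key])
    except KeyError:
        raise SchemaError(f"parameter '{name}': missing field '{key}'") from None
    except (TypeError, ValueError):
        raise SchemaError(f"parameter '{name}': field '{key}' is not numeric") from None


def load_parameter_specs(config: str | Path | Mapping) -> ParameterSpecSet:
    """Load and validate a parameter configuration.

    ``config`` may be a YAML/JSON file path or an already-parsed mapping with
    keys ``parameters`` (list of records), ``cohort_size``, ``wtp_thresholds``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as handle:
            document = yaml.safe_load(handle)
    else:
        document = dict(config)
    if not isinstance(document, Mapping) or "parameters" not in document:
        raise SchemaError("configuration must be a mapping with a 'parameters' list")

    specs: dict[str, ParameterSpec] = {}
    for record in document["parameters"]:
        name = record.get("name")
        if not name:
            raise SchemaError("parameter record without a name")
        if name in specs:
            raise SchemaError(f"duplicate parameter '{name}'")
        dist_raw = record.get("distribution")
        try:
            dist = Distribution(str(dist_raw).lower())
        except ValueError:
            raise SchemaError(f"parameter '{name}': unknown distribution '{dist_raw}'") from None
        specs[name] = ParameterSpec(
            name=name,
            base=_coerce_float(record, "base", name),
            lower=_coerce_float(record, "lower", name),
            upper=_coerce_float(record, "upper", name),
            distribution=dist,
            source=str(record.get("source", "")),
            kind=record.get("kind", REQUIRED_PARAMETERS.get(name, "factor")),
        )

    wtp = document.get("wtp_thresholds", (7017.54, 21052.62))
    if len(wtp) != 2:
        raise SchemaError("wtp_thresholds must hold exactly two values")
    return ParameterSpecSet(
        specs=specs,
        cohort_size=int(document.get("cohort_size", 1000)),
        cycle_length_years=float(document.get("cycle_length_years", 1.0)),
        wtp_thresholds=(float(wtp[0]), float(wtp[1])),
    )


def fit_beta_from_ci(mean: float, lower: float, upper: float) -> tuple[float, float]:
    """Method-of-moments Beta shapes from a mean and a symmetric 95% interval.

    Returns ``(alpha, beta)`` such that the fitted Beta has exactly the target
    mean and, to floating precision, the target sd ``(upper - lower) / 3.92``.
    """
    if not (0.0 < mean < 1.0):
        raise BoundsError(f"beta fit requires mean in (0, 1), got {mean}")
    if not (lower <= mean <= upper):
        raise BoundsError("beta fit requires lower <= mean <= upper")
    sd = (upper - lower) / Z95_WIDTH
    if sd == 0.0:
        raise DegenerateIntervalError("zero-width interval: treat as fixed point mass")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"sd^2={var:.3g} >= mean(1-mean)={mean * (1 - mean):.3g}: no Beta has these moments"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma_from_ci(mean: float, lower: float, upper: float) -> tuple[float, float]:
    """Method-of-moments Gamma (shape, scale) from a mean and 95% interval."""
    if mean <= 0.0:
        raise BoundsError(f"gamma fit requires mean > 0, got {mean}")
    sd = (upper - lower) / Z95_WIDTH
    if sd <= 0.0:
        raise BoundsError("gamma fit requires a positive-width interval")
    return (mean / sd) ** 2, sd * sd / mean


def _sample_one(spec: ParameterSpec, rng: np.random.Generator) -> float:
    if spec.distribution is Distribution.FIXED or spec.upper == spec.lower:
        return spec.base
    if spec.distribution is Distribution.BETA:
        alpha, beta = fit_beta_from_ci(spec.base, spec.lower, spec.upper)
        return float(rng.beta(alpha, beta))
    if spec.distribution is Distribution.GAMMA:
        shape, scale = fit_gamma_from_ci(spec.base, spec.lower, spec.upper)
        return float(rng.gamma(shape, scale))
    if spec.distribution is Distribution.UNIFORM:
        return float(rng.uniform(spec.lower, spec.upper))
    if spec.distribution is Distribution.NORMAL:
        # truncated to [lower, upper] to keep draws in-domain (e.g. ages)
        a = (spec.lower - spec.base) / spec.sd
        b = (spec.upper - spec.base) / spec.sd
        return float(stats.truncnorm.rvs(a, b, loc=spec.base, scale=spec.sd, random_state=rng))
    raise SchemaError(f"{spec.name}: unsupported distribution {spec.distribution}")


def sample_parameters(
    specs: ParameterSpecSet,
    rng: np.random.Generator,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> ParameterDraw:
    """Draw one value per parameter from its fitted distribution.

    Parameters listed in ``exclude`` (and ``fixed`` ones) return their base
    value.  Draws are consumed in the fixed order of :meth:`ParameterSpecSet.names`
    so that a given seed always yields the same draw.
    """
    values: dict[str, float] = {}
    for name in specs.names():
        spec = specs[name]
        if name in exclude:
            values[name] = spec.base
            continue
        try:
            values[name] = _sample_one(spec, rng)
        except ParameterError as err:
            raise type(err)(f"sampling '{name}': {err}") from err
    return ParameterDraw(values)
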