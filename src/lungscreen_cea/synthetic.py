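"""Synthetic inputs: the bundled parameter fixture and generated life tables.

The bundled fixture ships every model parameter (base, range, distribution).
General-population mortality is emulated with a Gompertz–Makeham hazard,
``mu(x) = c + a * exp(b * x)``, whose defaults produce adult death
probabilities of realistic magnitude for a middle-income country
(q(62) ≈ 0.013, strictly increasing with age).  Any user-supplied ``age,qx``
CSV can replace it without code changes.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

from .markov import LifeTable
from .parameters import (
    Distribution,
    ParameterSpec,
    ParameterSpecSet,
    load_parameter_specs,
)

__all__ = [
    "GompertzMakehamParams",
    "make_life_table",
    "base_case_fixture",
    "perturbed_fixture",
    "FIXTURE_RESOURCE",
]

FIXTURE_RESOURCE = "table1_base_case.yaml"


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Hazard ``mu(x) = makeham_c + gompertz_a * exp(gompertz_b * x)``."""

    makeham_c: float = 0.002
    gompertz_a: float = 3e-5
    gompertz_b: float = 0.095
    max_age: int = 100

    def __post_init__(self) -> None:
        if self.makeham_c < 0.0 or self.gompertz_a < 0.0 or self.gompertz_b <= 0.0:
            raise ValueError("require makeham_c >= 0, gompertz_a >= 0, gompertz_b > 0")
        if self.makeham_c + self.gompertz_a <= 0.0:
            raise ValueError("hazard must be positive at some age")
        if self.max_age < 1:
            raise ValueError("max_age must be >= 1")

    def hazard(self, age) -> np.ndarray:
        return self.makeham_c + self.gompertz_a * np.exp(self.gompertz_b * np.asarray(age, float))


def make_life_table(params: GompertzMakehamParams | None = None) -> LifeTable:
    """Annual life table ``qx(age) = 1 - exp(-mu(age))``, terminal qx = 1."""
    if params is None:
        params = GompertzMakehamParams()
    ages = np.arange(0, params.max_age + 1)
    qx = 1.0 - np.exp(-params.hazard(ages))
    qx = np.clip(qx, 0.0, 1.0)
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx).validate()


def base_case_fixture() -> ParameterSpecSet:
    """The bundled base-case parameter set, loaded and validated."""
    text = resources.files("lungscreen_cea.data").joinpath(FIXTURE_RESOURCE).read_text()
    return load_parameter_specs(yaml.safe_load(text))


def _clamped(spec: ParameterSpec, new_base: float) -> ParameterSpec:
    if spec.kind in ("probability", "utility"):
        new_base = float(np.clip(new_base, 0.0, 1.0))
    else:
        new_base = max(new_base, 0.0)
    lower = min(spec.lower, new_base)
    upper = max(spec.upper, new_base)
    return replace(spec, base=new_base, lower=lower, upper=upper)


def perturbed_fixture(rng: np.random.Generator, relative_noise: float) -> ParameterSpecSet:
    """Fixture with base values jittered by ±``relative_noise`` (for tests).

    Bounds are re-ordered and values re-clamped so every invariant of the
    parameter set still holds; property tests use this to avoid depending on
    the exact fixture numbers.
    """
    if not (0.0 <= relative_noise < 0.5):
        raise ValueError("relative_noise must be in [0, 0.5)")
    specs = base_case_fixture()
    if relative_noise == 0.0:
        return specs
    out = specs
    for name in specs.names():
        spec = specs[name]
        eps = rng.uniform(-relative_noise, relative_noise)
        out = out.with_spec(_clamped(spec, spec.base * (1.0 + eps)))
    return out
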