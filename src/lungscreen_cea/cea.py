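"""Cost-effectiveness layer: ICERs, NMB, threshold search, named scenarios.

Costs are reported at cohort scale (default 1,000 individuals), effectiveness
both per person and as cohort QALYs, matching the mixed convention of
published screening evaluations.  The ICER is invariant to cohort size.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .decision_tree import Strategy, evaluate_tree
from .markov import CohortTrace, LifeTable, ModelSettings, annual_rate_from_survival, run_cohort
from .parameters import MissingParameterError, ParameterDraw, ParameterSpecSet

__all__ = [
    "StrategyResult",
    "CEAResult",
    "BaseCaseResult",
    "ThresholdResult",
    "run_strategy",
    "run_deterministic",
    "compute_cea",
    "net_monetary_benefit",
    "threshold_prevalence",
    "scenario_overrides",
    "run_scenario",
    "SCENARIOS",
]


@dataclass(frozen=True)
class StrategyResult:
    strategy: Strategy
    total_cost: float              # USD, cohort scale
    total_qaly_per_person: float
    total_qaly_cohort: float
    cohort_size: int
    trace: CohortTrace

    def as_dict(self) -> dict:
        return {
            "strategy": self.strategy.value,
            "total_cost_usd": self.total_cost,
            "total_qaly_per_person": self.total_qaly_per_person,
            "total_qaly_cohort": self.total_qaly_cohort,
            "cohort_size": self.cohort_size,
        }


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of the alternative against the reference."""

    delta_cost: float      # USD, cohort scale
    delta_effect: float    # QALYs, cohort scale
    icer: float | None     # USD/QALY; None when dominance/undefined applies
    dominance: str | None  # "dominant", "dominated", "undefined-ratio" or None

    def as_dict(self) -> dict:
        return {
            "delta_cost_usd": self.delta_cost,
            "delta_effect_qaly": self.delta_effect,
            "icer_usd_per_qaly": self.icer,
            "dominance": self.dominance,
        }


@dataclass(frozen=True)
class BaseCaseResult:
    no_screening: StrategyResult
    screening: StrategyResult
    cea: CEAResult


@dataclass(frozen=True)
class ThresholdResult:
    prevalence: float | None
    converged: bool
    iterations: int
    wtp: float
    bracket: tuple[float, float]


def run_strategy(
    strategy: Strategy,
    draw: ParameterDraw,
    table: LifeTable,
    cohort_size: int = 1000,
    settings: ModelSettings = ModelSettings(),
) -> StrategyResult:
    """Decision tree + Markov cohort run for one strategy at one draw."""
    branches = evaluate_tree(strategy, draw)
    trace = run_cohort(branches, draw, table, settings)
    return StrategyResult(
        strategy=Strategy(strategy),
        total_cost=trace.total_cost_per_person * cohort_size,
        total_qaly_per_person=trace.total_qaly_per_person,
        total_qaly_cohort=trace.total_qaly_per_person * cohort_size,
        cohort_size=cohort_size,
        trace=trace,
    )


def compute_cea(ref: StrategyResult, alt: StrategyResult) -> CEAResult:
    """Incremental cost, incremental effect and their ratio (or dominance)."""
    delta_cost = alt.total_cost - ref.total_cost
    delta_effect = alt.total_qaly_cohort - ref.total_qaly_cohort
    if delta_effect == 0.0:
        dominance = "undefined-ratio" if delta_cost != 0.0 else None
        return CEAResult(delta_cost, delta_effect, None, dominance)
    if delta_cost < 0.0 and delta_effect > 0.0:
        return CEAResult(delta_cost, delta_effect, None, "dominant")
    if delta_cost > 0.0 and delta_effect < 0.0:
        return CEAResult(delta_cost, delta_effect, None, "dominated")
    return CEAResult(delta_cost, delta_effect, delta_cost / delta_effect, None)


def run_deterministic(
    specs: ParameterSpecSet,
    table: LifeTable,
    overrides: Mapping[str, float] | None = None,
    settings: ModelSettings = ModelSettings(),
) -> BaseCaseResult:
    """Deterministic run of both strategies at base values plus overrides."""
    draw = specs.base_draw()
    if overrides:
        unknown = set(overrides) - set(draw)
        if unknown:
            raise MissingParameterError(f"unknown override(s): {', '.join(sorted(unknown))}")
        draw = draw.replace(**overrides)
    ref = run_strategy(Strategy.NO_SCREENING, draw, table, specs.cohort_size, settings)
    alt = run_strategy(Strategy.SCREENING, draw, table, specs.cohort_size, settings)
    return BaseCaseResult(no_screening=ref, screening=alt, cea=compute_cea(ref, alt))


def net_monetary_benefit(result: CEAResult, wtp: float) -> float:
    """``wtp * delta_effect - delta_cost`` at willingness-to-pay ``wtp``."""
    if wtp < 0.0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * result.delta_effect - result.delta_cost


def _icer_at_prevalence(
    specs: ParameterSpecSet, table: LifeTable, prevalence: float, settings: ModelSettings
) -> float:
    result = run_deterministic(specs, table, {"prevalence": prevalence}, settings)
    if result.cea.icer is None:
        # dominant screening counts as "below any threshold" for the search
        return -math.inf if result.cea.dominance == "dominant" else math.inf
    return result.cea.icer


def threshold_prevalence(
    specs: ParameterSpecSet,
    table: LifeTable,
    wtp: float,
    bracket: tuple[float, float] = (0.005, 0.20),
    tol: float = 1e-4,
    max_iter: int = 60,
    settings: ModelSettings = ModelSettings(),
) -> ThresholdResult:
    """Prevalence at which the ICER crosses ``wtp`` (bisection, others at base).

    The ICER decreases with prevalence, so a crossing exists when
    ``ICER(lo) > wtp > ICER(hi)``; otherwise a no-crossing result is returned.
    """
    lo, hi = bracket
    f_lo = _icer_at_prevalence(specs, table, lo, settings) - wtp
    f_hi = _icer_at_prevalence(specs, table, hi, settings) - wtp
    if f_lo == 0.0:
        return ThresholdResult(lo, True, 0, wtp, bracket)
    if f_hi == 0.0:
        return ThresholdResult(hi, True, 0, wtp, bracket)
    if f_lo * f_hi > 0.0:
        return ThresholdResult(None, False, 0, wtp, bracket)
    iterations = 0
    while hi - lo > tol and iterations < max_iter:
        mid = 0.5 * (lo + hi)
        f_mid = _icer_at_prevalence(specs, table, mid, settings) - wtp
        iterations += 1
        if f_mid == 0.0:
            return ThresholdResult(mid, True, iterations, wtp, bracket)
        if f_lo * f_mid < 0.0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return ThresholdResult(0.5 * (lo + hi), True, iterations, wtp, bracket)


#: Named scenarios mapping to parameter overrides.  ``inca_survival`` replaces
#: the five-year survival basis (53.5% early / 3.9% advanced) with the values
#: reported by the Brazilian National Cancer Institute (25.0% / 2.5%).
SCENARIOS: dict[str, dict[str, float]] = {
    "inca_survival": {
        "mortality_rate_early": annual_rate_from_survival(0.25, 5.0),
        "mortality_rate_advanced": annual_rate_from_survival(0.025, 5.0),
    }
}


def scenario_overrides(name: str) -> dict[str, float]:
    try:
        return dict(SCENARIOS[name])
    except KeyError:
        raise KeyError(
            f"unknown scenario '{name}'; available: {', '.join(sorted(SCENARIOS))}"
        ) from None


def run_scenario(
    specs: ParameterSpecSet,
    overrides: Mapping[str, float] | None,
    table: LifeTable,
    scenario: str | None = None,
    settings: ModelSettings = ModelSettings(),
) -> BaseCaseResult:
    """Deterministic run with explicit and/or named-scenario overrides."""
    merged: dict[str, float] = {}
    if scenario is not None:
        merged.update(scenario_overrides(scenario))
    if overrides:
        merged.update(overrides)
    return run_deterministic(specs, table, merged, settings)
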