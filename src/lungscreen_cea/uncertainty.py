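"""Sensitivity analyses: tornado, probabilistic Monte Carlo, CEAC.

The tornado analysis re-runs the deterministic model with one parameter at a
time set to its lower and upper bound.  The PSA draws every parameter from
its fitted distribution (common draw across both strategy arms per iteration)
and records paired incremental cost/effect.  Every parameter with a declared
distribution is sampled, including the discount rate and the SIGTAP
adjustment factor (both Uniform); pass ``exclude`` to hold methodological
quantities at their base value instead.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import compute_cea, run_deterministic, run_strategy
from .decision_tree import Strategy
from .markov import LifeTable, ModelSettings
from .parameters import ParameterSpecSet, sample_parameters

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "CEACurve",
    "DEFAULT_PSA_EXCLUDE",
    "DEFAULT_WTP_GRID",
    "tornado",
    "tornado_frame",
    "run_psa",
    "percentile_interval",
    "ceac",
]

#: Methodological parameters one may wish to hold fixed in the PSA.
METHODOLOGICAL_PARAMETERS = frozenset({"discount_rate", "sigtap_adjustment_factor"})
DEFAULT_PSA_EXCLUDE: frozenset[str] = frozenset()
DEFAULT_WTP_GRID = np.arange(0.0, 150_001.0, 1_000.0)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_at_lower: float | None
    icer_at_upper: float | None
    label_at_lower: str | None = None
    label_at_upper: str | None = None

    @property
    def range_width(self) -> float:
        if self.icer_at_lower is None or self.icer_at_upper is None:
            return float("inf")  # dominance flips rank as maximally influential
        return abs(self.icer_at_upper - self.icer_at_lower)


def tornado(
    specs: ParameterSpecSet,
    table: LifeTable,
    settings: ModelSettings = ModelSettings(),
) -> list[TornadoEntry]:
    """One-way deterministic sensitivity analysis, widest ICER range first."""
    entries = []
    for name in specs.names():
        spec = specs[name]
        results = {}
        for end, value in (("lower", spec.lower), ("upper", spec.upper)):
            cea = run_deterministic(specs, table, {name: value}, settings).cea
            results[end] = (cea.icer, cea.dominance)
        entries.append(
            TornadoEntry(
                parameter=name,
                icer_at_lower=results["lower"][0],
                icer_at_upper=results["upper"][0],
                label_at_lower=results["lower"][1],
                label_at_upper=results["upper"][1],
            )
        )
    entries.sort(key=lambda e: e.range_width, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "icer_at_lower": [e.icer_at_lower for e in entries],
            "icer_at_upper": [e.icer_at_upper for e in entries],
            "range_width": [e.range_width for e in entries],
        }
    )


@dataclass
class PSAResult:
    """Paired incremental (cost, effect) per Monte Carlo iteration."""

    delta_cost: np.ndarray    # USD, cohort scale
    delta_effect: np.ndarray  # QALYs, cohort scale
    seed: int
    n: int

    def icers(self) -> np.ndarray:
        """Per-draw ICERs among draws with positive incremental effect."""
        mask = self.delta_effect > 0.0
        return self.delta_cost[mask] / self.delta_effect[mask]

    def median_icer(self) -> float:
        """Median per-draw ICER (draws with non-positive ΔE excluded)."""
        return float(np.median(self.icers()))

    def dominance_counts(self) -> dict[str, int]:
        dominant = int(np.sum((self.delta_cost < 0) & (self.delta_effect > 0)))
        dominated = int(np.sum((self.delta_cost > 0) & (self.delta_effect < 0)))
        return {"dominant": dominant, "dominated": dominated}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n),
                "delta_cost": self.delta_cost,
                "delta_effect": self.delta_effect,
            }
        )


def run_psa(
    specs: ParameterSpecSet,
    table: LifeTable,
    n: int,
    seed: int,
    exclude: frozenset[str] = DEFAULT_PSA_EXCLUDE,
    settings: ModelSettings = ModelSettings(),
) -> PSAResult:
    """``n`` Monte Carlo iterations; one parameter draw feeds both arms."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    delta_cost = np.empty(n)
    delta_effect = np.empty(n)
    for i in range(n):
        draw = sample_parameters(specs, rng, exclude=exclude)
        ref = run_strategy(Strategy.NO_SCREENING, draw, table, specs.cohort_size, settings)
        alt = run_strategy(Strategy.SCREENING, draw, table, specs.cohort_size, settings)
        delta_cost[i] = alt.total_cost - ref.total_cost
        delta_effect[i] = alt.total_qaly_cohort - ref.total_qaly_cohort
    return PSAResult(delta_cost=delta_cost, delta_effect=delta_effect, seed=seed, n=n)


def percentile_interval(
    values, lo_pct: float = 2.5, hi_pct: float = 97.5
) -> tuple[float, float]:
    """Empirical percentile interval with linear order-statistic interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty collection")
    lo, hi = np.percentile(values, [lo_pct, hi_pct], method="linear")
    return float(lo), float(hi)


@dataclass(frozen=True)
class CEACurve:
    """Probability that screening is cost-effective along a WTP grid."""

    wtp_grid: np.ndarray
    prob_cost_effective: np.ndarray

    def crossing(self, probability: float = 0.5) -> float | None:
        """Smallest grid WTP with acceptability above ``probability``."""
        above = self.prob_cost_effective > probability
        if not above.any():
            return None
        return float(self.wtp_grid[int(np.argmax(above))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wtp": self.wtp_grid, "probability_cost_effective": self.prob_cost_effective}
        )


def ceac(psa: PSAResult, wtp_grid=None) -> CEACurve:
    """Fraction of draws with positive net monetary benefit per WTP point."""
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) < 0):
        raise ValueError("wtp_grid must be non-empty and ascending")
    nmb = grid[:, None] * psa.delta_effect[None, :] - psa.delta_cost[None, :]
    return CEACurve(wtp_grid=grid, prob_cost_effective=(nmb > 0.0).mean(axis=1))
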