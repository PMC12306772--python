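"""Diagnostic decision tree: test outcomes to initial states and upfront costs.

Two comparators are modelled.  Under *no screening*, lung cancer is found by
clinical suspicion, with a clinical stage-at-diagnosis mix.  Under *screening*,
an autoantibody liquid-biopsy test stratifies the cohort by test result:
true positives are diagnosed with the (more favourable) screen-detected stage
mix, false negatives fall back to the clinical pathway, false positives incur
a confirmatory work-up but remain cancer-free, and true negatives only pay
for the test.  All diagnosis happens at cycle 0; the branch probabilities and
upfront costs feed the Markov cohort engine.

Diagnostic and staging work-up costs are SIGTAP federal reimbursements and are
scaled by the table adjustment factor (base 2.84) to approximate the full
public cost; the liquid-biopsy price is a market price and is not scaled.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .parameters import ParameterDraw

__all__ = [
    "Strategy",
    "Branch",
    "BranchSet",
    "evaluate_tree",
    "branch_upfront_cost",
    "effective_workup_costs",
    "branches_to_frame",
]

PROBABILITY_TOL = 1e-12


class Strategy(str, Enum):
    NO_SCREENING = "no_screening"
    SCREENING = "screening"


class HealthState(str, Enum):
    NO_CANCER = "no_cancer"
    EARLY_STAGE = "early_stage"
    ADVANCED_STAGE = "advanced_stage"


@dataclass(frozen=True)
class Branch:
    label: str
    initial_state: HealthState
    probability: float
    upfront_cost: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"branch '{self.label}': probability {self.probability} outside [0, 1]")
        if self.upfront_cost < 0.0:
            raise ValueError(f"branch '{self.label}': negative upfront cost")


@dataclass(frozen=True)
class BranchSet:
    strategy: Strategy
    branches: tuple[Branch, ...]

    def __post_init__(self) -> None:
        total = sum(b.probability for b in self.branches)
        if abs(total - 1.0) > PROBABILITY_TOL:
            raise ValueError(f"{self.strategy.value}: branch probabilities sum to {total!r}, not 1")

    def state_probabilities(self) -> dict[HealthState, float]:
        """Initial Markov state occupancy implied by the tree."""
        out = {state: 0.0 for state in HealthState}
        for b in self.branches:
            out[b.initial_state] += b.probability
        return out

    def expected_upfront_cost(self) -> float:
        """Probability-weighted upfront cost per person (USD)."""
        return sum(b.probability * b.upfront_cost for b in self.branches)


def effective_workup_costs(draw: ParameterDraw) -> tuple[float, float]:
    """(diagnostic, staging) work-up costs after the SIGTAP adjustment factor."""
    factor = draw["sigtap_adjustment_factor"]
    return draw["cost_diagnostic"] * factor, draw["cost_staging"] * factor


# label -> (strategy, initial state, cost components)
_BRANCH_COSTS: dict[str, tuple[Strategy, HealthState, bool, bool, bool]] = {
    # label: (strategy, state, pays_biopsy, pays_diagnostic, pays_staging)
    "clinical-early": (Strategy.NO_SCREENING, HealthState.EARLY_STAGE, False, True, False),
    "clinical-advanced": (Strategy.NO_SCREENING, HealthState.ADVANCED_STAGE, False, True, True),
    "no-cancer": (Strategy.NO_SCREENING, HealthState.NO_CANCER, False, False, False),
    "tp-early": (Strategy.SCREENING, HealthState.EARLY_STAGE, True, True, False),
    "tp-advanced": (Strategy.SCREENING, HealthState.ADVANCED_STAGE, True, True, True),
    "fn-early": (Strategy.SCREENING, HealthState.EARLY_STAGE, True, True, False),
    "fn-advanced": (Strategy.SCREENING, HealthState.ADVANCED_STAGE, True, True, True),
    "fp": (Strategy.SCREENING, HealthState.NO_CANCER, True, True, False),
    "tn": (Strategy.SCREENING, HealthState.NO_CANCER, True, False, False),
}


def branch_upfront_cost(label: str, draw: ParameterDraw) -> float:
    """Upfront cost (USD) of one diagnostic-outcome branch.

    Every screened individual pays the liquid-biopsy price (false negatives
    included); a positive test or clinical suspicion triggers the diagnostic
    work-up; advanced-stage diagnoses add invasive staging.
    """
    try:
        _, _, pays_biopsy, pays_diag, pays_staging = _BRANCH_COSTS[label]
    except KeyError:
        raise KeyError(f"unknown branch label '{label}'") from None
    c_diag, c_staging = effective_workup_costs(draw)
    cost = 0.0
    if pays_biopsy:
        cost += draw["cost_liquid_biopsy"]
    if pays_diag:
        cost += c_diag
    if pays_staging:
        cost += c_staging
    return cost


def evaluate_tree(strategy: Strategy, draw: ParameterDraw) -> BranchSet:
    """Resolve the decision tree for one strategy at one parameter draw."""
    strategy = Strategy(strategy)
    pi = draw["prevalence"]
    q_clin = draw["p_early_clinical"]

    if strategy is Strategy.NO_SCREENING:
        probs = {
            "clinical-early": pi * q_clin,
            "clinical-advanced": pi * (1.0 - q_clin),
            "no-cancer": 1.0 - pi,
        }
    else:
        se = draw["sensitivity"]
        sp = draw["specificity"]
        q_screen = draw["p_early_screened"]
        probs = {
            "tp-early": pi * se * q_screen,
            "tp-advanced": pi * se * (1.0 - q_screen),
            "fn-early": pi * (1.0 - se) * q_clin,
            "fn-advanced": pi * (1.0 - se) * (1.0 - q_clin),
            "fp": (1.0 - pi) * (1.0 - sp),
            "tn": (1.0 - pi) * sp,
        }

    branches = tuple(
        Branch(
            label=label,
            initial_state=_BRANCH_COSTS[label][1],
            probability=p,
            upfront_cost=branch_upfront_cost(label, draw),
        )
        for label, p in probs.items()
    )
    return BranchSet(strategy=strategy, branches=branches)


def branches_to_frame(branch_set: BranchSet) -> pd.DataFrame:
    """Serializable view: strategy, label, initial_state, probability, cost."""
    return pd.DataFrame(
        {
            "strategy": branch_set.strategy.value,
            "label": [b.label for b in branch_set.branches],
            "initial_state": [b.initial_state.value for b in branch_set.branches],
            "probability": [b.probability for b in branch_set.branches],
            "upfront_cost_usd": [b.upfront_cost for b in branch_set.branches],
        }
    )
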