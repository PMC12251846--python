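"""2024-2028 budget-impact projection of smart-inhaler policy configurations.

Five policy configurations are compared against the regular reusable
inhaler benchmark (policy R):

* ``SR1`` / ``SR2`` / ``SR3`` — *default* policy with module design A / B / C:
  every patient receives the smart prototype, and the learners (the
  ``learned_fraction`` of the cohort) additionally receive reduced-content
  cartridges whose content reduction follows the year's delivery-rate gain.
* ``SR2M`` / ``SR3M`` — *alternative* policy with design B / C: only
  non-learners keep the smart prototype (with standard cartridges); the
  learners no longer need device feedback and step down to regular reusable
  inhalers with reduced-content cartridges.

Savings are always expressed against the all-smart, standard-cartridge
cohort cost of the same design version and treatment pattern, so that
cost + savings = baseline holds per year in both units (EUR and SCC-EUR).
The simplified ICER against the benchmark is the arithmetic cost difference
(no QALY denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .costs import (
    CohortSpec,
    TreatmentPattern,
    UnitCosts,
    UnitFootprints,
    annual_pattern_cost_eur,
    annual_pattern_scc_eur,
    reduced_cartridge_cost_eur,
    reduced_cartridge_scc_eur,
)

__all__ = [
    "PolicyConfig",
    "POLICIES",
    "ProjectionResult",
    "project_default_policy",
    "project_alternative_policy",
    "benchmark_reusable",
    "project_policy",
    "icer_pair",
]


class PolicyConfigError(ValueError):
    """Raised when a policy id, design version and mode are inconsistent."""


@dataclass(frozen=True)
class PolicyConfig:
    policy_id: str
    design_version: Optional[str]
    mode: str  # default | alternative | benchmark

    _VALID = {
        "SR1": ("A", "default"),
        "SR2": ("B", "default"),
        "SR3": ("C", "default"),
        "SR2M": ("B", "alternative"),
        "SR3M": ("C", "alternative"),
        "R": (None, "benchmark"),
    }

    def __post_init__(self) -> None:
        expected = self._VALID.get(self.policy_id)
        if expected is None:
            raise PolicyConfigError(f"unknown policy id {self.policy_id!r}")
        if (self.design_version, self.mode) != expected:
            raise PolicyConfigError(
                f"policy {self.policy_id} requires design_version={expected[0]!r}, "
                f"mode={expected[1]!r}"
            )


POLICIES: Mapping[str, PolicyConfig] = {
    pid: PolicyConfig(pid, *spec) for pid, spec in PolicyConfig._VALID.items()
}


@dataclass(frozen=True)
class ProjectionResult:
    """Per-year and mean cohort costs and savings of one policy/pattern cell."""

    policy_id: str
    pattern_id: int
    cost_eur: pd.Series
    cost_scc_eur: pd.Series
    savings_eur: pd.Series
    savings_scc_eur: pd.Series

    @property
    def years(self) -> tuple:
        return tuple(self.cost_eur.index)

    @property
    def mean_cost_eur(self) -> float:
        return float(self.cost_eur.mean())

    @property
    def mean_cost_scc_eur(self) -> float:
        return float(self.cost_scc_eur.mean())

    @property
    def mean_savings_eur(self) -> float:
        return float(self.savings_eur.mean())

    @property
    def mean_savings_scc_eur(self) -> float:
        return float(self.savings_scc_eur.mean())


def _smart_standard_baseline(pattern, version, cohort, costs, footprints):
    """All-smart, standard-cartridge cohort cost (the savings baseline)."""
    eur = annual_pattern_cost_eur(pattern, version, costs.cartridge_eur, cohort.n_patients, costs)
    scc = annual_pattern_scc_eur(
        pattern, version, footprints.cartridge_kg, cohort.n_patients, footprints
    )
    return eur, scc


def project_default_policy(
    policy: PolicyConfig,
    pattern: TreatmentPattern,
    cohort: CohortSpec,
    costs: UnitCosts = UnitCosts(),
    footprints: UnitFootprints = UnitFootprints(),
) -> ProjectionResult:
    """Default policy: smart prototypes for all, reduced cartridges for learners.

    Per year the cartridge price (and footprint) is blended: the learned
    fraction pays the reduced-content price at that year's gain, the rest
    the standard price; every patient carries the electronic module.
    """
    if policy.mode != "default":
        raise PolicyConfigError(f"policy {policy.policy_id} is not a default-mode policy")
    f = cohort.learned_fraction
    base_eur, base_scc = _smart_standard_baseline(
        pattern, policy.design_version, cohort, costs, footprints
    )
    cost_eur, cost_scc = {}, {}
    for year, gain in cohort.gain_schedule.items():
        blended_eur = f * reduced_cartridge_cost_eur(gain, costs) + (1 - f) * costs.cartridge_eur
        blended_kg = footprints.cartridge_kg * (1 - f * gain / 100.0)
        cost_eur[year] = annual_pattern_cost_eur(
            pattern, policy.design_version, blended_eur, cohort.n_patients, costs
        )
        cost_scc[year] = annual_pattern_scc_eur(
            pattern, policy.design_version, blended_kg, cohort.n_patients, footprints
        )
    cost_eur = pd.Series(cost_eur)
    cost_scc = pd.Series(cost_scc)
    return ProjectionResult(
        policy_id=policy.policy_id,
        pattern_id=pattern.pattern_id,
        cost_eur=cost_eur,
        cost_scc_eur=cost_scc,
        savings_eur=base_eur - cost_eur,
        savings_scc_eur=base_scc - cost_scc,
    )


def project_alternative_policy(
    policy: PolicyConfig,
    pattern: TreatmentPattern,
    cohort: CohortSpec,
    costs: UnitCosts = UnitCosts(),
    footprints: UnitFootprints = UnitFootprints(),
) -> ProjectionResult:
    """Alternative policy: smart prototypes only for non-learners.

    Learners step down to regular reusable inhalers (no module) with
    reduced-content cartridges; non-learners keep the smart prototype with
    standard cartridges.  Savings are measured against the all-smart,
    standard-cartridge baseline of the same design version.
    """
    if policy.mode != "alternative":
        raise PolicyConfigError(f"policy {policy.policy_id} is not an alternative-mode policy")
    f = cohort.learned_fraction
    n = cohort.n_patients
    base_eur, base_scc = _smart_standard_baseline(
        pattern, policy.design_version, cohort, costs, footprints
    )
    cost_eur, cost_scc = {}, {}
    for year, gain in cohort.gain_schedule.items():
        smart_eur = annual_pattern_cost_eur(
            pattern, policy.design_version, costs.cartridge_eur, (1 - f) * n, costs
        )
        regular_eur = annual_pattern_cost_eur(
            pattern, None, reduced_cartridge_cost_eur(gain, costs), f * n, costs
        )
        cost_eur[year] = smart_eur + regular_eur
        smart_scc = annual_pattern_scc_eur(
            pattern, policy.design_version, footprints.cartridge_kg, (1 - f) * n, footprints
        )
        reduced_kg = footprints.cartridge_kg * (1 - gain / 100.0)
        regular_scc = annual_pattern_scc_eur(pattern, None, reduced_kg, f * n, footprints)
        cost_scc[year] = smart_scc + regular_scc
    cost_eur = pd.Series(cost_eur)
    cost_scc = pd.Series(cost_scc)
    return ProjectionResult(
        policy_id=policy.policy_id,
        pattern_id=pattern.pattern_id,
        cost_eur=cost_eur,
        cost_scc_eur=cost_scc,
        savings_eur=base_eur - cost_eur,
        savings_scc_eur=base_scc - cost_scc,
    )


def benchmark_reusable(
    pattern: TreatmentPattern,
    cohort: CohortSpec,
    costs: UnitCosts = UnitCosts(),
    footprints: UnitFootprints = UnitFootprints(),
) -> ProjectionResult:
    """Benchmark policy R: regular inhalers, standard cartridges, no modules.

    Its cost is flat across years and independent of any design version;
    savings are identically zero (the benchmark is its own reference).
    """
    years = list(cohort.gain_schedule.index)
    eur = annual_pattern_cost_eur(pattern, None, costs.cartridge_eur, cohort.n_patients, costs)
    scc = annual_pattern_scc_eur(
        pattern, None, footprints.cartridge_kg, cohort.n_patients, footprints
    )
    zero = pd.Series(0.0, index=years)
    return ProjectionResult(
        policy_id="R",
        pattern_id=pattern.pattern_id,
        cost_eur=pd.Series(eur, index=years, dtype=float),
        cost_scc_eur=pd.Series(scc, index=years, dtype=float),
        savings_eur=zero,
        savings_scc_eur=zero.copy(),
    )


def project_policy(
    policy: PolicyConfig,
    pattern: TreatmentPattern,
    cohort: CohortSpec,
    costs: UnitCosts = UnitCosts(),
    footprints: UnitFootprints = UnitFootprints(),
) -> ProjectionResult:
    """Dispatch on the policy mode (default / alternative / benchmark)."""
    if policy.mode == "default":
        return project_default_policy(policy, pattern, cohort, costs, footprints)
    if policy.mode == "alternative":
        return project_alternative_policy(policy, pattern, cohort, costs, footprints)
    return benchmark_reusable(pattern, cohort, costs, footprints)


def icer_pair(policy_result: ProjectionResult, benchmark_result: ProjectionResult) -> tuple:
    """Simplified ICER: mean-cost difference (policy - benchmark), both units.

    No QALY denominator — the comparison assumes equal clinical benefit, so
    the decision rule is simply which alternative is less costly.
    """
    if policy_result.years != benchmark_result.years:
        raise ValueError("ICER requires projections over the same period")
    if policy_result.pattern_id != benchmark_result.pattern_id:
        raise ValueError("ICER requires projections under the same treatment pattern")
    return (
        policy_result.mean_cost_eur - benchmark_result.mean_cost_eur,
        policy_result.mean_cost_scc_eur - benchmark_result.mean_cost_scc_eur,
    )
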