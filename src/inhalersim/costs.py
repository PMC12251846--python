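"""Unit economics, carbon footprints and annual cohort cost arithmetic.

All monetary parameters are per-item production costs in EUR; environmental
parameters are cradle-to-gate carbon footprints in kg CO2-eq, monetised via
the Social Cost of Carbon (SCC, EUR 40 per tonne in the baseline scenario).
A treatment pattern is an annual prescription mix: always 12 medication
cartridges per patient-year, combined with 12, 6 or 4 reusable inhaler
cases (single packs vs triple packs); a smart prototype carries one
electronic module per case.

Cartridge content can be reduced in proportion to a patient's simulated
delivery-rate gain, which scales both the cartridge's production cost and
its footprint linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional

__all__ = [
    "UnitCosts",
    "UnitFootprints",
    "TreatmentPattern",
    "CohortSpec",
    "PATTERNS",
    "reduced_cartridge_cost_eur",
    "reduced_cartridge_scc_eur",
    "reduced_cartridge_scc_cents",
    "annual_pattern_cost_eur",
    "annual_pattern_scc_eur",
]

DESIGN_VERSIONS = ("A", "B", "C")


def _frozen(d: dict) -> Mapping[str, float]:
    return MappingProxyType(dict(d))


@dataclass(frozen=True)
class UnitCosts:
    """Per-item production costs in EUR.

    Defaults: 42.96 per standard-content cartridge, 1.87 per reusable
    inhaler case, and per electronic-module costs of the three design
    versions (A feature-rich, B high-performance, C lightweight).
    """

    cartridge_eur: float = 42.96
    case_eur: float = 1.87
    module_eur: Mapping[str, float] = field(
        default_factory=lambda: _frozen({"A": 12.32, "B": 7.46, "C": 9.97})
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_eur", _frozen(self.module_eur))
        vals = [self.cartridge_eur, self.case_eur, *self.module_eur.values()]
        if any(v <= 0 for v in vals):
            raise ValueError("unit costs must be positive")


@dataclass(frozen=True)
class UnitFootprints:
    """Per-item carbon footprints (kg CO2-eq) and the SCC rate (EUR/tonne)."""

    cartridge_kg: float = 0.080
    case_kg: float = 1.035
    module_kg: Mapping[str, float] = field(
        default_factory=lambda: _frozen({"A": 0.317, "B": 0.197, "C": 0.174})
    )
    scc_eur_per_tonne: float = 40.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_kg", _frozen(self.module_kg))
        vals = [self.cartridge_kg, self.case_kg, self.scc_eur_per_tonne, *self.module_kg.values()]
        if any(v < 0 for v in vals):
            raise ValueError("footprints and the SCC rate must be non-negative")

    @property
    def scc_eur_per_kg(self) -> float:
        return self.scc_eur_per_tonne / 1000.0


@dataclass(frozen=True)
class TreatmentPattern:
    """Annual prescription mix of one treatment pattern.

    Every pattern dispenses 12 cartridges per patient-year (one annual
    medication cycle); the number of inhaler cases depends on the pack mix
    (12 single packs / 3 single + 3 triple packs / 4 triple packs).  Smart
    prototypes carry one electronic module per case.
    """

    pattern_id: int
    cases_per_year: int
    cartridges_per_year: int = 12

    def __post_init__(self) -> None:
        if self.cartridges_per_year != 12:
            raise ValueError("all treatment patterns use 12 cartridges per year")
        if self.cases_per_year not in (12, 6, 4):
            raise ValueError("cases per year must be 12, 6 or 4")

    @property
    def modules_per_year(self) -> int:
        """Electronic modules per patient-year when the inhaler is smart."""
        return self.cases_per_year


PATTERNS: Mapping[int, TreatmentPattern] = _frozen(
    {
        1: TreatmentPattern(1, cases_per_year=12),
        2: TreatmentPattern(2, cases_per_year=6),
        3: TreatmentPattern(3, cases_per_year=4),
    }
)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort used in the budget projection.

    ``learned_fraction`` is the share of patients who consistently adopted
    the proper inhalation technique during training; ``gain_schedule`` maps
    each post-training calendar year to the delivery-rate gain (%) applied
    to those learners' cartridges that year.
    """

    n_patients: float
    severity: str
    learned_fraction: float
    gain_schedule: "pd.Series"  # year -> percent

    def __post_init__(self) -> None:
        if not 0 <= self.learned_fraction <= 1:
            raise ValueError("learned_fraction must be in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


def _check_gain(gain_percent: float) -> None:
    if not 0 <= gain_percent <= 100:
        raise ValueError(f"delivery-rate gain must be in [0, 100] percent, got {gain_percent}")


def reduced_cartridge_cost_eur(gain_percent: float, costs: UnitCosts = UnitCosts()) -> float:
    """Production cost (EUR) of a cartridge whose content is reduced by gain_percent."""
    _check_gain(gain_percent)
    return costs.cartridge_eur * (1.0 - gain_percent / 100.0)


def reduced_cartridge_scc_eur(
    gain_percent: float, footprints: UnitFootprints = UnitFootprints()
) -> float:
    """SCC-monetised footprint (EUR) of a reduced-content cartridge."""
    _check_gain(gain_percent)
    return footprints.cartridge_kg * footprints.scc_eur_per_kg * (1.0 - gain_percent / 100.0)


def reduced_cartridge_scc_cents(
    gain_percent: float, footprints: UnitFootprints = UnitFootprints()
) -> float:
    """Same as :func:`reduced_cartridge_scc_eur` but in EUR cents (reporting unit)."""
    return 100.0 * reduced_cartridge_scc_eur(gain_percent, footprints)


def annual_pattern_cost_eur(
    pattern: TreatmentPattern,
    version: Optional[str],
    cartridge_eur: float,
    n_patients: float,
    costs: UnitCosts = UnitCosts(),
) -> float:
    """Annual economic cohort cost (EUR) of one treatment pattern.

    ``version`` selects the electronic-module design (A/B/C) of a smart
    prototype; ``None`` means the regular reusable inhaler (no module).
    ``cartridge_eur`` is passed explicitly so reduced-content (or blended)
    cartridge prices flow through the same arithmetic.
    """
    module = 0.0 if version is None else costs.module_eur[version]
    per_patient = (
        pattern.cartridges_per_year * cartridge_eur
        + pattern.cases_per_year * costs.case_eur
        + pattern.modules_per_year * module
    )
    return n_patients * per_patient


def annual_pattern_scc_eur(
    pattern: TreatmentPattern,
    version: Optional[str],
    cartridge_kg: float,
    n_patients: float,
    footprints: UnitFootprints = UnitFootprints(),
) -> float:
    """Annual SCC-monetised environmental cohort cost (EUR) of one pattern."""
    module = 0.0 if version is None else footprints.module_kg[version]
    per_patient_kg = (
        pattern.cartridges_per_year * cartridge_kg
        + pattern.cases_per_year * footprints.case_kg
        + pattern.modules_per_year * module
    )
    return n_patients * per_patient_kg * footprints.scc_eur_per_kg
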