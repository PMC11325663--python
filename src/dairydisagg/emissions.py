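"""Milk-equivalent litres and greenhouse-gas emissions from dairy intake.

Dairy products are converted to the litres of raw milk their production
requires (milk equivalents): a category-level factor in litres per kg of
product, with optional variety-level overrides (e.g. 9.5 L of milk per kg
of cheddar).  Liquid milk converts through its density (default 1.03 kg/L).
Litres then convert to emissions with a single production footprint
coefficient, default 1.2 kg CO2e per litre of raw milk produced in the UK.

The default non-milk factors other than cheddar are package conventions
(documented in the methods note) and should be replaced with
utilisation-based factors for any serious accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import MissingFactorError, SchemaError
from .intake import IntakeEstimate
from .taxonomy import CATEGORIES

DAYS_PER_YEAR = 365.0
DEFAULT_MILK_DENSITY_KG_PER_L = 1.03
DEFAULT_FOOTPRINT_KG_CO2E_PER_L = 1.2

#: Conventional litres of raw milk per kg of product; cheddar's 9.5 L/kg is
#: the published utilisation figure, the rest are round package defaults.
DEFAULT_LITRES_PER_KG = {
    "cheese": 9.5,
    "yogurt": 1.1,
    "cream": 8.0,
    "butter": 22.0,
}


@dataclass
class MilkEquivalenceFactors:
    """Litres of raw milk required per kg of product, per dairy category.

    ``variety_overrides`` maps (category, variety) to a factor that takes
    precedence, e.g. ``("cheese", "cheddar") -> 9.5``.  Milk's own factor is
    1/density litres per kg.
    """

    litres_per_kg: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LITRES_PER_KG)
    )
    variety_overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    milk_density_kg_per_l: float = DEFAULT_MILK_DENSITY_KG_PER_L

    def __post_init__(self):
        for k, v in {**self.litres_per_kg, **self.variety_overrides}.items():
            if v <= 0:
                raise SchemaError(f"milk-equivalence factor for {k!r} must be positive, got {v}")
        if self.milk_density_kg_per_l <= 0:
            raise SchemaError("milk density must be positive")

    def factor(self, category: str, variety: Optional[str] = None) -> float:
        if category == "milk":
            return 1.0 / self.milk_density_kg_per_l
        if variety is not None and (category, variety) in self.variety_overrides:
            return self.variety_overrides[(category, variety)]
        if category not in self.litres_per_kg:
            raise MissingFactorError(f"no milk-equivalence factor for category {category!r}")
        return self.litres_per_kg[category]


@dataclass
class FootprintConfig:
    kg_co2e_per_litre: float = DEFAULT_FOOTPRINT_KG_CO2E_PER_L

    def __post_init__(self):
        if self.kg_co2e_per_litre <= 0:
            raise SchemaError("footprint must be positive")


@dataclass
class EmissionsEstimate:
    """Per-capita annual emissions and the underlying milk-equivalent litres."""

    mode: str
    litres_per_capita_per_year: float
    kg_co2e_per_capita_per_year: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "mode": self.mode,
                    "litres_per_capita_per_year": self.litres_per_capita_per_year,
                    "kg_co2e_per_capita_per_year": self.kg_co2e_per_capita_per_year,
                }
            ]
        )


def to_milk_equivalents(
    intake: IntakeEstimate, factors: Optional[MilkEquivalenceFactors] = None
) -> float:
    """Convert a per-capita intake estimate to litres of raw milk per day.

    litres/day = sum over categories of (g/day / 1000) x factor_L_per_kg.
    Raises :class:`MissingFactorError` if a consumed category has no factor.
    """
    factors = factors or MilkEquivalenceFactors()
    litres = 0.0
    for cat in CATEGORIES:
        g_per_day = intake.mean.get(cat, 0.0)
        if g_per_day == 0.0:
            continue
        litres += (g_per_day / 1000.0) * factors.factor(cat)
    return litres


def annual_per_capita_emissions(
    litres_per_day: float,
    footprint: Optional[FootprintConfig] = None,
    mode: str = "unknown",
) -> EmissionsEstimate:
    """Annualise daily milk-equivalent litres into kg CO2e per person per year."""
    if litres_per_day < 0:
        raise SchemaError("litres_per_day must be non-negative")
    footprint = footprint or FootprintConfig()
    litres_per_year = litres_per_day * DAYS_PER_YEAR
    return EmissionsEstimate(
        mode=mode,
        litres_per_capita_per_year=litres_per_year,
        kg_co2e_per_capita_per_year=litres_per_year * footprint.kg_co2e_per_litre,
    )


def emissions_bias(
    est_with: EmissionsEstimate,
    est_without: EmissionsEstimate,
    convention: str = "denominator_without",
) -> float:
    """Percent emissions bias from not disaggregating, under a stated convention."""
    from .errors import UndefinedBiasError

    a = est_with.kg_co2e_per_capita_per_year
    b = est_without.kg_co2e_per_capita_per_year
    denom = a if convention == "denominator_with" else b
    if convention not in ("denominator_with", "denominator_without"):
        raise ValueError(f"unknown convention {convention!r}")
    if denom == 0:
        if a == b:
            return 0.0
        raise UndefinedBiasError("zero denominator with nonzero difference")
    return 100.0 * (a - b) / denom
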