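"""Per-food dairy profiles and database-level classification counts.

For each food the resolved base ingredients are looked up in the
classification map and the dairy ones summed per subtype, giving grams of
each dairy subtype per 100 g of product.  A food whose resolved ingredients
are *all* dairy is a pure (100%) dairy item; one with some but not all dairy
mass is a dairy-containing composite; one with none is non-dairy.  Purity is
structural, not a mass threshold: salted butter at 98.44 g dairy per 100 g
is still a composite because salt is not dairy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

from .errors import EmptyInputError
from .fooddb import RecipeDatabase, resolve_recipe
from .taxonomy import (
    CATEGORIES,
    NON_DAIRY,
    ClassificationMap,
    DairyClass,
    classify_ingredient,
)

PURE_DAIRY = "pure_dairy"
COMPOSITE_DAIRY = "composite_dairy"
NON_DAIRY_FOOD = "non_dairy"

_ABS_TOL = 1e-9


@dataclass
class DairyProfile:
    """Grams of each dairy subtype per 100 g of one food, plus its class."""

    food_code: str
    total_dairy_g_per_100g: float
    by_subtype: dict[DairyClass, float]
    food_class: str
    resolved_total_g: float

    def by_category(self) -> dict[str, float]:
        """Aggregate subtype grams up to the five category totals."""
        out = {c: 0.0 for c in CATEGORIES}
        for cls, grams in self.by_subtype.items():
            out[cls.category.value] += grams
        return out


@dataclass
class DatabaseSummary:
    n_foods: int
    n_pure_dairy: int
    n_composite_dairy: int
    n_non_dairy: int

    @property
    def percent_any_dairy(self) -> float:
        return 100.0 * (self.n_pure_dairy + self.n_composite_dairy) / self.n_foods

    def rounded_percents(self) -> dict[str, int]:
        """Class percentages rounded to the nearest integer, half away from zero."""
        return {
            "pure_dairy": round_half_away(100.0 * self.n_pure_dairy / self.n_foods),
            "composite_dairy": round_half_away(100.0 * self.n_composite_dairy / self.n_foods),
            "non_dairy": round_half_away(100.0 * self.n_non_dairy / self.n_foods),
            "any_dairy": round_half_away(self.percent_any_dairy),
        }


def round_half_away(x: float) -> int:
    """Round to nearest integer with ties going away from zero (not banker's)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def classify_food(
    resolved_ingredients: Iterable[tuple[str, float]], cmap: ClassificationMap
) -> str:
    """Classify a resolved food as pure dairy, composite dairy, or non-dairy.

    Pure iff all resolved ingredient mass is dairy-classified; non-dairy iff
    none is; composite otherwise.  Zero-gram components carry no mass and do
    not affect the class.  Classification errors propagate.
    """
    saw_dairy = saw_non_dairy = False
    for code, grams in resolved_ingredients:
        is_dairy = classify_ingredient(cmap, code) is not NON_DAIRY
        if grams > 0:
            if is_dairy:
                saw_dairy = True
            else:
                saw_non_dairy = True
    if saw_dairy and not saw_non_dairy:
        return PURE_DAIRY
    if saw_dairy:
        return COMPOSITE_DAIRY
    return NON_DAIRY_FOOD


def dairy_profile(
    db: RecipeDatabase, cmap: ClassificationMap, food_code: str
) -> DairyProfile:
    """Compute the dairy profile of one food (grams per 100 g by subtype)."""
    resolved = resolve_recipe(db, food_code)
    by_subtype: dict[DairyClass, float] = {}
    total = 0.0
    for code, grams in resolved:
        cls = classify_ingredient(cmap, code)
        if cls is NON_DAIRY:
            continue
        by_subtype[cls] = by_subtype.get(cls, 0.0) + grams
        total += grams
    return DairyProfile(
        food_code=food_code,
        total_dairy_g_per_100g=total,
        by_subtype=by_subtype,
        food_class=classify_food(resolved, cmap),
        resolved_total_g=sum(g for _, g in resolved),
    )


def profile_database(
    db: RecipeDatabase, cmap: ClassificationMap
) -> dict[str, DairyProfile]:
    """Dairy profile for every food in the food list, keyed by food code."""
    return {code: dairy_profile(db, cmap, code) for code in sorted(db.foods)}


def summarize_database(profiles: Mapping[str, DairyProfile]) -> DatabaseSummary:
    """Count pure / composite / non-dairy foods across a set of profiles."""
    if not profiles:
        raise EmptyInputError("no profiles to summarise")
    counts = {PURE_DAIRY: 0, COMPOSITE_DAIRY: 0, NON_DAIRY_FOOD: 0}
    for p in profiles.values():
        counts[p.food_class] += 1
    return DatabaseSummary(
        n_foods=len(profiles),
        n_pure_dairy=counts[PURE_DAIRY],
        n_composite_dairy=counts[COMPOSITE_DAIRY],
        n_non_dairy=counts[NON_DAIRY_FOOD],
    )


def profiles_frame(profiles: Mapping[str, DairyProfile]) -> pd.DataFrame:
    """Tidy per-food table: class, total, category columns, subtype columns.

    Category columns are always present (``milk`` … ``butter``); one extra
    ``subtype:``-prefixed column per full subtype key observed in the data.
    """
    subtype_keys = sorted({cls.key for p in profiles.values() for cls in p.by_subtype})
    subtype_cols = [f"subtype:{k}" for k in subtype_keys]
    rows = []
    for code in sorted(profiles):
        p = profiles[code]
        row: dict[str, object] = {
            "food_code": code,
            "food_class": p.food_class,
            "total_dairy_g_per_100g": p.total_dairy_g_per_100g,
        }
        row.update(p.by_category())
        by_key = {cls.key: g for cls, g in p.by_subtype.items()}
        for k in subtype_keys:
            row[f"subtype:{k}"] = by_key.get(k, 0.0)
        rows.append(row)
    cols = ["food_code", "food_class", "total_dairy_g_per_100g", *CATEGORIES, *subtype_cols]
    return pd.DataFrame(rows, columns=cols)


def write_profiles_csv(
    profiles: Mapping[str, DairyProfile], path: Union[str, Path]
) -> None:
    profiles_frame(profiles).to_csv(path, index=False)
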