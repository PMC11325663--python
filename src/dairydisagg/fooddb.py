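"""Hierarchical food/recipe database: loading, validation and resolution.

The recipe database maps each food code to its ingredient amounts in grams
per 100 g of product.  Components may themselves be food codes with their
own recipes (sub-recipes), so the parent → component relation forms a
directed acyclic graph.  :func:`resolve_recipe` flattens that graph so every
food can be expressed as base ingredients per 100 g.

Amounts are used exactly as recorded: there is no renormalisation of a
recipe to sum to 100 g and no cooking-yield (water loss) adjustment, because
disaggregation targets ingredient masses as produced, before cooking.  A
per-recipe validity window flags suspect totals without rejecting them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .errors import (
    DuplicateEntryError,
    RecipeCycleError,
    SchemaError,
    UnresolvableFoodError,
)

logger = logging.getLogger(__name__)

#: Per-recipe grams-per-100 g totals outside this window trigger a warning.
DEFAULT_VALIDITY_WINDOW = (50.0, 130.0)


@dataclass(frozen=True)
class FoodRecord:
    food_code: str
    description: str = ""
    food_group: str = ""


@dataclass(frozen=True)
class RecipeEntry:
    parent_code: str
    component_code: str
    grams_per_100g: float

    def __post_init__(self):
        if self.grams_per_100g < 0:
            raise SchemaError(
                f"negative amount {self.grams_per_100g} for "
                f"({self.parent_code}, {self.component_code})"
            )


@dataclass
class RecipeDatabase:
    """Validated food list plus recipe entries.

    ``entries`` is keyed by parent code; ``base_ingredients`` is the set of
    codes that appear only as components (the leaves of the hierarchy).
    """

    foods: dict[str, FoodRecord]
    entries: dict[str, list[RecipeEntry]] = field(default_factory=dict)

    def __post_init__(self):
        self.entries = {p: list(es) for p, es in self.entries.items() if es}
        self._validate()

    def _validate(self) -> None:
        unknown_parents = sorted(set(self.entries) - set(self.foods))
        if unknown_parents:
            raise SchemaError(f"recipe parents not in food list: {unknown_parents}")
        seen_pairs: set[tuple[str, str]] = set()
        for parent, es in self.entries.items():
            for e in es:
                pair = (e.parent_code, e.component_code)
                if pair in seen_pairs:
                    raise DuplicateEntryError(f"duplicate recipe entry {pair}")
                seen_pairs.add(pair)
        self._check_acyclic()
        self._check_totals()

    def _check_acyclic(self) -> None:
        graph = {p: [e.component_code for e in es] for p, es in self.entries.items()}
        ts = TopologicalSorter(graph)
        try:
            ts.prepare()
        except CycleError as exc:
            # graphlib reports the cycle as a node path; first == last
            cycle = exc.args[1]
            raise RecipeCycleError(dict.fromkeys(cycle)) from exc

    def _check_totals(self) -> None:
        lo, hi = DEFAULT_VALIDITY_WINDOW
        for parent, es in self.entries.items():
            total = sum(e.grams_per_100g for e in es)
            if total <= 0:
                raise SchemaError(f"recipe {parent!r} has non-positive total {total} g/100 g")
            if not lo <= total <= hi:
                warnings.warn(
                    f"recipe {parent!r} totals {total:.2f} g/100 g, outside [{lo}, {hi}]",
                    stacklevel=2,
                )

    @property
    def base_ingredients(self) -> set[str]:
        components = {e.component_code for es in self.entries.values() for e in es}
        return components - set(self.entries)

    def food_groups(self) -> dict[str, str]:
        """food_code → food_group for the naive (food-group) intake mode."""
        return {code: rec.food_group for code, rec in self.foods.items()}


@dataclass
class SubstitutionMap:
    """Nearest-neighbour substitutes for foods missing from the database.

    Chains are forbidden: a substitute must itself be a resolvable database
    code, never another missing code.
    """

    pairs: dict[str, str] = field(default_factory=dict)
    rationale: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        chained = sorted(set(self.pairs.values()) & set(self.pairs))
        if chained:
            raise SchemaError(f"substitution chains are not allowed: {chained}")


_FOOD_COLS = ["food_code", "description", "food_group"]
_RECIPE_COLS = ["parent_code", "component_code", "grams_per_100g"]
_SUBS_COLS = ["missing_code", "substitute_code", "rationale"]


def load_recipe_db(
    food_list_path: Union[str, Path], recipe_path: Union[str, Path]
) -> RecipeDatabase:
    """Load and validate the food list and recipe CSVs.

    Validation failures (missing columns, duplicate food codes, duplicate
    (parent, component) pairs, recipe cycles, non-positive recipe totals)
    each raise a distinct exception naming the offending rows or codes.
    """
    foods_df = _read_csv(food_list_path, _FOOD_COLS)
    dupes = foods_df["food_code"][foods_df["food_code"].duplicated()].unique()
    if len(dupes):
        raise DuplicateEntryError(f"{food_list_path}: duplicate food codes {sorted(dupes)}")
    foods = {
        row.food_code: FoodRecord(row.food_code, row.description, row.food_group)
        for row in foods_df.itertuples()
    }

    recipes_df = _read_csv(recipe_path, _RECIPE_COLS)
    entries: dict[str, list[RecipeEntry]] = {}
    for idx, row in recipes_df.iterrows():
        try:
            grams = float(row["grams_per_100g"])
        except (TypeError, ValueError) as exc:
            raise SchemaError(
                f"{recipe_path} row {idx + 2}: non-numeric grams_per_100g "
                f"{row['grams_per_100g']!r}"
            ) from exc
        entry = RecipeEntry(str(row["parent_code"]), str(row["component_code"]), grams)
        entries.setdefault(entry.parent_code, []).append(entry)

    return RecipeDatabase(foods=foods, entries=entries)


def load_substitutions(path: Union[str, Path]) -> SubstitutionMap:
    df = _read_csv(path, _SUBS_COLS)
    pairs = dict(zip(df["missing_code"].astype(str), df["substitute_code"].astype(str)))
    if len(pairs) != len(df):
        raise DuplicateEntryError(f"{path}: duplicate missing_code rows")
    rationale = dict(zip(df["missing_code"].astype(str), df["rationale"].astype(str)))
    return SubstitutionMap(pairs=pairs, rationale=rationale)


def _read_csv(path: Union[str, Path], required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def apply_substitutions(
    db: RecipeDatabase, subs: SubstitutionMap, query_codes: Iterable[str]
) -> dict[str, str]:
    """Map each query code to the code actually resolved against the database.

    Codes present in the database map to themselves; missing codes with a
    registered nearest-neighbour substitute map to that substitute (logged);
    anything else is an :class:`UnresolvableFoodError`.
    """
    mapping: dict[str, str] = {}
    unresolved: list[str] = []
    for code in query_codes:
        if code in db.foods:
            mapping[code] = code
        elif code in subs.pairs:
            sub = subs.pairs[code]
            if sub not in db.foods:
                unresolved.append(code)
                continue
            mapping[code] = sub
            logger.info(
                "substituting %s -> %s (%s)", code, sub, subs.rationale.get(code, "no rationale")
            )
        else:
            unresolved.append(code)
    if unresolved:
        raise UnresolvableFoodError(f"codes not resolvable via database or substitutions: {sorted(unresolved)}")
    return mapping


def resolve_recipe(db: RecipeDatabase, food_code: str) -> list[tuple[str, float]]:
    """Flatten a food to base ingredients in grams per 100 g of product.

    A sub-recipe contributing g grams per 100 g of its parent contributes
    g/100 of its own per-100 g composition; repeated base ingredients are
    summed.  A code with no recipe entries resolves to itself at 100 g.
    Output is sorted by ingredient code so results are reproducible
    bit-for-bit.
    """
    if food_code not in db.foods and food_code not in db.base_ingredients:
        raise UnresolvableFoodError(f"unknown food code {food_code!r}")
    cache: dict[str, dict[str, float]] = {}
    flat = _resolve(db, food_code, cache, visiting=[])
    return sorted(flat.items())


def _resolve(
    db: RecipeDatabase,
    code: str,
    cache: dict[str, dict[str, float]],
    visiting: list[str],
) -> dict[str, float]:
    if code in cache:
        return cache[code]
    if code in visiting:  # defensive: the constructor already checks acyclicity
        raise RecipeCycleError(visiting[visiting.index(code):] + [code])
    entries = db.entries.get(code)
    if not entries:
        result = {code: 100.0}
    else:
        visiting.append(code)
        result = {}
        for e in entries:
            for ingredient, grams in _resolve(db, e.component_code, cache, visiting).items():
                result[ingredient] = result.get(ingredient, 0.0) + e.grams_per_100g * grams / 100.0
        visiting.pop()
    cache[code] = result
    return result
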