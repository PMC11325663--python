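"""Synthetic recipe databases and recall surveys with known ground truth.

The generator emulates the structure of UK dietary-survey inputs: a food
list in which roughly 3% of foods are pure dairy items, 29% are
dairy-containing composites and 68% contain no dairy; composite dairy
content spread log-uniformly over four orders of magnitude
(0.01–98.44 g/100 g); recipes nested up to a configurable depth; recall
diaries of up to two days per person with positive survey weights.

Ground truth is recorded at generation time: per-food dairy profiles are
computed with a brute-force path-product flattener that shares no code with
the production resolver, and expected per-capita intakes under both
estimation modes follow in closed form from the sampling scheme.  Tests can
therefore check the whole pipeline against values it had no hand in
producing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .errors import GeneratorConfigError, RecipeCycleError
from .fooddb import FoodRecord, RecipeDatabase, RecipeEntry
from .taxonomy import (
    CATEGORIES,
    NON_DAIRY,
    CheeseVariety,
    ClassificationMap,
    DairyCategory,
    DairyClass,
    FatLevel,
)

# ---------------------------------------------------------------------------
# configuration

@dataclass
class GeneratorConfig:
    """All knobs of the synthetic world, with defaults at study scale."""

    seed: int
    n_foods: int = 1000
    fractions: tuple[float, float, float] = (0.03, 0.29, 0.68)  # pure, composite, non-dairy
    dairy_content_range: tuple[float, float] = (0.01, 98.44)  # log-uniform, g/100 g
    max_depth: int = 3
    p_nested: float = 0.3
    n_persons: int = 2000
    p_second_day: float = 0.8
    mean_items_per_day: float = 10.0
    portion_lognorm_mu: float = 4.3  # median portion ~74 g
    portion_lognorm_sigma: float = 0.6
    weight_shift: float = 0.1
    weight_gamma_shape: float = 9.0
    weight_gamma_scale: float = 0.1  # shift + shape*scale = mean 1.0
    p_composite_in_dairy_group: float = 0.08

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise GeneratorConfigError(f"fractions must sum to 1, got {self.fractions}")
        if any(f < 0 for f in self.fractions):
            raise GeneratorConfigError("fractions must be non-negative")
        lo, hi = self.dairy_content_range
        if not 0 < lo <= hi < 100:
            raise GeneratorConfigError("dairy content range must satisfy 0 < lo <= hi < 100")
        if self.max_depth < 1 and (self.fractions[0] > 0 or self.fractions[1] > 0):
            raise GeneratorConfigError(
                "nesting depth 0 is infeasible with a nonzero dairy fraction"
            )
        for name in (
            "n_foods",
            "mean_items_per_day",
            "portion_lognorm_sigma",
            "weight_gamma_shape",
            "weight_gamma_scale",
        ):
            if getattr(self, name) <= 0:
                raise GeneratorConfigError(f"{name} must be positive")
        if not 0 <= self.p_second_day <= 1:
            raise GeneratorConfigError("p_second_day must lie in [0, 1]")

    @property
    def mean_portion_g(self) -> float:
        return float(np.exp(self.portion_lognorm_mu + self.portion_lognorm_sigma**2 / 2))


# ---------------------------------------------------------------------------
# fixed ingredient and group rosters

_DAIRY_INGREDIENTS: dict[str, DairyClass] = {
    "ing_milk_skimmed": DairyClass(DairyCategory.MILK, FatLevel.SKIMMED),
    "ing_milk_semiskimmed": DairyClass(DairyCategory.MILK, FatLevel.SEMISKIMMED),
    "ing_milk_fullfat": DairyClass(DairyCategory.MILK, FatLevel.FULL_FAT),
    "ing_cheese_cheddar": DairyClass(
        DairyCategory.CHEESE, FatLevel.FULL_FAT, CheeseVariety.CHEDDAR
    ),
    "ing_cheese_cottage": DairyClass(
        DairyCategory.CHEESE, FatLevel.SKIMMED, CheeseVariety.COTTAGE
    ),
    "ing_cheese_soft": DairyClass(DairyCategory.CHEESE, FatLevel.FULL_FAT, CheeseVariety.OTHER),
    "ing_yogurt_fullfat": DairyClass(DairyCategory.YOGURT, FatLevel.FULL_FAT),
    "ing_yogurt_skimmed": DairyClass(DairyCategory.YOGURT, FatLevel.SKIMMED),
    "ing_cream_single": DairyClass(DairyCategory.CREAM, FatLevel.SEMISKIMMED),
    "ing_cream_double": DairyClass(DairyCategory.CREAM, FatLevel.FULL_FAT),
    "ing_butter": DairyClass(DairyCategory.BUTTER),
}

_NON_DAIRY_INGREDIENTS = [
    "ing_wheat_flour", "ing_sugar", "ing_egg", "ing_vegetable_oil", "ing_salt",
    "ing_water", "ing_tomato", "ing_onion", "ing_chicken", "ing_beef",
    "ing_potato", "ing_rice", "ing_pasta", "ing_oats", "ing_apple",
    "ing_banana", "ing_cocoa", "ing_yeast", "ing_lentils", "ing_carrot",
]

_DAIRY_GROUPS = {
    "GRP_MILK": "milk",
    "GRP_CHEESE": "cheese",
    "GRP_YOGURT": "yogurt",
    "GRP_CREAM": "cream",
    "GRP_BUTTER": "butter",
}
_NON_DAIRY_GROUPS = ["GRP_CEREALS", "GRP_MEAT_DISHES", "GRP_VEG", "GRP_SWEETS", "GRP_SANDWICHES"]


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class SyntheticTruth:
    """Everything the generator knows that the pipeline must recover."""

    profiles: dict[str, dict[str, float]]  # food -> {category: g/100g, 'total': ...}
    food_class: dict[str, str]  # food -> pure_dairy | composite_dairy | non_dairy
    food_groups: dict[str, str]
    group_map: dict[str, str]
    expected_intake: dict[str, dict[str, float]] = field(default_factory=dict)
    expected_shares: dict[str, float] = field(default_factory=dict)
    expected_noncomposite_percent: Optional[float] = None

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for code in sorted(self.profiles):
            row = {"food_code": code, "food_class": self.food_class[code]}
            row.update(self.profiles[code])
            rows.append(row)
        return pd.DataFrame(rows)


def brute_force_flatten(
    entries: Mapping[str, list[tuple[str, float]]], code: str
) -> dict[str, float]:
    """Flatten a recipe by multiplying grams along every root-to-leaf path.

    Deliberately independent of the production resolver: no memoisation, no
    recursion — an explicit stack of (code, multiplier, path) triples.  Used
    both for generator bookkeeping and as the oracle in equivalence tests.
    """
    totals: dict[str, float] = {}
    stack: list[tuple[str, float, tuple[str, ...]]] = [(code, 1.0, (code,))]
    while stack:
        c, mult, path = stack.pop()
        comps = entries.get(c)
        if not comps:
            totals[c] = totals.get(c, 0.0) + mult * 100.0
            continue
        for comp, grams in comps:
            if comp in path:
                raise RecipeCycleError(path[path.index(comp):] + (comp,))
            stack.append((comp, mult * grams / 100.0, path + (comp,)))
    return totals


def _truth_profile(
    entries: Mapping[str, list[tuple[str, float]]], code: str
) -> tuple[dict[str, float], str]:
    flat = brute_force_flatten(entries, code)
    per_cat = {c: 0.0 for c in CATEGORIES}
    dairy_mass = non_dairy_mass = 0.0
    for ing, grams in flat.items():
        cls = _DAIRY_INGREDIENTS.get(ing)
        if cls is None:
            non_dairy_mass += grams
        else:
            per_cat[cls.category.value] += grams
            dairy_mass += grams
    per_cat["total"] = dairy_mass
    if dairy_mass > 0 and non_dairy_mass == 0:
        klass = "pure_dairy"
    elif dairy_mass > 0:
        klass = "composite_dairy"
    else:
        klass = "non_dairy"
    return per_cat, klass


# ---------------------------------------------------------------------------
# database generation

def generate_recipe_db(
    config: GeneratorConfig,
) -> tuple[RecipeDatabase, ClassificationMap, dict[str, str], SyntheticTruth]:
    """Generate an acyclic recipe database honouring the configured fractions.

    Returns the database, its complete classification map, the food-group →
    dairy-category map for the naive mode, and the generator's ground truth.
    Identical config (including seed) reproduces identical output.
    """
    rng = np.random.default_rng(config.seed)
    classes = rng.choice(
        ["pure_dairy", "composite_dairy", "non_dairy"],
        size=config.n_foods,
        p=list(config.fractions),
    )

    entries: dict[str, list[tuple[str, float]]] = {}
    depth: dict[str, int] = {}
    groups: dict[str, str] = {}
    pure_foods: list[str] = []
    non_dairy_foods: list[str] = []
    dairy_cat_of: dict[str, str] = {}

    dairy_codes = sorted(_DAIRY_INGREDIENTS)
    lo, hi = config.dairy_content_range

    for i, klass in enumerate(classes):
        code = f"food_{i:05d}"
        if klass == "pure_dairy":
            _make_pure(code, rng, config, entries, depth, pure_foods, dairy_cat_of, dairy_codes)
            groups[code] = _dairy_group_for(dairy_cat_of[code])
            pure_foods.append(code)
        elif klass == "non_dairy":
            if config.max_depth >= 1:
                _make_non_dairy(code, rng, config, entries, depth, non_dairy_foods)
            else:
                depth[code] = 0  # base-only food record, no recipe
            groups[code] = str(rng.choice(_NON_DAIRY_GROUPS))
            non_dairy_foods.append(code)
        else:
            dairy_g = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            cat = _make_composite(
                code, dairy_g, rng, config, entries, depth,
                pure_foods, non_dairy_foods, dairy_codes,
            )
            dairy_cat_of[code] = cat
            if rng.random() < config.p_composite_in_dairy_group:
                groups[code] = _dairy_group_for(cat)
            else:
                groups[code] = str(rng.choice(_NON_DAIRY_GROUPS))

    foods = {
        code: FoodRecord(code, description=f"synthetic food {code}", food_group=groups[code])
        for code in groups
    }
    db = RecipeDatabase(
        foods=foods,
        entries={
            p: [RecipeEntry(p, comp, g) for comp, g in comps]
            for p, comps in entries.items()
        },
    )
    cmap = ClassificationMap(
        dairy=dict(_DAIRY_INGREDIENTS),
        non_dairy=set(_NON_DAIRY_INGREDIENTS),
    )
    group_map = {**_DAIRY_GROUPS, **{g: NON_DAIRY for g in _NON_DAIRY_GROUPS}}

    profiles: dict[str, dict[str, float]] = {}
    food_class: dict[str, str] = {}
    for code in foods:
        prof, klass = _truth_profile(entries, code)
        profiles[code] = prof
        food_class[code] = klass
    truth = SyntheticTruth(
        profiles=profiles, food_class=food_class, food_groups=dict(groups), group_map=group_map
    )
    _fill_expected(truth, config)
    return db, cmap, group_map, truth


def _dairy_group_for(category: str) -> str:
    return {v: k for k, v in _DAIRY_GROUPS.items()}[category]


def _split(total: float, n: int, rng) -> list[float]:
    """Split *total* grams into n positive parts (rounded to 0.01 g)."""
    if n == 1:
        return [round(total, 2)]
    cuts = np.sort(rng.uniform(0.1, 0.9, size=n - 1)) * total
    parts = np.diff(np.concatenate([[0.0], cuts, [total]]))
    parts = [round(float(p), 2) for p in parts]
    parts[-1] = round(total - sum(parts[:-1]), 2)
    return [p for p in parts if p > 0]


def _make_pure(code, rng, config, entries, depth, pure_foods, dairy_cat_of, dairy_codes):
    nest = pure_foods and rng.random() < config.p_nested
    components: list[tuple[str, float]] = []
    if nest:
        sub = str(rng.choice(pure_foods))
        if depth[sub] < config.max_depth:
            g_sub = float(rng.uniform(20, 80))
            components.append((sub, round(g_sub, 2)))
    n_ing = int(rng.integers(1, 3))
    remaining = 100.0 - sum(g for _, g in components)
    chosen = rng.choice(dairy_codes, size=n_ing, replace=False)
    for ing, g in zip(chosen, _split(remaining, n_ing, rng)):
        components.append((str(ing), g))
    entries[code] = components
    depth[code] = 1 + max((depth.get(c, 0) for c, _ in components), default=0)
    # dominant category decides the food group
    per_cat: dict[str, float] = {}
    for comp, g in components:
        cat = (
            _DAIRY_INGREDIENTS[comp].category.value
            if comp in _DAIRY_INGREDIENTS
            else dairy_cat_of[comp]
        )
        per_cat[cat] = per_cat.get(cat, 0.0) + g
    dairy_cat_of[code] = max(sorted(per_cat), key=per_cat.get)


def _make_non_dairy(code, rng, config, entries, depth, non_dairy_foods):
    components: list[tuple[str, float]] = []
    if non_dairy_foods and rng.random() < config.p_nested:
        sub = str(rng.choice(non_dairy_foods))
        if depth.get(sub, 0) < config.max_depth and depth.get(sub, 0) >= 1:
            components.append((sub, round(float(rng.uniform(20, 60)), 2)))
    n_ing = int(rng.integers(2, 5))
    remaining = 100.0 - sum(g for _, g in components)
    chosen = rng.choice(_NON_DAIRY_INGREDIENTS, size=n_ing, replace=False)
    for ing, g in zip(chosen, _split(remaining, n_ing, rng)):
        components.append((str(ing), g))
    entries[code] = components
    depth[code] = 1 + max((depth.get(c, 0) for c, _ in components), default=0)


def _make_composite(
    code, dairy_g, rng, config, entries, depth, pure_foods, non_dairy_foods, dairy_codes
) -> str:
    """Composite = dairy_g grams of dairy (direct or via a pure sub-recipe)
    plus a non-dairy remainder; returns the dairy category planted."""
    components: list[tuple[str, float]] = []
    nestable_pure = [f for f in pure_foods if depth[f] < config.max_depth]
    if nestable_pure and rng.random() < config.p_nested:
        sub = str(rng.choice(nestable_pure))
        components.append((sub, round(dairy_g, 2)))
        cat = _dominant_category(entries, sub)
    else:
        ing = str(rng.choice(dairy_codes))
        components.append((ing, round(dairy_g, 2)))
        cat = _DAIRY_INGREDIENTS[ing].category.value
    remainder = 100.0 - components[0][1]
    nestable_nd = [f for f in non_dairy_foods if 1 <= depth.get(f, 0) < config.max_depth]
    if nestable_nd and rng.random() < config.p_nested and remainder > 10:
        sub = str(rng.choice(nestable_nd))
        g_sub = round(float(rng.uniform(5, remainder / 2)), 2)
        components.append((sub, g_sub))
        remainder = round(remainder - g_sub, 2)
    n_ing = int(rng.integers(1, 4))
    chosen = rng.choice(_NON_DAIRY_INGREDIENTS, size=n_ing, replace=False)
    for ing, g in zip(chosen, _split(remainder, n_ing, rng)):
        components.append((str(ing), g))
    entries[code] = components
    depth[code] = 1 + max((depth.get(c, 0) for c, _ in components), default=0)
    return cat


def _dominant_category(entries, food_code) -> str:
    prof, _ = _truth_profile(entries, food_code)
    cats = {c: prof[c] for c in CATEGORIES}
    return max(sorted(cats), key=cats.get)


# ---------------------------------------------------------------------------
# analytic expectations

def _fill_expected(truth: SyntheticTruth, config: GeneratorConfig) -> None:
    """Closed-form expected per-capita intakes implied by the sampling scheme.

    Items are drawn uniformly over foods with Poisson day counts and
    log-normal portions, independently of weights and days, so the expected
    per-capita daily intake of category c is
    E[n_items] * E[portion] * mean_f(profile_c(f)) / 100.
    """
    n = len(truth.profiles)
    e_items = config.mean_items_per_day
    e_portion = config.mean_portion_g
    scale = e_items * e_portion / 100.0

    dis: dict[str, float] = {}
    for col in [*CATEGORIES, "total"]:
        dis[col] = scale * float(np.mean([p[col] for p in truth.profiles.values()]))
    naive = {c: 0.0 for c in CATEGORIES}
    for code in truth.profiles:
        cat = truth.group_map[truth.food_groups[code]]
        if cat != NON_DAIRY:
            naive[cat] += scale * 100.0 / n  # full reported weight counts
    naive["total"] = sum(naive[c] for c in CATEGORIES)
    truth.expected_intake = {"disaggregated": dis, "food_group": naive}

    group_mass: dict[str, float] = {}
    for code, prof in truth.profiles.items():
        group_mass.setdefault(truth.food_groups[code], 0.0)
        group_mass[truth.food_groups[code]] += prof["total"]
    grand = sum(group_mass.values())
    if grand > 0:
        truth.expected_shares = {g: 100.0 * m / grand for g, m in sorted(group_mass.items())}
        noncomp = sum(
            100.0 * m / grand
            for g, m in group_mass.items()
            if truth.group_map[g] != NON_DAIRY
        )
        truth.expected_noncomposite_percent = noncomp


# ---------------------------------------------------------------------------
# survey generation

def generate_survey(
    config: GeneratorConfig, db: RecipeDatabase, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw recall diaries and survey weights for the configured population.

    Returns ``(recalls, persons)`` DataFrames in the pipeline's input
    schemas.  The survey stream is seeded independently of the database
    stream (seed + 1) so the same database can host many surveys.
    """
    if config.n_persons <= 0:
        raise GeneratorConfigError("n_persons must be positive")
    rng = np.random.default_rng(config.seed + 1)
    food_codes = np.array(sorted(db.foods))

    person_ids = np.array([f"p{i:05d}" for i in range(config.n_persons)])
    weights = config.weight_shift + rng.gamma(
        config.weight_gamma_shape, config.weight_gamma_scale, size=config.n_persons
    )
    n_days = 1 + (rng.random(config.n_persons) < config.p_second_day).astype(int)
    persons = pd.DataFrame(
        {"person_id": person_ids, "weight": weights, "n_days_completed": n_days}
    )

    rows_person, rows_day = [], []
    for pid, nd in zip(person_ids, n_days):
        for day in range(1, nd + 1):
            k = int(rng.poisson(config.mean_items_per_day))
            rows_person.extend([pid] * k)
            rows_day.extend([day] * k)
    total_items = len(rows_person)
    foods = rng.choice(food_codes, size=total_items)
    portions = rng.lognormal(
        config.portion_lognorm_mu, config.portion_lognorm_sigma, size=total_items
    )
    recalls = pd.DataFrame(
        {
            "person_id": rows_person,
            "day": rows_day,
            "food_code": foods,
            "grams_consumed": np.round(portions, 2),
        }
    )
    return recalls, persons


# ---------------------------------------------------------------------------
# worked-example fixtures

def reference_fixtures() -> tuple[RecipeDatabase, ClassificationMap, dict[str, str]]:
    """Small fixture set of UK-style foods with published dairy contents.

    Includes a plain croissant (25 g butter / 100 g), a homemade Yorkshire
    pudding (60 g semi-skimmed milk / 100 g), spreadable butter (63 g butter
    / 100 g), salted butter (98.44 g butter + 1.56 g salt — a composite,
    because salt is not dairy), a kulfi-style ice cream (40 g cream / 100 g)
    and pure/plain controls (whole milk, white bread).
    """
    foods = {
        "croissant": FoodRecord("croissant", "croissant, plain", "GRP_SWEETS"),
        "yorkshire_pudding": FoodRecord(
            "yorkshire_pudding", "Yorkshire pudding, homemade", "GRP_CEREALS"
        ),
        "spreadable_butter": FoodRecord(
            "spreadable_butter", "butter, spreadable (with vegetable oil)", "GRP_BUTTER"
        ),
        "salted_butter": FoodRecord("salted_butter", "butter, salted", "GRP_BUTTER"),
        "kulfi": FoodRecord("kulfi", "Kulfi, Indian ice cream", "GRP_CREAM"),
        "whole_milk": FoodRecord("whole_milk", "milk, whole", "GRP_MILK"),
        "white_bread": FoodRecord("white_bread", "bread, white", "GRP_CEREALS"),
    }
    raw = {
        "croissant": [("ing_butter", 25.0), ("ing_wheat_flour", 60.0), ("ing_egg", 15.0)],
        "yorkshire_pudding": [
            ("ing_milk_semiskimmed", 60.0),
            ("ing_wheat_flour", 25.0),
            ("ing_egg", 15.0),
        ],
        "spreadable_butter": [("ing_butter", 63.0), ("ing_vegetable_oil", 37.0)],
        "salted_butter": [("ing_butter", 98.44), ("ing_salt", 1.56)],
        "kulfi": [("ing_cream_double", 40.0), ("ing_milk_fullfat", 30.0), ("ing_sugar", 30.0)],
        "whole_milk": [("ing_milk_fullfat", 100.0)],
        "white_bread": [
            ("ing_wheat_flour", 62.0),
            ("ing_water", 35.0),
            ("ing_salt", 1.0),
            ("ing_yeast", 2.0),
        ],
    }
    db = RecipeDatabase(
        foods=foods,
        entries={
            p: [RecipeEntry(p, c, g) for c, g in comps] for p, comps in raw.items()
        },
    )
    cmap = ClassificationMap(
        dairy=dict(_DAIRY_INGREDIENTS), non_dairy=set(_NON_DAIRY_INGREDIENTS)
    )
    group_map = {**_DAIRY_GROUPS, **{g: NON_DAIRY for g in _NON_DAIRY_GROUPS}}
    return db, cmap, group_map


# ---------------------------------------------------------------------------
# CSV emission (schemas consumed by fooddb / taxonomy / intake)

def write_tables(
    outdir: Union[str, Path],
    db: RecipeDatabase,
    cmap: ClassificationMap,
    group_map: Mapping[str, str],
    recalls: Optional[pd.DataFrame] = None,
    persons: Optional[pd.DataFrame] = None,
    truth: Optional[SyntheticTruth] = None,
) -> None:
    """Serialise a generated world to the pipeline's CSV input schemas."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"food_code": f.food_code, "description": f.description, "food_group": f.food_group}
            for f in db.foods.values()
        ]
    ).to_csv(outdir / "foods.csv", index=False)
    pd.DataFrame(
        [
            {
                "parent_code": e.parent_code,
                "component_code": e.component_code,
                "grams_per_100g": e.grams_per_100g,
            }
            for es in db.entries.values()
            for e in es
        ]
    ).to_csv(outdir / "recipes.csv", index=False)
    rows = [
        {
            "ingredient_code": code,
            "category": cls.category.value,
            "fat_level": "" if cls.fat_level is FatLevel.NOT_APPLICABLE else cls.fat_level.value,
            "cheese_variety": ""
            if cls.cheese_variety is CheeseVariety.NOT_APPLICABLE
            else cls.cheese_variety.value,
        }
        for code, cls in sorted(cmap.dairy.items())
    ]
    rows += [
        {"ingredient_code": code, "category": NON_DAIRY, "fat_level": "", "cheese_variety": ""}
        for code in sorted(cmap.non_dairy)
    ]
    pd.DataFrame(rows).to_csv(outdir / "classification.csv", index=False)
    pd.DataFrame(
        [{"food_group": g, "dairy_category": c} for g, c in sorted(group_map.items())]
    ).to_csv(outdir / "group_dairy_map.csv", index=False)
    if recalls is not None:
        recalls.to_csv(outdir / "recalls.csv", index=False)
    if persons is not None:
        persons.to_csv(outdir / "persons.csv", index=False)
    if truth is not None:
        truth.truth_frame().to_csv(outdir / "truth_profiles.csv", index=False)
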