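"""Dairy classification scheme for base ingredients.

Base ingredients are classified as one of five dairy categories — milk,
cheese, yogurt, cream, butter — or as explicitly non-dairy.  Milk, cheese,
yogurt and cream carry a fat level (skimmed / semi-skimmed / full fat);
cheese additionally carries a variety (cheddar / cottage / other).  Butter
carries neither.  The classification of an ingredient list is an input
artifact (produced upstream by human coders); this module validates and
applies it, and refuses to guess: an ingredient found in neither the dairy
roster nor the non-dairy roster is an error, never silently non-dairy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .errors import DuplicateEntryError, InvalidClassError, SchemaError, UnclassifiedIngredientError


class DairyCategory(str, enum.Enum):
    MILK = "milk"
    CHEESE = "cheese"
    YOGURT = "yogurt"
    CREAM = "cream"
    BUTTER = "butter"


class FatLevel(str, enum.Enum):
    SKIMMED = "skimmed"
    SEMISKIMMED = "semiskimmed"
    FULL_FAT = "full_fat"
    NOT_APPLICABLE = "not_applicable"


class CheeseVariety(str, enum.Enum):
    CHEDDAR = "cheddar"
    COTTAGE = "cottage"
    OTHER = "other"
    NOT_APPLICABLE = "not_applicable"


#: Sentinel returned by :func:`classify_ingredient` for rostered non-dairy codes.
NON_DAIRY = "non_dairy"

CATEGORIES = tuple(c.value for c in DairyCategory)


@dataclass(frozen=True)
class DairyClass:
    """A (category, fat level, cheese variety) label for a dairy ingredient.

    Field compatibility is enforced at construction time:

    * butter carries neither a fat level nor a variety;
    * cream's fat level is semi-skimmed or full fat (cream is never skimmed);
    * only cheese may carry a cheese variety.
    """

    category: DairyCategory
    fat_level: FatLevel = FatLevel.NOT_APPLICABLE
    cheese_variety: CheeseVariety = CheeseVariety.NOT_APPLICABLE

    def __post_init__(self):
        cat, fat, var = self.category, self.fat_level, self.cheese_variety
        if cat is DairyCategory.BUTTER and fat is not FatLevel.NOT_APPLICABLE:
            raise InvalidClassError("butter cannot carry a fat level")
        if cat is DairyCategory.CREAM and fat not in (
            FatLevel.SEMISKIMMED,
            FatLevel.FULL_FAT,
        ):
            raise InvalidClassError(
                f"cream fat level must be semiskimmed or full_fat, got {fat.value!r}"
            )
        if cat is not DairyCategory.CHEESE and var is not CheeseVariety.NOT_APPLICABLE:
            raise InvalidClassError(f"cheese_variety only applies to cheese, not {cat.value}")

    @property
    def key(self) -> str:
        """Stable string key ``category[/fat][/variety]`` used in outputs."""
        parts = [self.category.value]
        if self.fat_level is not FatLevel.NOT_APPLICABLE:
            parts.append(self.fat_level.value)
        if self.cheese_variety is not CheeseVariety.NOT_APPLICABLE:
            parts.append(self.cheese_variety.value)
        return "/".join(parts)


Classification = Union[DairyClass, str]  # DairyClass or the NON_DAIRY sentinel


@dataclass
class ClassificationMap:
    """Ingredient code → dairy class, plus an explicit non-dairy roster.

    The two rosters are disjoint; together they must cover every base
    ingredient of the database in use.
    """

    dairy: dict[str, DairyClass] = field(default_factory=dict)
    non_dairy: set[str] = field(default_factory=set)

    def __post_init__(self):
        overlap = set(self.dairy) & self.non_dairy
        if overlap:
            raise DuplicateEntryError(
                f"codes in both dairy and non-dairy rosters: {sorted(overlap)}"
            )

    def covers(self, codes: Iterable[str]) -> set[str]:
        """Return the subset of *codes* not covered by either roster."""
        return {c for c in codes if c not in self.dairy and c not in self.non_dairy}


_REQUIRED_COLS = ["ingredient_code", "category", "fat_level", "cheese_variety"]


def load_classification_map(path: Union[str, Path]) -> ClassificationMap:
    """Load and validate an ingredient classification CSV.

    Expected columns: ``ingredient_code``, ``category`` (one of the five
    dairy categories or ``non_dairy``), ``fat_level``, ``cheese_variety``
    (empty cells mean *not applicable*).  Invariant violations are reported
    with their row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    dupes = df["ingredient_code"][df["ingredient_code"].duplicated()].unique()
    if len(dupes):
        raise DuplicateEntryError(f"{path}: duplicate ingredient codes {sorted(dupes)}")

    dairy: dict[str, DairyClass] = {}
    non_dairy: set[str] = set()
    for idx, row in df.iterrows():
        code = row["ingredient_code"].strip()
        category = row["category"].strip()
        if not code:
            raise SchemaError(f"{path} row {idx + 2}: empty ingredient_code")
        if category == NON_DAIRY:
            non_dairy.add(code)
            continue
        try:
            cls = DairyClass(
                category=DairyCategory(category),
                fat_level=_token(row["fat_level"], FatLevel),
                cheese_variety=_token(row["cheese_variety"], CheeseVariety),
            )
        except ValueError as exc:  # unknown enum token
            raise SchemaError(f"{path} row {idx + 2}: {exc}") from exc
        except InvalidClassError as exc:
            raise InvalidClassError(f"{path} row {idx + 2}: {exc}") from exc
        dairy[code] = cls
    return ClassificationMap(dairy=dairy, non_dairy=non_dairy)


def _token(raw: str, enum_cls):
    raw = raw.strip()
    if not raw:
        return enum_cls.NOT_APPLICABLE
    return enum_cls(raw)


def classify_ingredient(cmap: ClassificationMap, ingredient_code: str) -> Classification:
    """Return the :class:`DairyClass` of a dairy ingredient, or ``NON_DAIRY``.

    Raises :class:`UnclassifiedIngredientError` for a code in neither
    roster — an unclassified ingredient indicates data drift between the
    recipe database and the classification map and must never be silently
    treated as non-dairy.
    """
    if ingredient_code in cmap.dairy:
        return cmap.dairy[ingredient_code]
    if ingredient_code in cmap.non_dairy:
        return NON_DAIRY
    raise UnclassifiedIngredientError(f"ingredient {ingredient_code!r} is in neither roster")
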