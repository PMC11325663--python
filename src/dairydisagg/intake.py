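"""Survey-weighted per-capita dairy intake, with and without disaggregation.

Two estimation modes:

* **disaggregated** — each recall item contributes
  ``grams_consumed x profile_g_per_100g / 100`` to every dairy subtype of the
  food's resolved recipe.
* **food_group** (the naive mode) — an item whose food group is a dairy
  group contributes its *full* reported weight to that group's dairy
  category; all other items contribute nothing.  This is how dairy intake is
  usually tallied when composite foods are not decomposed: fruit yogurts and
  ice-cream products count fully (overestimation), while cheese hidden in a
  lasagna counts not at all (underestimation).

Per person, day totals are averaged over the days that person completed
(one or two recall days), then weighted across persons.  Estimates are per
capita: non-consumers contribute zeros, never dropped.  The weighted SD is
the frequency-weighted standard deviation with the same weights; complex
survey design effects (strata, clusters) are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .disaggregate import DairyProfile, PURE_DAIRY
from .errors import EmptyInputError, SchemaError, UndefinedBiasError, UnresolvableFoodError
from .taxonomy import CATEGORIES, NON_DAIRY

DISAGGREGATED = "disaggregated"
FOOD_GROUP = "food_group"
MODES = (DISAGGREGATED, FOOD_GROUP)

DENOM_WITH = "denominator_with"
DENOM_WITHOUT = "denominator_without"

_COLUMNS = [*CATEGORIES, "total"]


@dataclass(frozen=True)
class RecallItem:
    person_id: str
    day: int
    food_code: str
    grams_consumed: float


@dataclass(frozen=True)
class SurveyPerson:
    person_id: str
    weight: float
    n_days_completed: int = 1

    def __post_init__(self):
        if self.weight <= 0:
            raise SchemaError(f"person {self.person_id!r}: weight must be positive")


#: food_group -> dairy category (or the non-dairy marker) for the naive mode.
GroupDairyMap = Mapping[str, str]


@dataclass
class IntakeEstimate:
    """Weighted per-capita mean and SD of daily intake, g/day, by category."""

    mode: str
    mean: dict[str, float]
    sd: dict[str, float]
    n_persons: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subtype": _COLUMNS,
                "mean_g_per_day": [self.mean[c] for c in _COLUMNS],
                "sd_g_per_day": [self.sd[c] for c in _COLUMNS],
                "mode": self.mode,
            }
        )


@dataclass
class BiasReport:
    """Percent bias of the naive mode relative to disaggregation.

    Positive = the naive mode *under*estimates; negative = overestimates.
    The denominator convention is recorded explicitly because the percent
    depends on whether the disaggregated or the naive mean divides.
    """

    convention: str
    percent: dict[str, float]

    def rounded(self) -> dict[str, int]:
        from .disaggregate import round_half_away

        return {k: round_half_away(v) for k, v in self.percent.items()}

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subtype": list(self.percent),
                "percent_bias": list(self.percent.values()),
                "convention": self.convention,
            }
        )


@dataclass
class ContributionTable:
    """Percent of total disaggregated dairy mass contributed per food group."""

    by_group: dict[str, float]
    composite_percent: float
    noncomposite_percent: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"food_group": list(self.by_group), "percent_of_dairy": list(self.by_group.values())}
        )


def recalls_frame(recalls) -> pd.DataFrame:
    if isinstance(recalls, pd.DataFrame):
        df = recalls.copy()
    else:
        df = pd.DataFrame([vars(r) for r in recalls])
    missing = [c for c in ("person_id", "day", "food_code", "grams_consumed") if c not in df.columns]
    if missing:
        raise SchemaError(f"recalls: missing columns {missing}")
    if (pd.to_numeric(df["grams_consumed"]) < 0).any():
        raise SchemaError("recalls: grams_consumed must be non-negative")
    return df


def persons_frame(persons) -> pd.DataFrame:
    if isinstance(persons, pd.DataFrame):
        df = persons.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "person_id": p.person_id,
                    "weight": p.weight,
                    "n_days_completed": p.n_days_completed,
                }
                for p in persons
            ]
        )
    missing = [c for c in ("person_id", "weight") if c not in df.columns]
    if missing:
        raise SchemaError(f"persons: missing columns {missing}")
    if (pd.to_numeric(df["weight"]) <= 0).any():
        raise SchemaError("persons: survey weights must be positive")
    if df["person_id"].duplicated().any():
        raise SchemaError("persons: duplicate person_id")
    return df


def _category_per_100g(profiles: Mapping[str, DairyProfile]) -> pd.DataFrame:
    rows = []
    for code, p in profiles.items():
        row = {"food_code": code}
        row.update(p.by_category())
        rows.append(row)
    return pd.DataFrame(rows, columns=["food_code", *CATEGORIES])


def person_daily_intake(
    recalls,
    persons,
    mode: str,
    profiles: Optional[Mapping[str, DairyProfile]] = None,
    food_groups: Optional[Mapping[str, str]] = None,
    group_map: Optional[GroupDairyMap] = None,
) -> pd.DataFrame:
    """Per-person mean daily intake (g/day) by dairy category plus total.

    Returns one row per person in *persons* (zeros for non-consumers),
    columns ``milk ... butter, total``.  Day totals are averaged over each
    person's completed recall days.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    rec = recalls_frame(recalls)
    per = persons_frame(persons)

    unknown_persons = set(rec["person_id"]) - set(per["person_id"])
    if unknown_persons:
        raise SchemaError(f"recalls reference persons without survey weights: {sorted(unknown_persons)}")

    if mode == DISAGGREGATED:
        if profiles is None:
            raise ValueError("disaggregated mode requires profiles")
        unknown = set(rec["food_code"]) - set(profiles)
        if unknown:
            raise UnresolvableFoodError(f"recall foods without a dairy profile: {sorted(unknown)}")
        merged = rec.merge(_category_per_100g(profiles), on="food_code", how="left")
        for cat in CATEGORIES:
            merged[cat] = merged["grams_consumed"].astype(float) * merged[cat] / 100.0
    else:
        if food_groups is None or group_map is None:
            raise ValueError("food_group mode requires food_groups and group_map")
        unknown = set(rec["food_code"]) - set(food_groups)
        if unknown:
            raise UnresolvableFoodError(f"recall foods without a food group: {sorted(unknown)}")
        merged = rec.copy()
        groups = merged["food_code"].map(food_groups)
        unknown_groups = set(groups) - set(group_map)
        if unknown_groups:
            raise SchemaError(f"food groups missing from the group-dairy map: {sorted(unknown_groups)}")
        assigned = groups.map(group_map)
        for cat in CATEGORIES:
            merged[cat] = np.where(assigned == cat, merged["grams_consumed"].astype(float), 0.0)

    day_totals = merged.groupby(["person_id", "day"], sort=True)[list(CATEGORIES)].sum()
    person_means = _day_average(day_totals, per)
    out = person_means.reindex(per["person_id"].sort_values(), fill_value=0.0)
    out["total"] = out[list(CATEGORIES)].sum(axis=1)
    out.attrs["mode"] = mode
    return out


def _day_average(day_totals: pd.DataFrame, per: pd.DataFrame) -> pd.DataFrame:
    """Average per-day totals over each person's completed days.

    The divisor is the person's declared ``n_days_completed`` when the
    persons table carries one (a completed day with no dairy items still
    counts), otherwise the number of days observed in the recalls.
    """
    sums = day_totals.groupby(level="person_id", sort=True).sum()
    if "n_days_completed" in per.columns:
        divisor = (
            per.set_index("person_id")["n_days_completed"].astype(float).reindex(sums.index)
        )
    else:
        divisor = day_totals.groupby(level="person_id").size().astype(float)
    return sums.div(divisor, axis=0)


def population_mean(
    person_values: pd.DataFrame, persons, mode: Optional[str] = None
) -> IntakeEstimate:
    """Survey-weighted per-capita mean and SD across all persons.

    mean = sum(w_i x_i) / sum(w_i); SD from the frequency-weighted variance
    with the same weights.  Non-consumers are included (per capita).
    """
    per = persons_frame(persons)
    if per.empty:
        raise EmptyInputError("no persons in the survey")
    values = person_values.reindex(per["person_id"], fill_value=0.0)
    w = per["weight"].astype(float).to_numpy()
    if w.sum() <= 0:
        raise SchemaError("survey weights sum to zero")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for col in _COLUMNS:
        x = values[col].to_numpy(dtype=float)
        m = float(np.average(x, weights=w))
        var = float(np.average((x - m) ** 2, weights=w))
        mean[col] = m
        sd[col] = float(np.sqrt(var))
    return IntakeEstimate(
        mode=mode or person_values.attrs.get("mode", "unknown"),
        mean=mean,
        sd=sd,
        n_persons=len(per),
    )


def weighted_mean_se(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted mean and its linearised standard error (no design effects)."""
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    m = float(np.average(x, weights=w))
    se = float(np.sqrt(np.sum(w**2 * (x - m) ** 2)) / w.sum())
    return m, se


def bias_report(
    est_with: IntakeEstimate, est_without: IntakeEstimate, convention: str = DENOM_WITH
) -> BiasReport:
    """Percent bias of the naive estimate per subtype and total.

    ``percent = 100 x (mean_with - mean_without) / denominator`` where the
    denominator is the disaggregated mean (``denominator_with``) or the
    naive mean (``denominator_without``).  Positive values mean the naive
    mode underestimates.
    """
    if convention not in (DENOM_WITH, DENOM_WITHOUT):
        raise ValueError(f"unknown convention {convention!r}")
    percent: dict[str, float] = {}
    for col in _COLUMNS:
        num = est_with.mean[col] - est_without.mean[col]
        denom = est_with.mean[col] if convention == DENOM_WITH else est_without.mean[col]
        if denom == 0:
            if num == 0:
                percent[col] = 0.0
                continue
            raise UndefinedBiasError(f"zero denominator for {col!r} with nonzero difference")
        percent[col] = 100.0 * num / denom
    return BiasReport(convention=convention, percent=percent)


def contribution_shares(
    recalls,
    profiles: Mapping[str, DairyProfile],
    persons,
    food_groups: Mapping[str, str],
    group_map: Optional[GroupDairyMap] = None,
) -> ContributionTable:
    """Share of total disaggregated dairy mass contributed by each food group.

    Weighted per-capita dairy mass per food group divided by the weighted
    grand total, x100.  Groups are also rolled up into noncomposite (dairy
    food groups, when *group_map* is given) versus composite (everything
    else); without a *group_map* the rollup uses each food's own class
    (pure dairy = noncomposite).
    """
    rec = recalls_frame(recalls)
    per = persons_frame(persons)
    unknown = set(rec["food_code"]) - set(profiles)
    if unknown:
        raise UnresolvableFoodError(f"recall foods without a dairy profile: {sorted(unknown)}")

    totals = {code: p.total_dairy_g_per_100g for code, p in profiles.items()}
    rec = rec.copy()
    rec["dairy_g"] = rec["grams_consumed"].astype(float) * rec["food_code"].map(totals) / 100.0
    rec["food_group"] = rec["food_code"].map(food_groups)
    if rec["food_group"].isna().any():
        missing = sorted(rec.loc[rec["food_group"].isna(), "food_code"].unique())
        raise SchemaError(f"recall foods without a food group: {missing}")

    # per person-day per group, then per-person day-average, then weight
    day_group = rec.groupby(["person_id", "day", "food_group"])["dairy_g"].sum().unstack(fill_value=0.0)
    person_group = _day_average(day_group, per)
    person_group = person_group.reindex(per["person_id"], fill_value=0.0)
    w = per["weight"].astype(float).to_numpy()
    group_mass = person_group.mul(w, axis=0).sum(axis=0)
    grand = float(group_mass.sum())
    if grand == 0:
        warnings.warn("no dairy consumed: contribution table is empty", stacklevel=2)
        return ContributionTable(by_group={}, composite_percent=0.0, noncomposite_percent=0.0)

    by_group = {g: 100.0 * float(v) / grand for g, v in group_mass.sort_index().items()}

    if group_map is not None:
        noncomposite_groups = {g for g, cat in group_map.items() if cat != NON_DAIRY}
        noncomp = sum(p for g, p in by_group.items() if g in noncomposite_groups)
    else:
        pure_codes = {c for c, p in profiles.items() if p.food_class == PURE_DAIRY}
        pure_mass = rec.loc[rec["food_code"].isin(pure_codes)]
        # rollup at item level by food class, same weighting path
        day_pure = pure_mass.groupby(["person_id", "day"])[["dairy_g"]].sum()
        person_pure = (
            _day_average(day_pure, per)["dairy_g"].reindex(per["person_id"], fill_value=0.0)
        )
        noncomp = 100.0 * float((person_pure.to_numpy() * w).sum()) / grand
    return ContributionTable(
        by_group=by_group,
        composite_percent=100.0 - noncomp,
        noncomposite_percent=noncomp,
    )
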