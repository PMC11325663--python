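"""Survey-weighted intake estimation, bias, and contribution shares."""

import numpy as np
import pandas as pd
import pytest

import dairydisagg as dd
from dairydisagg.disaggregate import DairyProfile, PURE_DAIRY, NON_DAIRY_FOOD
from dairydisagg.errors import EmptyInputError, SchemaError, UndefinedBiasError, UnresolvableFoodError
from dairydisagg.intake import (
    DENOM_WITH,
    DENOM_WITHOUT,
    DISAGGREGATED,
    FOOD_GROUP,
    weighted_mean_se,
)
from dairydisagg.taxonomy import CATEGORIES, DairyCategory, DairyClass, FatLevel, NON_DAIRY


def _milk_profile(code, g_per_100g, klass=PURE_DAIRY):
    cls = DairyClass(DairyCategory.MILK, FatLevel.SEMISKIMMED)
    return DairyProfile(code, g_per_100g, {cls: g_per_100g} if g_per_100g else {}, klass, 100.0)


PROFILES = {
    "milky": _milk_profile("milky", 60.0, PURE_DAIRY),
    "cereal": _milk_profile("cereal", 0.0, NON_DAIRY_FOOD),
}
FOOD_GROUPS = {"milky": "GRP_MILK", "cereal": "GRP_CEREALS"}
GROUP_MAP = {"GRP_MILK": "milk", "GRP_CEREALS": NON_DAIRY}


def _recalls(rows):
    return pd.DataFrame(rows, columns=["person_id", "day", "food_code", "grams_consumed"])


def _persons(rows):
    return pd.DataFrame(rows, columns=["person_id", "weight"])


class TestPersonDailyIntake:
    def test_disaggregated_is_proportional(self):
        pv = dd.person_daily_intake(
            _recalls([("p1", 1, "milky", 200.0)]), _persons([("p1", 1.0)]),
            DISAGGREGATED, profiles=PROFILES,
        )
        assert pv.loc["p1", "milk"] == pytest.approx(120.0)
        assert pv.loc["p1", "total"] == pytest.approx(120.0)

    def test_naive_mode_ignores_non_dairy_groups(self):
        pv = dd.person_daily_intake(
            _recalls([("p1", 1, "cereal", 200.0)]), _persons([("p1", 1.0)]),
            FOOD_GROUP, food_groups=FOOD_GROUPS, group_map=GROUP_MAP,
        )
        assert pv.loc["p1", "total"] == 0.0

    def test_naive_mode_counts_dairy_group_foods_fully(self):
        pv = dd.person_daily_intake(
            _recalls([("p1", 1, "milky", 150.0)]), _persons([("p1", 1.0)]),
            FOOD_GROUP, food_groups=FOOD_GROUPS, group_map=GROUP_MAP,
        )
        assert pv.loc["p1", "milk"] == pytest.approx(150.0)

    def test_two_day_average(self):
        pv = dd.person_daily_intake(
            _recalls([("p1", 1, "milky", 100.0 / 0.6), ("p1", 2, "milky", 300.0 / 0.6)]),
            _persons([("p1", 1.0)]),
            DISAGGREGATED, profiles=PROFILES,
        )
        assert pv.loc["p1", "milk"] == pytest.approx(200.0)

    def test_declared_days_divide_even_if_a_day_has_no_items(self):
        persons = pd.DataFrame(
            {"person_id": ["p1"], "weight": [1.0], "n_days_completed": [2]}
        )
        pv = dd.person_daily_intake(
            _recalls([("p1", 1, "milky", 200.0)]), persons, DISAGGREGATED, profiles=PROFILES
        )
        assert pv.loc["p1", "milk"] == pytest.approx(60.0)  # 120 on day 1, 0 on day 2

    def test_unknown_food_raises(self):
        with pytest.raises(UnresolvableFoodError):
            dd.person_daily_intake(
                _recalls([("p1", 1, "nope", 1.0)]), _persons([("p1", 1.0)]),
                DISAGGREGATED, profiles=PROFILES,
            )

    def test_recall_without_weight_raises(self):
        with pytest.raises(SchemaError, match="p2"):
            dd.person_daily_intake(
                _recalls([("p2", 1, "milky", 1.0)]), _persons([("p1", 1.0)]),
                DISAGGREGATED, profiles=PROFILES,
            )


class TestPopulationMean:
    def _pv(self, values, persons):
        df = pd.DataFrame(0.0, index=[p for p, _ in persons], columns=[*CATEGORIES, "total"])
        df.index.name = "person_id"
        for (pid, _), v in zip(persons, values):
            df.loc[pid, "milk"] = v
            df.loc[pid, "total"] = v
        return df

    def test_uniform_weights_reduce_to_arithmetic_mean(self):
        persons = [("p1", 1.0), ("p2", 1.0)]
        est = dd.population_mean(self._pv([100.0, 300.0], persons), _persons(persons))
        assert est.mean["total"] == pytest.approx(200.0)

    def test_weighted_mean_hand_computed(self):
        persons = [("p1", 3.0), ("p2", 1.0)]
        est = dd.population_mean(self._pv([100.0, 300.0], persons), _persons(persons))
        assert est.mean["total"] == pytest.approx(150.0)

    def test_nonconsumers_count_in_per_capita_mean(self):
        persons = [("p1", 1.0), ("p2", 1.0)]
        pv = self._pv([100.0, 0.0], persons).drop(index="p2")
        est = dd.population_mean(pv, _persons(persons))
        assert est.mean["total"] == pytest.approx(50.0)

    def test_empty_population_raises(self):
        with pytest.raises(EmptyInputError):
            dd.population_mean(self._pv([], []), _persons([]))

    def test_total_mean_equals_sum_of_category_means(self, synth_world):
        cfg, db, cmap, gm, truth = synth_world
        profiles = dd.profile_database(db, cmap)
        recalls, persons = dd.generate_survey(cfg, db, truth)
        for mode, kwargs in [
            (DISAGGREGATED, {"profiles": profiles}),
            (FOOD_GROUP, {"food_groups": db.food_groups(), "group_map": gm}),
        ]:
            est = dd.population_mean(
                dd.person_daily_intake(recalls, persons, mode, **kwargs), persons
            )
            assert est.mean["total"] == pytest.approx(
                sum(est.mean[c] for c in CATEGORIES), abs=1e-9
            )

    def test_scale_and_weight_invariance(self, synth_world):
        cfg, db, cmap, gm, truth = synth_world
        profiles = dd.profile_database(db, cmap)
        recalls, persons = dd.generate_survey(cfg, db, truth)
        base = dd.population_mean(
            dd.person_daily_intake(recalls, persons, DISAGGREGATED, profiles=profiles), persons
        )
        scaled = recalls.assign(grams_consumed=recalls["grams_consumed"] * 3.0)
        est_scaled = dd.population_mean(
            dd.person_daily_intake(scaled, persons, DISAGGREGATED, profiles=profiles), persons
        )
        reweighted = persons.assign(weight=persons["weight"] * 17.0)
        est_rw = dd.population_mean(
            dd.person_daily_intake(recalls, reweighted, DISAGGREGATED, profiles=profiles),
            reweighted,
        )
        for col in [*CATEGORIES, "total"]:
            assert est_scaled.mean[col] == pytest.approx(3.0 * base.mean[col], rel=1e-12)
            assert est_rw.mean[col] == pytest.approx(base.mean[col], rel=1e-12)


def _estimate(mode, **means):
    mean = {c: 0.0 for c in [*CATEGORIES, "total"]}
    mean.update(means)
    return dd.IntakeEstimate(mode=mode, mean=mean, sd={k: 0.0 for k in mean}, n_persons=1)


class TestBias:
    def test_published_totals_give_8_percent_underestimation(self):
        with_ = _estimate(DISAGGREGATED, total=238.6)
        without = _estimate(FOOD_GROUP, total=218.4)
        report = dd.bias_report(with_, without, DENOM_WITH)
        assert report.rounded()["total"] == 8

    def test_equal_means_give_zero(self):
        report = dd.bias_report(_estimate("a", total=5.0), _estimate("b", total=5.0))
        assert report.percent["total"] == 0.0

    def test_meat_style_overestimation_is_44_percent(self):
        # 145 g counted fully vs 81 g disaggregated, naive-denominator convention
        with_ = _estimate(DISAGGREGATED, total=81.0)
        without = _estimate(FOOD_GROUP, total=145.0)
        report = dd.bias_report(with_, without, DENOM_WITHOUT)
        assert report.rounded()["total"] == -44

    def test_zero_denominator_with_nonzero_difference_raises(self):
        with pytest.raises(UndefinedBiasError):
            dd.bias_report(_estimate("a", total=1.0), _estimate("b"), DENOM_WITHOUT)


class TestContributions:
    def test_single_group_gets_100_percent(self):
        shares = dd.contribution_shares(
            _recalls([("p1", 1, "milky", 100.0)]), PROFILES, _persons([("p1", 1.0)]),
            FOOD_GROUPS, GROUP_MAP,
        )
        assert shares.by_group == {"GRP_MILK": pytest.approx(100.0)}
        assert shares.noncomposite_percent == pytest.approx(100.0)

    def test_direct_ratio_74_26(self):
        profiles = {
            "milky": _milk_profile("milky", 60.0, PURE_DAIRY),
            "lasagna": _milk_profile("lasagna", 60.0, "composite_dairy"),
        }
        groups = {"milky": "GRP_MILK", "lasagna": "GRP_CEREALS"}
        recalls = _recalls([("p1", 1, "milky", 74.0), ("p1", 1, "lasagna", 26.0)])
        shares = dd.contribution_shares(
            recalls, profiles, _persons([("p1", 1.0)]), groups, GROUP_MAP
        )
        assert shares.by_group["GRP_MILK"] == pytest.approx(74.0)
        assert shares.by_group["GRP_CEREALS"] == pytest.approx(26.0)
        assert shares.composite_percent == pytest.approx(26.0)

    def test_no_dairy_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no dairy"):
            shares = dd.contribution_shares(
                _recalls([("p1", 1, "cereal", 100.0)]), PROFILES, _persons([("p1", 1.0)]),
                FOOD_GROUPS, GROUP_MAP,
            )
        assert shares.by_group == {}

    def test_shares_sum_to_100_and_match_generator_truth(self, synth_world):
        cfg, db, cmap, gm, truth = synth_world
        profiles = dd.profile_database(db, cmap)
        recalls, persons = dd.generate_survey(cfg, db, truth)
        shares = dd.contribution_shares(recalls, profiles, persons, db.food_groups(), gm)
        assert sum(shares.by_group.values()) == pytest.approx(100.0, abs=1e-6)
        # Monte-Carlo agreement with the generator's planted noncomposite share
        assert shares.noncomposite_percent == pytest.approx(
            truth.expected_noncomposite_percent, abs=8.0
        )


def test_weighted_mean_se_matches_closed_form():
    x = np.array([1.0, 2.0, 4.0])
    w = np.array([1.0, 1.0, 2.0])
    m, se = weighted_mean_se(x, w)
    assert m == pytest.approx(2.75)
    expected_se = np.sqrt(np.sum(w**2 * (x - m) ** 2)) / w.sum()
    assert se == pytest.approx(expected_se)
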