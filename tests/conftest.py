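import pytest

import dairydisagg as dd


@pytest.fixture(scope="session")
def ref_bundle():
    """Worked-example fixture set (croissant, Yorkshire pudding, ...)."""
    return dd.reference_fixtures()


@pytest.fixture(scope="session")
def ref_profiles(ref_bundle):
    db, cmap, _ = ref_bundle
    return dd.profile_database(db, cmap)


@pytest.fixture(scope="session")
def synth_world():
    """One mid-size generated world shared across tests."""
    cfg = dd.GeneratorConfig(seed=7, n_foods=300, n_persons=500)
    db, cmap, group_map, truth = dd.generate_recipe_db(cfg)
    return cfg, db, cmap, group_map, truth


def random_acyclic_entries(rng, n_foods=20, n_base=8, max_children=4):
    """Random acyclic recipe graph: food i may only use foods j > i or bases.

    Returns the plain ``{parent: [(component, grams), ...]}`` mapping used
    by the brute-force flattener; grams need not sum to 100.
    """
    foods = [f"f{i:02d}" for i in range(n_foods)]
    bases = [f"b{i:02d}" for i in range(n_base)]
    entries = {}
    for i, food in enumerate(foods):
        if rng.random() < 0.25:  # leave some foods base-only
            continue
        pool = foods[i + 1 :] + bases
        k = int(rng.integers(1, min(max_children, len(pool)) + 1))
        chosen = rng.choice(pool, size=k, replace=False)
        entries[food] = [
            (str(c), round(float(rng.uniform(1, 80)), 2)) for c in chosen
        ]
    return foods, bases, entries


def entries_to_db(foods, entries, group="GRP_CEREALS"):
    import warnings

    records = {f: dd.FoodRecord(f, "", group) for f in foods}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # random totals stray outside the validity window
        return dd.RecipeDatabase(
            foods=records,
            entries={
                p: [dd.RecipeEntry(p, c, g) for c, g in comps]
                for p, comps in entries.items()
            },
        )
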