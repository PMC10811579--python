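"""Trial pipeline: gating, randomization, filtering, density, estimation."""

import numpy as np
import pandas as pd
import pytest

from nutriswap import (
    AllocationPlan,
    Catalog,
    Participant,
    ancova,
    basket_density,
    check_engagement,
    filter_purchases,
    progression_report,
    randomize,
    unadjusted_change,
)
from nutriswap.trial import blocks_for, report_percentage

from conftest import make_product, purchase_rows


# ---------------------------------------------------------------------------
# engagement gating

def _log(trips):
    """trips: list of (day, [barcodes])."""
    frames = [
        purchase_rows("P1", barcodes, timestamp=f"2021-04-{5 + day:02d} 10:00")
        for day, barcodes in trips
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def category_catalog(taxonomy):
    # one product per category-like barcode; categories via distinct ids
    from nutriswap import Category, CategoryTaxonomy

    cats = [Category(f"c{i}", f"cat {i}") for i in range(12)]
    products = [make_product(f"B{i}", category_id=f"c{i}") for i in range(12)]
    return Catalog(products, CategoryTaxonomy(cats))


def test_engagement_pass_two_trips_three_categories(category_catalog):
    log = _log([(0, ["B0", "B1", "B2"]), (3, ["B3", "B4", "B5"])])
    result = check_engagement(log, category_catalog)
    assert result.passed
    assert result.qualifying_trips == 2
    assert result.distinct_categories == 6


def test_engagement_needs_two_qualifying_trips(category_catalog):
    log = _log([(0, [f"B{i}" for i in range(10)])])  # 1 trip, 10 categories
    result = check_engagement(log, category_catalog)
    assert not result.passed
    assert result.failed_clauses == ("a",)


def test_engagement_needs_five_categories_overall(category_catalog):
    log = _log([
        (0, ["B0", "B1", "B2"]),
        (2, ["B1", "B2", "B3"]),
        (4, ["B0", "B2", "B3"]),
    ])  # 3 qualifying trips but only 4 distinct categories
    result = check_engagement(log, category_catalog)
    assert not result.passed
    assert result.failed_clauses == ("b",)


# ---------------------------------------------------------------------------
# randomization

def _participants(n, stratum="sugars"):
    return [Participant(id=f"P{i}", nutrient_of_concern=stratum) for i in range(n)]


def test_block_of_four_forces_three_to_one():
    for seed in range(20):
        people = _participants(4)
        randomize(people, AllocationPlan(seed=seed, block_sizes=(4,)))
        arms = [p.arm for p in people]
        assert arms.count("intervention") == 3
        assert arms.count("control") == 1


def test_twelve_participants_always_nine_intervention():
    for seed in range(50):
        people = _participants(12)
        assignments = randomize(people, AllocationPlan(seed=seed))
        assert sum(a == "intervention" for a in assignments.values()) == 9


def test_randomization_is_reproducible_and_single_shot():
    a = randomize(_participants(20), AllocationPlan(seed=11))
    b = randomize(_participants(20), AllocationPlan(seed=11))
    assert a == b
    people = _participants(4)
    randomize(people, AllocationPlan(seed=1))
    with pytest.raises(ValueError):
        randomize(people, AllocationPlan(seed=2))


def test_blocks_are_exactly_three_to_one():
    rng = np.random.default_rng(5)
    for _ in range(300):
        n = int(rng.integers(1, 60))
        for block in blocks_for(n, AllocationPlan(seed=0), rng):
            assert len(block) in (4, 8)
            i = block.count("intervention")
            assert (i, len(block) - i) in ((3, 1), (6, 2))


def test_allocation_balance_closes_after_complete_blocks():
    """Within a stratum the 3:1 balance is exact after every complete
    block and boundedly off inside one (at most one 6+2 block's worth)."""
    rng = np.random.default_rng(9)
    for _ in range(200):
        blocks = blocks_for(40, AllocationPlan(seed=0), rng)
        i = c = 0
        for block in blocks:
            for arm in block:
                i += arm == "intervention"
                c += arm == "control"
                assert abs(i - 3 * c) <= 6
            assert i == 3 * c  # complete block closes the ratio


# ---------------------------------------------------------------------------
# purchase filtering and basket density

@pytest.fixture
def filter_catalog(taxonomy):
    return Catalog(
        [
            make_product("OK1"), make_product("OK2"), make_product("OK3"),
            make_product("OK4"), make_product("OK5"), make_product("OK6"),
            make_product("FRUIT", category_id="fruit"),
            make_product("NOPACK", pack_amount=None),
        ],
        taxonomy,
    )


def test_filter_accounting_fixture(filter_catalog):
    log = pd.concat(
        [
            purchase_rows("P1", ["OK1", "OK2", "OK3", "OK4", "OK5", "OK6"]),
            purchase_rows("P1", [None, None]),          # 2 manual entries
            purchase_rows("P1", ["FRUIT"]),             # minimal-nutrient
            purchase_rows("P1", ["NOPACK"]),            # missing pack size
        ],
        ignore_index=True,
    )
    included, tallies = filter_purchases(log, filter_catalog)
    assert len(included) == 6
    assert tallies == {"manual_entry": 2, "minimal_nutrient": 1,
                       "missing_info": 1}
    assert len(included) + sum(tallies.values()) == len(log)


def test_filter_precedence_manual_wins(filter_catalog):
    # a manually entered fresh-fruit item is counted once, as manual
    log = purchase_rows("P1", [None])
    log.loc[0, "barcode"] = "FRUIT"
    log.loc[0, "manual_entry"] = 1
    _, tallies = filter_purchases(log, filter_catalog)
    assert tallies == {"manual_entry": 1, "minimal_nutrient": 0,
                       "missing_info": 0}


def test_unresolvable_barcode_counts_as_missing_info(filter_catalog):
    included, tallies = filter_purchases(
        purchase_rows("P1", ["UNKNOWN"]), filter_catalog
    )
    assert len(included) == 0
    assert tallies["missing_info"] == 1


def _basket(items, taxonomy):
    """items: list of (pack_amount, sugars, quantity)."""
    products = [
        make_product(f"I{i}", pack_amount=pack, sugars=s)
        for i, (pack, s, _) in enumerate(items)
    ]
    catalog = Catalog(products, taxonomy)
    frames = [
        purchase_rows("P1", [f"I{i}"], quantity=q)
        for i, (_, _, q) in enumerate(items)
    ]
    log = pd.concat(frames, ignore_index=True)
    included, _ = filter_purchases(log, catalog, ("sugars",))
    return included


@pytest.mark.parametrize(
    "items,expected",
    [
        ([(500, 4.0, 1)], 4.0),
        ([(500, 4.0, 1), (500, 8.0, 1)], 6.0),
        ([(900, 0.0, 1), (100, 10.0, 1)], 1.0),
    ],
)
def test_basket_density_weighted_mean(items, expected, taxonomy):
    included = _basket(items, taxonomy)
    assert basket_density(included, None, "sugars") == pytest.approx(expected)


def test_basket_density_split_invariance(taxonomy):
    whole = _basket([(600, 9.0, 1), (300, 3.0, 1)], taxonomy)
    split = _basket([(300, 9.0, 1), (300, 9.0, 1), (300, 3.0, 1)], taxonomy)
    assert basket_density(whole, None, "sugars") == pytest.approx(
        basket_density(split, None, "sugars")
    )


def test_basket_density_zero_mass_is_undefined(taxonomy):
    included = _basket([(500, 4.0, 1)], taxonomy)
    assert np.isnan(basket_density(included.iloc[:0], None, "sugars"))


# ---------------------------------------------------------------------------
# estimation

def test_unadjusted_change_degenerate_and_symmetric():
    zero = unadjusted_change([3.0, 4.0], [3.0, 4.0])
    assert zero.mean == 0.0 and zero.ci_low == 0.0 and zero.ci_high == 0.0

    sym = unadjusted_change([0.0, 0.0, 0.0], [-2.0, 0.0, 2.0])
    assert sym.mean == 0.0
    # closed-form t-interval: t_{.975,2} * sd/sqrt(n) = 4.30265*2/sqrt(3)
    assert sym.ci_high == pytest.approx(4.9683, abs=1e-3)
    assert sym.ci_low == pytest.approx(-sym.ci_high)

    single = unadjusted_change([1.0], [2.0])
    assert single.mean == 1.0 and np.isnan(single.ci_low)


def _six_row_data():
    return pd.DataFrame(
        {
            "arm": ["intervention"] * 3 + ["control"] * 3,
            "baseline": [5.0, 6.5, 4.0, 5.5, 6.0, 4.5],
            "followup": [4.2, 5.1, 3.9, 5.6, 6.2, 4.4],
        }
    )


def test_ancova_matches_normal_equations():
    data = _six_row_data()
    est = ancova(data)
    X = np.column_stack(
        [
            np.ones(6),
            (data["arm"] == "intervention").to_numpy(float),
            data["baseline"].to_numpy(float),
        ]
    )
    y = data["followup"].to_numpy(float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)  # independent oracle
    assert est.difference == pytest.approx(beta[1], rel=1e-12)
    assert est.ci_low < est.difference < est.ci_high
    assert 0.0 <= est.p_value <= 1.0


def test_ancova_identical_arms_give_zero_effect():
    data = pd.DataFrame(
        {
            "arm": ["intervention"] * 4 + ["control"] * 4,
            "baseline": [5.0, 6.0, 7.0, 8.0] * 2,
            "followup": [4.0, 5.0, 6.0, 7.0] * 2,
        }
    )
    est = ancova(data)
    assert est.difference == pytest.approx(0.0, abs=1e-12)


def test_ancova_arm_coefficient_is_adjusted_mean_difference():
    est = ancova(_six_row_data())
    assert est.difference == pytest.approx(
        est.adjusted_change["intervention"][0] - est.adjusted_change["control"][0]
    )


def test_ancova_without_baseline_reduces_to_raw_mean_difference():
    data = _six_row_data()
    est = ancova(data, adjust_baseline=False)
    raw = (
        data.loc[data["arm"] == "intervention", "followup"].mean()
        - data.loc[data["arm"] == "control", "followup"].mean()
    )
    assert est.difference == pytest.approx(raw, rel=1e-12)


def test_ancova_collinear_design_names_column():
    data = _six_row_data()
    data["dup"] = data["baseline"]
    with pytest.raises(ValueError, match="dup"):
        ancova(data, covariates=["dup"])


def test_ancova_recovers_simulated_effect():
    """Parameter recovery with a known additive −1.0 effect."""
    rng = np.random.default_rng(2024)
    n = 200
    baseline = rng.normal(5.0, 1.0, 2 * n)
    arm = np.array(["intervention"] * n + ["control"] * n)
    effect = np.where(arm == "intervention", -1.0, 0.0)
    followup = 0.8 * baseline + effect + rng.normal(0, 1.0, 2 * n)
    est = ancova(pd.DataFrame({"arm": arm, "baseline": baseline,
                               "followup": followup}))
    mc_se = 1.0 * np.sqrt(2.0 / n)
    assert abs(est.difference - (-1.0)) < 3 * mc_se


def test_ancova_with_categorical_covariate():
    data = _six_row_data()
    data["gender"] = ["woman", "man", "woman", "man", "woman", "man"]
    est = ancova(data, covariates=["gender"])
    assert est.covariates == ("gender",)
    assert np.isfinite(est.difference)


# ---------------------------------------------------------------------------
# progression

def test_report_percentage_rounds_to_nearest_integer():
    assert report_percentage(30, 37) == 81
    assert report_percentage(0, 0) == 0


def _progression_inputs(n_int, k_query, k_complete):
    rand = pd.Timestamp("2021-05-03")
    roster = pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n_int)],
            "arm": ["intervention"] * n_int,
            "randomization_date": [rand] * n_int,
        }
    )
    queries = pd.DataFrame(
        [
            (f"P{i}", "t", "b", "sugars", rand + pd.Timedelta(days=5))
            for i in range(k_query)
        ],
        columns=["participant_id", "trip_id", "source_barcode", "nutrient",
                 "timestamp"],
    )
    purchases = pd.concat(
        [
            pd.concat(
                [
                    purchase_rows(f"P{i}", ["X"], timestamp="2021-05-10 10:00"),
                    purchase_rows(f"P{i}", ["X"], timestamp="2021-05-18 10:00"),
                ]
            )
            for i in range(k_complete)
        ],
        ignore_index=True,
    ) if k_complete else purchase_rows("P", ["X"]).iloc[:0]
    return roster, purchases, queries


def test_progression_small_cohort():
    roster, purchases, queries = _progression_inputs(4, 3, 2)
    report = progression_report(roster, purchases, queries)
    assert report.app_use.percentage == 75
    assert report.app_use.passed  # 75 >= 70
    assert report.follow_up.percentage == 50
    assert not report.follow_up.passed  # 50 < 60
    assert not report.proceed


def test_progression_nobody_logs():
    roster, purchases, queries = _progression_inputs(5, 0, 0)
    report = progression_report(roster, purchases, queries)
    assert report.app_use.percentage == 0
    assert report.follow_up.percentage == 0
    assert not report.proceed
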