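"""Synthetic catalogs and two-arm shopper cohorts with known ground truth.

The generator emulates the data structure of a barcode-scanning dietary
feasibility trial: a multi-retailer catalog of categorized products with
right-skewed per-100 g nutrient spreads, a 2-week run-in of logged
shopping for every participant, stratified allocation to intervention or
control, and a 4-week follow-up in which intervention participants query
the swap engine and sometimes accept a suggestion.

The intervention effect is injected mechanistically through actual swap
engine calls, never by shifting densities post hoc: a simulated shopper
who accepts a swap replaces the scanned item with the suggestion whose
per-100 g reduction in their nutrient of concern is closest to the
configured target reduction δ (δ = 0 selects the smallest available
strict reduction).  The generator records, for every intervention
participant, the counterfactual purchase log with no swaps applied; the
realized ground-truth effect per stratum is the mean difference between
actual and counterfactual follow-up basket densities, computed with the
same filtering and density code the analysis uses.  Recovery tests score
estimates against this realized truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import (
    Catalog,
    Category,
    CategoryTaxonomy,
    NutrientProfile,
    Product,
    SWAP_NUTRIENTS,
)
from .session import GOAL_COLUMNS, PURCHASE_COLUMNS, QUERY_COLUMNS, SWAP_COLUMNS, trip_id_for
from .swap import InvalidSwapQuery, SwapQuery, find_swaps
from .trial import participant_densities

#: Default seed recorded in every output's metadata.
DEFAULT_SEED = 20210411


@dataclass
class SimulationConfig:
    """Knobs of the synthetic catalog and cohort generator.

    Cohort sizes, run-in/follow-up durations and behaviour rates default
    to the two analyzed strata of a 3:1 feasibility trial: sugar
    (40 intervention / 15 control) and saturated fat (38 / 13), 2-week
    run-in, 4-week follow-up, roughly weekly shops of ~10 items, about
    3 in 10 scans triggering a swap query, and per-swap target
    reductions of −12.5 g sugars and −4 g saturates per 100 g.
    """

    seed: int = DEFAULT_SEED
    # catalog
    n_products: int = 300
    n_categories: int = 20
    n_retailers: int = 3
    minimal_category_fraction: float = 0.15
    drink_fraction: float = 0.15
    #: log-scale location and spread of the per-100 g draws, per nutrient
    nutrient_lognorm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "fat": (1.8, 0.9),
            "saturates": (0.4, 0.9),  # clipped to fat after drawing
            "sugars": (2.0, 1.0),
            "salt": (-1.0, 0.9),
        }
    )
    category_location_sd: float = 0.5
    missing_field_prob: float = 0.03
    # cohort
    arm_sizes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"sugars": (40, 15), "saturates": (38, 13)}
    )
    start_date: str = "2021-04-05"
    weeks_baseline: int = 2
    weeks_followup: int = 4
    trips_per_week: float = 1.5
    items_per_trip: float = 10.0
    manual_entry_prob: float = 0.05
    query_prob: float = 0.3
    swap_uptake: float = 0.5
    #: targeted per-swap reduction, g/100 g, <= 0; scalar or per-stratum
    delta: float | dict[str, float] = field(
        default_factory=lambda: {"sugars": -12.5, "saturates": -4.0, "salt": -1.0}
    )
    goal_mean: float = 2.0
    app_use_prob: float = 0.84
    followup_logging_prob: float = 0.91
    max_suggestions: int = 10

    def validate(self) -> None:
        for name in ("minimal_category_fraction", "drink_fraction",
                     "missing_field_prob", "manual_entry_prob", "query_prob",
                     "swap_uptake", "app_use_prob", "followup_logging_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        deltas = (self.delta.values() if isinstance(self.delta, dict)
                  else [self.delta])
        for d in deltas:
            if d > 0:
                raise ValueError("delta must be <= 0 (improvement)")

    def delta_for(self, stratum: str) -> float:
        if isinstance(self.delta, dict):
            return float(self.delta.get(stratum, 0.0))
        return float(self.delta)


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the injected effect."""

    seed: int
    per_participant: pd.DataFrame  # home retailer, app user, completes follow-up
    counterfactual_purchases: pd.DataFrame  # follow-up log with no swaps applied
    realized_effects: dict[str, float]  # stratum -> mean actual−counterfactual density


@dataclass
class SimulatedTrial:
    """One generated trial: logs, roster, and the generating truth."""

    catalog: Catalog
    roster: pd.DataFrame
    purchases: pd.DataFrame
    queries: pd.DataFrame
    swaps: pd.DataFrame
    goals: pd.DataFrame
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# catalog generation

def _draw_products(config: SimulationConfig, rng: np.random.Generator) -> tuple[list[Product], CategoryTaxonomy]:
    n_min = max(1, int(round(config.minimal_category_fraction * config.n_categories)))
    cats = []
    for i in range(config.n_categories):
        minimal = i < n_min
        cats.append(
            Category(
                category_id=f"cat{i:03d}",
                display_name=("fresh produce " if minimal else "category ") + str(i),
                minimal_nutrient=minimal,
            )
        )
    taxonomy = CategoryTaxonomy(cats)

    # per-category lognormal location offsets, one per nutrient
    offsets = {
        n: rng.normal(0.0, config.category_location_sd, config.n_categories)
        for n in config.nutrient_lognorm
    }
    products: list[Product] = []
    for i in range(config.n_products):
        ci = int(rng.integers(config.n_categories))
        cat = cats[ci]
        retailer = f"store_{int(rng.integers(config.n_retailers))}"
        is_drink = bool(rng.random() < config.drink_fraction)
        pack = float(np.round(rng.lognormal(5.8, 0.5), 0))  # ~330 g median
        vals: dict[str, float | None] = {}
        for n, (mu, sigma) in config.nutrient_lognorm.items():
            v = rng.lognormal(mu + offsets[n][ci], sigma)
            if cat.minimal_nutrient:
                v *= 0.05  # fresh produce: negligible fat/salt, low labelled sugars
            vals[n] = float(np.round(min(v, 95.0), 2))
        fat = vals.get("fat", 0.0)
        saturates = min(vals.get("saturates", 0.0), fat)
        profile = {
            "fat": fat,
            "saturates": saturates,
            "sugars": vals.get("sugars", 0.0),
            "salt": vals.get("salt", 0.0),
            "energy_kcal": float(np.round(rng.lognormal(5.0, 0.6), 0)),
        }
        # occasional missing fields, as in real label data
        pack_amount: float | None = pack
        if rng.random() < config.missing_field_prob:
            which = rng.integers(3)
            if which == 0:
                pack_amount = None
            elif which == 1:
                profile["sugars"] = None
            else:
                profile["saturates"] = None
                profile["fat"] = None
        products.append(
            Product(
                barcode=f"50{i:010d}",
                name=f"{cat.display_name} product {i}",
                retailer=retailer,
                category_id=cat.category_id,
                pack_amount=pack_amount,
                is_drink=is_drink,
                own_label=bool(rng.random() < 0.4),
                nutrients=NutrientProfile(**profile),
            )
        )
    return products, taxonomy


def _swappable_fraction(products: list[Product],
                        taxonomy: CategoryTaxonomy) -> float:
    """Fraction of non-minimal products with a strictly lower same-category
    alternative in at least one swap nutrient."""
    by_cat: dict[str, list[Product]] = {}
    for p in products:
        by_cat.setdefault(p.category_id, []).append(p)
    ok = 0
    total = 0
    for cat, members in by_cat.items():
        if taxonomy.is_minimal(cat):
            continue
        for p in members:
            total += 1
            found = False
            for n in SWAP_NUTRIENTS:
                v = p.nutrients.get(n)
                if v is None:
                    continue
                for q in members:
                    if q.barcode != p.barcode:
                        qv = q.nutrients.get(n)
                        if qv is not None and qv < v:
                            found = True
                            break
                if found:
                    break
            ok += found
    return ok / total if total else 0.0


def generate_catalog(config: SimulationConfig,
                     max_retries: int = 10) -> Catalog:
    """Generate a schema-valid catalog, deterministic in the seed.

    Resamples (bounded retries) until at least 80% of products have a
    strictly lower same-category alternative in some swap nutrient, so
    the swap engine has work to do; an unsatisfiable configuration
    (e.g. zero-variance nutrient draws) raises.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    for _ in range(max_retries):
        products, taxonomy = _draw_products(config, rng)
        if _swappable_fraction(products, taxonomy) >= 0.8:
            return Catalog(products, taxonomy,
                           version=f"synthetic-{config.seed}")
    raise RuntimeError(
        f"could not satisfy the swap-spread constraint in {max_retries} tries; "
        "widen the nutrient distributions"
    )


# ---------------------------------------------------------------------------
# cohort simulation

def _precompute_swap_targets(
    catalog: Catalog, nutrient: str, delta: float, max_suggestions: int
) -> dict[str, tuple[str, float]]:
    """For every product, the suggestion a δ-targeting shopper would accept.

    Maps barcode -> (chosen candidate barcode, signed reduction); products
    with no valid query or no suggestions are absent.  Built through real
    swap-engine calls so simulation exercises the production ranking path.
    """
    out: dict[str, tuple[str, float]] = {}
    target = abs(delta)
    for product in catalog:
        try:
            suggestions = find_swaps(
                catalog,
                SwapQuery(source=product, target_nutrient=nutrient,
                          max_suggestions=max_suggestions),
            )
        except InvalidSwapQuery:
            continue
        if not suggestions:
            continue
        best = min(suggestions,
                   key=lambda s: (abs(s.reduction_per_100 - target),
                                  s.candidate.barcode))
        out[product.barcode] = (best.candidate.barcode, -best.reduction_per_100)
    return out


def simulate_cohort(config: SimulationConfig, catalog: Catalog) -> SimulatedTrial:
    """Simulate run-in and follow-up shopping for a two-arm cohort.

    Both arms log purchases throughout; intervention participants who
    use the app additionally query the swap engine on a fraction of
    scans and accept a suggestion at the uptake probability, replacing
    the purchased item.  Same config and seed → identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)

    products = list(catalog)
    n_products = len(products)
    barcodes = np.array([p.barcode for p in products])
    retailers = sorted({p.retailer for p in products})
    retailer_of = np.array([retailers.index(p.retailer) for p in products])

    swap_targets = {
        stratum: _precompute_swap_targets(
            catalog, stratum, config.delta_for(stratum), config.max_suggestions
        )
        for stratum in config.arm_sizes
    }

    start = pd.Timestamp(config.start_date)
    rand_date = start + pd.Timedelta(days=7 * config.weeks_baseline)
    genders = np.array(["woman", "man", "other"])
    ethnicities = np.array(["White", "Asian", "Black", "mixed", "other"])
    incomes = np.array(["<15k", "15-25k", "25-40k", "40-75k", ">75k"])

    roster_rows = []
    truth_rows = []
    purchase_rows: list[tuple] = []
    cf_rows: list[tuple] = []
    query_rows: list[tuple] = []
    swap_rows: list[tuple] = []
    goal_rows: list[tuple] = []

    pid_counter = 0
    for stratum in sorted(config.arm_sizes):
        n_i, n_c = config.arm_sizes[stratum]
        arms = ["intervention"] * n_i + ["control"] * n_c
        rng.shuffle(arms)
        targets = swap_targets[stratum]
        for arm in arms:
            pid = f"P{pid_counter:04d}"
            pid_counter += 1
            home = int(rng.integers(len(retailers)))
            app_user = bool(rng.random() < config.app_use_prob)
            completes = bool(rng.random() < config.followup_logging_prob)
            roster_rows.append(
                (
                    pid, stratum, arm, rand_date,
                    float(np.clip(np.round(rng.normal(45, 12), 0), 18, 80)),
                    str(rng.choice(genders, p=[0.6, 0.38, 0.02])),
                    str(rng.choice(ethnicities, p=[0.8, 0.08, 0.05, 0.04, 0.03])),
                    str(rng.choice(incomes)),
                )
            )
            truth_rows.append((pid, retailers[home], app_user, completes))

            # persistent product preferences (shared across windows)
            pref = rng.gamma(0.5, size=n_products)

            total_weeks = config.weeks_baseline + config.weeks_followup
            for week in range(total_weeks):
                in_followup = week >= config.weeks_baseline
                if in_followup and not completes and week > config.weeks_baseline:
                    continue  # drop-out: logs only the first follow-up week
                n_trips = 1 + int(rng.poisson(max(config.trips_per_week - 1, 0)))
                n_trips = min(n_trips, 7)
                days = rng.choice(7, size=n_trips, replace=False)
                for day in np.sort(days):
                    date = start + pd.Timedelta(days=int(week * 7 + day))
                    if rng.random() < 0.8:
                        r = home
                    else:
                        r = int(rng.integers(len(retailers)))
                    retailer = retailers[r]
                    tid = trip_id_for(pid, retailer, date.date())
                    mask = retailer_of == r
                    w = pref[mask]
                    idx_pool = np.flatnonzero(mask)
                    n_items = 1 + int(rng.poisson(max(config.items_per_trip - 1, 0)))
                    idx = rng.choice(idx_pool, size=n_items, p=w / w.sum())
                    quantities = 1 + (rng.random(n_items) < 0.1).astype(int)
                    manual = rng.random(n_items) < config.manual_entry_prob
                    ts = date + pd.Timedelta(hours=10)

                    swapping = in_followup and arm == "intervention" and app_user
                    if swapping:
                        goal_rows.append((pid, tid, int(rng.poisson(config.goal_mean))))
                    do_query = rng.random(n_items) < config.query_prob
                    do_swap = rng.random(n_items) < config.swap_uptake

                    for k in range(n_items):
                        j = int(idx[k])
                        bc = barcodes[j]
                        final_bc = bc
                        if manual[k]:
                            purchase_rows.append(
                                (pid, ts, retailer, None, "manual item",
                                 int(quantities[k]), 1)
                            )
                            if in_followup:
                                cf_rows.append(purchase_rows[-1])
                            continue
                        if swapping and do_query[k] and bc in targets:
                            query_rows.append((pid, tid, bc, stratum, ts))
                            if do_swap[k]:
                                chosen, signed_red = targets[bc]
                                swap_rows.append(
                                    (pid, tid, bc, chosen, stratum,
                                     signed_red, ts)
                                )
                                final_bc = chosen
                        purchase_rows.append(
                            (pid, ts, retailer, final_bc, None,
                             int(quantities[k]), 0)
                        )
                        if in_followup:
                            cf_rows.append(
                                (pid, ts, retailer, bc, None,
                                 int(quantities[k]), 0)
                            )

    roster = pd.DataFrame(
        roster_rows,
        columns=["participant_id", "nutrient_of_concern", "arm",
                 "randomization_date", "age", "gender", "ethnicity", "income"],
    )
    purchases = pd.DataFrame(purchase_rows, columns=PURCHASE_COLUMNS)
    counterfactual = pd.DataFrame(cf_rows, columns=PURCHASE_COLUMNS)
    queries = pd.DataFrame(query_rows, columns=QUERY_COLUMNS)
    swaps = pd.DataFrame(swap_rows, columns=SWAP_COLUMNS)
    goals = pd.DataFrame(goal_rows, columns=GOAL_COLUMNS)

    realized = _realized_effects(config, catalog, roster, purchases, counterfactual)
    truth = GroundTruth(
        seed=config.seed,
        per_participant=pd.DataFrame(
            truth_rows,
            columns=["participant_id", "home_retailer", "app_user",
                     "completes_followup"],
        ),
        counterfactual_purchases=counterfactual,
        realized_effects=realized,
    )
    return SimulatedTrial(
        catalog=catalog,
        roster=roster,
        purchases=purchases,
        queries=queries,
        swaps=swaps,
        goals=goals,
        ground_truth=truth,
    )


def _realized_effects(
    config: SimulationConfig,
    catalog: Catalog,
    roster: pd.DataFrame,
    purchases: pd.DataFrame,
    counterfactual: pd.DataFrame,
) -> dict[str, float]:
    """Mean actual−counterfactual follow-up density among intervention
    participants, per stratum — the estimand recovery tests score against."""
    out: dict[str, float] = {}
    for stratum in sorted(config.arm_sizes):
        sub = roster[(roster["nutrient_of_concern"] == stratum)]
        actual = participant_densities(purchases, sub, catalog, stratum)
        cf = participant_densities(counterfactual, sub, catalog, stratum)
        merged = actual.merge(cf, on=["participant_id", "arm"],
                              suffixes=("_act", "_cf"))
        mask = merged["arm"] == "intervention"
        diff = (merged.loc[mask, "followup_act"]
                - merged.loc[mask, "followup_cf"]).dropna()
        out[stratum] = float(diff.mean()) if len(diff) else float("nan")
    return out


def config_metadata(config: SimulationConfig) -> dict:
    """Config echo (including the seed) recorded alongside every output."""
    return dataclasses.asdict(config)
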