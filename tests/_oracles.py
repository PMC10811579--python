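"""Independent oracles used by unit and acceptance tests.

The brute-force swap oracle re-derives the suggestion list from first
principles (filter then sort with an explicitly spelled-out key) without
touching the engine's code path.
"""

from __future__ import annotations

import numpy as np

from nutriswap import Catalog, Category, CategoryTaxonomy, NutrientProfile, Product
from nutriswap.catalog import SWAP_NUTRIENTS
from nutriswap.traffic_light import Color, classify_nutrient


def brute_force_swaps(catalog: Catalog, source: Product, nutrient: str,
                      max_suggestions: int, cross_retailer: bool) -> list[str]:
    """Expected suggestion barcodes, by exhaustive filter-and-sort."""
    src_value = source.nutrients.get(nutrient)
    candidates = []
    for p in catalog.category_members(source.category_id):
        if p.barcode == source.barcode:
            continue
        if not cross_retailer and p.retailer != source.retailer:
            continue
        v = p.nutrients.get(nutrient)
        if v is None or v >= src_value:
            continue
        reds = 0
        for other in SWAP_NUTRIENTS + ("fat",):
            if other == nutrient:
                continue
            ov = p.nutrients.get(other)
            if ov is not None and classify_nutrient(ov, other, p.is_drink) is Color.RED:
                reds += 1
        candidates.append((-(src_value - v), reds, p.barcode))
    candidates.sort()
    return [bc for _, _, bc in candidates[:max_suggestions]]


def random_catalog(rng: np.random.Generator, max_products: int = 50) -> Catalog:
    """A small random catalog with occasional missing values and ties."""
    n_products = int(rng.integers(2, max_products + 1))
    n_categories = int(rng.integers(1, 5))
    taxonomy = CategoryTaxonomy(
        [Category(f"c{i}", f"category {i}", minimal_nutrient=(i == 0))
         for i in range(n_categories)]
    )
    retailers = ["r0", "r1"]
    products = []
    for i in range(n_products):
        # coarse grid of values so ties are common
        def val():
            if rng.random() < 0.1:
                return None
            return float(rng.integers(0, 8)) * 2.5

        fat = val()
        saturates = None if fat is None else round(fat * float(rng.random()), 1)
        products.append(
            Product(
                barcode=f"b{i:03d}",
                name=f"item {i}",
                retailer=retailers[int(rng.integers(2))],
                category_id=f"c{int(rng.integers(n_categories))}",
                pack_amount=float(rng.integers(50, 1000)),
                is_drink=bool(rng.random() < 0.2),
                own_label=False,
                nutrients=NutrientProfile(
                    fat=fat, saturates=saturates, sugars=val(), salt=val()
                ),
            )
        )
    return Catalog(products, taxonomy)
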