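"""Shared fixtures: tiny hand-built catalogs and log builders."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from nutriswap import (
    Catalog,
    Category,
    CategoryTaxonomy,
    NutrientProfile,
    Product,
)


def make_product(
    barcode: str,
    category_id: str = "yogurt",
    retailer: str = "storeA",
    sugars: float | None = 10.0,
    saturates: float | None = 2.0,
    fat: float | None = 5.0,
    salt: float | None = 0.5,
    pack_amount: float | None = 500.0,
    is_drink: bool = False,
    name: str | None = None,
) -> Product:
    return Product(
        barcode=barcode,
        name=name or f"product {barcode}",
        retailer=retailer,
        category_id=category_id,
        pack_amount=pack_amount,
        is_drink=is_drink,
        own_label=False,
        nutrients=NutrientProfile(
            fat=fat, saturates=saturates, sugars=sugars, salt=salt
        ),
    )


@pytest.fixture
def taxonomy() -> CategoryTaxonomy:
    return CategoryTaxonomy(
        [
            Category("yogurt", "Yogurts"),
            Category("cereal", "Breakfast cereals"),
            Category("fruit", "Fresh fruit", minimal_nutrient=True),
            Category("unused", "Unused category"),
        ]
    )


@pytest.fixture
def small_catalog(taxonomy) -> Catalog:
    """Five yogurts with a spread of sugar values, plus one cereal and
    one fresh-fruit item."""
    products = [
        make_product("Y1", sugars=10.0),
        make_product("Y2", sugars=2.0),
        make_product("Y3", sugars=7.0),
        make_product("Y4", sugars=12.0),
        make_product("Y5", sugars=4.0, retailer="storeB"),
        make_product("C1", category_id="cereal", sugars=20.0),
        make_product("F1", category_id="fruit", sugars=9.0, fat=0.1,
                     saturates=0.0, salt=0.0),
    ]
    return Catalog(products, taxonomy)


def purchase_rows(
    participant_id: str,
    barcodes: list[str | None],
    timestamp: str = "2021-04-07 10:00",
    retailer: str = "storeA",
    quantity: int = 1,
) -> pd.DataFrame:
    rows = [
        {
            "participant_id": participant_id,
            "timestamp": pd.Timestamp(timestamp),
            "retailer": retailer,
            "barcode": bc,
            "manual_name": None if bc is not None else "manual item",
            "quantity": quantity,
            "manual_entry": 0 if bc is not None else 1,
        }
        for bc in barcodes
    ]
    return pd.DataFrame(rows)
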