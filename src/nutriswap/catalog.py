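"""Product catalog: domain types, validation, and indexed access.

A catalog is a barcode-indexed collection of grocery products, each
carrying a per-100 g (or per-100 ml for drinks) nutrient profile and a
category identifier resolving into a flat category taxonomy.  The swap
engine searches within a category; the trial pipeline uses the taxonomy's
``minimal_nutrient`` flag (fresh fruit and vegetables, negligible-nutrient
items such as sugar-free gum) to exclude items from basket-density
outcomes.

Missing nutrient or pack-size values are encoded explicitly as ``None``
(empty cell in CSV), never imputed as zero: downstream analyses exclude
items with missing information, so missingness must stay distinguishable
from a true zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

#: Nutrients classified by the front-of-pack scheme, per 100 g or 100 ml.
NUTRIENTS = ("fat", "saturates", "sugars", "salt")

#: Nutrients a participant may elect to reduce (the trial's strata).
SWAP_NUTRIENTS = ("saturates", "sugars", "salt")

CATALOG_COLUMNS = [
    "barcode", "name", "retailer", "category_id", "pack_amount", "unit",
    "is_drink", "own_label", "fat", "saturates", "sugars", "salt",
    "energy_kcal",
]

TAXONOMY_COLUMNS = ["category_id", "display_name", "minimal_nutrient"]


class CatalogError(Exception):
    """Structural problem with a catalog (duplicate barcode, broken taxonomy)."""


class CatalogValidationError(CatalogError):
    """A catalog-wide invariant is violated."""


@dataclass(frozen=True)
class NutrientProfile:
    """Nutrient content per 100 g of product (100 ml for drinks).

    ``None`` marks a missing value, distinct from 0.
    """

    fat: float | None = None
    saturates: float | None = None
    sugars: float | None = None
    salt: float | None = None
    energy_kcal: float | None = None

    def get(self, nutrient: str) -> float | None:
        if nutrient not in NUTRIENTS and nutrient != "energy_kcal":
            raise KeyError(f"unknown nutrient {nutrient!r}")
        return getattr(self, nutrient)

    def problems(self) -> list[str]:
        """Reasons this profile violates its invariants (empty = valid)."""
        out = []
        for n in (*NUTRIENTS, "energy_kcal"):
            v = getattr(self, n)
            if v is not None and v < 0:
                out.append(f"negative {n}")
        if (
            self.fat is not None
            and self.saturates is not None
            and self.saturates > self.fat
        ):
            out.append("saturates exceeds fat")
        return out


@dataclass(frozen=True)
class Product:
    """One barcoded grocery item.

    ``pack_amount`` is grams for foods and millilitres for drinks; when
    missing the product is excluded from basket-density outcomes.
    """

    barcode: str
    name: str
    retailer: str
    category_id: str
    pack_amount: float | None
    is_drink: bool
    own_label: bool
    nutrients: NutrientProfile

    def problems(self) -> list[str]:
        out = []
        if not self.barcode:
            out.append("empty barcode")
        if self.pack_amount is not None and self.pack_amount <= 0:
            out.append("non-positive pack_amount")
        out.extend(self.nutrients.problems())
        return out


@dataclass(frozen=True)
class Category:
    category_id: str
    display_name: str
    minimal_nutrient: bool = False


class CategoryTaxonomy:
    """Flat (non-hierarchical) set of predefined food categories."""

    def __init__(self, categories: Iterable[Category]):
        self._by_id: dict[str, Category] = {}
        for c in categories:
            if c.category_id in self._by_id:
                raise CatalogValidationError(
                    f"duplicate category_id {c.category_id!r}"
                )
            self._by_id[c.category_id] = c

    def __contains__(self, category_id: str) -> bool:
        return category_id in self._by_id

    def __iter__(self) -> Iterator[Category]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def __eq__(self, other) -> bool:
        return isinstance(other, CategoryTaxonomy) and self._by_id == other._by_id

    def get(self, category_id: str) -> Category:
        try:
            return self._by_id[category_id]
        except KeyError:
            raise KeyError(f"category_id {category_id!r} not in taxonomy") from None

    def is_minimal(self, category_id: str) -> bool:
        return self.get(category_id).minimal_nutrient

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.category_id, c.display_name, int(c.minimal_nutrient))
                for c in self
            ],
            columns=TAXONOMY_COLUMNS,
        )


@dataclass
class RejectedRow:
    """A catalog input row that failed row-level validation."""

    row_number: int
    barcode: str
    reasons: list[str]


class Catalog:
    """Barcode-indexed product collection with its category taxonomy.

    Lookup is exact-match only; an unknown barcode yields ``None`` (the
    caller falls back to manual entry), never a fuzzy match.
    """

    def __init__(
        self,
        products: Iterable[Product],
        taxonomy: CategoryTaxonomy,
        version: str = "",
        rejects: list[RejectedRow] | None = None,
    ):
        self.taxonomy = taxonomy
        self.version = version
        self.rejects: list[RejectedRow] = rejects or []
        self._by_barcode: dict[str, Product] = {}
        self._by_category: dict[str, list[Product]] = {}
        for p in products:
            if p.barcode in self._by_barcode:
                raise CatalogValidationError(f"duplicate barcode {p.barcode!r}")
            if p.category_id not in taxonomy:
                raise CatalogValidationError(
                    f"product {p.barcode!r}: unknown category_id {p.category_id!r}"
                )
            self._by_barcode[p.barcode] = p
            self._by_category.setdefault(p.category_id, []).append(p)

    def __len__(self) -> int:
        return len(self._by_barcode)

    def __iter__(self) -> Iterator[Product]:
        return iter(self._by_barcode.values())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Catalog)
            and self._by_barcode == other._by_barcode
            and self.taxonomy == other.taxonomy
        )

    def lookup(self, barcode: str) -> Product | None:
        """Exact barcode lookup; ``None`` signals not-found (not an error)."""
        if not barcode:
            return None
        return self._by_barcode.get(barcode)

    def category_members(self, category_id: str) -> list[Product]:
        """All products in a category (possibly empty); unknown id raises."""
        if category_id not in self.taxonomy:
            raise KeyError(f"category_id {category_id!r} not in taxonomy")
        return list(self._by_category.get(category_id, []))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self:
            n = p.nutrients
            rows.append(
                (
                    p.barcode, p.name, p.retailer, p.category_id,
                    p.pack_amount, "ml" if p.is_drink else "g",
                    int(p.is_drink), int(p.own_label),
                    n.fat, n.saturates, n.sugars, n.salt, n.energy_kcal,
                )
            )
        return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


# ---------------------------------------------------------------------------
# loading / writing

def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, str) and v.strip() == "") or pd.isna(v):
        return None
    return float(v)


def _row_to_product(row: dict) -> Product:
    return Product(
        barcode=str(row.get("barcode", "") or ""),
        name=str(row.get("name", "") or ""),
        retailer=str(row.get("retailer", "") or ""),
        category_id=str(row.get("category_id", "") or ""),
        pack_amount=_opt_float(row.get("pack_amount")),
        is_drink=bool(int(row.get("is_drink", 0) or 0)),
        own_label=bool(int(row.get("own_label", 0) or 0)),
        nutrients=NutrientProfile(
            fat=_opt_float(row.get("fat")),
            saturates=_opt_float(row.get("saturates")),
            sugars=_opt_float(row.get("sugars")),
            salt=_opt_float(row.get("salt")),
            energy_kcal=_opt_float(row.get("energy_kcal")),
        ),
    )


def load_taxonomy(path: str | Path) -> CategoryTaxonomy:
    """Read a taxonomy CSV: category_id,display_name,minimal_nutrient{0|1}."""
    df = pd.read_csv(path, dtype={"category_id": str, "display_name": str})
    return CategoryTaxonomy(
        Category(r.category_id, r.display_name, bool(int(r.minimal_nutrient)))
        for r in df.itertuples()
    )


def load_catalog(
    path: str | Path,
    taxonomy: CategoryTaxonomy | str | Path,
    format: str | None = None,
    version: str = "",
) -> Catalog:
    """Load and validate a product catalog from CSV or JSON.

    Rows failing row-level validation (negative nutrient, saturates above
    total fat, empty barcode, non-positive pack size) are collected in the
    returned catalog's ``rejects`` list with their reasons — never silently
    dropped.  Structural faults (duplicate barcode, category missing from
    the taxonomy, unreadable file) raise instead.

    Parameters
    ----------
    path
        Catalog file.  Format inferred from the suffix unless ``format``
        is given (``"csv"`` or ``"json"``).
    taxonomy
        A :class:`CategoryTaxonomy` or a path to a taxonomy CSV.
    """
    path = Path(path)
    if isinstance(taxonomy, (str, Path)):
        taxonomy = load_taxonomy(taxonomy)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, dtype={"barcode": str, "category_id": str})
        records = df.to_dict("records")
    elif fmt == "json":
        with open(path) as fh:
            records = json.load(fh)
        if not isinstance(records, list):
            raise CatalogError("JSON catalog must be a list of product objects")
    else:
        raise ValueError(f"unknown format {fmt!r}")

    products: list[Product] = []
    rejects: list[RejectedRow] = []
    for i, rec in enumerate(records):
        p = _row_to_product(rec)
        problems = p.problems()
        if problems:
            rejects.append(RejectedRow(i, p.barcode, problems))
        else:
            products.append(p)
    return Catalog(products, taxonomy, version=version, rejects=rejects)


def write_catalog(
    catalog: Catalog,
    path: str | Path,
    taxonomy_path: str | Path | None = None,
    format: str | None = None,
) -> None:
    """Write a catalog (and optionally its taxonomy) back to disk.

    Round-trips with :func:`load_catalog` field-for-field.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    df = catalog.to_frame()
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        records = df.to_dict("records")
        for rec in records:
            for k, v in list(rec.items()):
                if pd.isna(v):
                    rec[k] = None
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if taxonomy_path is not None:
        catalog.taxonomy.to_frame().to_csv(taxonomy_path, index=False)
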