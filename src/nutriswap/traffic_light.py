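"""UK front-of-pack traffic-light classification of nutrients.

Classifies fat, saturates, total sugars and salt as green / amber / red
per 100 g of food or 100 ml of drink, using the UK Department of Health /
FSA 2016 front-of-pack guidance thresholds.  Green and amber upper bounds
are inclusive; red is strictly above the amber bound ("more than" in the
guidance).  When a portion exceeds 100 g, a per-portion red override
applies: a nutrient whose per-portion amount exceeds the override
threshold is red regardless of its per-100 g colour.

The thresholds live in one table (:data:`DEFAULT_THRESHOLDS`) and can be
overridden from a YAML config via :func:`load_thresholds`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import yaml

from .catalog import NUTRIENTS, Product


class Color(enum.IntEnum):
    """Traffic-light colour, ordered by severity."""

    GREEN = 0
    AMBER = 1
    RED = 2
    UNKNOWN = -1  # nutrient value missing

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


@dataclass(frozen=True)
class Cutoffs:
    """Per-(nutrient, regime) bounds in g/100 g (or g/100 ml).

    ``low``: green iff value ≤ low.  ``high``: amber iff value ≤ high,
    red otherwise.  ``portion_red``: grams per portion above which the
    nutrient is red whenever the portion exceeds 100 g.
    """

    low: float
    high: float
    portion_red: float


# DH/FSA 2016 front-of-pack guidance.
DEFAULT_THRESHOLDS: dict[tuple[str, str], Cutoffs] = {
    ("fat", "food"): Cutoffs(3.0, 17.5, 21.0),
    ("saturates", "food"): Cutoffs(1.5, 5.0, 6.0),
    ("sugars", "food"): Cutoffs(5.0, 22.5, 27.0),
    ("salt", "food"): Cutoffs(0.3, 1.5, 1.8),
    ("fat", "drink"): Cutoffs(1.5, 8.75, 21.0),
    ("saturates", "drink"): Cutoffs(0.75, 2.5, 6.0),
    ("sugars", "drink"): Cutoffs(2.5, 11.25, 27.0),
    ("salt", "drink"): Cutoffs(0.3, 0.75, 1.8),
}


def load_thresholds(path: str | Path) -> dict[tuple[str, str], Cutoffs]:
    """Read a threshold override table from YAML.

    Schema: ``{nutrient: {regime: {low: x, high: y, portion_red: z}}}``;
    entries not present fall back to the defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    table = dict(DEFAULT_THRESHOLDS)
    for nutrient, regimes in raw.items():
        if nutrient not in NUTRIENTS:
            raise ValueError(f"unknown nutrient {nutrient!r} in threshold config")
        for regime, bounds in regimes.items():
            if regime not in ("food", "drink"):
                raise ValueError(f"unknown regime {regime!r} in threshold config")
            base = table[(nutrient, regime)]
            table[(nutrient, regime)] = Cutoffs(
                low=float(bounds.get("low", base.low)),
                high=float(bounds.get("high", base.high)),
                portion_red=float(bounds.get("portion_red", base.portion_red)),
            )
    return table


def classify_nutrient(
    value: float | None,
    nutrient: str,
    is_drink: bool = False,
    portion_g: float | None = None,
    thresholds: dict[tuple[str, str], Cutoffs] = DEFAULT_THRESHOLDS,
    portion_override: bool = True,
) -> Color:
    """Classify one nutrient value (g per 100 g/ml) as green/amber/red.

    A missing value yields :attr:`Color.UNKNOWN`; a negative value is an
    error.  The per-portion red override fires only when ``portion_g``
    exceeds 100 g and the per-portion amount exceeds the override bound.
    """
    if nutrient not in NUTRIENTS:
        raise ValueError(f"unknown nutrient {nutrient!r}")
    if value is None:
        return Color.UNKNOWN
    if value < 0:
        raise ValueError(f"negative nutrient value {value}")
    cut = thresholds[(nutrient, "drink" if is_drink else "food")]
    if (
        portion_override
        and portion_g is not None
        and portion_g > 100
        and value * portion_g / 100.0 > cut.portion_red
    ):
        return Color.RED
    if value <= cut.low:
        return Color.GREEN
    if value <= cut.high:
        return Color.AMBER
    return Color.RED


@dataclass(frozen=True)
class TrafficLightLabel:
    """Per-nutrient colours for one product, as shown on scanning."""

    fat: Color
    saturates: Color
    sugars: Color
    salt: Color
    regime: str  # "food_per_100g" | "drink_per_100ml"
    portion_red_override_applied: tuple[str, ...] = ()

    def color(self, nutrient: str) -> Color:
        if nutrient not in NUTRIENTS:
            raise KeyError(f"unknown nutrient {nutrient!r}")
        return getattr(self, nutrient)

    def red_count(self, exclude: str | None = None) -> int:
        """Number of red lights, optionally ignoring one nutrient."""
        return sum(
            1
            for n in NUTRIENTS
            if n != exclude and self.color(n) is Color.RED
        )


def label_product(
    product: Product,
    portion_g: float | None = None,
    thresholds: dict[tuple[str, str], Cutoffs] = DEFAULT_THRESHOLDS,
    portion_override: bool = True,
) -> TrafficLightLabel:
    """Traffic-light label for a product; missing nutrients stay unknown."""
    colors: dict[str, Color] = {}
    overridden: list[str] = []
    for n in NUTRIENTS:
        v = product.nutrients.get(n)
        c = classify_nutrient(
            v, n, product.is_drink, portion_g, thresholds, portion_override
        )
        if (
            portion_override
            and v is not None
            and portion_g is not None
            and portion_g > 100
            and c is Color.RED
            and classify_nutrient(
                v, n, product.is_drink, None, thresholds, False
            )
            is not Color.RED
        ):
            overridden.append(n)
        colors[n] = c
    return TrafficLightLabel(
        regime="drink_per_100ml" if product.is_drink else "food_per_100g",
        portion_red_override_applied=tuple(overridden),
        **colors,
    )
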