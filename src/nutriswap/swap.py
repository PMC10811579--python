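"""Healthier-swap engine: rank same-category alternatives by nutrient reduction.

Given a scanned product and the shopper's nutrient of concern (saturated
fat, total sugars, or salt), the engine returns same-category candidates
that are strictly lower in that nutrient per 100 g, ranked from the
largest to the smallest reduction.  Ties are broken deterministically:
fewer red traffic lights across the other three nutrients first, then
barcode order.  By default candidates are restricted to the source
product's retailer, so every suggestion is actually on the shelf.

Sign convention: a stored swap's ``reduction_per_100`` is signed
(candidate minus source, so negative means improvement), matching how
per-swap nutrient changes are averaged in process reports; suggestion
lists display the magnitude of the improvement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .catalog import SWAP_NUTRIENTS, Catalog, Product
from .traffic_light import TrafficLightLabel, label_product


class InvalidSwapQuery(ValueError):
    """The query violates its contract (e.g. missing target nutrient)."""


@dataclass(frozen=True)
class SwapQuery:
    source: Product
    target_nutrient: str
    max_suggestions: int = 10
    cross_retailer: bool = False

    def validate(self) -> None:
        if self.target_nutrient not in SWAP_NUTRIENTS:
            raise InvalidSwapQuery(
                f"target nutrient must be one of {SWAP_NUTRIENTS}, "
                f"got {self.target_nutrient!r}"
            )
        if self.max_suggestions < 1:
            raise InvalidSwapQuery("max_suggestions must be positive")
        if self.source.nutrients.get(self.target_nutrient) is None:
            raise InvalidSwapQuery(
                f"source {self.source.barcode!r} has no value for "
                f"{self.target_nutrient!r}"
            )


@dataclass(frozen=True)
class SwapSuggestion:
    """A healthier candidate and the magnitude of its per-100 g reduction."""

    candidate: Product
    reduction_per_100: float  # > 0, magnitude of improvement
    candidate_label: TrafficLightLabel


@dataclass(frozen=True)
class SwapRecord:
    """A swap the participant recorded during a trip (signed reduction)."""

    participant_id: str
    trip_id: str
    source_barcode: str
    chosen_barcode: str
    nutrient: str
    reduction_per_100: float  # signed; negative = improvement
    timestamp: str


def reduction(source: Product, candidate: Product, nutrient: str) -> float:
    """Signed per-100 g change in ``nutrient``: candidate minus source.

    Negative values are improvements; averaging stored records therefore
    reproduces the usual negative-means-better convention of per-swap
    nutrient-change summaries.
    """
    if nutrient not in SWAP_NUTRIENTS:
        raise ValueError(f"unknown swap nutrient {nutrient!r}")
    sv = source.nutrients.get(nutrient)
    cv = candidate.nutrients.get(nutrient)
    if sv is None or cv is None:
        raise ValueError(
            f"missing {nutrient!r} on "
            f"{source.barcode if sv is None else candidate.barcode!r}"
        )
    return cv - sv


def find_swaps(catalog: Catalog, query: SwapQuery) -> list[SwapSuggestion]:
    """Ranked healthier same-category alternatives for the query's source.

    Candidates come only from the source's category, exclude the source
    itself and anything missing the target nutrient, and must be strictly
    lower in the target nutrient per 100 g.  Sorted by reduction
    descending, ties by (fewer red lights on the other nutrients, barcode),
    truncated to ``max_suggestions``.  An empty candidate set returns an
    empty list, not an error.
    """
    query.validate()
    src = query.source
    src_value = src.nutrients.get(query.target_nutrient)
    out: list[tuple[tuple, SwapSuggestion]] = []
    for cand in catalog.category_members(src.category_id):
        if cand.barcode == src.barcode:
            continue
        if not query.cross_retailer and cand.retailer != src.retailer:
            continue
        cv = cand.nutrients.get(query.target_nutrient)
        if cv is None or cv >= src_value:
            continue
        label = label_product(cand)
        sugg = SwapSuggestion(
            candidate=cand,
            reduction_per_100=src_value - cv,
            candidate_label=label,
        )
        key = (
            -sugg.reduction_per_100,
            label.red_count(exclude=query.target_nutrient),
            cand.barcode,
        )
        out.append((key, sugg))
    out.sort(key=lambda t: t[0])
    return [s for _, s in out[: query.max_suggestions]]


def record_swap(
    suggestions: list[SwapSuggestion],
    chosen_barcode: str,
    *,
    participant_id: str,
    trip_id: str,
    source: Product,
    nutrient: str,
    timestamp: str,
) -> SwapRecord:
    """Persist the participant's choice as a signed-reduction record.

    The chosen barcode must be one of the suggestions generated for this
    source; anything else is an error (the stored reduction is copied
    from the suggestion, so off-list choices would be unquantified).
    """
    for s in suggestions:
        if s.candidate.barcode == chosen_barcode:
            return SwapRecord(
                participant_id=participant_id,
                trip_id=trip_id,
                source_barcode=source.barcode,
                chosen_barcode=chosen_barcode,
                nutrient=nutrient,
                reduction_per_100=-s.reduction_per_100,
                timestamp=timestamp,
            )
    raise ValueError(
        f"barcode {chosen_barcode!r} was not among the suggestions for "
        f"{source.barcode!r}"
    )
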