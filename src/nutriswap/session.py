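"""Trip-level shopper behaviour: segmentation, goals, feedback, process metrics.

Purchase, swap-query and swap logs are tabular (pandas DataFrames read
from CSV or JSON-lines).  A shopping trip is the unit of behaviour: all
scan events by one participant at one retailer on one calendar date.
Trip identifiers are the string ``participant|retailer|date`` so that
swap and goal records can reference trips across files.

Log schemas
-----------
purchase log : participant_id, timestamp, retailer, barcode, manual_name,
    quantity, manual_entry{0|1}
swap log     : participant_id, trip_id, source_barcode, chosen_barcode,
    nutrient, reduction_per_100 (signed, negative = improvement), timestamp
query log    : participant_id, trip_id, source_barcode, nutrient, timestamp
goal log     : participant_id, trip_id, swaps_target
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import NUTRIENTS, SWAP_NUTRIENTS, Catalog

PURCHASE_COLUMNS = [
    "participant_id", "timestamp", "retailer", "barcode", "manual_name",
    "quantity", "manual_entry",
]
SWAP_COLUMNS = [
    "participant_id", "trip_id", "source_barcode", "chosen_barcode",
    "nutrient", "reduction_per_100", "timestamp",
]
QUERY_COLUMNS = ["participant_id", "trip_id", "source_barcode", "nutrient", "timestamp"]
GOAL_COLUMNS = ["participant_id", "trip_id", "swaps_target"]


def read_log(path: str | Path) -> pd.DataFrame:
    """Read a log table from CSV (.csv) or JSON-lines (.jsonl/.json)."""
    path = Path(path)
    barcode_cols = ("barcode", "source_barcode", "chosen_barcode")
    if path.suffix.lower() in (".jsonl", ".json"):
        df = pd.read_json(path, lines=True)
        for col in barcode_cols:
            if col in df.columns:
                s = df[col]
                if pd.api.types.is_float_dtype(s):  # nulls made it float
                    s = s.astype("Int64")
                df[col] = s.astype("string")
    else:
        # force string parsing up front: a barcode column with missing
        # values would otherwise be read as float ("...066.0")
        header = pd.read_csv(path, nrows=0).columns
        dtype = {c: "string" for c in barcode_cols if c in header}
        df = pd.read_csv(path, dtype=dtype)
    return df


def write_log(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".json"):
        df.to_json(path, orient="records", lines=True)
    else:
        df.to_csv(path, index=False)


def trip_id_for(participant_id: str, retailer: str, date) -> str:
    return f"{participant_id}|{retailer}|{date}"


@dataclass(frozen=True)
class ScanEvent:
    """One barcode scan or manual product entry."""

    participant_id: str
    timestamp: pd.Timestamp
    retailer: str
    barcode: str | None
    quantity: int = 1
    manual_entry: bool = False
    manual_name: str | None = None

    def __post_init__(self):
        if self.quantity < 1:
            raise ValueError("quantity must be >= 1")
        if self.barcode is None and not self.manual_entry:
            raise ValueError("missing barcode requires manual_entry")


@dataclass
class Trip:
    """All events by one participant at one retailer on one date."""

    trip_id: str
    participant_id: str
    retailer: str
    date: object
    events: pd.DataFrame
    swaps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SWAP_COLUMNS)
    )


@dataclass(frozen=True)
class Goal:
    """Per-trip swap target a participant set in the app."""

    participant_id: str
    swaps_target: int

    def __post_init__(self):
        if self.swaps_target < 0:
            raise ValueError("swaps_target must be >= 0")


@dataclass(frozen=True)
class FeedbackSummary:
    """Goal-achievement and cumulative-reduction feedback for one trip."""

    trip_id: str
    swaps_made: int
    goal_met: bool
    total_reduction: float  # signed sum over the trip's swaps
    mean_reduction: float | None  # None when no swaps were made


def _with_trip_id(events: pd.DataFrame) -> pd.DataFrame:
    events = events.copy()
    ts = pd.to_datetime(events["timestamp"])
    events["_date"] = ts.dt.date
    events["trip_id"] = (
        events["participant_id"].astype(str)
        + "|" + events["retailer"].astype(str)
        + "|" + events["_date"].astype(str)
    )
    return events


def segment_trips(
    events: pd.DataFrame, swaps: pd.DataFrame | None = None
) -> list[Trip]:
    """Partition scan events into trips by (participant, retailer, date).

    Every event lands in exactly one trip; swap records are attached to
    their trip by ``trip_id``.
    """
    if events.empty:
        return []
    events = _with_trip_id(events)
    if swaps is None:
        swaps = pd.DataFrame(columns=SWAP_COLUMNS)
    trips = []
    for tid, grp in events.groupby("trip_id", sort=True):
        first = grp.iloc[0]
        trip_swaps = swaps[swaps["trip_id"] == tid] if len(swaps) else swaps
        trips.append(
            Trip(
                trip_id=tid,
                participant_id=str(first["participant_id"]),
                retailer=str(first["retailer"]),
                date=first["_date"],
                events=grp.drop(columns=["_date"]),
                swaps=trip_swaps,
            )
        )
    return trips


def goal_feedback(trip: Trip, goal: Goal) -> FeedbackSummary:
    """Feedback after a trip: swaps made vs goal, cumulative reduction.

    The cumulative reduction is the signed sum of the trip's recorded
    per-100 g reductions; the mean is reported missing when no swap was
    made.
    """
    swaps_made = len(trip.swaps)
    total = float(trip.swaps["reduction_per_100"].sum()) if swaps_made else 0.0
    return FeedbackSummary(
        trip_id=trip.trip_id,
        swaps_made=swaps_made,
        goal_met=swaps_made >= goal.swaps_target,
        total_reduction=total,
        mean_reduction=total / swaps_made if swaps_made else None,
    )


def nutrient_contributors(
    purchases: pd.DataFrame, catalog: Catalog, nutrient: str
) -> tuple[pd.DataFrame, int]:
    """Rank purchased products by their total contribution to one nutrient.

    Contribution of a product = nutrient g/100 g × pack grams / 100 ×
    quantity, summed over all its purchases.  Items that cannot be
    resolved to a product with both pack size and the nutrient value are
    skipped and tallied, not fatal.

    Returns
    -------
    ranking : DataFrame with columns barcode, name, total_g, sorted by
        total_g descending then barcode.
    skipped : number of purchase rows that could not contribute.
    """
    if nutrient not in NUTRIENTS:
        raise ValueError(f"unknown nutrient {nutrient!r}")
    rows = []
    skipped = 0
    for rec in purchases.itertuples():
        prod = catalog.lookup(str(rec.barcode)) if pd.notna(rec.barcode) else None
        if prod is None or prod.pack_amount is None:
            skipped += 1
            continue
        value = prod.nutrients.get(nutrient)
        if value is None:
            skipped += 1
            continue
        rows.append(
            (prod.barcode, prod.name,
             value * prod.pack_amount / 100.0 * int(rec.quantity))
        )
    if not rows:
        return pd.DataFrame(columns=["barcode", "name", "total_g"]), skipped
    df = pd.DataFrame(rows, columns=["barcode", "name", "total_g"])
    out = (
        df.groupby(["barcode", "name"], as_index=False)["total_g"]
        .sum()
        .sort_values(["total_g", "barcode"], ascending=[False, True],
                     kind="mergesort")
        .reset_index(drop=True)
    )
    return out, skipped


@dataclass
class ProcessReport:
    """Per-participant and arm-level app-use process metrics.

    ``per_participant`` has one row per participant; ``arm_summary`` has
    the across-participant mean and SD of each metric (mean of
    per-participant means, unweighted).  Trips "where the app was used"
    are counted two ways: by swap *query* (primary) and by completed
    swap (secondary).
    """

    per_participant: pd.DataFrame
    arm_summary: pd.DataFrame


def process_metrics(
    purchases: pd.DataFrame,
    queries: pd.DataFrame,
    swaps: pd.DataFrame,
    goals: pd.DataFrame | None = None,
    participants: list[str] | None = None,
) -> ProcessReport:
    """App-use process metrics over one arm's follow-up logs.

    Per participant: number and percentage of trips with at least one
    swap query, query occasions per trip, completed-swap trips, mean
    goal set per trip, and mean signed reduction per swap for each
    nutrient.  Participants with zero trips get missing metrics.
    """
    events = _with_trip_id(purchases) if len(purchases) else purchases
    if participants is None:
        participants = sorted(set(map(str, events["participant_id"])) if len(events) else set())
    goals = goals if goals is not None else pd.DataFrame(columns=GOAL_COLUMNS)

    rows = []
    for pid in participants:
        ev = events[events["participant_id"].astype(str) == pid] if len(events) else events
        n_trips = ev["trip_id"].nunique() if len(ev) else 0
        row: dict = {"participant_id": pid, "n_trips": n_trips}
        if n_trips == 0:
            for k in ("trips_with_query", "pct_trips_with_query",
                      "queries_per_trip", "trips_with_swap", "goals_per_trip"):
                row[k] = np.nan
            for n in SWAP_NUTRIENTS:
                row[f"mean_reduction_{n}"] = np.nan
            rows.append(row)
            continue
        q = queries[queries["participant_id"].astype(str) == pid] if len(queries) else queries
        s = swaps[swaps["participant_id"].astype(str) == pid] if len(swaps) else swaps
        g = goals[goals["participant_id"].astype(str) == pid] if len(goals) else goals
        trips_with_query = q["trip_id"].nunique() if len(q) else 0
        row["trips_with_query"] = trips_with_query
        row["pct_trips_with_query"] = 100.0 * trips_with_query / n_trips
        row["queries_per_trip"] = (len(q) if len(q) else 0) / n_trips
        row["trips_with_swap"] = s["trip_id"].nunique() if len(s) else 0
        row["goals_per_trip"] = (
            float(g["swaps_target"].mean()) if len(g) else np.nan
        )
        for n in SWAP_NUTRIENTS:
            sn = s[s["nutrient"] == n] if len(s) else s
            row[f"mean_reduction_{n}"] = (
                float(sn["reduction_per_100"].mean()) if len(sn) else np.nan
            )
        rows.append(row)

    per_participant = pd.DataFrame(rows)
    metrics = [c for c in per_participant.columns if c != "participant_id"]
    arm_summary = pd.DataFrame(
        {
            "mean": per_participant[metrics].mean(),
            "sd": per_participant[metrics].std(ddof=1),
            "n": per_participant[metrics].count(),
        }
    )
    return ProcessReport(per_participant=per_participant, arm_summary=arm_summary)
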