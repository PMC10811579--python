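"""Trip segmentation, goal feedback, contributor ranking, process metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nutriswap import (
    Goal,
    goal_feedback,
    nutrient_contributors,
    process_metrics,
    segment_trips,
)
from nutriswap.session import SWAP_COLUMNS, read_log, write_log

from conftest import make_product, purchase_rows
from nutriswap import Catalog


def test_trips_split_by_retailer_and_date():
    a = purchase_rows("P1", ["X"] * 3, retailer="storeA")
    b = purchase_rows("P1", ["X"] * 3, retailer="storeB")
    trips = segment_trips(pd.concat([a, b], ignore_index=True))
    assert len(trips) == 2
    assert {t.retailer for t in trips} == {"storeA", "storeB"}

    c = purchase_rows("P1", ["X"], timestamp="2021-04-07 09:00")
    d = purchase_rows("P1", ["X"], timestamp="2021-04-08 09:00")
    assert len(segment_trips(pd.concat([c, d], ignore_index=True))) == 2

    assert segment_trips(pd.DataFrame(columns=a.columns)) == []


@settings(max_examples=50, deadline=None)
@given(st.lists(
    st.tuples(st.sampled_from(["P1", "P2"]),
              st.sampled_from(["storeA", "storeB"]),
              st.integers(0, 3)),
    max_size=30,
))
def test_trip_partition_conserves_events(rows):
    """Every event lands in exactly one trip."""
    events = pd.DataFrame(
        [
            {
                "participant_id": pid,
                "timestamp": pd.Timestamp("2021-04-05") + pd.Timedelta(days=day),
                "retailer": retailer,
                "barcode": "X",
                "manual_name": None,
                "quantity": 1,
                "manual_entry": 0,
            }
            for pid, retailer, day in rows
        ]
    )
    trips = segment_trips(events)
    assert sum(len(t.events) for t in trips) == len(events)
    keys = [(t.participant_id, t.retailer, t.date) for t in trips]
    assert len(keys) == len(set(keys))


def _trip_with_swaps(reductions):
    events = purchase_rows("P1", ["X", "Y"])
    swaps = pd.DataFrame(
        [
            ("P1", "P1|storeA|2021-04-07", "X", "Y", "sugars", r, "2021-04-07")
            for r in reductions
        ],
        columns=SWAP_COLUMNS,
    )
    (trip,) = segment_trips(events, swaps)
    return trip


def test_goal_feedback_arithmetic():
    trip = _trip_with_swaps([-4.0, -1.0, -5.0])
    fb = goal_feedback(trip, Goal("P1", 2))
    assert fb.goal_met is True
    assert fb.swaps_made == 3
    assert fb.total_reduction == -10.0
    assert fb.mean_reduction == pytest.approx(-10.0 / 3)


def test_goal_feedback_degenerate_cases():
    trip = _trip_with_swaps([])
    fb = goal_feedback(trip, Goal("P1", 2))
    assert fb.goal_met is False and fb.mean_reduction is None
    assert goal_feedback(trip, Goal("P1", 0)).goal_met is True  # 0 >= 0


def test_contributor_ranking(taxonomy):
    catalog = Catalog(
        [
            make_product("A", sugars=5.0, pack_amount=500.0),
            make_product("B", sugars=30.0, pack_amount=100.0),
            make_product("C", sugars=None),
        ],
        taxonomy,
    )
    log = pd.concat(
        [
            purchase_rows("P1", ["A"], quantity=2),  # 2 x 500 g x 5/100 = 50 g
            purchase_rows("P1", ["B"]),              # 1 x 100 g x 30/100 = 30 g
            purchase_rows("P1", ["C"]),              # missing sugars -> skipped
        ],
        ignore_index=True,
    )
    ranking, skipped = nutrient_contributors(log, catalog, "sugars")
    assert list(ranking["barcode"]) == ["A", "B"]
    assert list(ranking["total_g"]) == [50.0, 30.0]
    assert skipped == 1

    only_missing = purchase_rows("P1", ["C", "C"])
    ranking, skipped = nutrient_contributors(only_missing, catalog, "sugars")
    assert ranking.empty and skipped == 2

    single, skipped = nutrient_contributors(purchase_rows("P1", ["B"]), catalog, "sugars")
    assert len(single) == 1 and single.loc[0, "total_g"] == 30.0 and skipped == 0


def test_process_metrics_bookkeeping():
    """Per-participant means are exact counts, not estimates."""
    # P1: 4 trips on distinct days, swap queries in 3 of them
    frames = [
        purchase_rows("P1", ["X", "Y"], timestamp=f"2021-05-{10 + d:02d} 10:00")
        for d in range(4)
    ]
    purchases = pd.concat(frames, ignore_index=True)
    tids = [f"P1|storeA|2021-05-{10 + d:02d}" for d in range(4)]
    queries = pd.DataFrame(
        [("P1", tids[d], "X", "sugars", f"2021-05-{10 + d:02d} 10:05")
         for d in (0, 1, 2)]
        + [("P1", tids[0], "Y", "sugars", "2021-05-10 10:06")],
        columns=["participant_id", "trip_id", "source_barcode", "nutrient",
                 "timestamp"],
    )
    swaps = pd.DataFrame(
        [
            ("P1", tids[0], "X", "Y", "sugars", -10.0, "2021-05-10"),
            ("P1", tids[1], "X", "Y", "sugars", -15.0, "2021-05-11"),
        ],
        columns=SWAP_COLUMNS,
    )
    report = process_metrics(purchases, queries, swaps)
    row = report.per_participant.iloc[0]
    assert row["n_trips"] == 4
    assert row["trips_with_query"] == 3
    assert row["pct_trips_with_query"] == 75.0
    assert row["queries_per_trip"] == 1.0  # 4 occasions / 4 trips
    assert row["trips_with_swap"] == 2
    assert row["mean_reduction_sugars"] == -12.5
    assert np.isnan(row["mean_reduction_salt"])


def test_process_metrics_no_queries_and_no_trips():
    purchases = purchase_rows("P1", ["X"])
    empty = pd.DataFrame(columns=["participant_id", "trip_id",
                                  "source_barcode", "nutrient", "timestamp"])
    swaps = pd.DataFrame(columns=SWAP_COLUMNS)
    report = process_metrics(purchases, empty, swaps, participants=["P1", "P2"])
    by_id = report.per_participant.set_index("participant_id")
    assert by_id.loc["P1", "pct_trips_with_query"] == 0.0
    assert np.isnan(by_id.loc["P2", "pct_trips_with_query"])  # zero trips


def test_log_round_trip(tmp_path):
    log = purchase_rows("P1", ["X", None, "Y"])
    for name in ("log.csv", "log.jsonl"):
        path = tmp_path / name
        write_log(log, path)
        back = read_log(path)
        assert len(back) == 3
        assert list(back["barcode"].fillna("??")) == ["X", "??", "Y"]
        assert list(back["quantity"]) == [1, 1, 1]
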