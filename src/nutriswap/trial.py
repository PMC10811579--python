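"""Feasibility-trial computations.

Implements the analytic path of a two-arm (3:1) feasibility trial of a
healthier-swap shopping app: run-in engagement gating, stratified
permuted-block randomization, purchase-inclusion filtering, mass-weighted
basket nutrient density (g per 100 g of purchased food), progression
criteria, and exploratory baseline-adjusted effect estimation (ANCOVA:
OLS of follow-up density on arm + baseline density, optionally plus
covariates; the arm coefficient is the between-group difference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .catalog import SWAP_NUTRIENTS, Catalog
from .session import _with_trip_id

ARMS = ("intervention", "control")

#: Exclusion reasons, in precedence order: each item gets exactly one.
EXCLUSION_REASONS = ("manual_entry", "minimal_nutrient", "missing_info")


@dataclass
class Participant:
    """A trial participant; the stratum is the chosen nutrient of concern."""

    id: str
    nutrient_of_concern: str
    age: float | None = None
    gender: str | None = None
    ethnicity: str | None = None
    income: str | None = None
    arm: str = "unassigned"

    def __post_init__(self):
        if self.nutrient_of_concern not in SWAP_NUTRIENTS:
            raise ValueError(
                f"stratum must be one of {SWAP_NUTRIENTS}, "
                f"got {self.nutrient_of_concern!r}"
            )


@dataclass(frozen=True)
class AllocationPlan:
    """Stratified permuted-block allocation, 3:1 intervention:control.

    Each block contains interventions and controls in exact 3:1
    proportion (3+1 for size 4, 6+2 for size 8); the block size is drawn
    uniformly from ``block_sizes`` per block within each stratum.
    """

    seed: int
    ratio: tuple[int, int] = (3, 1)
    block_sizes: tuple[int, ...] = (4, 8)

    def __post_init__(self):
        unit = sum(self.ratio)
        for b in self.block_sizes:
            if b % unit:
                raise ValueError(
                    f"block size {b} incompatible with ratio {self.ratio}"
                )


def blocks_for(n: int, plan: AllocationPlan,
               rng: np.random.Generator) -> list[list[str]]:
    """Randomly permuted 3:1 blocks covering at least ``n`` slots.

    The block size is drawn uniformly from the permitted sizes that do
    not overshoot the remaining slots (falling back to the smallest size
    when none fits), so enrolment counts reachable by complete blocks
    always close exactly on the allocation ratio.
    """
    blocks: list[list[str]] = []
    unit = sum(plan.ratio)
    filled = 0
    while filled < n:
        fitting = [b for b in plan.block_sizes if b <= n - filled]
        size = int(rng.choice(fitting if fitting else [min(plan.block_sizes)]))
        k = size // unit
        block = (["intervention"] * (plan.ratio[0] * k)
                 + ["control"] * (plan.ratio[1] * k))
        rng.shuffle(block)
        blocks.append(block)
        filled += size
    return blocks


def allocation_sequence(n: int, plan: AllocationPlan,
                        rng: np.random.Generator) -> list[str]:
    """At-least-``n``-long arm sequence of randomly permuted 3:1 blocks."""
    return [arm for block in blocks_for(n, plan, rng) for arm in block]


def randomize(participants: Sequence[Participant],
              plan: AllocationPlan) -> dict[str, str]:
    """Assign arms within each stratum by permuted blocks.

    Assignment order is enrollment order (the order participants appear);
    the same seed always reproduces the same assignments.  A participant
    that already has an arm raises.
    """
    for p in participants:
        if p.arm != "unassigned":
            raise ValueError(f"participant {p.id!r} already assigned to {p.arm!r}")
    rng = np.random.default_rng(plan.seed)
    strata: dict[str, list[Participant]] = {}
    for p in participants:
        strata.setdefault(p.nutrient_of_concern, []).append(p)
    assignments: dict[str, str] = {}
    for stratum in sorted(strata):
        members = strata[stratum]
        seq = allocation_sequence(len(members), plan, rng)
        for p, arm in zip(members, seq):
            p.arm = arm
            assignments[p.id] = arm
    return assignments


# ---------------------------------------------------------------------------
# engagement gating

@dataclass(frozen=True)
class EngagementResult:
    """Run-in engagement check: both clauses must hold to randomize.

    Clause a: at least 2 trips each containing products from at least 3
    distinct food categories.  Clause b: at least 5 distinct categories
    across the whole run-in window.
    """

    passed: bool
    qualifying_trips: int
    distinct_categories: int
    failed_clauses: tuple[str, ...]

    min_trips: int = 2
    min_categories_per_trip: int = 3
    min_categories_overall: int = 5


def check_engagement(
    run_in_log: pd.DataFrame,
    catalog: Catalog,
    min_trips: int = 2,
    min_categories_per_trip: int = 3,
    min_categories_overall: int = 5,
) -> EngagementResult:
    """Evaluate one participant's run-in engagement against both clauses."""
    if len(run_in_log) == 0:
        return EngagementResult(False, 0, 0, ("a", "b"),
                                min_trips, min_categories_per_trip,
                                min_categories_overall)
    events = _with_trip_id(run_in_log)
    cats = []
    for bc in events["barcode"]:
        prod = catalog.lookup(str(bc)) if pd.notna(bc) else None
        cats.append(prod.category_id if prod is not None else None)
    events = events.assign(_category=cats)
    resolved = events.dropna(subset=["_category"])
    per_trip = resolved.groupby("trip_id")["_category"].nunique()
    qualifying = int((per_trip >= min_categories_per_trip).sum())
    overall = int(resolved["_category"].nunique())
    failed = []
    if qualifying < min_trips:
        failed.append("a")
    if overall < min_categories_overall:
        failed.append("b")
    return EngagementResult(
        passed=not failed,
        qualifying_trips=qualifying,
        distinct_categories=overall,
        failed_clauses=tuple(failed),
        min_trips=min_trips,
        min_categories_per_trip=min_categories_per_trip,
        min_categories_overall=min_categories_overall,
    )


# ---------------------------------------------------------------------------
# purchase filtering and basket density

def _catalog_lookup_frame(catalog: Catalog,
                          nutrients: tuple[str, ...]) -> pd.DataFrame:
    # cached per catalog: catalogs are immutable after construction
    cache = getattr(catalog, "_lookup_cache", None)
    if cache is None:
        cache = {}
        catalog._lookup_cache = cache  # type: ignore[attr-defined]
    key = tuple(nutrients)
    if key not in cache:
        df = catalog.to_frame()
        df["minimal"] = [
            catalog.taxonomy.is_minimal(c) for c in df["category_id"]
        ]
        df["barcode"] = df["barcode"].astype("string")
        cache[key] = df[["barcode", "pack_amount", "minimal", *nutrients]]
    return cache[key]


def filter_purchases(
    log: pd.DataFrame,
    catalog: Catalog,
    nutrients: tuple[str, ...] = ("saturates", "sugars"),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the trial's purchase-inclusion rules.

    Excludes, with one reason per item in this precedence order:
    manual entries first, then items in minimal-nutrient categories
    (fresh fruit and vegetables, negligible-nutrient products), then
    items missing pack size or any of the outcome ``nutrients`` (an
    unresolvable barcode counts as missing information).

    Returns the included rows — augmented with ``pack_amount`` and the
    nutrient columns, so density computations need no second lookup —
    and the exclusion tallies.  Tallies plus included rows always equal
    the logged rows.
    """
    tallies = {r: 0 for r in EXCLUSION_REASONS}
    if len(log) == 0:
        return log.copy(), tallies
    df = log.copy().reset_index(drop=True)
    lookup = _catalog_lookup_frame(catalog, nutrients)
    df["barcode"] = df["barcode"].astype("string")
    merged = df.merge(lookup, on="barcode", how="left")

    manual = merged["manual_entry"].astype(bool)
    minimal = merged["minimal"].eq(True)
    missing = (
        merged["pack_amount"].isna()
        | merged[list(nutrients)].isna().any(axis=1)
        | ~merged["minimal"].notna()  # barcode absent from catalog
    )

    reason = np.select(
        [manual, ~manual & minimal, ~manual & ~minimal & missing],
        ["manual_entry", "minimal_nutrient", "missing_info"],
        default="",
    )
    for r in EXCLUSION_REASONS:
        tallies[r] = int((reason == r).sum())
    included = merged[reason == ""].drop(columns=["minimal"])
    return included, tallies


def basket_density(
    included: pd.DataFrame,
    catalog: Catalog | None,
    nutrient: str,
) -> float:
    """Mass-weighted nutrient density of a basket, g per 100 g.

    density = 100 × Σ(nutrient/100 × mass × qty) / Σ(mass × qty), with
    drink millilitres counted as grams.  Items must carry ``pack_amount``
    and the nutrient (either from :func:`filter_purchases` or resolved
    here when a catalog is given).  Zero total mass returns ``nan`` —
    the undefined signal; such a participant is dropped from that
    window's analysis.
    """
    if nutrient not in included.columns:
        if catalog is None:
            raise ValueError(f"column {nutrient!r} absent and no catalog given")
        lookup = _catalog_lookup_frame(catalog, (nutrient,))
        included = included.merge(lookup[["barcode", "pack_amount", nutrient]],
                                  on="barcode", how="left")
    mass = included["pack_amount"].astype(float) * included["quantity"].astype(float)
    total_mass = float(mass.sum())
    if total_mass <= 0 or len(included) == 0:
        return float("nan")
    nutrient_total = float((included[nutrient].astype(float) / 100.0 * mass).sum())
    return 100.0 * nutrient_total / total_mass


@dataclass
class BasketSummary:
    """Per-window basket accounting for one participant."""

    participant_id: str
    window: str  # "baseline" | "follow-up"
    total_mass_g: float
    nutrient_totals_g: dict[str, float]
    densities: dict[str, float]
    exclusions: dict[str, int]
    n_logged: int
    n_included: int


def basket_summary(
    log: pd.DataFrame,
    catalog: Catalog,
    participant_id: str,
    window: str,
    nutrients: tuple[str, ...] = ("saturates", "sugars"),
) -> BasketSummary:
    """Filter one participant's window log and summarise mass and density."""
    sub = log[log["participant_id"].astype(str) == str(participant_id)]
    included, tallies = filter_purchases(sub, catalog, nutrients)
    if len(included):
        mass = included["pack_amount"].astype(float) * included["quantity"].astype(float)
        total_mass = float(mass.sum())
        totals = {
            n: float((included[n].astype(float) / 100.0 * mass).sum())
            for n in nutrients
        }
    else:
        total_mass = 0.0
        totals = {n: 0.0 for n in nutrients}
    densities = {
        n: (100.0 * totals[n] / total_mass if total_mass > 0 else float("nan"))
        for n in nutrients
    }
    return BasketSummary(
        participant_id=str(participant_id),
        window=window,
        total_mass_g=total_mass,
        nutrient_totals_g=totals,
        densities=densities,
        exclusions=tallies,
        n_logged=len(sub),
        n_included=len(included),
    )


# ---------------------------------------------------------------------------
# estimation

@dataclass(frozen=True)
class MeanChange:
    """Arm-level mean change (follow-up − baseline) with a t-interval."""

    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float


def unadjusted_change(baseline: Iterable[float],
                      followup: Iterable[float],
                      alpha: float = 0.05) -> MeanChange:
    """Mean within-arm change with a 95% t-interval on n−1 df.

    Baseline and follow-up must be paired per participant.  With n < 2
    the interval is undefined (nan bounds).
    """
    b = np.asarray(list(baseline), dtype=float)
    f = np.asarray(list(followup), dtype=float)
    if b.shape != f.shape:
        raise ValueError("baseline and follow-up must be paired")
    d = f - b
    n = d.size
    mean = float(d.mean()) if n else float("nan")
    if n < 2:
        return MeanChange(n, mean, float("nan"), float("nan"), float("nan"))
    sd = float(d.std(ddof=1))
    half = scipy.stats.t.ppf(1 - alpha / 2, n - 1) * sd / np.sqrt(n)
    return MeanChange(n, mean, sd, mean - half, mean + half)


@dataclass
class EffectEstimate:
    """Baseline-adjusted between-group effect for one nutrient outcome."""

    nutrient: str
    n_intervention: int
    n_control: int
    unadjusted: dict[str, MeanChange]
    adjusted_change: dict[str, tuple[float, float, float]]  # arm -> (est, lo, hi)
    difference: float  # intervention − control (arm coefficient)
    ci_low: float
    ci_high: float
    p_value: float
    covariates: tuple[str, ...]
    model: object = None  # statsmodels RegressionResults

    def summary(self) -> str:
        lines = [
            f"Outcome: {self.nutrient} density (g/100 g)",
            f"n = {self.n_intervention} intervention / {self.n_control} control"
            + (f", adjusted for {', '.join(self.covariates)}"
               if self.covariates else ""),
            "",
            f"{'arm':<14}{'change (95% CI)':<28}{'adjusted change (95% CI)':<30}",
        ]
        for arm in ARMS:
            u = self.unadjusted[arm]
            a = self.adjusted_change[arm]
            lines.append(
                f"{arm:<14}"
                f"{u.mean:.2f} ({u.ci_low:.2f} to {u.ci_high:.2f})"
                f"{'':<8}"
                f"{a[0]:.2f} ({a[1]:.2f} to {a[2]:.2f})"
            )
        lines += [
            "",
            f"Between-group difference (intervention − control): "
            f"{self.difference:.2f} (95% CI {self.ci_low:.2f} to "
            f"{self.ci_high:.2f}), p = {self.p_value:.3f}",
        ]
        return "\n".join(lines)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) == arr.shape[1]:
        return
    # name the first column that adds no rank
    rank = 0
    for j, col in enumerate(X.columns):
        r = np.linalg.matrix_rank(arr[:, : j + 1])
        if r == rank:
            raise ValueError(f"design matrix is collinear at column {col!r}")
        rank = r
    raise ValueError("design matrix is rank deficient")


def ancova(
    data: pd.DataFrame,
    covariates: Sequence[str] | None = None,
    nutrient: str = "",
    alpha: float = 0.05,
    adjust_baseline: bool = True,
) -> EffectEstimate:
    """Baseline-adjusted effect of the intervention on follow-up density.

    Fits OLS of ``followup`` on an intervention indicator and
    ``baseline`` (plus any covariates; categorical covariates are
    dummy-coded).  The arm coefficient is the between-group difference
    with a Wald 95% CI.  Adjusted within-arm changes are the fitted
    follow-up at the grand-mean baseline (and covariate means) minus the
    grand-mean baseline.

    ``data`` needs columns ``arm`` ("intervention"/"control"),
    ``baseline`` and ``followup``; rows with missing values are dropped
    (complete-case).  With ``adjust_baseline=False`` the baseline column
    is omitted and the arm coefficient reduces to the difference of raw
    follow-up means.
    """
    covariates = tuple(covariates or ())
    cols = ["arm", "baseline", "followup", *covariates]
    df = data[cols].dropna().copy()
    n_i = int((df["arm"] == "intervention").sum())
    n_c = int((df["arm"] == "control").sum())
    if n_i == 0 or n_c == 0:
        raise ValueError("both arms must be non-empty after dropping missing rows")

    X = pd.DataFrame(
        {
            "const": 1.0,
            "intervention": (df["arm"] == "intervention").astype(float),
        },
        index=df.index,
    )
    if adjust_baseline:
        X["baseline"] = df["baseline"].astype(float)
    for cov in covariates:
        col = df[cov]
        if pd.api.types.is_numeric_dtype(col):
            X[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            for c in dummies.columns:
                X[c] = dummies[c].astype(float)
    _check_full_rank(X)

    y = df["followup"].astype(float)
    res = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    names = list(X.columns)
    params = pd.Series(res.params, index=names)
    cov_params = pd.DataFrame(res.cov_params(), index=names, columns=names)
    j = names.index("intervention")
    diff = float(params["intervention"])
    se = float(np.sqrt(cov_params.iloc[j, j]))
    tcrit = scipy.stats.t.ppf(1 - alpha / 2, int(res.df_resid))
    pval = float(res.pvalues[j])

    # adjusted change = E[followup | arm, baseline = grand mean] − grand mean
    grand_mean = float(df["baseline"].mean())
    xbar = X.mean()
    adjusted: dict[str, tuple[float, float, float]] = {}
    for arm in ARMS:
        c = xbar.copy()
        c["const"] = 1.0
        c["intervention"] = 1.0 if arm == "intervention" else 0.0
        if adjust_baseline:
            c["baseline"] = grand_mean
        cv = c.to_numpy(dtype=float)
        est = float(cv @ params.to_numpy()) - grand_mean
        se_arm = float(np.sqrt(cv @ cov_params.to_numpy() @ cv))
        adjusted[arm] = (est, est - tcrit * se_arm, est + tcrit * se_arm)

    unadj = {
        arm: unadjusted_change(
            df.loc[df["arm"] == arm, "baseline"],
            df.loc[df["arm"] == arm, "followup"],
            alpha,
        )
        for arm in ARMS
    }
    return EffectEstimate(
        nutrient=nutrient,
        n_intervention=n_i,
        n_control=n_c,
        unadjusted=unadj,
        adjusted_change=adjusted,
        difference=diff,
        ci_low=diff - tcrit * se,
        ci_high=diff + tcrit * se,
        p_value=pval,
        covariates=covariates,
        model=res,
    )


def participant_densities(
    purchases: pd.DataFrame,
    roster: pd.DataFrame,
    catalog: Catalog,
    nutrient: str,
    baseline_days: tuple[int, int] = (-14, 0),
    followup_days: tuple[int, int] = (15, 28),
) -> pd.DataFrame:
    """Per-participant baseline and follow-up basket densities.

    Windows are day offsets from each participant's randomization date
    (half-open: day d is included when lo < d ≤ hi, with day 0 the
    randomization date): baseline defaults to the 2-week run-in,
    follow-up to the final 2 weeks of the 4-week follow-up.

    Returns a frame with columns participant_id, arm, baseline, followup;
    a window with no included purchases (or zero mass) is ``nan``.
    """
    included, _ = filter_purchases(purchases.reset_index(drop=True),
                                   catalog, (nutrient,))
    out = roster[["participant_id", "arm"]].copy()
    out["participant_id"] = out["participant_id"].astype(str)
    out["baseline"] = float("nan")
    out["followup"] = float("nan")
    if len(included):
        rand = dict(
            zip(roster["participant_id"].astype(str),
                pd.to_datetime(roster["randomization_date"]).dt.normalize())
        )
        pid = included["participant_id"].astype(str)
        off = (
            pd.to_datetime(included["timestamp"]).dt.normalize()
            - pid.map(rand)
        ).dt.days
        window = np.select(
            [
                (off > baseline_days[0]) & (off <= baseline_days[1]),
                (off > followup_days[0]) & (off <= followup_days[1]),
            ],
            ["baseline", "followup"],
            default="",
        )
        sub = included[window != ""].copy()
        sub["_window"] = window[window != ""]
        sub["_pid"] = pid[window != ""]
        mass = sub["pack_amount"].astype(float) * sub["quantity"].astype(float)
        sub["_mass"] = mass
        sub["_nut"] = sub[nutrient].astype(float) / 100.0 * mass
        agg = sub.groupby(["_pid", "_window"])[["_mass", "_nut"]].sum()
        dens = (100.0 * agg["_nut"] / agg["_mass"]).where(agg["_mass"] > 0)
        for window_name in ("baseline", "followup"):
            if window_name in dens.index.get_level_values("_window"):
                col = dens.xs(window_name, level="_window")
                out[window_name] = out["participant_id"].map(col).astype(float)
    return out.reset_index(drop=True)


def estimate_effect(
    purchases: pd.DataFrame,
    roster: pd.DataFrame,
    catalog: Catalog,
    nutrient: str,
    covariates: Sequence[str] | None = None,
    baseline_days: tuple[int, int] = (-14, 0),
    followup_days: tuple[int, int] = (15, 28),
) -> EffectEstimate:
    """End-to-end exploratory effect estimate for one nutrient stratum.

    Computes complete-case per-participant densities for both windows,
    then the baseline-adjusted ANCOVA.  When covariates are requested
    they are joined from the roster by participant id.
    """
    dens = participant_densities(purchases, roster, catalog, nutrient,
                                 baseline_days, followup_days)
    if covariates:
        extra = roster.set_index(roster["participant_id"].astype(str))[list(covariates)]
        dens = dens.join(extra, on="participant_id")
    return ancova(dens, covariates, nutrient=nutrient)


# ---------------------------------------------------------------------------
# progression criteria

def report_percentage(numerator: int, denominator: int) -> int:
    """Percentage rounded to the nearest integer, as reported."""
    if denominator == 0:
        return 0
    return int(round(100.0 * numerator / denominator))


@dataclass(frozen=True)
class CriterionResult:
    description: str
    numerator: int
    denominator: int
    percentage: int
    threshold_pct: float
    passed: bool


@dataclass(frozen=True)
class ProgressionReport:
    """Feasibility progression decision: both criteria must pass."""

    app_use: CriterionResult
    follow_up: CriterionResult

    @property
    def proceed(self) -> bool:
        return self.app_use.passed and self.follow_up.passed


def progression_report(
    roster: pd.DataFrame,
    purchases: pd.DataFrame,
    queries: pd.DataFrame,
    app_use_threshold: float = 70.0,
    follow_up_threshold: float = 60.0,
    followup_weeks: int = 4,
) -> ProgressionReport:
    """Evaluate both pre-specified progression criteria.

    Criterion 1 (app use): percentage of intervention participants with
    at least one swap query within 14 days of randomization, against
    70%.  Criterion 2 (follow-up): percentage of all participants with
    at least 2 distinct ISO weeks containing a logged purchase during
    the 4-week follow-up, against 60%.  Percentages are rounded to the
    nearest integer for reporting.

    ``roster`` needs participant_id, arm, randomization_date.
    """
    rand = roster.set_index(roster["participant_id"].astype(str))[
        "randomization_date"
    ].map(pd.Timestamp)

    q_ts = pd.to_datetime(queries["timestamp"]) if len(queries) else pd.Series(dtype="datetime64[ns]")
    p_ts = pd.to_datetime(purchases["timestamp"]) if len(purchases) else pd.Series(dtype="datetime64[ns]")

    intervention_ids = [
        str(r.participant_id) for r in roster.itertuples()
        if r.arm == "intervention"
    ]
    used = 0
    for pid in intervention_ids:
        r0 = rand[pid].normalize()
        mine = queries[queries["participant_id"].astype(str) == pid] if len(queries) else queries
        if len(mine) == 0:
            continue
        days = (q_ts[mine.index].dt.normalize() - r0).dt.days
        if ((days > 0) & (days <= 14)).any():
            used += 1
    c1 = CriterionResult(
        description="intervention participants obtaining a swap within 14 days",
        numerator=used,
        denominator=len(intervention_ids),
        percentage=report_percentage(used, len(intervention_ids)),
        threshold_pct=app_use_threshold,
        passed=(
            len(intervention_ids) > 0
            and 100.0 * used / len(intervention_ids) >= app_use_threshold
        ),
    )

    all_ids = [str(r.participant_id) for r in roster.itertuples()]
    completed = 0
    for pid in all_ids:
        r0 = rand[pid].normalize()
        mine = purchases[purchases["participant_id"].astype(str) == pid] if len(purchases) else purchases
        if len(mine) == 0:
            continue
        mts = p_ts[mine.index]
        days = (mts.dt.normalize() - r0).dt.days
        in_window = mts[(days > 0) & (days <= 7 * followup_weeks)]
        if len(in_window) == 0:
            continue
        iso = in_window.dt.isocalendar()
        weeks = set(zip(iso["year"], iso["week"]))
        if len(weeks) >= 2:
            completed += 1
    c2 = CriterionResult(
        description="participants logging purchases in >=2 distinct weeks of follow-up",
        numerator=completed,
        denominator=len(all_ids),
        percentage=report_percentage(completed, len(all_ids)),
        threshold_pct=follow_up_threshold,
        passed=(
            len(all_ids) > 0
            and 100.0 * completed / len(all_ids) >= follow_up_threshold
        ),
    )
    return ProgressionReport(app_use=c1, follow_up=c2)
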