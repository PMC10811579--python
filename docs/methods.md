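# Methods

## Scope and model

`nutriswap` models a purchase-level dietary intervention: shoppers scan
barcodes, see a front-of-pack traffic-light label, and are offered
same-category product swaps that strictly reduce one target nutrient
per 100 g. Around that engine sits the analytic pipeline of a two-arm
feasibility trial — engagement gating during a 2-week run-in,
stratified 3:1 permuted-block randomization, a 4-week follow-up,
purchase filtering, basket nutrient density as the outcome, progression
criteria, and exploratory baseline-adjusted (ANCOVA) effect estimation
— plus a synthetic generator that produces all inputs with recorded
ground truth.

## Traffic-light classification

Thresholds are the UK Department of Health / FSA 2016 front-of-pack
guidance, held in one table (`DEFAULT_THRESHOLDS`) and overridable from
YAML. Per 100 g food: fat ≤3.0 green / ≤17.5 amber / >17.5 red;
saturates 1.5/5.0; sugars 5.0/22.5; salt 0.3/1.5. Per 100 ml drink:
fat 1.5/8.75; saturates 0.75/2.5; sugars 2.5/11.25; salt 0.3/0.75.
Green/amber upper bounds are inclusive, red is strictly above, matching
the guidance's "more than" wording. When a portion exceeds 100 g, a
nutrient goes red if its per-portion amount exceeds 21 g fat / 6 g
saturates / 27 g sugars / 1.8 g salt; the override is on by default and
can be disabled, since front-of-pack implementations differ on it.
A missing nutrient value is always classified `unknown`, never guessed.

## Swap ranking

Candidates come from the source product's category only (one flat
category level; no cross-category swaps), exclude the source, anything
missing the target nutrient, and — by default — other retailers, so
suggestions are actually available where the shopper is standing
(`cross_retailer=True` lifts this). Only strict per-100 g reductions
survive; equal values are not "lower". Ordering is by reduction
descending, with deterministic tie-breaks: fewer red lights across the
other three nutrients, then barcode lexicographic. The list truncates
at `max_suggestions` (default 10; a screen-sized cap). Stored swap
records carry the *signed* reduction (candidate − source, negative =
improvement), so averaging records gives per-swap nutrient change with
the conventional sign; suggestion lists display magnitudes.

## Trips, engagement, progression

A shopping trip is (participant, retailer, calendar date) — the
simplest reproducible segmentation of a scan stream. Run-in engagement
requires (a) at least 2 trips each containing products from ≥3 distinct
categories and (b) ≥5 distinct categories over the whole 2-week
window; the result object reports which clause failed. Progression
criterion 1 is the percentage of intervention participants with ≥1
swap query within 14 days of randomization (threshold 70%); criterion 2
is the percentage of all participants whose follow-up logs span ≥2
distinct ISO weeks within the 4-week window (threshold 60%).
"Distinct ISO weeks with at least one logged purchase" operationalizes
"scanning for a minimum of 2 weeks" in an auditable way. Reported
percentages are rounded to the nearest integer. Process metrics count
a trip as "app-used" primarily by swap *query* and secondarily by
completed swap, since either reading of the phrase is defensible; both
are emitted. Arm-level process statistics are unweighted means and SDs
of per-participant means.

## Randomization

Within each stratum (the participant's nutrient of concern), arms come
from randomly permuted blocks with exact 3:1 composition (3+1 or 6+2).
The block size is drawn uniformly from {4, 8}, restricted to sizes
that do not overshoot the remaining enrolment — so any enrolment count
reachable by complete blocks (e.g. 12) closes exactly on the ratio —
falling back to size 4 when fewer than 4 slots remain (the final block
may then be truncated). Assignment order is enrolment order;
everything is reproducible from the plan's seed. Inside an incomplete
block the intervention-vs-3×control imbalance is bounded by 6 (the
worst prefix of a 6+2 block) and returns to 0 at every block boundary.

## Outcome construction and estimation

Purchase filtering applies one reason per excluded item in fixed
precedence: manual entry → minimal-nutrient category → missing
nutrient-or-pack information (an unresolvable barcode counts as
missing). Precedence makes the tallies disjoint and exactly
complementary to the included set. Basket density is the mass-weighted
mean in g/100 g; drinks contribute millilitres as grams (no density
model). A window with zero included mass yields `nan` and the
participant drops from that window's analysis (complete-case).

Baseline density is computed over the 2-week run-in (days −13…0
relative to randomization), follow-up over days 15–28 — the final two
weeks of follow-up — so both windows are two comparable weekly cycles.

The effect model is OLS of follow-up density on an intervention
indicator and baseline density, optionally plus covariates (age,
gender, ethnic group, income in the sensitivity set; categorical ones
are dummy-coded). The arm coefficient is the between-group difference,
with a t-based Wald 95% CI and p-value; adjusted within-arm changes
are fitted values at the grand-mean baseline (and covariate means)
minus that baseline, with delta-method intervals. Unadjusted within-arm
changes use the paired t-interval on n−1 df; n<2 yields an undefined
interval, and an all-zero change vector yields the degenerate [0,0].
CIs are 95% throughout and significance is 0.05; no multiplicity
adjustment is applied across the two nutrient outcomes, which are
exploratory and reported per stratum. A rank-deficient design raises
an error naming the first offending column rather than silently
dropping it.

## Synthetic data

`generate_catalog` draws products over categories with per-category
log-normal nutrient distributions (location shifted per category,
SD 0.5 on the log scale) — non-negative and right-skewed like real
label data; saturates is drawn from its own log-normal and clipped to
total fat. About 3% of products are missing a pack size or a nutrient,
and a configurable fraction of categories is flagged minimal-nutrient,
so every exclusion path is exercised. Generation resamples (bounded
retries) until ≥80% of non-minimal products have a strictly lower
same-category alternative in some swap nutrient; degenerate
(zero-variance) configurations therefore fail loudly.

`simulate_cohort` gives each participant a persistent product-
preference vector (Gamma(0.5) weights), a home retailer (80% of
trips), 1+Poisson(0.5) trips per week and 1+Poisson(9) items per trip
— weekly-shop behaviour consistent with the trial's process metrics
(about 1.5 trips/week, ~10 items/trip, ~3 queries per 10 scans).
Defaults reproduce the trial's structure: strata sugar (40/15
intervention/control) and saturated fat (38/13), 84% of intervention
participants actually using the swap function and 91% completing
follow-up (non-completers log only the first follow-up week). The salt
stratum, which the trial could not recruit, is omitted from the
default configuration.

**Effect injection.** A purchase log carries only barcodes, and the
analysis reads nutrients from the catalog, so the injected effect must
flow through which product gets bought. On each eligible scan an
app-using intervention participant queries with probability 0.3 and
accepts with probability 0.5 the suggestion whose per-100 g reduction
is closest to the configured target δ (δ ≤ 0; δ = 0 picks the smallest
available strict reduction; a very negative δ picks the top-ranked
suggestion). Defaults target −12.5 g sugars and −4 g saturates per
swap, the per-swap magnitudes typical of this kind of intervention.
Because the achievable reduction depends on the catalog, δ is a target,
not a guarantee; the generator therefore records the *realized* effect:
for every intervention participant it keeps the counterfactual no-swap
log, computes actual and counterfactual follow-up densities with the
same filtering/density code the analysis uses, and stores the mean
difference per stratum. Recovery is always scored against this
realized truth, which makes the check exact bookkeeping rather than a
calibration exercise.

**What the generator does not emulate:** price, promotions and store
choice economics; seasonal or holiday purchasing; household structure;
within-category brand loyalty beyond the static preference vector;
measurement error in the catalog's nutrient values. Passing tests
therefore demonstrate that the pipeline recovers what the mechanism
injected under clean logging — not that a real trial of this design
would show an effect.

## Problem sizes and numerical choices

The oracle-equivalence check runs every (product, nutrient) query on
1,000 random catalogs of ≤50 products; randomization composition is
checked over 10,000 simulated sequences; ANCOVA null coverage uses
1,000 replicates at n=30/arm simulated directly from correlated
Gaussian baseline/follow-up pairs (a property of the estimator, so the
generator is bypassed there); effect recovery uses 500 simulated trials
at n=100/arm with δ = −1.0 against one fixed catalog. These sizes keep
the full suite to a few minutes while leaving Monte-Carlo error well
inside the tolerances tested. Ties in rankings are always broken by
barcode so output is platform-independent; all randomness flows from
explicit `numpy.random.default_rng` seeds.

## Known limitations

- Trip segmentation by calendar date merges a morning and evening visit
  to the same store; the trial data cannot distinguish them either.
- The engagement rule counts categories via resolvable barcodes only;
  manual entries never contribute.
- Drinks' ml-as-g aggregation slightly misweights dense liquids.
- `estimate_effect` assumes one randomization date per roster row and
  half-open day windows; staggered multi-date enrolment works, but the
  default windows must then be interpreted per participant.
- The ANCOVA CI is a homoskedastic Wald interval; with n ≈ 10 per
  control arm it can be optimistic under variance imbalance.
- The swap mechanism's benefit grows with a shopper's baseline nutrient
  preference, so the arm coefficient (an effect at the grand-mean
  baseline) sits slightly below the participant-average realized effect
  — a small, real estimand difference visible in the recovery checks,
  not an estimator defect.
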