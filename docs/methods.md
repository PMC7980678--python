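# Methods

This note records the modelling choices behind `promoscan`, the parameters
that matter, what the synthetic generator does and does not emulate, and the
numerical conventions used at edge cases.

## Exposure construction

**Week calendar.** The year is represented as 52 week bins of 7 days; the
final two days of the calendar year fold into week 52. Every annual
denominator is therefore exactly 52. This is a fixed convention of the
package, not a claim about any particular retailer's week definition.

**Price basis.** Prices are stored per fluid ounce (shelf price divided by
package ounces) so that discounts are comparable across package sizes.

**Modal price.** The regular-price reference for each (store, product) is
the most frequently observed weekly unit price over the whole year — no
rolling window. Frequency ties are broken to the *highest* tied price:
promotions deflect prices downward, so the regular price is the upper mode.
A single observation is its own mode. Modal-price detection presumes
promotions are intermittent; if a product is discounted at one constant
depth for more than half the year the discounted price becomes the mode and
no method of this family can see the promotion (see "Generator" below).

**Discount clamping.** Weekly prices above the modal price yield a discount
of 0, not a negative promotion.

**Volume weights.** Product-level discounts are combined into a store-week
magnitude by a weighted mean with weights proportional to each product's
total purchased ounces in the analytic sample, computed once globally (not
store-specifically) and renormalized within each store-week over the
products observed there. If every observed product happens to carry zero
weight, the plain mean of discounts is used. A `uniform` scheme is
available as an alternative.

**Missingness convention.** A store-week with no price record contributes
*no information* — it is skipped in the across-store aggregation rather
than treated as "no discount offered". A household-week in which no shopped
store has any defined magnitude scores 0, which keeps the denominator of
the annual formulas at 52.

**Store sets and aggregation.** A household's store set is the year-long
set of covered stores at which it bought SSBs. The main weekly exposure
definition takes the largest store-week magnitude over that set (the
premise being that the most salient discount drives the purchase
incentive); the sensitivity definition takes the average. `largest`
dominates `average` week by week, so annual magnitude under `largest` is
always at least that under `average` — the mechanical reason the
average-discount sensitivity estimate is attenuated.

**Annualization.** Frequency counts weeks at or *above* the promotion
threshold (default 5%, inclusive); magnitude averages all 52 weekly values
including sub-threshold weeks.

## Cohort

**Inclusion.** Households are retained when at least 80% (inclusive, and
configurable over {60, 70, 80, 90%}) of their SSB purchase volume was made
at stores present in the price data. The filter conditions on coverage
only; the outcome still sums *all* of a household's purchase lines,
covered and uncovered.

**Outcome.** Annual per-capita ounces = total household SSB ounces /
household size, log-transformed in regression because of its strong right
skew. Only purchasing households enter, so the log is always defined.

**Income per capita.** Bracket midpoints (12,500 / 29,500 / 42,000 /
59,500 / 84,500, with the open top bracket top-coded at its floor of
100,000) divided by household size, then binned into ≤15k / 15–30k /
30–50k / ≥50k with boundary values assigned to the higher bin. Boundary
cases are essentially unreachable from midpoint arithmetic except at
exactly 50,000 (midpoint 100,000, size 2), which lands in the top bin.

**Quartiles.** Rank-based with stable tie-breaking; group sizes are as
equal as possible and earlier groups are never larger than later ones (so
n = 11,299 splits as 2824/2825/2825/2825). Exposure-quartile boundaries in
the descriptive tables are always computed empirically, never hard-coded.

## Inference

**Design.** Dummy coding against the first listed level of each covariate
block (e.g. race reference "white"); exposure-slope inference is invariant
to this choice. Because a household without a male (or female) head is
"absent" simultaneously in that head's age, education and occupation
fields, a naive per-block dummy expansion would repeat an identical no-head
column three times and make the design singular. The design therefore
carries one no-head indicator per head, and codes that head's age
(ref <35), education (ref high-school-or-less) and occupation (ref white
collar) only among households where the head is present.

**Errors and intervals.** Classical OLS standard errors and t-based 95%
intervals; no robust or clustered variants. Complete-case analysis.
Rank deficiency is detected by pivoted QR and reported with the names of
the dependent columns.

**Scaling and reporting.** Frequency enters ×10 and magnitude ×100, so
exp(β) reads as the multiplicative change per 10 pp of frequency or 1 pp of
magnitude; percent change = 100·(exp(β) − 1), reported to one decimal.

**Interactions.** A single model with exposure×modifier terms. Per-stratum
slopes are exp(main + interaction) with delta-method standard errors
(Var(b_e) + Var(b_int) + 2Cov). The Type-3 interaction p-value is the
extra-sum-of-squares partial F-test of the whole interaction block against
the main-effects model — exact under the normal-error generating family
used by the synthetic data, which is what makes the size-calibration test
meaningful. Two-sided p-values throughout; no multiplicity adjustment
across the sensitivity grid.

## Synthetic generator

The generator emulates: a complete weekly price panel (every store carries
every product every week) with per-(store, product) regular prices drawn
uniformly on $0.03–0.09/oz; Bernoulli(`promo_prob`) per-product weekly
discounts with truncated-normal depths on (0, 1); household store sets of
1–5 covered stores; demographic covariates drawn from category margins
resembling a large US consumer panel (including consistent "no head"
status across a head's age/education/occupation); an uncovered-store
volume share, Beta(1.5, 6) for a `coverage_mix` fraction of households, so
that every coverage filter in the 60–90% grid excludes someone; and a
log-normal outcome whose log-mean is linear in the household's true annual
exposure with a planted multiplicative coefficient plus covariate shifts.

**Default conditions.** 1,000 households, 20 stores, 10 products;
`promo_prob = 0.10`, depth ~ TN(0.25, 0.08); these defaults place the
derived mean annual frequency near 0.44 and mean magnitude near 0.05 —
the ranges reported for US scanner panels — without being calibrated
claims. The outcome intercept and noise (5.65 and 1.6 on the natural-log
scale) put the median per-capita purchase near 500 oz (≈0.8 12-oz servings
per week) with a realistic right skew. Planted defaults are 1.137 per
10 pp frequency and 1.153 per 1 pp magnitude; `outcome_driver` selects
which exposure generates the outcome (frequency by default — with
frequency and magnitude strongly correlated across households, fitting the
non-driving exposure also yields a positive estimate, as in real data).

**Exact planted truth.** Every household buys the same global product mix
(one shared Dirichlet draw). Sample-volume product weights are then equal
to that mix by construction — for any subsample of households — so the
exposure recomputed by the pipeline from the emitted tables equals the
generator's planted truth to floating-point precision (`verify_truth`
checks ≤ 1e−9; observed ~1e−17). This removes the circularity that would
otherwise arise because weights depend on volumes, volumes on exposure,
and exposure on weights.

**Truth basis.** Truth is defined against the regular (base) price. Under
intermittent promotion the modal price equals the base price and pipeline
output matches truth exactly. Under perpetual constant-depth promotion
(`promo_prob = 1`, zero depth spread) the true frequency is 1 and the true
magnitude equals the depth, but the modal price collapses onto the
discounted price and the pipeline reports no promotion — a real limitation
of modal-price detection, surfaced rather than hidden.

**What the generator does not emulate.** Stockpiling dynamics, store-choice
behaviour, within-year seasonality (purchases are spread uniformly over
weeks; the analysis only uses annual sums and store identities), product
heterogeneity in household mix, missing covariates, and promotion-type
(feature/display) structure. Passing tests therefore demonstrate
correctness of the derivation and estimation machinery and calibration
under the assumed generating family — not that real purchase behaviour
follows the planted log-linear model.

## Study runner

Exposure tables are cached per (threshold, aggregation) and reused across
coverage cells, since the exposure derivation does not depend on the
inclusion filter. The main cell (5%, largest, 80%) must always be present.
A failing cell is recorded in the bundle and skipped; the rest of the grid
still runs. The bundle is a pure function of (data, manifest): no
timestamps are written, so identical runs are byte-identical.

## Problem sizes used in the test suite

Monte-Carlo parameter recovery uses 200 replicate cohorts of n = 10,000
via `generate_cohort`, a fast path that skips materializing purchase line
items; interaction-test size calibration uses 200 replicates of n = 4,000;
exposure-engine equivalence checks 500 random micro-instances (≤3 stores,
≤3 products, ≤6 weeks) against a plain-python brute-force enumeration.
These sizes give Monte-Carlo standard errors small relative to the asserted
bands (e.g. coverage 95% ± ~1.5% over 200 replicates).

## Known limitations

* Modal-price detection fails under near-perpetual promotion (above).
* The two-category product flag (carbonated vs fruit drink) stands in for
  a full product taxonomy; no diet/100%-juice exclusion logic is modelled —
  the input tables are assumed to contain SSBs only.
* No survey projection weights, no clustered variances, and no
  causal/policy simulation: estimates are cross-sectional associations.
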