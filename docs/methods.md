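# Methods

`pollenforage` quantifies the pollen foraging of two social bee species —
honeybees (*Apis mellifera*) and common eastern bumble bees (*Bombus
impatiens*) — from corbicular pollen loads ("pellets"), relates what the
bees collected to what a surveyed agricultural landscape offered, and
classifies per-morphotype preference and avoidance with a resampling null
model. This note records the model, its assumptions, the tunable
parameters, and the design decisions taken where the procedure left room.

## Sampling model and units

The sampling unit is one pellet per returning forager. ~500 grains per
pellet are counted under light microscopy and assigned to **morphotypes**
(categories of grain size/shape/ornamentation; one morphotype may pool
several plant species, e.g. Fabaceae_Tricolporate covers alfalfa, soybean,
crown vetch and white clover). Every morphotype belongs to exactly one
plant family; family-level analyses sum counts within families.

**Rare-grain filter.** Within each pellet, any morphotype making up less
than 3% of the counted grains is excluded (`min_frac = 0.03`, boundary
inclusive: exactly 3% is retained). Decisions taken here:

* The filter is applied **per pellet**, before all downstream metrics.
* The denominator is the pellet's current count sum. Removing rare
  categories only increases the survivors' shares, so the filter is
  idempotent.
* Retained counts are **not** renormalised to 500; downstream proportions
  use the retained sum. This preserves integer counts for the chi-square
  scaling.
* Morphotypes found in pellets but absent from the taxonomy are accepted
  and auto-registered under an UNKNOWN family (pollen-only morphotypes are
  a genuine feature of such data); a strict mode rejects them instead.

## Foraging metrics

For each colony-day (species x site x day) at each level
(morphotype/family):

* **Flower constancy** — a trip is constant when a single category holds at
  least 97% of the pellet's retained grains (`threshold = 0.97`,
  inclusive); the daily statistic is the constant fraction of trips.
  Constancy is evaluated after the 3% filter (order matters only in edge
  cases near both thresholds).
* **Richness S** — the number of distinct categories over the day's
  pellets.
* **Simpson diversity SDI = 1 − Σ pᵢ²** on the grain counts pooled over the
  day's pellets (not the mean of per-pellet SDIs), matching "diversity of
  pollen collected over all bees sampled from a colony on a given day".
  SDI is 0 for a single category and bounded by 1 − 1/k for k categories.

Merging morphotypes into families can only concentrate composition, so
family constancy ≥ morphotype constancy, family S ≤ morphotype S and family
SDI ≤ morphotype SDI — these are enforced as randomized property tests.

## Resource availability (efc)

Floral resources are surveyed four times (June–September) over a landscape
of `total_area_ha` (339 in the original design) split between crop fields
and wildflowers.

* **Wildflowers**: floral units (open flowers, or racemes/umbels/heads for
  clustered inflorescences — treated as equivalent counts, with no
  per-unit flower correction) summed per species over the survey's 150
  1 m² quadrats (3 sites × 5 transects × 10 quadrats).
* **Crops**: alfalfa = mean racemes per 1 m² quadrat; corn = mean stalks
  per 2 m² quadrat ÷ 2 (the halving happens at the density stage); soybean
  = mean over quadrats of (mean racemes/stem on the ~50% stem subsample ×
  stems per quadrat). Crop totals are scaled to the same notional 150
  quadrats to be commensurate with wildflower totals.
* **efc** (estimated floral count): each total multiplied by the
  proportional area of its stratum — crop area / total area for crops,
  (total − all crop hectares)/total for wildflowers. Minor crops
  contribute no floral counts but their hectares are still subtracted from
  the wildflower area.
* **Availability**: per survey, morphotype proportion = Σ member-species
  efcs / Σ all efcs.

Bloom windows gate crop contributions. Corn and soybean default to
{July, August} (one mass-flowering period in late July–early August);
alfalfa, a perennial cut and re-flowering through the season, defaults to
all four surveys with a single measured density. Both are configuration
inputs, since the original procedure does not fix this mapping.

Pellets are collected over five periods but resources surveyed four times,
so both July collection periods (P2, P3) are pooled onto the July survey.

## Chi-square comparisons with proportion-preserving "other" rows

Observed and expected proportion vectors are scaled to counts out of 500
(largest-remainder rounding so each side totals exactly 500; ties broken
by category name). A category keeps its own row iff it appears on both
sides with scaled counts strictly greater than 5; shared-but-small
categories and one-sided categories are pooled into a terminal "other" row
per side. This keeps the retained categories at their original observed
proportions — dropping unshared categories (the common alternative) would
renormalise and distort them. The goodness-of-fit statistic is
Σ(O−E)²/E with df = rows − 1; the species-vs-species comparison is a 2×k
contingency test with margin-based expectations (no continuity
correction). An expected "other" of zero with observed mass is reported as
a degenerate-expectation error rather than an infinite statistic. p-values
carry no multiple-testing correction by default (none was applied in the
original analysis); Benjamini–Hochberg across morphotypes is available to
users who want it via `statsmodels`-style post-processing of the output
table.

## Availability-proportional null model

The null hypothesis: bees allocate pollen across morphotypes in proportion
to availability. With each pellet (individual bee) as a replicate, each
pellet's retained grain total is redrawn from a multinomial over the
availability proportions; the species-level summary is the pooled
proportion (pooled grains / total grains). A morphotype's observed pooled
proportion above the null's [2.5%, 97.5%] percentile interval is a
**preference**, below it an **avoidance**, inside **proportional**;
morphotypes with zero availability (collected but never surveyed, e.g.
plants blooming outside the survey area) are **unassessable**.

Implementation notes:

* Because independent multinomials with a common probability vector add,
  the pooled null counts are distributed exactly Multinomial(Σ totals,
  availability). The default draw mode samples this pooled distribution
  directly; a literal per-pellet mode is retained (and tested for
  distributional agreement) and alternative null schemes, e.g. preserving
  per-pellet richness, can be plugged in at `PreferenceModel._null_draws`.
* Percentile CIs (numpy linear interpolation) at α = 0.05; n_iter = 1000
  by default, with a warning below 100.
* The model resamples the counts it is given and does not re-apply the 3%
  filter. The filter deflates small observed proportions relative to an
  unfiltered null — a property of the field procedure itself, worth
  remembering when interpreting borderline avoidance calls on rare
  morphotypes.
* A fixed seed makes the fit reproducible, and classifications are
  invariant to pellet order.

Calibration: with pellets generated exactly availability-proportionally,
the non-proportional classification rate matches the nominal α = 0.05
within Monte-Carlo error (the acceptance suite checks 200 replicates of
200 pellets at n_iter = 1000, and the power to detect a 5× preference at
200 pellets, which is essentially 1).

## Synthetic study generator

The generator emulates the full field design with known ground truth. One
pellet of G = 500 grains: with probability c (the constancy parameter) all
grains come from one morphotype drawn ∝ availability × preference
multiplier; otherwise counts are Dirichlet-multinomial with mean ∝
availability × multiplier and concentration 1/θ. θ = 0 degrades to a pure
multinomial — exactly the null model's generative form, which the coverage
tests require. Quadrat floral units are negative-binomial (gamma–Poisson,
dispersion `nb_dispersion = 2` by default — patchy but not extreme)
around each species' share of `quadrat_mean_scale = 40` floral units per
quadrat.

Study-scale fixtures mirror the design: 2 bee species × 3 sites × 5
periods, 40 honeybee / 20 bumblebee pellets per colony-day, the packaged
28-morphotype / 16-family inventory, 15 transects × 10 quadrats × 4
surveys. The species-contrast scenario couples the two species' reported
daily constancy means (0.87 vs 0.62) with a honeybee concentration on
Fabaceae (4× multipliers on the two legume morphotypes, reflecting
recruitment onto mass-flowering legumes) against a more even bumblebee
spread (2× on spiny Asteraceae). Note that constancy alone does not move
pooled composition — the diversity contrast comes from the multipliers,
as it does in the field from the two species' different floral choices.

What the generator does **not** emulate: spatial foraging (distances,
recruitment dynamics), within-survey phenology, per-species floral-unit
size differences, observer error in morphotyping. Passing recovery tests
therefore show the pipeline is correct and calibrated for compositional
count data of this shape, not that field inference is unbiased against
those processes.

## Problem sizes and numerical choices

Randomized suites use 1000 pellets (pooling monotonicity), 100 random
tables (chi-square oracle agreement at 1e-9), 200 replicates × 200 pellets
× 1000 iterations (interval calibration) and 100 replicates (power);
the pooled-multinomial identity makes these cheap. Proportion sums are
validated to 1e-9 (availability) and 1e-6 (test-table inputs); proportions
of retained chi-square categories are preserved bit-exactly. Degenerate
inputs (zero grain totals, zero expected counts, zero availability
everywhere, overcommitted crop areas) raise typed errors rather than
propagating NaNs.

## Known limitations

* Floral "units" are heterogeneous objects (flowers vs racemes vs heads)
  treated as equivalent; availability is therefore unit-biased for taxa
  with large inflorescences.
* Availability is a landscape-level quantity; the null model ignores
  site-level heterogeneity and distance from the colony.
* The "other" row makes the chi-square df depend on the retention pattern,
  so statistics are comparable across surveys only together with their df.
* Unassessable morphotypes (zero availability) are reported but excluded
  from calibration statements.
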