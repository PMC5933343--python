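# Methods

## The observational unit and its invariants

An event couples one predator (shell length apex-to-base, mm) with one
prey item (shell length for gastropods, longest shell axis for bivalves,
anterior–posterior body length for crustaceans). Sizes are positive and
recorded at 0.1 mm resolution; conspecific prey must carry the predator's
own species label. Pouches containing only sand record no identifiable
prey and are not successful predation events: rows with a missing prey
size are excluded at parse time with a logged warning and reported in the
table's issue list, never silently dropped. Unknown prey taxa are
row-level errors rather than guesses; the taxon→group dictionary ships
with every taxon of the field composition table pre-registered and is
caller-extensible.

All size intervals in the package — filters, size classes, generation
windows — are half-open `[lo, hi)`. This makes the 4-mm classes
(17–21, 21–25, …, 57–61 mm) a partition of the size axis; the shared-edge
convention (21.0 mm belongs to 21–25) is the lower-inclusive reading of
the class labels. The grid is configurable so the upper-inclusive
alternative can be examined; nothing downstream depends on the default.

Percentages are derived quantities: they are always recomputed from
counts and rounded half away from zero (1 decimal in spectrum tables,
integers for recovery rates), matching the conventions of the reported
composition table (165/327 → 50.5).

## GMFR / standardized major axis

With both variables subject to error, the fitted line is the standardized
major axis: `|b| = s_y / s_x` (sample standard deviations, n−1
denominator; the ratio is denominator-invariant), signed by the Pearson
correlation, intercept through the centroid. `r²` is the squared Pearson
correlation. When r is exactly zero the slope sign is theoretically
undefined; the implementation returns +1 deterministically and flags
`sign_of_r = 0`. Fits require n ≥ 3 and positive variance in both
variables; violations raise typed errors that the pipeline converts to
"skipped" report sections with reasons. No confidence intervals are
computed for SMA parameters, and no OLS or (unstandardized) major-axis
variants are offered.

## Ratio threshold and field-expectation tests

Gastropod prey (hetero- and conspecific) is governed by a predator:prey
length-ratio floor of 1.45. Classification in `ratio_summary` is strict
("above" means ratio > threshold), because the field statement is "more
than 1.45 times"; the threshold is a parameter, not a constant.

Field tests ask whether a region of the size plane is underpopulated:
`p_field` is the share of all successful predators satisfying the
predator-side predicate (size ≥ cutoff, lower-inclusive to match the grid
convention), the expected count is `p_field · n_focal`, and the reported
probability is the exact lower tail `P(X ≤ observed)` of
Binomial(n_focal, p_field). The tail is summed term by term in log space
(log-gamma coefficients, logsumexp accumulation): n is small and the
quantities of interest are of order 10⁻⁶ and below, where a normal
approximation would be useless. The default predator cutoff for the
sparse large-predator/gastropod-prey field is 41 mm — the class edge
shared by the cannibalism analysis — and is exposed as a parameter since
40 mm is an equally defensible reading.

## Random-encounter cannibalism model

Encounter universe: all ordered pairs (i, j), i ≠ j, over the pool of
successful predators, equal probability per pair — the literal reading of
"individuals meet randomly", with self-pairs excluded. Attack success is
a right-continuous step function of the ratio L_i/L_j: 1 at ≥ 1.46, 0
below 1.18, 0.5 in between ("at least" on both thresholds). The
observational ratio floor (1.45) and the experimental success threshold
(1.46) are kept as separate configurable constants rather than merged.

The raw cannibal propensity of individual i is `W_i = Σ_{j≠i} w_ij`;
summing W over class members and rescaling so the classes sum to the
observed number of cannibalization events yields the expected per-class
counts. The rescaling makes the χ² a comparison of shapes. In the χ² sum,
classes with expected = observed = 0 are skipped and df is (classes
entering) − 1; expected = 0 with observed > 0 is surfaced as an explicit
error because the statistic is undefined there. On synthetic tables the
extreme classes are typically empty on both sides, so df is usually 6–8
rather than the maximum 10 an 11-class grid allows; df is always reported
alongside the statistic.

A seeded Monte-Carlo mode draws random ordered pairs, resolves each
attack as a Bernoulli trial and histograms the successful attackers. It
exists to validate the analytic expectation (agreement within 3 standard
errors is part of the test suite) and is never used in its place.

## Synthetic-data generator

The generator emulates what the field data documents, and only that:

- **Predator sizes**: lognormal truncated to [18.0, 57.4] mm, mode 30 mm,
  log-scale SD 0.165. The family is a free choice (only the histogram
  shape and the "76% between 25 and 37 mm" figure are documented); the SD
  is calibrated so the truncated mass on [25, 37) is ≈ 0.764. Sizes are
  rounded to 0.1 mm.
- **Taxon mix**: multinomial with probabilities 165/327, 88/327, 43/327,
  31/327; sub-taxa within each group follow the documented conditional
  frequencies (e.g. 163:2 for the two heterospecific gastropods).
- **Bivalve prey**: `prey = 3.7 + (min(L, 40) − 3.7) · B`, `B ~ Beta(8, 8)`.
  This keeps the hard 3.7 mm floor, caps prey at the predator's own length
  and at 40 mm, and makes prey-size variance grow with the window width —
  the "widening predation window". The Beta concentration is the one free
  shape parameter; 8 reproduces the observed predator–bivalve association
  (r² ≈ 0.33 at n ≈ 88). A flat window fill (concentration 1) would yield
  r² ≈ 0.08 and was rejected on that calibration; the trade-off is that
  the generator under-represents the very smallest bivalves relative to
  the field data, which reports a fifth of bivalve prey within 1 mm of the
  floor.
- **Gastropod prey**: predators sampled below the 41 mm cap; prey uniform
  on [5, min(19, L/1.45)], with the upper bound snapped down to the 0.1 mm
  grid so the realized ratio respects the floor under the same
  floating-point arithmetic the analysis uses. A configurable outlier
  probability (default 1/163) produces ratio violators; for predators
  whose sub-19 mm prey cannot violate the ratio, outlier prey may exceed
  the 19 mm cap instead, mirroring the single observed outlier.
- **Crustacean prey**: predators ≥ 23 mm with small prey uniform on
  [4, 15] mm; with probability 2/43 the event is a large-prey capture
  (prey 30–40 mm, predator 26.5–35 mm), reproducing the isolated cluster
  of over-sized, incapacitated prey and the empty intermediate band.
- **Conspecific prey**: predators ≥ 41 mm except with probability 3/31
  (small cannibals, 25–41 mm); victims uniform on [13 mm, L/1.45], again
  ratio-safe on the 0.1 mm grid, capped at 19 mm for small cannibals.

One `SeedSequence` per table spawns independent substreams for group
assignment, each prey group, and dates, so resizing one taxon's draw does
not perturb another's. Infeasible rule combinations (e.g. a victim floor
that no admissible predator can clear at the ratio threshold) are
rejected before any sampling.

What the generator does **not** emulate: spatial structure and tidal
migration, seasonal and inter-annual variation, the empirical fine
structure of prey-size distributions beyond ranges and the calibrated
bivalve association, and any correlation between events. Tests passing on
synthetic data therefore validate the *computations* — binning, fitting,
exact tails, the encounter model — under the documented marginal
structure; they do not re-establish the field findings themselves, which
require the original raw table.

## Numerical choices and degenerate inputs

- Exact binomial tails via log-space summation; `p = 0` and `p = 1`
  short-circuit to the degenerate CDFs.
- χ² sum-consistency between observed and expected is enforced at 1e-6
  relative tolerance; scaling conservation of the expectation is exact to
  1e-9.
- An all-equal size pool has all pairwise weights zero; the expectation is
  then undefined and raises rather than returning NaN.
- Empty event tables are legal everywhere counts are computed (all-zero
  distributions) and illegal where a model needs data (fits, field tests,
  the cannibalism analysis), always with typed errors.
- The pipeline isolates its only non-deterministic fields (timestamp,
  elapsed time) inside `provenance`, so two runs with one config are
  otherwise byte-identical.

## Problem sizes

Default analyses run on 327-event tables (the documented field sample
size). Generator constraint checks in the test suite scan 10⁴-event
tables; Monte-Carlo validation of the cannibalism expectation uses 10⁵
encounter draws on pools of 10–300 individuals; the acceptance script
uses 5 000 draws for the size-distribution calibration fraction. All are
chosen to keep sampling error well inside the asserted bands.

## Known limitations

- The package reproduces the paper-trail arithmetic and validates the
  models on synthetic data; exact reproduction of the field dataset's
  headline statistics (e.g. its χ² of ~22 with df 10) requires that
  dataset, which is not bundled.
- No multiple-testing correction (single planned tests), no confidence
  intervals on SMA parameters, no spatially structured encounter model —
  the random-encounter null is exactly the hypothesis the χ² rejects.
- `validate` reports violations; it does not repair rows. Repair policy
  is left to the caller.
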