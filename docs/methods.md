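# Methods

## Recipe resolution

The recipe database maps each food code to ingredient amounts in grams per
100 g of product; components may themselves be food codes with recipes, so
the parent → component relation is a DAG. Resolution expands recursively: a
sub-recipe contributing *g* grams per 100 g of its parent contributes
*g*/100 of its own per-100 g composition, repeated base ingredients are
summed, and output is sorted by ingredient code so downstream results are
bit-reproducible. Amounts are used exactly as recorded — no renormalisation
to 100 g, no cooking-yield/water-loss adjustment — because the target is the
ingredient mass as produced (the quantity relevant for environmental
accounting), not as consumed.

Consequences of no-renormalisation: the "nested resolution conserves mass"
property (resolved total = direct entry total) holds exactly when every
sub-recipe's own entries sum to 100 g/100 g. Real recipe data may not; a
validity window of [50, 130] g/100 g per recipe warns on suspect totals
without rejecting them, and a non-positive total is a hard error. The
synthetic generator emits recipes that sum to 100, so the conservation
property is asserted there. Cycles are a hard error (stdlib topological sort
at load, plus a defensive visiting-stack check in the resolver): a cycle
means corrupt input, and silent truncation would silently bias profiles.

Foods missing from the database can be mapped to nearest-neighbour
substitutes through an explicit substitution table; chains (a substitute
that is itself substituted) are rejected, and a code in neither the database
nor the table is an error that names the code.

## Dairy classification

Base ingredients are classified as milk / cheese / yogurt / cream / butter
or explicitly non-dairy. Fat level applies to milk, cheese, yogurt and cream
(cream only semi-skimmed or full fat); cheese variety (cheddar / cottage /
other) applies only to cheese; butter carries neither. The classification is
an input artifact produced by human coders; this package validates it and
refuses to guess: an ingredient in neither roster raises rather than
defaulting to non-dairy, because silent defaults would mask drift between
the recipe database and the classification map.

A food is **pure dairy** iff all of its resolved ingredient *mass* is
dairy-classified, **non-dairy** iff none is, otherwise **composite**. The
definition is structural, not a threshold: salted butter (98.44 g dairy per
100 g) is a composite. Zero-gram components carry no mass and cannot flip a
food's class.

## Intake estimation

Disaggregated mode: each recall item contributes
`grams_consumed × profile/100` per subtype. Naive (food-group) mode: an item
whose food group is a dairy group contributes its full reported weight to
that group's category, all other items contribute zero — the only definition
consistent with the observed sign pattern (fruit yogurts and ice cream
overcount; cheese and butter hidden in composites undercount).

Day handling: per person, day totals are averaged over the person's
completed recall days (1 or 2). When the persons table declares
`n_days_completed`, that is the divisor (a completed day with no dairy items
still counts); otherwise the days observed in the recalls are used. The rule
is isolated in one function because survey conventions differ.

Estimates are per capita: every weighted person contributes, non-consumers
as zeros. The weighted mean is `Σwx/Σw`; the SD is the frequency-weighted
standard deviation with the same weights, with no finite-population
correction and no design effects (strata/clusters out of scope). The
standard error used in recovery tests is the linearised
`sqrt(Σ w²(x−m)²)/Σw`.

Percent bias carries an explicit denominator convention
(`denominator_with` = disaggregated mean, `denominator_without` = naive
mean) because published summary percentages use both conventions in
different places; neither is guessed as canonical. Sign: positive = the
naive mode underestimates. Rounding of reported percents is
half-away-from-zero, applied only at reporting time.

Contribution shares divide the weighted per-capita dairy mass of each food
group by the weighted grand total. The composite/noncomposite rollup treats
dairy food groups as "noncomposite" when a group-dairy map is supplied
(matching how a naive analysis would delimit "dairy foods", which places
ice-cream-style products on the noncomposite side); without one it falls
back to each food's own structural class.

## Emissions

Intake converts to litres of raw milk per day as
`Σ (g/day ÷ 1000) × factor_L_per_kg`, annualised with a 365-day year and
multiplied by a footprint of 1.2 kg CO₂e per litre (configurable). Milk
itself converts through a density of 1.03 kg/L (configurable; not a
published constant of the analysis). Category-level factors are the
default, with variety overrides available; cheddar's 9.5 L/kg is the only
published utilisation figure, so the remaining defaults (yogurt 1.1, cream
8.0, butter 22.0 L/kg) are round package conventions to be replaced with
utilisation-based values for serious accounting. Emissions are therefore
homogeneous of degree one in intake, factors and footprint, which the tests
exploit.

## Synthetic data

The generator emulates the structure of the real inputs, with defaults
fixed at the study conditions: 3% pure-dairy, 29% composite-dairy, 68%
dairy-free foods (drawn multinomially); composite dairy content log-uniform
on [0.01, 98.44] g/100 g (four orders of magnitude); recipe nesting up to
depth 3 with recipes summing to exactly 100 g/100 g; up to two recall days
per person (second day with probability 0.8); ~10 items per day (Poisson);
log-normal portions (μ=4.3, σ=0.6 on the log scale, median ≈74 g, mean
≈88 g); positive survey weights from a shifted gamma with mean 1 (0.1 +
Gamma(9, 0.1)). A configurable fraction (8%) of composites is filed in
dairy food groups to reproduce the ice-cream/fruit-yogurt mechanism that
makes the naive mode overcount some categories.

Ground truth is computed at generation time with a brute-force path-product
flattener that shares no code with the production resolver, so generator
and pipeline cannot share a bug. Expected per-capita intakes follow in
closed form (items uniform over foods, independent of weights and days):
`E[items/day] × E[portion] × mean_food(profile)/100` per subtype, and the
analogous full-weight expression for the naive mode.

What the generator does **not** emulate: real food descriptions and coding
noise, correlated food choices within a person, consumption frequency
differences between foods, demographic structure, or cluster/stratum survey
design. Passing recovery tests therefore demonstrates correctness of the
estimator under independent sampling with heterogeneous weights — not
robustness to the measurement properties of real recall data.

## Problem sizes and numerical choices

Oracle-equivalence suites use random acyclic databases of ≤30 foods;
recovery suites use 300 foods × 2,000 persons × 20 seeds, which keeps the
whole test suite in single-digit seconds while leaving Monte-Carlo error
well inside the 3-standard-error acceptance band. Tolerances: exact
equality where arithmetic is exact (resolution is pure multiplication and
addition), 1e-9 absolute/relative for conservation identities, 3 SE for
statistical recovery. Ties in rounding go away from zero. Degenerate inputs
(empty food list, empty profile set, zero weights, zero grand total) raise
distinct named errors or warn-and-return-empty as documented per function.

## Worked-example fixtures

`reference_fixtures()` ships a small set of UK-style foods with published
dairy contents used throughout the tests: croissant (25 g butter/100 g),
homemade Yorkshire pudding (60 g semi-skimmed milk/100 g), spreadable
butter (63 g butter/100 g), salted butter (98.44 g butter + 1.56 g salt),
kulfi-style ice cream (40 g cream/100 g), plus pure whole milk and plain
bread as controls. Non-dairy remainders (flour, egg, oil, sugar) are
package conventions chosen to complete each recipe to 100 g; only the dairy
amounts are externally sourced.
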