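# Methods

## The model

`bluedebt` ranks candidate countries for marine debt-conversion deals by a
threat-adjusted cost-effectiveness score

    ce = B · I_a · (1 − α·I_u) · P / C

- **B** — a biodiversity benefit in km²: the shipped benefit fields are EEZ
  area (`eez_area_km2`) and coral-reef area (`coral_area_km2`); any
  additional non-negative benefit column can be addressed by name.
- **I_a, I_u** — additive burdens of abatable and unabatable threats: sums
  of per-country mean values of normalized [0, 1] human-impact layers over
  the layers of each class. Threats are assumed additive; antagonistic or
  synergistic interactions are out of scope. Because the burdens are sums
  (not means), I_u routinely exceeds 1.
- **α** — the scaling multiplier keeping (1 − α·I_u) non-negative. Under the
  default `pool_max_reciprocal` policy α = 1/max(I_u) over the candidate
  pool; this is the largest α for which no pool member's discount is
  negative, and it pins the discount to exactly 0 at the argmax country. A
  pool whose I_u is identically 0 maps to α = 0 (every discount is 1); a
  `fixed` policy is available and is rejected if it would drive any pool
  member negative. We follow the 1/max(I_u) formula as the defining rule.
- **P, C** — probability of success and cost. Both default to the constant
  1, in which case priorities are driven solely by the expected benefit
  B·I_a·(1 − α·I_u); per-country columns can be switched on when credible
  estimates exist.

The interpretation of the two threat terms: a marine-protection action can
only convert abatable pressure into benefit (hence the B·I_a factor), while
the unabatable load discounts the action's effectiveness — a quantitative
substitute for expert counterfactual estimation. A candidate with I_a = 0
scores 0 and is flagged (`no_abatable_threat`) so that users can tell "no
benefit" apart from "nothing to abate".

## Shared α across the scenario matrix

α is derived once per classification scheme over the **full** loaded pool
and shared across all filter × benefit scenarios of that scheme, so a
country keeps one (I_a, I_u, discount) triple wherever the scheme matches
and expected benefits are comparable across filters. A single α across
*different* schemes would be unsound: moving a layer (shipping) into the
unabatable class raises max(I_u), and an α derived under the stricter
scheme's complement would produce negative discounts. A `per_scenario`
switch recomputes α over each post-screening pool instead.

## Screening

Enabling conditions are threshold/flag rules on country fields
(attributes, benefit columns, or `extras` such as a governance index).
Composition is conjunctive only — no OR, no weights — because collapsing
heterogeneous enabling factors into an arbitrary score hides why a
candidate was kept or dropped; disjunctions can be expressed as separate
scenarios. Comparisons are inclusive (≥, ≤), matching thresholds phrased
as "60% or higher". A rule referencing a field a record lacks raises a
configuration error rather than silently excluding the record. Pass-sets
are order-independent; only the "first failing rule" annotation depends on
rule order. Debt ratios are stored as ratios (0.60), never percent; the
loaders accept a `percent` flag that divides by 100 on ingest.

## Scenario matrix and ranking

The shipped design crosses four debt-to-GDP filters (none, ≥0.40, ≥0.60,
≥0.80) with two benefits and two classification schemes (shipping abatable
vs. unabatable) — 16 scenarios, ordered filters-outer, schemes-inner.
Ranking is by descending score with ties broken by ascending country id;
ties receive distinct consecutive ranks. No tie rule is inherent to the
score, so a deterministic lexicographic rule was chosen for bit-for-bit
reproducibility. Scores are carried at full floating precision end to end;
results CSVs are written with shortest-round-trip floats (so rerunning a
run is byte-identical and reading a table back is lossless), and rounding
for humans (Jaccard to 2 decimals, membership to whole percent, half away
from zero) happens only in the rendered text report.

## Set comparison

Top-k sets are compared pairwise by Jaccard index; both-empty input is an
error (comparing empty priority sets signals a misconfigured run), not 1.
Scenarios with pool_size < k are excluded with the reason recorded — a
generalization of dropping filters that leave too few candidates to fill a
top-k. Membership counts are over the compared scenarios only, and the
report names its union scope explicitly. For two equal-size k-sets the
attainable Jaccard values are exactly i/(2k−i), i = 0..k; for k = 10 the
smallest positive value is 1/19 ≈ 0.053 (one shared country in ten).

## Synthetic data generator

The generator emulates the statistical structure of per-EEZ country data:

- **Debt ratios** uniform on (0.10, 1.20), so all three screening
  thresholds bite on a default pool.
- **Areas** log-normal: EEZ with log-mean 12.2 / log-sd 1.4 (median
  ≈ 2·10⁵ km², heavy right tail reaching the multi-million-km² EEZs of
  large island states); coral with log-mean 6.0 / log-sd 1.5 and a 0.15
  probability of zero reef area.
- **Threat layers** Beta(mean·c, (1−mean)·c) with concentration c per
  layer, a two-parameter bounded distribution in which class-level
  mean/variance contrasts are directly expressible. The default catalog has
  19 layers: 11 abatable (five commercial-fishing gears, artisanal fishing,
  benthic structures, shipping, four direct human / ocean-based pressures;
  means 0.10–0.35, c = 6, between-country CV ≈ 0.6–1.0) and 8 unabatable
  (climate-driven and land-based; means 0.60–0.70, c = 60, CV ≈ 0.09). The
  unabatable means sum to 5.20, so a 53-country pool's max(I_u) lands near
  5.6 and the derived α near 0.18 — the scale regime the method is designed
  for, where summed unabatable burdens far exceed 1.
- The shipping layer is emitted once; scheme A classifies it abatable,
  scheme B unabatable — the classification-sensitivity pair.
- All draws come from a single `numpy.random.Generator` (PCG64) in a fixed
  order, so identical configs are reproducible across platforms. The
  defaults (n = 53, the ranges above) are fixed study conditions.

What the generator does **not** emulate: spatial structure (threat layers
are drawn independently per country, with no geographic autocorrelation or
realistic inter-layer correlation), real-country identities, or any
relationship between debt ratios and threat or benefit fields. Tests
passing on synthetic pools therefore demonstrate the correctness and
invariances of the machinery — non-negativity, conservation, nesting,
determinism — not that any particular country would rank highly on real
data.

### Discount calibration

On real per-EEZ data the unabatable discount removes roughly half the
expected benefit on average; on the default catalog, whose unabatable
layers are deliberately near-uniform across countries, mean(α·I_u) sits
near 0.9 instead. `calibrate_discount` reconciles the two when desired: it
rescales the unabatable layer means by a common factor until mean(α·I_u)
reaches a target (default 0.54, tolerance ±0.10). Pure rescaling would
cancel out of α·I_u if the spread scaled too, but with the Beta
concentration held fixed a smaller mean has a larger coefficient of
variation, which widens the gap between the pool mean and the pool maximum
and lowers mean(α·I_u) monotonically — so a deterministic bisection on the
scale factor (same seed at every evaluation, ~60 iterations maximum)
converges. An unattainable target (e.g. a near-degenerate pool where every
country's I_u is equal and the ratio is pinned at 1) raises an error
carrying the closest achievable value. The calibration target is a property
of the synthetic defaults, not an asserted reproduction of any particular
dataset's statistic.

## Numerical choices and degenerate inputs

- Discounts more negative than 10⁻⁹ raise a domain error (never clamped);
  the tolerance absorbs only the float rounding of α·max(I_u) = 1.
- Missing threat cells are hard errors at both load and construction time —
  an implicit zero would masquerade as "no threat" and inflate the discount.
- Duplicate country ids, out-of-range layer values ([0, 1]), negative
  areas, cost ≤ 0 and p outside [0, 1] all fail loudly with the offending
  row/cell named.
- Empty post-screening pools yield an empty ranking with a warning, not an
  error; an empty pool for α derivation is an error.
- CSV reading uses round-trip float parsing, so write→read preserves every
  field exactly.

## Problem sizes

The test suite and the acceptance script run on pools of 53 countries (the
default), 200–500 for sampling-based checks of the generator's statistics,
and 1,000 small random pools for the non-negativity property; the whole
pipeline over 16 scenarios at these sizes completes in seconds.

## Known limitations

- No budget allocation: the framework ranks candidates, it does not select
  a portfolio under a budget constraint.
- No threat-interaction models (additivity is assumed throughout).
- No spatial processing: the package consumes precomputed per-country layer
  means; producing them from rasters is outside its scope, as are
  governance-index construction and the financial/legal transaction
  structure itself.
- Fixed α across a scenario's pool means a candidate added to the pool can
  change every other candidate's discount via max(I_u); this is inherent to
  the pool-relative definition of α.
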