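# Methods

## Visual-inspection scoring

Each sampled product carries an explicit pass/fail value for a fixed
criterion set: six packaging/labelling criteria (API name on the pack,
leaflet present, dose stated, expiry date stated, manufacturer name and
address, batch number) and five physical criteria (shape, colour, size,
breaks/cracks, contamination). A sample is compliant iff it fails
nothing; the summary reports per-criterion failure counts as column
sums and the noncompliant count as the size of the union of failing
samples, so the union is always between the largest single column and
the column sum. Input files may omit the physical columns, which then
default to pass — surveys that record only labelling criteria are
implicitly reporting no physical defects. Percentage rows use the full
sample count as denominator; per-category noncompliance uses that
category's count. Whether an expiry-date failure means "absent" or
"expired" is not modelled; it is a generic fail flag.

## Retail-audit sales estimation

For one outlet-product visited at dates t₀ < … < tₙ with stock counts
Sᵢ and interval-logged additions Aᵢ and disposals Dᵢ,

    units sold = S₀ − Sₙ + Σ Aᵢ − Σ Dᵢ.

This telescopes over intervals, so the estimate is independent of the
visit schedule whenever corrections are fully logged; the simulator
verifies exact recovery for arbitrary schedules. A negative estimate
means the audit identity was violated (typically unreported additions);
it is retained with a flag and a warning rather than floored at zero,
because reporting error is informative. Products marketed under several
routes keep the route on the sales estimate, not the product, so one
product can contribute to several route rows; a multi-route product
needs an explicit route-of-sale attribution since stock counts alone
cannot split it.

Consumption tables sum API grams per group (drug, class, route, outlet,
category), with shares = group/total × 100 and a daily column dividing
by the period length. The grand total is invariant to the grouping; an
outlet with no sales in a category is absent from the table, distinct
from an explicit zero.

**Reporting period.** The default `period_days` is 26: the bundled
survey's published monthly and daily masses imply a divisor of ≈26
(80,238 g / 3,073 g·day⁻¹ ≈ 26.1; 118,059 / 4,547 ≈ 26.0), i.e. a
trading month. It is explicit configuration everywhere.

## Mass conversion

Strength parsing accepts only mg, g, IU, % w/v and % w/w; free text is
rejected. Percent w/v is g per 100 mL (dose unit: mL), percent w/w g
per 100 g. IU→mg factors are substance-specific configuration with a
documented default table (benzylpenicillin 0.0006 mg/IU, procaine
benzylpenicillin 0.001, benzathine benzylpenicillin 0.00075,
streptomycin 0.00125); unknown substances raise rather than default.
Combination products are one record per active ingredient sharing a
`product_id` and a `display_label`, so masses aggregate per ingredient
or per combination row as reporting requires.

## Biomass and the population correction unit

Per-species formulas (all homogeneous of degree 1 in counts and
weights):

- slaughtered stock: `n × mean live weight`;
- cattle herd: `census × Σ weightᵢ × proportionᵢ` over age classes
  (calves, young, adults), plus slaughter throughput when supplied;
- live sheep/goats: `w_slaughter × n_slaughtered +
  (census − n_slaughtered / cycles) × w_breeding`, defaults 20 kg
  slaughter weight, 1.5 breeding cycles/year, 75 kg breeding weight —
  the division applies to the slaughter count only, and a negative
  retained population is an error;
- poultry: `(total birds − chicks under 2 weeks) × 1 kg`.

Default age-class weights ship for sheep (18/27/30 kg) and goats
(15/25/30 kg); cattle weights and proportions have no regional standard
and must be user-supplied. Draft animals and swine are excluded from
the food-producing PCU by default (`food_producing: false`), with
head-count shares computable over the food species only or over all
species. No import/export corrections or within-year dynamics are
modelled.

The bundled census carries the published surveillance denominator
(40,615,099 kg) as `total_pcu_override_kg`: it rests on a national
slaughter extrapolation whose inputs are not published, so it cannot be
recomputed from the local census and is treated as an input constant.
The demonstration census values (cattle age weights 100/200/300 kg at
20/30/50 %, sheep/goat slaughter 3,000/10,000) are the package's own
plausible scenario; they reproduce the published biomass *ordering*
(cattle ≫ sheep > goats > poultry) but not its shares, which depend on
the undisclosed extrapolation.

## Consumption metrics

`mg/PCU = mass (mg) / biomass (kg)` as an exact ratio; the report
carries both the period-total convention and the daily convention
(daily mass / PCU), the latter being how headline figures for this kind
of survey are usually quoted. Route-restricted variants divide a route
subset of the numerator by a caller-chosen biomass subset; no
route-to-species pairing is hard-coded because "which species plausibly
consumed the oral powders" is a study-specific judgement. `nDDDvet`
divides total mass by a configured DDDvet; DDDvet values are pure
configuration and the default table ships empty. Internal values stay
at full precision; rounding happens only in display writers.

## Synthetic data

The simulator emulates a short audit campaign: per outlet-product,
daily demand is Poisson(λ) truncated at available stock, disposals
occur with small probability, and stock at or below a threshold
triggers a fixed restock batch; visits fall on day 0, every k days, and
the final day. Truth (actual units sold) is recorded alongside the
visit records. Optional reporting noise thins recorded additions
binomially by a fraction f, biasing the estimator by −f × (true
additions) in expectation — verified by Monte Carlo within three
standard errors. All randomness flows from one seeded NumPy generator;
a fixed seed yields byte-identical output files.

The inspection-fixture generator is deterministic: given per-criterion
failure counts and a target union size u (feasible iff
max ≤ u ≤ sum and u ≤ n), each criterion's failures are placed
cyclically over the first u samples — no criterion can hit a sample
twice since its count is ≤ u — and any sample left empty receives a
failure moved from a sample holding several, preserving column sums.

What the simulator does **not** emulate: demand seasonality, dispenser
behaviour, price effects, stock-out substitution between products, or
correlated reporting errors. Passing recovery tests therefore shows the
estimator is exact under the audit identity, not that field audits are
unbiased — under/over-reporting in real audits enters exactly as the
bias term above.

## Reference dataset reconciliation

The bundled survey's published antibiotic injection column lists
per-drug masses summing to 160 g more than the published column total,
while every published percentage is consistent with the column totals.
The dataset follows the totals and charges the 160 g to the
penicillin-streptomycin combination row, the one row whose published
share is itself internally inconsistent; all other rows and every
derived share match the published values exactly. The published daily
anthelmintic mass appears as both 3,073 and 3,078 g in different
places; the package uses 3,073. One per-criterion inspection
percentage (9/44) is published at whole-percent precision and is
compared at that precision.

Reconstructed audit records use an abstraction of one "unit" = 10 mg of
API, so each published two-decimal gram value maps to an integer stock
count; outlet allocation uses largest-remainder rounding against the
published outlet shares, preserving drug-route totals exactly.

## Numerical choices

Proportion vectors must sum to 1 within 1e-9. Share computations keep
full float precision; tests compare published percentages at ±0.05 pp
(consumption shares), ±0.15 pp (inspection percentages, which the
source rounds inconsistently) or at the printed precision. Problem
sizes throughout (44 samples, ≤ a few hundred audit series, ~120
Monte-Carlo replicates for the bias check) keep the whole suite and the
acceptance script in the seconds range on one CPU.
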