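# Methods

## Setting and data

The package analyses annual public-payer reimbursement of the three TNF
inhibitors with biosimilar competition in Poland — infliximab (INF, first
biosimilar covered 1 January 2014), etanercept (ETN, 1 July 2016) and
adalimumab (ADA, 1 January 2019). The unit of observation is drug × calendar
year × indication sector: milligrams reimbursed, expenditure (EUR) and
patients treated, for the combined rheumatology + gastroenterology +
dermatology sector ("ALL") and the rheumatic-musculoskeletal-disease subset
("RMD"). The packaged fixture covers 2013–2021; expenditures are stored in
EUR at full precision (the source publishes millions to 3 decimals, i.e.
thousand-EUR precision, converted from PLN at the period-average rate of
4.4124 PLN per EUR). Population exposure uses the period-average population
of 37.99 million inhabitants.

These are census data of a single-payer system, not a sample: no confidence
intervals or inflation adjustment are applied anywhere, matching the payer's
nominal accounting.

## Savings models

Let `E_t` be expenditure, `V_t` milligrams and `N_t` patients in year `t`,
and `r` a drug-specific reference year.

**Estimated savings** (price counterfactual): the reference unit price is
`p_r = E_r / V_r` at full precision — never the rounded published per-mg
cost, which is what lets the published potential-value cells reproduce to
their printed 3 decimals. With actual volumes, `S_t = p_r V_t − E_t` for
every `t > r`; with fixed volume, the potential is `p_r V_r = E_r` held
constant. Savings may be negative and are kept algebraically ("increase in
expenses" is a rendering convention, not a data transformation).

**Real-life savings** (expenditure difference): `S_t = E_r − E_t`, `t > r`.
At a pre-biosimilar reference the fixed-volume estimated model and the
real-life model coincide identically (`p_r V_r = E_r`); this identity is
exercised as a test invariant.

Reference years are configuration, not code: the primary analysis anchors
estimated savings at each drug's pre-biosimilar year (INF 2013, ETN 2015,
ADA 2018) and real-life savings at INF's 2018 expenditure peak (patient
numbers before 2014 were too small for 2013 to be a meaningful spending
anchor) with ETN/ADA at their pre-biosimilar years. The alternative
scenarios — fixed-volume estimated, and real-life with INF anchored at
2013 — are reachable by the same configuration mechanism. Selection rules
(`PRE_BIOSIMILAR`, `PEAK_EXPENDITURE`, ties to the earliest year) can stand
in for literal years. Aggregation sums drugs within one sector only;
aggregating ALL with RMD would double-count the rheumatology share.

## Treatment costs and the sensitivity check

Two independent costing routes: per-mg (`E_t / V_t`) and per-patient
(`E_t / N_t`). The payer published its per-patient costs from a different
data set than spend/volume/patients, so the package also ships those
published cost values (`poland_reported_costs.csv`) alongside the
recomputable ones; for etanercept 2017–2021 the two sources genuinely differ
by up to ~1.7%. The sensitivity comparison therefore passes or fails on the
**overall** cost reduction (100·(1 − cost_last/cost_ref)) difference between
methods — ≤ 5 percentage points by default — while per-year
percent-of-reference differences are reported as diagnostics: single years
can diverge more when the patient mix shifts faster than volume (the 2016
infliximab cells differ by 8 points in the source itself).

Display rounding follows the source: per-mg to 2 decimals, per-patient to
whole EUR, percentages to whole points, all half-away-from-zero; every
computation and comparison is full precision.

## Exposure, access and reinvestment

DDD exposure is `V_t / ddd_mg` (WHO defined daily doses: INF 3.75 mg,
ETN 7 mg, ADA 2.9 mg — configurable, since WHO revises DDDs) and
`DDD per 1000 inhabitants per year` divides by population/1000. Dose counts
are kept fractional internally and rounded to the nearest whole dose for
display, which reproduces the published counts (truncation does not).
Exposure is computed on the combined sector only, making the rate invariant
to how a year's volume splits across sectors.

The reinvestment counterfactual converts each year's real-life savings into
`floor(S_t / c_t)` additional fundable patients at that year's per-patient
cost `c_t`, flooring because a partial patient-year cannot be funded, and
clamping negative savings to zero additional patients. The pipeline costs
this at the payer's published per-patient values when present (that is the
basis on which the published counterfactual reproduces within ±2 patients or
0.5%) and falls back to `E_t / N_t` otherwise. Era growth compares patient
counts between the last pre-biosimilar year and the series end; market share
splits product-level reimbursement by biosimilar flag; eligible-population
coverage is `100 · total_potential / (ia_population · eligibility_rate)`,
with the inflammatory-arthritis population (~550 000 in Poland) and the
eligibility threshold (40–60%) supplied by the caller.

## Synthetic data generator

`MarketScenarioConfig` emulates what the real series exhibit: a flat
pre-entry unit price `p0`; post-entry price `p0 · d^(t−entry+1)` (the entry
year itself is already discounted, as observed in tenders); volume
`v0 · g^(t−start)`; patients = volume / mean annual dose (rounded);
reimbursement = price × volume; and a biosimilar spend share growing
linearly by `share_takeover` per year, capped at 1. Multiplicative
lognormal noise with mean 1 and coefficient of variation `noise_cv` hits
price and volume independently — multiplicative because payer aggregates are
positive by construction.

Defaults are fixed once to the infliximab-like trajectory: `p0 = 4.80`
EUR/mg, `d = 0.79` (unit cost ≈ 15% of reference after 8 post-entry years),
`v0 = 0.96e6` mg growing at `g = 1.20`, entry 2014 in a 2013–2021 span, 1540
mg per patient-year (≈ the 2013 ratio of volume to patients), `noise_cv =
0.05` (a few percent of year-to-year administrative noise), population 38M.

`expected_estimated_savings` evaluates the noise-free expectation
`Σ V_t (p0 − p_t)` as a difference of geometric sums (with the `x = 1`
limits handled explicitly), giving an oracle that is independent of the
savings engine; because both price and volume noise are mean-1 and
independent of each other and of the reference year, the noisy estimator is
unbiased for the same quantity, which the 200-replicate recovery test checks
at two standard errors.

What the generator does *not* emulate: tender-level price discreteness
(real prices move in steps when contracts turn over), sector structure (it
emits the combined sector only), patient-mix changes that decouple the
per-mg and per-patient costings, and cross-drug substitution. Passing tests
on synthetic data therefore validate the arithmetic and its invariants, not
the behavioural realism of any market forecast.

## Data corrections in the fixture

The published source tables contain internal inconsistencies. The fixture
stores the value used for computation and keeps every affected published
value, with a note, in `poland_meta.yaml` under `flagged_cells`:

- The RMD etanercept milligram column is inconsistent with the same table's
  own monetary columns (the implied unit price would drift 4.29 → 5.57
  EUR/mg instead of equalling the constant 2015 reference price, while
  potential − actual = savings holds exactly). The 2015 volume is taken from
  the combined-sector value (its published RMD value, 4 481 792, also
  exceeds the combined sector's 4 296 845, which is impossible) and
  2016–2021 volumes are back-derived from the published potential values at
  the 2015 reference price.
- RMD infliximab 2013 expenditure appears as 0.790 in one table and 0.789 in
  another; 0.790 is stored (the reference price quoted downstream derives
  from it) and the alternative is flagged.
- Two corrected RMD etanercept volumes marginally exceed the combined-sector
  value (an artefact of the published potentials' 3-decimal rounding); they
  are flagged, and the RMD ≤ ALL validation exempts flagged cells only.

## Numerical choices and degenerate inputs

Monetary arithmetic is plain float (all quantities ≤ 1e9, integer-EUR
inputs, exactly representable); CSV round-trips preserve cents. Missing
years are absent, never zero-filled, and any operation that needs one raises
a `MissingYearError` naming it. Zero volume or zero patients in a year make
the respective unit cost undefined and raise rather than propagate
infinities. Reference-year selection breaks expenditure ties toward the
earliest year. Report rendering uses a thin-space thousands separator and
"Reference"/"N/A" markers, writes no timestamps, and is byte-identical
across repeated runs on the same inputs.

## Known limitations

- Sums of savings computed at full precision differ from sums of the
  published rounded cells in the third decimal (e.g. the RMD estimated grand
  total computes to 166.718 vs the published 166.711 from inputs printed at
  thousand-EUR precision); tests and the acceptance script state their
  tolerances accordingly.
- The published alternative-scenario totals (fixed-volume estimated model)
  are not exactly reproducible from any combination of published inputs;
  the pipeline reports its own full-precision values.
- Market-exclusivity-era comparisons (pre-2013 patient counts) are supported
  by `era_growth` on any supplied series but cannot be demonstrated on the
  fixture, which starts in 2013.
- Market-share analysis needs product-level spend, which the public source
  reports only graphically; the operation is exercised on synthetic data.
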