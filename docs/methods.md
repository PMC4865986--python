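# Methods

## The counting model

`drugtally` computes, per patient and per measure, the number of
distinct drugs in the regimen. A measure fixes three components; the
engine evaluates them in order.

**Scope.** Each product carries five classification attributes
(prescription status, drug type, route, dosage form, common use) plus
supply and metered-dose-inhaler flags. A scope is a set of admitted
values per attribute; a fill whose product fails any attribute filter
is discarded before anything else happens. Route filtering offers
either an include-list or an exclude-list, never both, so a scope
always reads unambiguously. Vocabularies are closed sets with an
`other` escape token: the listed values cover common practice but no
such list is exhaustive.

**Uniqueness.** In-scope fills are mapped to counting keys. Under the
product basis a product yields one key — its ingredient list joined
(lower-cased, sorted, so key identity is independent of ingredient
order) plus route/form/strength as the level demands. Under the
ingredient basis each ingredient yields its own key at the same levels.
Eligibility under the ingredient basis is evaluated *per product
first*: each product's own fill chain defines its anchor and gaps, and
an ingredient counts if any product containing it passes the timeframe
rule. The alternative — pooling all products sharing an ingredient into
one fill chain before finding the anchor — can reject an ingredient
whose recent fill came from a different product than its last fill;
the per-product rule matches the intuition that possession of any
qualifying product keeps the ingredient in the regimen.

**Timeframe (cross-sectional).** For each key, the anchor is the last
fill strictly before the index date; a fill dated on the index day is
not "prior" (it is treated as a post-index event, and the post-index
rescue looks strictly after the index date, so an index-day fill
contributes to neither side). Same-key fills on one date are summed
into a single anchor event, treating them as split fills of one
prescription. The observed index gap is exact calendar-day
subtraction. The key counts when observed gap < allowable gap, with
strict inequality throughout: a supply that runs out exactly on the
index date does not count. Flexible allowable gaps (multiplier × days
supply) may be non-integral and are compared as real numbers without
rounding — rounding would silently shift thresholds for multipliers
like 1.2.

Three optional extensions widen the allowable gap or rescue a failed
key, and by construction can only increase a count:

* *Cabinet supply*: fills of the same key within a lookback window
  (default 180 days) before the anchor are replayed chronologically
  with carry `c ← max(0, c + days_supply − gap_to_next_fill)`; the
  final carry is added to the allowable gap. The carry is uncapped —
  nothing in refill data bounds how far ahead a patient can stockpile —
  and the floor at zero encodes that supply cannot be borrowed from the
  past. The recurrence is verified in tests against a literal
  day-by-day consumption replay. The lookback window is anchored at the
  last pre-index fill, not at the index date, because the quantity
  being estimated is the supply on hand *at that fill*.
* *Hospitalization adjustment*: inpatient days strictly inside the open
  interval (anchor, index) are added to the allowable gap, since the
  home supply is not consumed in hospital. Stays are counted as
  [admit, discharge) — admission day inpatient, discharge day not —
  with overlapping stays unioned first. Claims sources differ on the
  day convention, so `both_inclusive` and `both_exclusive` dialects are
  selectable (`stay_convention` keyword, `--hospital-day-convention`
  flag) rather than hard-coded.
* *Post-index rescue*: a key that failed the index-gap test counts if
  the gap from its anchor to its first fill strictly after index is
  under the allowable pre–post fill gap (flexible or fixed). A drug
  first filled after the index date has no anchor and can never count
  cross-sectionally; it yields no evidence row.

*Overrides* attach an alternative index-gap rule to products matching
an attribute predicate (e.g. `common_use = as_needed`, or the
metered-dose-inhaler flag); a matching key counts if it passes either
the base rule or the override, so an override likewise never removes a
drug. Overrides are matched against the anchor fill's product.

**Timeframe (longitudinal).** The count is the number of distinct keys
among in-scope fills inside a day-offset window around the index date,
ends inclusive. No preset uses it; it completes the framework and is
available through configs.

Every counted or rejected key is returned with a `DrugEvidence` record
(anchor date, observed and allowable gaps, cabinet and inpatient days,
which rule fired), so any count can be audited drug by drug.

## Preset registry

The `default` measure is: prescription products only, product basis at
the ingredient–route–form level, cross-sectional with a flexible
allowable index gap of 1.0 × days supply. Variants `v1`–`v14` each
change exactly one component (scope: `v1` adds OTC, `v2` oral-only,
`v3` excludes topical, `v4` excludes as-needed; uniqueness: `v5`
ingredient level, `v6` ingredient–route level; timeframe: `v7`
multiplier 1.2, `v8` fixed 90 d, `v9` fixed 180 d, `v10` post-index
rescue at 2 × days supply, `v11` cabinet supply with 180-day lookback,
`v12` hospitalization adjustment, `v13` as-needed override at fixed
180 d, `v14` MDI override at fixed 180 d). Modelling the default's
flexible gap as multiplier 1.0 makes `v7` the same rule family with a
different constant. The single-component property is enforced by a
test that diffs each variant's serialized components against the
default.

## Preprocessing

Fills are dropped (and tallied by reason, never fatal) when their
product is a medical supply, is absent from the dictionary, or when
days supply is 0 or 999 — both sentinel codes for unknown/invalid in
claims extracts; neither is usable as a denominator for a flexible
gap. Dates are ISO 8601; ingredient lists are pipe-delimited within
CSV cells.

## Cohort analytics

Per measure: count percentiles (25th, 50th, 75th, 95th) using the
nearest-rank convention (value at rank ⌈p·n⌉ of the sorted counts), so
integer counts give integer percentiles; linear interpolation is
available as a switch. Against a reference measure: the percentage of
patients whose count changed by 0, 1 or ≥2 drugs, binned on the
absolute difference (direction-symmetric). Percentages are rounded to
one decimal in the CSV; the text rendering shows values in (0, 1) as
"<1". No inferential statistics are attached — these are descriptive
summaries of a methodological sensitivity analysis.

## Synthetic cohort generator

The generator emulates the structural features of refill data that the
measures are sensitive to, not any particular disease area. Per
patient: a Poisson number of chronic drugs (default mean 4, typical of
an elderly multimorbid cohort); days supplies drawn from {30: 0.6,
90: 0.25, 28: 0.15}; refill chains whose inter-fill step is days
supply plus a discretized-exponential adherence lapse (default mean
5 days) minus a uniform early-refill component of up to 5 days — the
early component is what builds stockpiles, without it the cabinet-supply
rule would never fire; a 20 % chance per chronic drug of
discontinuation before index; a 30 % chance of using an as-needed
product with a few sparse fills; hospital stays at 0.5 per
patient-year lasting 2–7 days; a 365-day pre-index observation window
and 60 post-index days. The product dictionary mixes routes and forms
(oral tablets dominant, some inhalers flagged as MDIs, topicals,
patches), 15 % two-ingredient combinations, 10 % OTC, 15 % as-needed
products. All draws come from one seeded generator; output files are
byte-identical across runs of the same config.

What the generator does *not* model: dose changes, therapy switching
within a class, pharmacy switching, prices/coverage, seasonal effects,
or real drug names; and all simulated patients share one index date.
Tests passing on synthetic cohorts therefore demonstrate the engine's
rules and invariants, not agreement with any real cohort's count
distribution.

## Problem sizes and numerical choices

The test suite exercises the worked-example fixture (14 fills), unit
examples computed by hand or by brute-force oracles (day-by-day supply
replay; calendar-day enumeration for inpatient days), 1000 randomized
fill sets for the cabinet recurrence, and 100 seeded 50-patient cohorts
for the monotonicity suites — sizes chosen so the whole suite runs in
well under a minute while each property still sees thousands of
distinct patient histories. All date arithmetic is integral
(`datetime.date`); the only real-valued quantities are flexible gaps
and cabinet carries, which involve no subtractive cancellation, so no
tolerances are needed — comparisons are exact.

## Known limitations

* Quantity is carried but unused; dose-aware measures (PDC/MPR-style
  adherence) are out of scope.
* No therapeutic classification: overrides can only predicate on the
  shipped product attributes.
* One index event per patient per run; repeated-measures designs need
  one run per index.
* The longitudinal orientation counts fills only; it does not carry
  pre-window supply into the window.
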