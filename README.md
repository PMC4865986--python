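# drugtally

Counting how many drugs a patient uses sounds trivial, but every study
that derives a drug count from a pharmacy refill database makes a stack
of methodological choices — and different choices give different counts
for the same patient. `drugtally` makes those choices explicit and
computable. It is aimed at pharmacoepidemiologists and health-services
researchers who construct drug-count covariates or outcomes from claims
data and need to state, vary and stress-test their counting rules.

## The measure framework

A drug-count measure is a configuration of three components:

1. **Scope** — which products qualify as drugs: prescription vs OTC
   status, drug type (standard, vitamin, herbal, ...), route of
   administration, dosage form, and common use (regular vs as-needed).
2. **Uniqueness** — how duplicates merge into one counted drug:
   *product-based* (a combination product counts once) or
   *ingredient-based* (dissected into ingredients), keyed at one of four
   levels: ingredient, ingredient–route, ingredient–route–form, or
   ingredient–route–form–strength. Example: a regimen of an
   albuterol/ipratropium inhaler, albuterol nebulizer solution and
   albuterol tablets is 2 drugs ingredient-based at the ingredient
   level, 3 at the ingredient–route level.
3. **Timeframe** — cross-sectional at an index date or longitudinal
   over a window. Cross-sectionally, a drug with last pre-index fill at
   observed index gap *g* days and days supply *DS* counts when
   *g* < allowable gap, where the allowable gap is flexible (*m* × *DS*)
   or fixed (e.g. 90 or 180 days), optionally extended by the estimated
   **cabinet supply** on hand at the last fill (leftover days
   accumulated from earlier fills: carry *c* ← max(0, *c* + *DS* −
   gap-to-next-fill)), by **inpatient days** inside the gap (hospital
   days don't consume home supply), rescued by a **post-index fill**
   whose pre–post fill gap is under its own allowable gap, or widened by
   per-drug-class **overrides** (e.g. a fixed 180-day gap for as-needed
   drugs).

Fifteen preset measures ship in a registry: a `default` (prescription
scope, product basis at ingredient–route–form, flexible gap of the days
supply) and fourteen variants `v1`–`v14`, each altering exactly one
component — the classic design for probing how sensitive a count is to
each choice.

## Worked example

The packaged hypothetical patient fills an estradiol patch, metoprolol
and an ezetimibe/simvastatin combination tablet monthly, filled
sublingual nitroglycerin once 73 days before an index hospital
admission on 2008-07-01, and starts lisinopril at discharge.

```python
from drugtally import count_drugs, preset
from drugtally.synthetic import table3_fixture

history, dictionary = table3_fixture()
result = count_drugs(history, preset("default"), dictionary)
```

Running `python examples/01_count_single_patient.py` prints:

```
patient hypo: count = 3 under measure 'default'

drug key                                    gap  allow  counted  rule
estradiol-transdermal-patch                  13   28.0  True     base_gap
ezetimibe/simvastatin-oral-tablet            13   30.0  True     base_gap
metoprolol succinate-oral-tablet             13   30.0  True     base_gap
nitroglycerin-sublingual-tablet              73    9.0  False    none
```

Three chronic drugs count (each last filled 13 days before index,
within its supply); nitroglycerin's 73-day gap exceeds its 9-day supply,
and post-discharge lisinopril has no pre-index fill. The count becomes
4 under ingredient-based uniqueness (`v5`, `v6`: the combination splits
in two), under fixed 90/180-day gaps (`v8`, `v9`) or an as-needed
override (`v13`), and drops to 2 under oral-only scope (`v2`). See
`examples/` for cohort-level comparisons and custom measure configs.

## Command line

```bash
drugtally simulate --seed 42 --n-patients 200 --out-dir cohort/
drugtally count --fills cohort/fills.csv --dictionary cohort/dictionary.csv \
    --index cohort/index.csv --measure v9 --out counts.csv
drugtally compare --fills cohort/fills.csv --dictionary cohort/dictionary.csv \
    --index cohort/index.csv --hospitalizations cohort/hospitalizations.csv \
    --out report
```

`simulate` writes a seeded synthetic claims extract (chronic regimens
with imperfect adherence, discontinuations, as-needed drugs,
combination/OTC products, hospital stays); `count` writes per-patient
counts for one measure (`--evidence` adds a per-drug audit trail);
`compare` writes a measure-comparison table of count percentiles and
change-from-reference distributions.

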