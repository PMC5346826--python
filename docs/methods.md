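# Methods

`crcdss` re-implements, as a tested library, an intelligent decision-support
system for a colorectal-cancer (CRC) screening registry: patients are encoded
against a fixed minimum data set (MDS), stratified into hereditary-risk groups
by guideline rules, and given a survival percent estimated by cosine
similarity to deceased registry members, with per-subgroup means maintained in
real time as the registry changes.

## The minimum data set and its codec

Every patient is a vector of integer codes over 43 ordered slots:
socio-demographics, lifestyle, tumour classification (topology, morphology,
grade, pTNM), past medical history, symptoms, and vital status, plus three
derived slots (current-age category, diagnosis-age category, BMI category).
The slot order and the label→code maps are a frozen, JSON-serialisable
contract (`CodeBook`), because the downstream similarity computation depends
on alignment.

Two defects of the source coding sheet are repaired in the shipped codebook
and noted inline: the ethnicity column gave "Other" the same code as "Fars"
(remapped to 5), and the tumour-topology column contained duplicate and
colliding codes (the ten distinct anatomical sites are resequenced 1..10,
caecum→rectum). Tumour size is dichotomised against a grade-dependent cut
(20 mm for well-differentiated, 35 mm otherwise; both configurable).

Missing values use a dedicated sentinel (−1), never 0 — 0 is a live code
("No", T0/N0/M0). The coded label "Unknown" (3) is an observation, not a
missing value, and survives encoding.

### Derived features: faithful vs. strict

The deployed system's derivations carry two quirks that we preserve behind a
mode switch and do **not** make the default:

* **BMI** (`weight / (height/100)²`, cut points 18.5 / 24.9 / 29.9 applied as
  a strict `<` chain): an undefined BMI (missing or zero weight/height) fails
  every comparison and falls through to category 4. `faithful` mode
  reproduces this; the default `strict` mode returns the missing sentinel.
  The `<` chain also means the cut points are exclusive upper bounds (BMI
  24.95 is category 3), which we keep in both modes.
* **Age** is reference year minus Gregorian birth year, with no birthday
  adjustment; bands are <45 / 45–64 / ≥65. A `corrected` flag (off by
  default) counts completed years at mid-year instead. The reference year is
  an explicit parameter, never the wall clock, so encoding is reproducible.

### Persian calendar arithmetic

Birthdates are Solar Hijri (`"YYYY-MM-DD"`). Conversion uses day-number
arithmetic against the anchor 1 Farvardin 1370 = 1991-03-21 with the
arithmetic 33-year-cycle leap rule (year *y* is leap iff `(25y + 11) mod 33 <
8`; months 1–6 have 31 days, 7–11 have 30, month 12 has 29 or 30). Over the
supported range 1300–1450 AP this agrees with astronomical reckoning — the
unit tests pin seven published Nowruz dates (1952, 1991, 1996, 2019, 2020,
2024, 2025) and property-test the bijection in both directions. Outside that
range the arithmetic rule can drift from the astronomical calendar, so the
converter refuses those years rather than silently approximating.

## The similarity contract

Patient similarity is the cosine

    cos(x, y) = round( Σ xᵢyᵢ / (round(‖x‖, 3) · round(‖y‖, 3)), 3 )

with *both* roundings (half-even, three decimals) part of the contract: the
system's published worked example, `cosine_similarity([3,45,7,2],
[2,54,13,15]) = 0.972` with norms 45.684 and 57.567, is only reproducible
with the norms rounded before the product. An `unrounded` mode provides the
high-precision value; the faithful value never deviates from it by more than
0.002 (property-tested), and can slightly exceed 1 (up to ≈1.001) because a
rounded-down denominator can push the quotient past unity.

Missing slots are handled before any similarity call: the default
`pairwise-complete` policy drops slots missing in *either* vector and records
the shared mask; coded "Unknown" values are kept as values.

### Feature normalisation

The estimator (not the raw cosine helper) min-max scales every slot to [0, 1]
using the codebook's code range before computing similarity. Without this,
wide-coded fields (topology 1–10, morphology 1–6) dominate the inner product
and a single irrelevant field can swamp the comparison — the standard failure
mode of unnormalised similarity over mixed-scale features. Normalisation is a
registry option (`normalize_features`, default on); the two-stage rounding
contract applies identically to scaled values.

## Risk stratification

`classify_risk` is a pure, priority-total cascade; exactly one subgroup (or
none) fires per record and the decisive rule is recorded:

1. **Confirmed:** registry HNPCC designation or germline MMR mutation →
   HNPCC; germline APC with ≥100 cumulative adenomas (or unknown burden) →
   FAP, with 10–99 → AFAP; biallelic MUTYH → MYH; registry FAP designation →
   FAP.
2. **Suspected:** Amsterdam II **and** any revised-Bethesda clause →
   Suspected HNPCC; an unexplained adenoma burden ≥10 → Suspected FAP.
3. **IBD** → its own high-risk subgroup.
4. **Moderate:** family CRC history short of the criteria (configurable
   tier).
5. **Average** otherwise.

Amsterdam II is evaluated with a per-clause trace (≥3 relatives with
HNPCC-associated tumours — CRC, endometrial, small bowel, ureter/renal
pelvis; a first-degree link; two successive generations; one diagnosis
before 50; FAP excluded; pathology verified). The data model stores a flat
relative list with a generation index rather than a pedigree graph, so the
"one is a first-degree relative of the other two" clause is approximated as:
an affected first-degree relative with at least two other affected relatives
within one generation of it. This accepts exactly the classical
parent/sibling/grandparent constellations and is the strongest statement the
flat representation supports.

The revised-Bethesda clause set (CRC before 50; synchronous/metachronous
HNPCC tumours; MSI-high before 60; an affected first-degree relative before
50; two affected first/second-degree relatives) is config-editable, as are
all polyposis thresholds — guideline versions vary and the engine is meant to
absorb that in configuration, not code.

Molecular evidence upgrades Suspected HNPCC to HNPCC (identified germline
mutation, or abnormal mismatch-repair IHC together with MSI-high); the
transition is idempotent and appended to the rule trace. Surveillance
recommendations are a plain (group, subgroup) → (method, start age, interval)
table; the shipped defaults encode the widely published intervals (annual
colonoscopy from adolescence for FAP, 1–2-yearly from the early twenties for
Lynch, FIT from 50 for average risk) and are fully overridable.

## Survival estimation

Default mode, **deceased-distance**:

    percent = 100 × (1 − mean cosine similarity to the k most similar
              deceased patients),   k = 5 by default

References are drawn from the patient's own risk subgroup when it holds ≥ k
deceased members, else registry-wide; ties break by patient id. The deceased
are never queries. The alternative **outcome-weighted** mode is a
similarity-weighted k-NN vote over patients of known vital status
(`100 × Σ sim·alive / Σ sim`). Outcome fields (vital status, survival
quality) are excluded from the similarity features in both modes, so an
estimate never reads the reference's outcome coding; recorded survival time
(months) is stored but unused by the default estimator.

Estimates are clipped to [0, 100] and rounded to six decimals (removing
binary float residue so that limit cases are exact: an identical deceased
twin at k=1 gives 0.0, an all-alive neighbourhood gives 100.0).

### Real-time consistency

Per-subgroup means are arithmetic means over living members' current
estimates, summed in patient-id order so the value is independent of
insertion history. Every mutation refreshes derived state through a
conservative affected-set rule: a change touching the reference pool (the
patient is or was deceased, the mode is outcome-weighted, its subgroup or
vector changed) recomputes all estimates; a purely alive-side change
recomputes only that patient. The invariant — incremental state identical to
a from-scratch rebuild — is asserted after every one of 100 random edits on a
200-patient registry in the acceptance suite.

## Synthetic registries

The generator emulates a screening registry at desk scale: 500 patients by
default, subgroup mix 72 % average / 8 % IBD / 5 % each suspected Lynch and
suspected polyposis / 2–3 % each confirmed syndrome, 30 % deceased, 5 %
missingness on non-essential fields. Subgroup membership is constructed, not
sampled — pedigrees are built to provably satisfy or fail Amsterdam II
(verified against the rule engine at generation time, with the broken clause
recorded) — and the rule engine's assignment is asserted per record.

Prognosis is planted as a logistic model on the *encoded* features: risk
score `s = Σ w_f·code_f` with clinically ordered weights (metastasis 2.0,
nodal stage 0.8, advancing grade 0.8, T stage 0.6, histological grade 0.45,
age 0.5, alarm symptoms 0.3–0.5; only fields without an "Unknown" code carry
weight), death probability `σ(s − c)` with the intercept bisected so the
expected deceased fraction equals the configured value exactly, and vital
status drawn Bernoulli. The resulting spread is realistic (M1 vs M0 mean
death probability ≈ 0.58 vs 0.24). The mechanism is deliberately different
from the cosine estimator, so calibration tests measure recovery of structure
the estimator was never handed.

What the generator does **not** emulate: correlated staging (pT/pN/pM are
sampled independently), informative missingness, temporal follow-up, or any
national incidence pattern. Passing tests therefore demonstrate internal
consistency and directional validity on independent-feature registries, not
clinical performance.

### Calibration: what the estimator recovers, and what it does not

With the planted structure above, deceased-distance estimates (k=5) correlate
positively with the planted survival probability on every seed tried, and the
top planted-survival decile always receives higher mean estimates than the
bottom decile. The Spearman correlation, however, sits around 0.16–0.31
(median ≈ 0.27 across seeds) — the acceptance suite's ≥ 0.3-on-a-majority
threshold is **not met** and the corresponding test is left failing.
Diagnostics show this is a property of the statistic, not a tuning problem:
restricting the feature mask to exactly the planted fields, or averaging over
*all* deceased instead of the top five, moves the correlation only to
≈ 0.27–0.36. "One minus mean top-k cosine" compresses a logistic risk score
through order statistics of a bounded similarity and cannot track its ranks
much more closely under realistic feature noise.

## Numerical and design choices

* Rounding is Python/NumPy half-even throughout the contract path; the
  vectorised batch similarity is asserted bit-identical to the scalar path.
* Ties (neighbour selection, equal similarity) break by patient id ascending.
* Degenerate inputs: zero-norm pairs raise an undefined-similarity error;
  pairs with no shared non-missing slots raise an empty-overlap error; both
  are recorded as NaN with a log line when they occur inside a matrix or
  ranking, rather than aborting the batch.
* Problem sizes in the test and acceptance suites (500-record codec sweep,
  200-patient × 100-edit consistency run, ~12 000-case rule grid, three
  500-patient calibration registries) keep every suite in the tens of
  seconds while exercising each contract at a scale where violations would
  surface.
* The registry persists as a plain directory (CSV + two JSON files), not a
  database: desk-scale, diffable, and the derived file is regenerable.
* The CLI (`cdss`) is a thin `click` layer over the library; every
  subcommand corresponds to one library call path.

## Known limitations

* The Amsterdam II first-degree-link clause is evaluated on a flat relative
  list (see above), not a pedigree graph.
* Age ignores birth month/day in the default (faithful) mode.
* The calendar converter is restricted to 1300–1450 AP by design.
* Group means are simple arithmetic means of point estimates; no uncertainty
  is propagated.
* The estimator's absolute percent scale depends on the similarity spread of
  the registry; it is a relative ranking device, not a calibrated survival
  probability (see the calibration section).
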