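# crcdss

Clinical decision support for **colorectal-cancer (CRC) screening
registries**: a coded minimum data set, a guideline-driven hereditary-risk
rule engine (Amsterdam II / revised Bethesda, FAP/AFAP/MYH/HNPCC/IBD
subgroups), and a case-based survival estimator that scores each living
patient by cosine similarity to deceased registry members — with
per-subgroup survival statistics kept consistent in real time as the
registry changes.

It is written for registry engineers and screening-programme analysts who
need the decision logic of such a system as an importable, testable library
rather than a web application.

## The model

Every patient is encoded as an ordered vector of integer codes over a fixed
43-slot minimum data set (demographics, lifestyle, tumour topology/morphology
/grade/pTNM, past medical history, symptoms, vital status, plus derived BMI
and age categories; Persian-calendar birthdates are converted by exact
33-year-cycle arithmetic). Similarity between two patients is the cosine
with a fixed two-stage rounding contract,

```
cos(x, y) = round( Σ xᵢyᵢ / ( round(‖x‖₂, 3) · round(‖y‖₂, 3) ), 3 )
```

and a living patient's survival percent is estimated from the *k* most
similar deceased patients (drawn from their own risk subgroup when it has at
least *k* deceased members):

```
percent = 100 × (1 − mean top-k cosine similarity to the deceased),  k = 5
```

Risk stratification is a deterministic, priority-ordered cascade —
mutation-confirmed syndromes, then pedigree-suspected syndromes (Amsterdam II
∧ Bethesda ⇒ Suspected HNPCC, with molecular findings able to upgrade it to
confirmed HNPCC), then IBD, a moderate family-history tier, and average risk
— each assignment carrying the trace of the rule that fired and a
surveillance recommendation (method, start age, interval) from a
configurable table.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

```python
from crcdss import (Registry, SimulationConfig, generate_registry,
                    cosine_similarity, classify_risk, recommend_screening,
                    RawPatientRecord, RelativeCancer)

# the similarity contract, bit-exact
print(cosine_similarity([3, 45, 7, 2], [2, 54, 13, 15]))     # 0.972

# a proband whose pedigree meets Amsterdam II, no molecular work-up yet
proband = RawPatientRecord(
    "IR-000241", diagnosis_age=46, birthdate_persian="1350-04-12",
    weight=81, height=170, sex="Male",
    family_history=[
        RelativeCancer("first", 1, "CRC", 44, pathology_verified=True),
        RelativeCancer("first", 0, "CRC", 58),
        RelativeCancer("second", 2, "endometrial", 61),
    ])
assignment = classify_risk(proband)
print(assignment.group, assignment.subgroup, assignment.fired_rules)
# high Suspected HNPCC ('amsterdam-ii-met', 'bethesda-met')
rec = recommend_screening(assignment)
print(rec.method, rec.start_age, rec.interval)                # colonoscopy 20 24

# a synthetic 300-patient registry with survival estimates
records, truth = generate_registry(SimulationConfig(seed=42, n_patients=300))
reg = Registry(k=5)
reg.bulk_load(records)
e = reg.entries["P00007"]
print(e.group_key, e.estimate.percent, e.estimate.neighbors[:2])
# average 35.54 (('P00244', 0.673), ('P00040', 0.669))
print({g: (round(s.mean_percent, 1), s.n) for g, s in reg.stats.items()
       if g in ("HNPCC", "FAP")})
# {'FAP': (38.2, 4), 'HNPCC': (35.9, 4)}
```

The proband is assigned to the *Suspected HNPCC* subgroup because his
pedigree satisfies every Amsterdam II clause and his diagnosis age (<50)
fires a Bethesda trigger; the recommendation row says 1–2-yearly colonoscopy
from age 20. Patient `P00007`'s 35.54 % means his five most similar deceased
registry members have a mean (normalised, rounded) cosine similarity of
0.6446 to him; the dictionary shows per-subgroup mean survival over living
members.

The same pipeline is scriptable from a shell:

```
cdss simulate --n 200 --seed 7 --out sim
cdss ingest sim/registry.csv --families sim/families.json --store store
cdss stats --store store
cdss search --store store --field subgroup=FAP
```

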