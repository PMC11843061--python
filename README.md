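# sorpkit

Risk-stratified early forewarning of septic shock in the ICU: a
scorecard pipeline over arterial-blood-gas and vital-sign features, with
Sepsis-3 onset labeling and a synthetic cohort generator for end-to-end
testing without credentialed patient data.

Septic shock kills a large fraction of the patients who develop it, and
every hour of delayed treatment costs survival.  `sorpkit` is aimed at
clinical-informatics researchers who want a transparent, bedside-computable
alternative to black-box early-warning models: the entire model is a
printed card — a base score plus one number per feature bin — built from
features obtainable within minutes (point-of-care blood gas, monitor
vitals).

## The model

At each hour `t`, features are summarized by their mean over the look-back
window `[t−6, t)` and the card predicts septic shock onset within
`(t, t+6]`.  Each feature is discretized by supervised chi-merge binning
and encoded by its weight of evidence,

    WOE_i = ln( Dist_NS_i / Dist_S_i ),
    IV    = Σ_i (Dist_NS_i − Dist_S_i) · WOE_i,

where `Dist_S_i` and `Dist_NS_i` are the shock / non-shock class shares of
bin `i` and the information value IV selects the final bin count.  A
logistic regression on the WOE-encoded features is then re-expressed as
points: with `factor = PDO/ln 2` and offset `P0`, bin `j` of feature `i`
is worth `−factor · β_i · woe_ij` points on top of a base score, and one
affine rescale maps the achievable total exactly onto [0, 100].  **Lower
total score = higher risk.**  Scores stratify patients into high (0–40),
medium (40–60), low (60–80), and ultralow (80–100) risk groups, evaluated
by KS, AUC, PSI, per-group incidence, and forewarning lead times.

Ground-truth labels follow the Sepsis-3 definitions: suspected infection
from antibiotic/culture pairing (24 h / 72 h windows), sepsis at an acute
SOFA rise ≥ 2 within [−48 h, +24 h] of suspicion, and septic shock at the
earliest hour with an active vasopressor, adequate fluid resuscitation
(> 30 mL/kg or > 1000 mL in 3 h), and a first post-resuscitation lactate
> 2 mmol/L.  See `docs/methods.md` for every operational choice.

## Worked example

```python
from sorpkit import CohortSpec, RunConfig, generate_cohort, run_pipeline

bundle = generate_cohort(CohortSpec(n_patients=600), seed=4)   # 5 event tables
result = run_pipeline(bundle, RunConfig(seed=4))               # label -> card
print(result.metrics["auc"])
```

prints (from `examples/03_train_scorecard.py`):

```
cohort: 600 patients, 85 shock
AUC train/val/test: 0.932 / 0.864 / 0.842
KS on test scores: 0.611 (peak near score 55)
base score: 44.33; first feature's bin points:
  ph      (-inf, 7.381]: -0.77
  ph     (7.381, 7.392]: -0.27
  ph     (7.392, 7.412]: +2.05
  ph       (7.412, inf]: +0.84
```

A patient's score is the base score plus one bin score per feature; here an
acidotic blood gas (pH ≤ 7.381) *subtracts* points, pushing the total
toward the high-risk zone.  The AUCs measure how well the card ranks
impending shock six hours ahead on held-out patients, and the KS peak marks
the score where shock and non-shock distributions separate most.

The other scripts in `examples/` walk the remaining capabilities:
closed-loop Sepsis-3 labeling (`01`), chi-merge/WOE binning on planted
odds (`02`), risk-group incidence and PSI (`04`), and hourly trajectories
with lead-time statistics (`05`).  A thin CLI wraps the same pipeline:

```bash
sorpkit simulate --n 500 --seed 1 --out cohort/
sorpkit run-all --cohort cohort/ --seed 1 --out run/
```

## Input contract

Five CSVs (ISO-8601 timestamps or float hours from admission):
`measurements.csv` (patient_id, time, channel, value), `medications.csv`
(patient_id, time, drug_class), `fluids.csv` (patient_id, start, end,
volume_ml), `cultures.csv` (patient_id, time), `patients.csv` (patient_id,
weight_kg, icu_in, icu_out, death_time).  There are no direct readers for
MIMIC-IV or eICU schemas; map exports onto this contract.

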