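# Methods

## Problem and model

`sorpkit` builds an early-forewarning score for septic shock (SS) in ICU
patients with sepsis.  At any hour `t`, the mean of each clinical feature
over the look-back window `[t-6, t)` hours is mapped to a total score in
[0, 100]; low scores mean high risk of SS onset within `(t, t+6]` hours.
The score is a *scorecard*: a weight-of-evidence (WOE) logistic model whose
log-odds are re-expressed as additive integer-friendly points, so it can be
computed at the bedside from a printed card as easily as by software.

The pipeline has five stages.

### 1. Sepsis-3 phenotyping

Onset times are operationalized from raw event streams:

* **t_suspicion** — earliest qualifying antibiotic/culture pair: a culture
  within 24 h after an antibiotic, or an antibiotic within 72 h after a
  culture, timestamped at the earlier member.
* **t_sepsis** — within `[t_suspicion − 48 h, t_suspicion + 24 h]`, the
  first hour at which the hourly SOFA total exceeds its baseline by ≥ 2
  points.  The baseline is the *running minimum* of SOFA inside the window
  up to the candidate hour; a window-start baseline is available behind
  `baseline="window_start"`.  The running minimum is robust to chronic
  organ dysfunction present on admission.
* **t_septic_shock** — earliest hour ≥ t_sepsis at which (i) a vasopressor
  is active, (ii) fluid resuscitation was adequate, and (iii) the first
  lactate drawn within 6 h after the resuscitation window exceeds
  2 mmol/L.  "Adequate" means > 30 mL/kg *or* > 1000 mL infused during the
  3 h before `t_ref`, where `t_ref` is the earlier of the first vasopressor
  start and the first hourly cell with MBP < 65 mmHg (both at or after
  t_sepsis).  Fluid events partially overlapping the window count pro-rata
  by overlap duration; with no recorded weight only the absolute 1000 mL
  criterion applies.

SOFA uses the standard six 0–4 subscores (respiration P/F, platelets,
bilirubin, MAP, GCS, creatinine), configurable as a JSON table.  The CSV
contract carries no vasopressor dose, so an active vasopressor raises the
cardiovascular subscore to 2 rather than selecting among the dose-dependent
grades 2–4; the hourly SOFA ceiling is therefore 22 in practice.  A missing
subsystem scores 0.

### 2. Hourly timeline

Measurements are floored to hours from ICU admission (a reading exactly on
a boundary belongs to the later hour), averaged within the hour, and
forward-filled without bound.  Cells before a channel's first observation
stay missing; no value ever depends on later measurements, so every derived
sample is causal (tested by prefix stability).  Intervals are half-open
`[a, b)`; relative to shock onset the conventional windows are look-back
`[-12, -6)`, preonset `[-6, 0)`, and postonset `[0, +6)`.

Training samples: one positive per shock patient anchored at
`t_septic_shock − 6` (features from `[-12, -6)` relative to onset) and one
negative per non-shock patient at a uniformly random in-stay hour with a
complete look-back window (seeded).  This matches patient-level cohort
counting.  `all_hours` sampling serves real-time scoring; samples with a
missing feature are dropped from training (count logged) but scored at
run time through the missing bin.

### 3. WOE binning

Per feature: ~10 quantile bins; any bin containing a single outcome class
is merged into its smaller-count neighbour (ties toward the left) until
every bin is mixed; then *chi-merge* — repeatedly merge the adjacent pair
with the largest Pearson 2×2 chi-square p-value (no continuity correction;
p-ties merge the leftmost pair) — recording the information value
IV = Σ (Dist_NS − Dist_S)·WOE at each bin count.  The final count is the
smallest k whose IV retains at least (1 − τ) of the best IV along the path
(τ = 0.05): coarser cards are easier to use, and IV can only fall under
merging (log-sum inequality, asserted along every path).

WOE is oriented as ln(Dist_NS / Dist_S): positive WOE marks a bin enriched
in non-shock patients, so higher points mean lower risk and the card reads
"lower total = higher risk".  The opposite orientation differs only in sign
and is absorbed by the scorecard rescale.  A dedicated missing bin is
created when ≥ 1% of training values are missing; otherwise missing maps to
WOE 0 (the neutral encoding).

### 4. Scorecard

Unregularized maximum-likelihood logistic regression on the WOE-encoded
features (label 1 = shock); quasi-perfect separation falls back to a weak
L2 penalty with a warning.  With `factor = PDO/ln 2` and `offset = P0`, the
raw total `offset + factor·logit(P(NS))` splits into a base score plus
per-bin points `−factor·β_i·WOE_ij`, and one final affine map sends the
*achievable* raw range exactly onto [0, 100].  Consequently P0/PDO
(defaults 60/20, the conventional choice) have no effect on the emitted
card, the total is exactly affine in the model log-odds, and ranking by
score reproduces the logistic model's AUC.  Points are printed at two
decimals; scoring uses unrounded values, with an integer mode for
bedside-card emulation.

### 5. Evaluation

* **Risk groups**: HR `[0,40)`, MR `[40,60)`, LR `[60,80)`, ULR `[80,100]`
  — fixed cutoffs, half-open upward (a boundary score belongs to the safer
  group; 100 is ULR).  A research mode can re-derive a threshold from the
  KS argmax.
* **KS**: maximum gap between the class-wise cumulative score
  distributions, evaluated at every observed score so it equals the
  brute-force maximum over thresholds; integer-grid curves are kept for
  plotting.
* **AUC**: Mann–Whitney concordance of the reversed score (lower = riskier),
  ties counting one half.
* **PSI**: Σ (p_b − q_b)·ln(p_b/q_b) over the four risk groups; zero-mass
  bins smoothed by ε = 1e-4 with renormalization (perturbs PSI by ≤ 1e-3
  whenever all counts are ≥ 10).
* **Incidence**: per-group shock rate with numerator/denominator and the
  percentage at one decimal.
* **Lead times**: hourly scores from the sliding look-back; a shock
  patient's lead is onset hour minus the first hour the score enters HR.
  Patients never entering HR are excluded from the median/IQR but retained
  in "fraction in HR by lead L" denominators.
* **Escalation**: a patient escalates when the group series moves from the
  source group to *at least* the target group (ULR < LR < MR < HR) within
  the window before onset.

The train/validation/test split is patient-level 60/20/20, seeded, and
stratified by shock label to stabilize small-cohort evaluations.

## Synthetic cohorts

The generator emits the five-table CSV contract plus ground truth.  Study
conditions (fixed as defaults): shock prevalence 0.15; stays lognormal
around 90 h clipped to [40, 240] h; weights lognormal around 75 kg (so the
30 mL/kg and 1000 mL resuscitation criteria both bind in different
patients); vitals roughly hourly with 5% dropout (MBP continuous), blood-gas
panels every 4–8 h, other labs every 8–16 h.

Every patient is septic: one antibiotic/culture pair plants t_suspicion and
a creatinine step to the renal-subscore-2 range plants t_sepsis six hours
later.  Shock patients add a scripted motif at the planted onset hour `T`:
an adequate fluid bolus inside `[T−5, T−2)`, hypotension (MBP ≈ 56 mmHg)
from `T−2`, vasopressor from `T−1`, and a first post-resuscitation lactate
> 2 mmol/L at `T`.  Non-shock patients violate exactly one criterion —
no hypotension/vasopressor episode (70%), inadequate fluids (15%), or
lactate capped below threshold (15%).  Channels feeding onset criteria
report the exact hourly value (no within-hour jitter) and noise on every
channel is clipped inside threshold-safe bands, so hourly averaging and
forward filling reproduce the planted onsets *exactly*; the closed-loop
tests assert 100% recovery and zero false shock flags.

Risk is graded: a per-patient severity (shock ~ U(0.15, 1), non-shock ~
0.8·Beta(1.5, 3.5)) scales a 16 h linear pre-onset drift of lactate, blood
pressures, pH, heart rate, and the other model features toward shock-like
values, with a milder constant shift after sepsis onset in non-shock
patients.  Severity grading yields overlapping score distributions and
hence graded per-group incidence, as in real cohorts.  `plant_bin_risk`
pins a (non-criterion) feature to planted per-bin odds for parameter
recovery; `sample_bin_risk` draws the equivalent tabular samples directly,
together with each sample's true Bayes log-odds.

What the generator does **not** emulate: real marginal distributions or
inter-feature correlations, measurement artifacts, treatment feedback
beyond a linear post-onset relaxation, multiple suspicion episodes per
patient, and dose-titrated vasopressors.  Passing closed-loop and recovery
tests therefore demonstrates correctness of the algorithms under the
stated generative model, not clinical performance on real ICU data.

## Numerical choices

* Bin intervals are right-closed `(a, b]` with unbounded outer bins; a
  value on an internal edge joins the bin that edge closes.
* Quantile edges are deduplicated; interior edges equal to the feature
  maximum are trimmed so no empty top bin arises; a feature is *unusable*
  (dropped, logged) when fewer than two mixed-class bins can be formed.
* Chi-square on a 2×2 with all-positive margins is always defined; p = 1
  for identical class ratios makes homogeneous pairs merge first.
* The scorecard rescale denominator is the achievable raw range; a
  degenerate card (all totals equal) is rejected.
* Scores are clamped to [0, 100] after summation (a no-op for achievable
  combinations).
* Forward filling is unbounded; a maximum carry-forward horizon was left
  out deliberately (flagged for sensitivity work) because the source
  procedure states none.

## Problem sizes

The bundled studies run at sizes chosen for a laptop-class machine:
closed-loop phenotyping on 500 patients, stratification and trajectory
statistics on a 2000-patient cohort, and parameter recovery on 20,000
tabular samples.  All are regenerated from seeds at run time; nothing is
shipped as data.

## Known limitations

* Cardiovascular SOFA saturates at 2 (no dose data in the schema).
* Whether vasopressor initiation must *follow* adequate resuscitation is
  ambiguous in the consensus wording; the implementation requires only
  joint satisfaction at the candidate hour.
* The eICU-style ICD-code shock label is supported only as a pass-through
  flag, not a method.
* No direct readers for MIMIC-IV/eICU schemas; the documented CSV contract
  stands in.  Mapping real exports onto it is the user's responsibility.
* Headline figures quoted for credentialed cohorts elsewhere (e.g. test
  AUC near 0.95) are not reproducible from synthetic data; this package's
  own evaluation reports whatever its seeds produce.
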