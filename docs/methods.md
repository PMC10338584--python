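# Methods

## Scope and model

`lltsim` models a *sequential treatment-intensification pathway* for LDL-C
lowering in a fixed cohort of patients at high or very-high cardiovascular
risk who are already on lipid-lowering therapy. The model is deliberately
minimal: no statin initiation or up-titration, no PCSK9-inhibitor or
inclisiran stage, no adherence, adverse-event or cardiovascular-outcome
modelling, and no time dynamics beyond the implicit week-12 efficacy
horizon of the treatment-effect distributions. Each patient is an
independent unit; treatment responses are independent across patients,
steps and replicates.

### Goal logic

At-goal status is a strict comparison, `ldl < threshold`, with thresholds
70 mg/dL (high risk) and 55 mg/dL (very-high risk) stored natively in
mg/dL; a value exactly at the threshold is *not* at goal. The mmol/L
equivalents (1.8, 1.4) are supported only through the conversion utility
(1 mmol/L = 38.67 mg/dL) and agree with the mg/dL thresholds within 1 mg/dL
of rounding.

### LDL-C resolution and eligibility

Baseline LDL-C is the directly recorded value when present, otherwise the
Friedewald estimate TC − HDL − TG/5 (all mg/dL). The Friedewald formula is
refused at TG ≥ 400 mg/dL (the formula's standard validity bound; the VLDL
≈ TG/5 approximation fails above it) and a negative estimate raises a
data-inconsistency error; in both cases the patient's LDL-C stays missing.
The eligibility filter applies five exclusions in a fixed order —
unresolvable LDL-C, missing risk class, statin users with undocumented
intensity, no lipid-lowering therapy, PCSK9-inhibitor use — counting each
patient at the first failing stage. Patients on "other LLT" only are
retained (they have therapy documented).

### Efficacy distributions

* **Ezetimibe**: fractional reduction r ~ Beta(1.6, 5.4), mean 22.9%, SD
  14.8%. Bounded support means ezetimibe can only lower LDL-C in the model.
  A moment-matching helper (`beta_from_moments`) converts any feasible
  (mean, SD) pair to shape parameters — the 22.7%/16.5% literature effect
  maps to ≈ (1.24, 4.21) — but the default is the (1.6, 5.4) pair itself,
  kept as the authoritative reproduction target rather than re-derived.
* **Bempedoic acid**: week-12/baseline ratio x ~ Lognormal(μ, σ), two pools
  by statin background: (−0.2137, 0.2505) for moderate/high-intensity
  statin users, (−0.3176, 0.2931) for no/low-intensity users. The ratio
  mean is exp(μ + σ²/2) and P(increase) = 1 − Φ(−μ/σ) ≈ 0.20 and 0.14
  respectively; no truncation or cap is applied to large ratios.
* **Fitting**: `fit_lognormal_ratios` is the plain MLE — log-mean and
  *population* (1/n) log-SD. At the pooled-trial sample sizes (1922, 399)
  the 1/n vs 1/(n−1) difference (< 0.0004 in log-SD) is far below recovery
  tolerance. Constant input returns a degenerate fit (log_sd = 0) with a
  warning rather than an error.

### Pathway and Monte Carlo engine

Within a replicate: patients at goal at baseline are never touched (their
LDL-C is carried forward unchanged through all steps); patients not at
goal and not on ezetimibe receive ezetimibe; patients still not at goal
after that stage — including baseline ezetimibe users who were never at
goal — receive bempedoic acid. A patient reaching goal after ezetimibe
receives no bempedoic acid and no further draws. Consequently the treated
set at the ezetimibe stage is structural (identical in every replicate)
while the bempedoic-stage set varies with the ezetimibe draws.

Replicate `i` of a run with master seed `s` uses the generator seeded by
`SeedSequence((s, i))`, making every replicate independently reproducible.
Draws are consumed in a fixed documented order: one beta block for all
ezetimibe recipients in cohort order, then one lognormal block per
bempedoic pool (moderate/high-statin pool first, cohort order within each
block). `simulate_patient` is the scalar per-patient reference
implementation; `run_replicate` is the vectorised equivalent, and a test
pins their agreement under injected deterministic draws.

Summaries use empirical quantiles with linear interpolation between order
statistics (numpy's default, type 7); no convention is canonical here and
the choice only matters at half-integer medians of counts, which are
reported as-is with a rounded companion field. End-of-pathway ezetimibe
utilisation is baseline users plus simulated additions; percentages use
the full simulation-cohort denominator.

Default problem size is 10,000 replicates of a 144-patient cohort (~1 s on
one core); `n_reps` is configurable.

## Synthetic cohort calibration

Patient-level data for the target cohort are unpublished, so the generator
reproduces its printed aggregates.

* **LDL-C family**: one lognormal per risk stratum — positive support,
  right-skewed (the pooled CV 43.59/76.38 ≈ 0.57 is far from normal), two
  parameters per stratum against five pooled constraints: mean, SD,
  P(<55), P(<70) and the expected at-goal count
  n_vh·P_vh(<55) + n_h·P_h(<70). Calibration minimises the sum of squared
  *relative* residuals (Nelder–Mead over (μ, log σ) per stratum, started
  from the pooled moment-matched lognormal). The high-risk stratum holds
  only 9 of 144 patients and is weakly identified, so a small ridge (1e−3)
  shrinks its parameters toward the very-high stratum's. The published
  aggregates turn out to be nearly consistent with a common lognormal: all
  five relative residuals calibrate below 1%. Calibration fails loudly
  (with residuals attached) if any relative residual exceeds 5%.
* **Structural layout** (exact for every seed): 135 very-high / 9 high
  risk; 52 at goal, split across strata by the calibrated goal
  probabilities (largest-remainder apportionment → 47 + 5); 35 ezetimibe
  users — 20 not at goal, 15 at goal — spread across strata proportionally
  to stratum size; 134 moderate/high-intensity statin users (alternating
  assignment), 1 low-intensity, 9 off statin, of whom 6 are
  ezetimibe-alone and 3 other-LLT-only. That 6/3 completion of the
  overlapping published regimen categories is an assumption; the published
  tables do not pin the overlap down.
* **LDL-C values**: drawn from the patient's stratum lognormal *truncated
  to the assigned at-goal side* of their threshold — rejection sampling in
  batches with a 10^5-draw budget per patient, falling back to
  inverse-transform sampling of the truncated distribution for thin
  regions. At-goal membership is therefore exact by construction, while
  means, SDs and cutoff fractions fluctuate around the calibrated values
  (cohort-mean SD across seeds ≈ 3 mg/dL at n = 144); this cohort-shape
  noise is the dominant seed-to-seed variation in all downstream stochastic
  outputs.
* **Registry fixture (N = 310)**: the 144 eligible patients plus 166
  single-defect patients sized to the published sequential attrition (13
  unresolvable LDL-C, 17 missing risk, 5 unknown statin intensity, 76
  untreated, 55 on PCSK9i), each defect on a distinct patient so the
  waterfall stages separate cleanly and are seed-invariant. The published
  total of PCSK9i users (61) exceeds the sequential difference (55); the
  sequential differences are treated as authoritative. Every fifth
  eligible patient is stored as a consistent lipid panel rather than a
  direct LDL-C, so the Friedewald path is exercised inside the fixture.

**What passing tests show — and don't.** The generator reproduces the
published *aggregates*; it cannot reproduce unpublished features of the
real cohort (covariate correlations, within-stratum multimodality, the
true ezetimibe × risk × LDL-C cross-tabulation, digit-preference in
measured lipids). Agreement of simulated goal attainment with the
published results therefore validates the pathway logic and the efficacy
model under a *plausible* cohort shape, not the cohort shape itself;
stochastic comparisons are made at tolerances wide enough (±5 percentage
points / ±5 mg/dL, ±7 pp for cutoff fractions) to absorb that uncertainty.

## Numerical choices

* Quantiles: linear-interpolation empirical quantiles (type 7).
* Sample SD (ddof = 1) in cohort summaries; a single-patient cohort
  reports SD 0 rather than NaN. Population SD (ddof = 0) in the lognormal
  MLE, as above.
* Strict `<` at every goal re-check; thresholds in mg/dL exactly.
* Degenerate inputs: empty cohorts, zero-width beta moments, non-positive
  ratios, TG ≥ 400, zero-mass truncation regions all raise typed errors
  rather than propagating NaN.
* Results JSON contains no timestamps, so fixed-seed reruns are
  byte-identical; wall-clock provenance goes to stderr logging.

## Known limitations

* Efficacy draws are independent across drugs within a patient; a patient
  who responds poorly to ezetimibe is not modelled as a poor responder to
  bempedoic acid.
* The beta ezetimibe model forbids LDL-C increases under ezetimibe, which
  real-world data do show occasionally.
* Aggregate-calibrated cohorts understate real between-cohort variability;
  conclusions transfer to the real cohort only insofar as a two-stratum
  lognormal is an adequate LDL-C model.
* No missing-data imputation: the eligibility filter drops incomplete
  patients exactly as the published selection did.
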