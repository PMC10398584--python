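# Methods

## Scope and model

`lipidsim` simulates guideline-directed escalation of lipid-lowering
therapy (LLT) in a cohort of patients who are above their risk-based LDL-C
goal on a stable regimen, and converts the achieved LDL-C lowering into
10-year cardiovascular risk reductions. The simulation is a static
treatment-response model: no titration timelines, adherence, intolerance,
or competing risks. Patients already on a PCSK9 inhibitor are excluded at
cohort construction; novel agents outside the guideline algorithm
(bempedoic acid, inclisiran) are not modelled.

## The stepwise algorithm

Within one Monte Carlo replicate each patient walks steps 1→2→3 and is
**frozen at first goal attainment** (no further intensification). Goal
comparison is strict (`LDL < goal`), matching the guideline's "less than"
wording. Default goals (mmol/L): low 3.0, moderate 2.6, high 1.8,
very-high and non-recurrent ASCVD 1.4, recurrent ASCVD 1.0. The optional
"≥50% reduction" component of the high/very-high goals is deliberately not
applied; goal checks are pure thresholds.

* **Step 1 (statin intensification).** Eligible: on a statin below the
  highest available dose *of the currently prescribed agent* and not on
  ezetimibe (no agent switching). The untreated LDL-C is back-calculated
  deterministically from the current regimen's mean expected reduction
  (components multiply on the residual: `1−(1−r_statin)(1−r_eze)`), then
  the top-dose reduction is *sampled* and applied to the untreated value.
  Ineligible patients carry their observed value forward. Note an internal
  tension in the source descriptions of step 1: the figure footnote scopes
  eligibility by "highest available dose of the current statin", the text
  by statin *intensity class*. We follow the dose reading, so a patient on
  atorvastatin 40 mg (already high-intensity) still up-titrates to 80 mg.
* **Step 2 (ezetimibe).** Patients not at goal and not already on
  ezetimibe multiply their current LDL-C by `(1 − r_eze)`; patients already
  on ezetimibe carry over unchanged.
* **Step 3 (PCSK9 inhibitor).** Only very-high-risk patients (established
  ASCVD or very-high primary prevention). Drug chosen uniformly between
  alirocumab and evolocumab; sampled reduction applied multiplicatively.
* **Combined scenario.** Statin up-titration and ezetimibe are applied as
  one step to every patient not already on ezetimibe, then the PCSK9 step.
  Because reductions compose multiplicatively, a patient not at goal after
  stepwise step 1 ends the combined step at exactly the stepwise step-2
  value (an identity we test). The reported "extra ezetimibe" count is the
  number of very-high-risk patients who attain goal at stepwise step 1
  while not on ezetimibe — exactly those who would have stopped before
  receiving it.

Ezetimibe-monotherapy patients are never given a statin at step 1 (the
algorithm up-titrates, it does not initiate statins); they pass unchanged
to the PCSK9 step if eligible.

## Treatment effects

Per-replicate percent reductions are drawn from normal distributions
truncated to **[2%, 98%] on the value scale** (not percentile trimming; the
bounds live on the same percent scale as the reductions). Sampling is by
inverse CDF, so one uniform is consumed per draw regardless of parameters,
and `sd = 0` degenerates cleanly to the clamped mean (used by the
brute-force oracle tests).

Default efficacy table (mean % reduction, SD 7 for statins):
atorvastatin 10/20/40/80 mg → 37/43/49/55; rosuvastatin 5/10/20/40 mg →
38/43/48/53; simvastatin 10/20/40 mg → 27/32/37; pravastatin 10/20/40 mg →
20/24/29; ezetimibe +22 (SD 8); alirocumab +56, evolocumab +60 (SD 13).
Values follow published dose-response meta-analyses (≈6 percentage points
per dose doubling); intensity labels use the conventional <30 / 30–49 /
≥50% classes. Everything is config data (`lipidsim dump-config`).

## Risk equations

* **Primary prevention:** SCORE fatal-CVD risk, the published two-cause
  Weibull form — per cause `1 − (S0(age+10)/S0(age))^exp(w)` with
  `S0(a) = exp(−exp(α)(a−20)^p)` and
  `w = β_chol(TC−6) + β_SBP(SBP−120) + β_smoke·smoker` — summed over
  coronary and non-coronary causes, by sex and region class (low/high-risk
  Europe). Ages below 20 are clamped to 20 (the equation's support).
  Fatal→total conversion multiplies by 3 (men) / 4 (women), capped at 1.
  A TC/HDL-ratio cholesterol term is available behind a config switch.
* **Established ASCVD:** a 20-month next-event model of Cox relative-risk
  form, `1 − S0^exp(lp − lp_offset)`, over age, sex, smoking, diabetes,
  BMI, number of vascular beds, event-in-past-year, CHF, AF, statin and
  aspirin use, and region. The original coefficient table is not
  reproduced in our sources, so the shipped defaults are calibrated values
  following the published model's covariate structure and hazard-ratio
  magnitudes (baseline 20-month survival 0.925 at the reference linear
  predictor 2.47, giving cohort-mean 10-year risk near 40%); they are
  plain config data and should be replaced by users with access to the
  published coefficients. Horizon conversion assumes a constant event
  rate: `1 − (1 − r_20m)^(120/20)`.
* **Risk reduction:** one rate-ratio draw per patient × replicate,
  independent of the treatment-effect draws, from a log-normal whose
  median is 0.78 and whose 2.5th/97.5th percentiles hit the 0.76–0.80 CI.
  `ΔLDL-C` is the **observed** baseline minus the final simulated value
  (not the back-calculated untreated value), floored at 0 for tail draws;
  `RRR = 1 − rr^Δ`, `residual = baseline(1 − RRR)`, `ARR = baseline −
  residual` (conserving `residual + ARR = baseline` to machine precision).

## Synthetic cohort

The default cohort reproduces the published structure of the 2,482
above-goal patients: six strata (low 55, moderate 424, high 409, very-high
74; ASCVD non-recurrent 1,470, recurrent 50) with the published sex, age,
smoking, comorbidity and vascular-bed marginals, and baseline LDL-C
~N(3.1, 0.8²) without ASCVD / N(2.3, 0.8²) with ASCVD, **left-truncated at
each patient's goal** so the inclusion criterion (above goal) holds by
construction — truncation rather than rejection keeps generation O(n) with
the same marginal law.

The baseline regimen mixture uses the published overall figures: statin
use 98.5% (the residual 1.5% is ezetimibe monotherapy; the printed count
n = 1448 is arithmetically inconsistent with its own percentage and is
ignored in favour of the percentage), intensity split 4.8/57.9/35.5%
low/moderate/high overall with the printed per-group high-intensity shares
(23.1% without vs 43.4% with ASCVD), and ~10% any-ezetimibe in both
groups. Agent-and-dose composition within an intensity class, and the
per-stratum treatment cross-tabulation, are not published at that
granularity; the defaults weight atorvastatin/rosuvastatin most heavily in
the moderate class, which is what makes large step-1 jumps (top dose =
high intensity) possible for most patients.

Covariates never reported at patient level (SBP, BMI, HDL-C, total
cholesterol, aspirin, event-in-past-year, region class) are drawn from
plausible clipped-normal/Bernoulli defaults per stratum; they feed only
the risk equations, never the goal logic, and are user-overridable.
Comorbidities are sampled independently within a stratum (only marginals
are published). ASCVD patients with no vascular bed drawn are assigned one
by normalised marginal weight, guaranteeing ≥1 bed.

What the generator does **not** emulate: joint comorbidity correlations,
within-stratum LDL/treatment dependence (in reality, intensively treated
patients have different residual LDL-C), country effects, and the real
study's covariate-conditional risk distribution. Consequently the
simulation recovers the published *qualitative pattern* (attainment
roughly doubling with ezetimibe, ~90% attainment at step 3 for very-high
risk, ASCVD RRR in the 15–35% range) but not the exact printed
percentages; step-1/step-2 attainment runs a few points lower and the
recurrent stratum (n = 50, goal <1.0 mmol/L, identical LDL distribution to
the other ASCVD stratum by construction) attains ~73% at step 3 versus the
published 84.6%.

## Randomness and reproducibility

One master seed drives everything. Cohort synthesis consumes the child
seed-sequence `(0,)` (one grandchild per stratum); replicate `k` of a
simulation consumes `(1, k)`. Replicates are therefore independent of
execution order, cohorts are reusable across simulation runs, and a given
(seed, replicate) pair always yields the same draws — the engine draws
fixed-order patient-indexed vectors per step (statin, ezetimibe, drug
choice, PCSK9, rate ratio). Two runs from the same manifest produce
byte-identical CSVs.

## Reporting conventions

Attainment is cumulative ("at goal by step s") and summarised as mean/SD
of the per-replicate proportions; LDL-C and risk quantities are pooled
over all patient × replicate values (2,482 × 1,000 = 2,482,000 at the
default sizes). Step-3 columns are reported only for groups wholly
PCSK9-eligible (very-high, the ASCVD strata and their CAD/PAD/CeVD
subgroups) and are NaN elsewhere. Printed proportions use half-up rounding
to one decimal, which reproduces every published count/percentage pair we
test. Default problem sizes — 2,482 patients, 1,000 replicates — run in
seconds; tests use smaller replicate counts where the quantity under test
stabilises earlier.

## Known limitations

* REACH-style coefficients are calibrated stand-ins (see above), so
  absolute ASCVD risk levels are indicative, not validated.
* SCORE is the pre-2021 equation by design; SCORE2/SCORE2-OP are out of
  scope.
* Maximum *tolerated* dose is assumed equal to maximum available dose;
  statin intolerance and adherence are not modelled.
* The ≥50%-reduction goal component, agent switching at step 1, and statin
  initiation for ezetimibe-monotherapy patients are intentionally absent,
  matching the simulated algorithm rather than the full guideline text.
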