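# Methods

## The study design being modeled

The default design is an eight-cohort, first-in-human escalation of a
long-half-life biologic in healthy volunteers. A single-ascending-dose part
(cohorts A–E: 30-, 90-, 300-mg SC; 300-, 750-mg IV, dosed on Day 1, PK
sampled on Days 1, 2, 5, 8, 15, 29, 43, 57 and 85, ADA on Days 1, 29, 57,
85) is followed by a multiple-ascending-dose part (cohorts F–H: 150-, 300-,
600-mg SC every 4 weeks × 3, Days 1/29/57; PK on Days 1, 5, 8, 15, 29, 43,
57, 61, 71, 85, 113, 141; ADA on Days 1, 29, 43, 57, 113, 141). Every cohort
allocates 6 active : 2 placebo by permuted blocks; an optional ninth cohort
(600-mg SC, 12:4) models a terminated patient cohort. Randomization uses one
block per cohort equal to the full cohort size, so the allocation ratio is
exact at completion; the source study does not state a block size, and
smaller blocks are supported when they hold the reduced ratio exactly.

## PK simulation model

One compartment, first-order SC absorption, linear elimination; repeated
doses by superposition. This is the simplest model consistent with the
linear, approximately dose-proportional, IgG-like kinetics the analyses
assume. Defaults (units in parentheses):

| parameter | default | why |
|---|---|---|
| CL (L/day) | 0.2 | typical IgG clearance; reproduces reported apparent clearance ≈ 0.20–0.27 L/day |
| V (L) | 7.0 | plasma-like distribution volume; with CL gives t½ ≈ 24 d (reported cohort means 16.4–27.6 d) |
| ka (1/day) | 0.5 | places the SC peak near day 6 (reported medians 5–7 d) |
| F_abs | 0.9 | reported SC CL/F ≈ IV CL and a GM-AUC bioavailability ratio of ~1.09 imply near-complete absorption |
| sigma_prop | 0.20 | proportional residual CV, typical of ligand-binding assays |
| omega_cl / omega_v / omega_ka | 0.25 / 0.15 / 0.25 | between-subject log-SDs giving the reported 10–60% CV range |

IV infusions default to 1 h; the simulator adds an end-of-infusion PK sample
for IV cohorts, since that is where the observed peak lies (reported IV tmax
medians of 0.02–0.05 day correspond to the end of a 30–75-min infusion,
which is never stated explicitly). When `ka` equals `k = CL/V` the analytic
limiting form `F·D·ka·t/V·e^(−k·t)` replaces the two-exponential solution.

Residual noise is log-normal with `s = sqrt(ln(1 + CV²))` so that the
multiplicative CV equals `sigma_prop`. BLQ censoring sets values strictly
below 140 ng/mL to zero and flags them; values exactly at the limit are
quantifiable.

Seeding: one master seed; each subject's streams (arm, PK variability, PK
noise, ADA, biomarker, safety) derive from a CRC32 hash of the subject id
plus a stream tag, so adding or removing a subject never perturbs any other
subject's data and regeneration is bit-for-bit reproducible.

An allometric body-weight hook was considered and left out: the analyses
downstream never use weight-adjusted PK, and the source summaries report no
weight dependence to calibrate against.

## ADA scenarios and classification

The generator emits scripted scenarios (`never`, `induced_transient`,
`induced_persistent`, `enhanced`, `baseline_positive_stable`) whose
construction forces the classifier's verdict, so generator and classifier
can be cross-validated exactly on noiseless data. Default per-arm scenario
mixes put single-dose treated incidence near one half and multiple-dose
treated incidence near saturation — the qualitative pattern the modeled
study reported — with placebo positivity around 10–20% as rare borderline
low-titer signals.

Classification rules (titers are log-type "titer units", handled
additively):

- *treatment-induced*: baseline negative or missing, ≥ 1 positive
  postbaseline sample;
- *treatment-enhanced*: baseline positive and some postbaseline titer
  ≥ baseline + 0.60, threshold inclusive ("at least");
- *persistent*: positive at the last postbaseline sampling timepoint, or
  first-to-last positive span ≥ 112 days (16 weeks on study-day
  arithmetic); *transient* otherwise. A transient call therefore requires a
  negative final sample; this is implied but not spelled out by the usual
  wording, and the truth-table test pins the behavior.
- A baseline-positive subject without a qualifying rise is ADA-negative for
  incidence (treatment-unaffected).
- Subjects without any postbaseline sample are not evaluable and drop out of
  the incidence denominator; subjects without a baseline sample drop out of
  the prevalence denominator only.

## NCA conventions

- Default AUC method is linear-up/log-down (dominant practice for biologics;
  the plain linear rule is retained behind a flag). The log trapezoid uses
  `Δt·(C1−C2)/(ln C1 − ln C2)` on strictly decreasing positive segments.
- BLQ handling: leading BLQ values enter as zeros at their times; embedded
  BLQ values are dropped from integration (standard NCA-software
  convention); the AUC terminates at the last quantifiable concentration.
  BLQ values never enter the λz fit.
- λz window selection: all suffixes of quantifiable points strictly after
  the peak (the peak itself excluded) with ≥ 3 points; best adjusted R²
  wins; ties within 1e-4 go to the window with more points. Nonnegative
  slopes are rejected; a profile still rising at its last sample reports
  "nonnegative terminal slope".
- Validity: a fit whose selected window spans less than `2·t½` is reported
  but flagged invalid, and half-life-dependent summaries drop it with the
  reduced `n` annotated — the same exclusion behavior the modeled study's
  footnotes describe.
- Units: doses convert mg → ng so `dose/AUC` emerges in mL/day and is
  reported in L/day; all times are in days.
- Undefined parameters propagate as NaN plus a text reason, never
  exceptions.
- Multiple-dose subjects contribute a Day-1 profile (samples up to the
  second dose) and a final-dose profile (samples from the last dose,
  re-referenced to it). The final-dose AUC0-t is computed to the last
  sample as defined; a dosing-interval AUC can be obtained by truncating
  the input series to the interval.
- Geometric CV% is `100·sqrt(exp(s²)−1)` with `s` the SD of log values;
  because it is not stated which scale the reported "Mean (CV%)" rows for
  kel/t½/CL use, summaries emit both geometric and arithmetic statistics.

A deliberate consequence of mirroring the reported summaries: a
bioavailability computed from geometric-mean AUCs of small independent
groups can exceed 1 at equal doses (the reported ratio is ≈ 1.09); the
implementation reproduces this summary-level artifact rather than
"correcting" it.

## Biomarker engagement

Total IL-17AA/IL-17FF rise after dosing because antibody capture extends the
cytokine's half-life; the generator uses
`baseline + Emax·C/(C50 + C)` with log-normal noise (Emax 40 / 25 pg/mL,
C50 5000 ng/mL, noise log-SD 0.2 — chosen so that placebo subjects are
essentially never flagged, matching the qualitative observation that placebo
levels did not rise). Baselines fall below the MQC for 80% of subjects. BLQ
values are analyzed and plotted at MQC/2 (4 and 3 pg/mL). The elevation
criterion — peak ≥ max(2 × baseline, baseline + MQC) — is an extrinsic
design choice (the underlying observation is qualitative), is configurable,
and is recorded in the output metadata. The dose-trend statistic is a
Spearman correlation between dose and cohort-median peak with a seeded
subject-permutation p-value (10,000 permutations by default).

## Safety rules

TEAE: onset on/after the first dose and within the study window (the
observation end is configurable; the source does not define it). DLAE:
related, clinically significant Grade ≥ 2 TEAE with onset within 14 days of
dosing, any allergic/hypersensitivity reaction, or ANC < 1000 cells/μL.
"Clinically significant" and relatedness are explicit input fields — they
encode investigator judgment that cannot be derived — and the generator sets
them. Hy's law uses the standard numeric rule (ALT or AST ≥ 3×ULN with
bilirubin ≥ 2×ULN within 14 days); eosinophilia is Grade ≥ 2 strictly above
1500 cells/μL with the remaining ladder boundaries configurable. AE coding
uses a small fixed preferred-term → SOC map rather than a full regulatory
dictionary.

## What the synthetic data does and does not emulate

The generator reproduces the *statistical structure* the analyses assume:
allocation ratios, sampling calendars, censoring limits, log-normal PK
variability, scenario-driven ADA patterns, saturating biomarker response,
and sparse AE/lab streams. It does not emulate assay drift, drug
interference in the ADA assay, target-mediated disposition, ADA-mediated
clearance changes, or correlated dropout — so passing tests demonstrate the
correctness of the analysis engines under the stated model, not robustness
to every feature of real bioanalytical data.

## Problem sizes and numerical checks

The test suite and the acceptance script run the full eight-cohort design
(64 subjects), a 27-point (CL, V, ka) noiseless recovery grid at 0.25-day
sampling over ten half-lives (recovery within 1%), and 200 noisy replicates
on the sparse single-dose calendar (median clearance error ≈ 6% at 20%
proportional noise). Closed-form oracles: `AUC0-∞ = F·D/CL`, SC peak time
`ln(ka/k)/(ka−k)`, and the three-dose bolus accumulation ratio
`(1 − 2⁻³)/(1 − 2⁻¹) = 1.75` at τ = t½.

## Known limitations

- One-compartment kinetics cannot produce the early distribution phase of a
  real IV profile; IV λz estimates are correspondingly clean.
- The λz tie-break (1e-4 adjusted-R² tolerance) follows common software
  convention but is not the only defensible rule.
- Incidence denominators follow the evaluability rule above; source
  denominators driven by unexplained sample-availability details are
  reproduced through the count-level fixtures, not derived.
- The permutation dose-trend test conditions on cohort sizes and ignores
  any within-cohort correlation structure.
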