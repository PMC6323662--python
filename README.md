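# sadmad

Simulation and analysis of phase-1 **single and multiple ascending-dose
(SAD/MAD)** trials of long-half-life biologics, built around the analytical
machinery of a first-in-human study of an IgG4 bispecific antibody: synthetic
trial generation, non-compartmental pharmacokinetics (NCA), anti-drug-antibody
(ADA) immunogenicity classification, total-target biomarker engagement
summaries, and rule-based safety adjudication.

It is written for trial statisticians, pharmacometricians and methods
developers who need a fully reproducible, end-to-end testbed for these
analyses when the underlying subject-level clinical data cannot be shared.

## What it computes

**Synthetic trial** (`sadmad.simulate`). Permuted-block randomization per
cohort (6:2 active:placebo by default); serum concentrations from a
one-compartment model with first-order subcutaneous absorption and linear
elimination, superposed over repeated doses:

- SC: `C(t) = F·D·ka / (V·(ka − k)) · (e^(−k·t) − e^(−ka·t))`, `k = CL/V`
- IV: zero-order infusion followed by mono-exponential decline

with log-normal between-subject variability and proportional residual error;
BLQ censoring at the assay LLOQ (140 ng/mL); scripted ADA titer scenarios;
a saturating total-target biomarker response; adverse-event and laboratory
streams with injectable edge cases.

**NCA** (`sadmad.nca`). Cmax/tmax (earliest tie), linear-up/log-down or
linear trapezoidal AUC to the last quantifiable concentration, terminal
slope λz by best adjusted R² over suffix windows (peak excluded),
`t½ = ln 2/λz`, `AUC0-∞ = AUC0-t + Clast/λz`, `CL/F = D/AUC0-∞`,
`V/F = CL/F/λz`, accumulation ratio `Rac(Cmax) = Cmax(last dose)/Cmax(dose 1)`,
bioavailability `F = GM(AUC0-∞, SC)/GM(AUC0-∞, IV)` at matched dose,
geometric-mean/CV% summaries, and a power-model dose-proportionality fit
`ln(param) = a + b·ln(dose)`. Fits whose terminal window spans less than
`2·t½` are flagged invalid and excluded from half-life-dependent summaries.

**Immunogenicity** (`sadmad.immunogenicity`). Treatment-induced
(baseline-negative/missing with a positive postbaseline sample) vs
treatment-enhanced (baseline-positive with a rise ≥ 0.60 titer units,
inclusive); transient vs persistent (positive at the final timepoint, or a
first-to-last positive span ≥ 16 weeks = 112 days); prevalence/incidence
with explicit denominators; ADA-stratified PK overlays.

**Biomarker** (`sadmad.biomarker`). BLQ imputation at half the minimum
quantifiable concentration (MQC/2: 4 pg/mL for IL-17AA, 3 pg/mL for
IL-17FF), per-subject engagement flags, and a permutation-tested dose trend.

**Safety** (`sadmad.safety`). TEAE tabulation by SOC/preferred term with
subject-level counting; DLAE, AESI (Hy's law, injection-site ≥ Grade 2,
infection ≥ Grade 3, hypersensitivity) and eosinophilia (> 1500 cells/μL ⇒
Grade ≥ 2) rules.

## Worked example

```python
from sadmad import simulate_trial, nca_subject_table, nca_summary_table
from sadmad.design import default_study_design

ds = simulate_trial(default_study_design(), seed=1)
nca = nca_subject_table(ds.pk_conc, ds.dosing, ds.subjects)
summary = nca_summary_table(nca)
cohort_a = summary[(summary.cohort == "A") & summary.parameter.isin(
    ["cmax_ng_ml", "auc_0_inf", "t_half_day", "cl_over_f_l_day"])]
print(cohort_a[["parameter", "n", "geometric_mean", "cv_pct", "arithmetic_mean"]]
      .round(3).to_string(index=False))
```

prints

```
      parameter  n  geometric_mean  cv_pct  arithmetic_mean
     cmax_ng_ml  6        3248.359  24.672         3332.309
      auc_0_inf  3      148949.484  48.062       159024.585
     t_half_day  3          23.909  42.879           25.861
cl_over_f_l_day  3           0.201  46.877            0.216
```

— the 30-mg SC cohort's geometric-mean Cmax (~3.2 μg/mL), AUC0-∞
(~1.5·10⁵ day·ng/mL), half-life (~24 days) and apparent clearance
(~0.2 L/day), all on the scale expected for an IgG-like antibody. `n = 3`
for the half-life-dependent rows because the other subjects' terminal
windows failed the `2·t½` span rule and were excluded, with the reason
recorded per subject.

The immunogenicity engine run on the count-level reference fixture:

```python
from sadmad.immunogenicity import classification_table, compute_prevalence_incidence
from sadmad.reference import build_part_a_ada_timelines

cls = classification_table(build_part_a_ada_timelines())
inc = compute_prevalence_incidence(cls, arm="active")
# treated incidence: 53.3% (16 of 30); baseline prevalence: 7.7% (3 of 39)
```

A full pipeline run (simulate → NCA → ADA → biomarker → safety → report):

```sh
sadmad all --seed 1 --out trial_run
```

writes the dataset CSVs, `nca_subject.csv` / `nca_summary.csv`,
`ada_class.csv` / `ada_summary.csv`, `engagement.csv`, `teae_table.csv` /
`safety_flags.csv`, plots, a plain-text report and a hash manifest; reruns
with the same seed are byte-identical.

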