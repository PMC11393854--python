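# cmmc — circulating multiple myeloma cell enumeration dynamics

Circulating multiple myeloma cells (CMMCs) are clonal plasma cells detected
in peripheral blood (CD138+/CD38+/DAPI+/CD19−/CD45−), counted as an absolute
number per 4 mL. Because a blood draw can be repeated every few months where
a bone-marrow aspirate cannot, the *trajectory* of CMMC counts under therapy
is a candidate minimally invasive marker of disease dynamics in multiple
myeloma (MM) and its asymptomatic precursor, smouldering MM (SMM).

This package implements, as a tested and reusable library, the full analysis
pipeline for such longitudinal enumeration data:

- **Cohort I/O** — validated CSV schemas for patients, longitudinal
  enumerations with biochemical markers, bone-marrow MRD measurements, and
  arm-level single-cell / bulk copy-number tables.
- **coMMstant classification** — the binary trajectory index: 1 for patients
  whose CMMCs stay detectable (count ≥ 1) at every usable on-treatment
  enumeration, 0 otherwise; patients with < 2 usable enumerations are
  indeterminate. Baseline stratification at the cohort median (ties go high)
  and conversion of absolute counts to flow-cytometry-equivalent percentages
  via calibration pairs.
- **Association statistics** — pairwise Pearson/Spearman correlation
  matrices with pairwise-complete deletion, Kruskal–Wallis, Fisher exact
  (two-sided probability-mass rule), and the longitudinal model: a Gaussian
  linear mixed model of log(count + 1) on the biomarker panel
  (β2-microglobulin, albumin, κ/λ ratio, LDH, M-protein, total protein) with
  a per-patient random intercept, reporting multiplicative effects exp(β).
- **MRD concordance** — milestone-based pairing of marrow MRD with
  contemporaneous blood enumerations, hemodilution-aware exclusion, and
  detectability agreement.
- **Survival** — Kaplan–Meier curves, log-rank tests and Cox hazard ratios
  between coMMstant (or any binary) groups, via lifelines with Efron ties.
- **Single-cell CNA clonality** — per-cell vs bulk comparison: clonal
  (fraction ≥ 0.89) / subclonal / rare (≤ 2 cells or ≤ 0.11) calls, emerging
  alterations (absent from the diagnostic bulk profile), and main-ploidy
  summaries.
- **Synthetic cohort generator** — zero-inflated negative-binomial counts on
  a log-linear mean (multiplicative β2M effect, per-phase treatment
  reduction, patient random intercept), two latent trajectory classes,
  exponential proportional-hazards PFS/OS with class hazard ratios, MRD
  detectability coupled to the true count, and constructive single-cell
  experiments — all carrying ground-truth labels for validation.

## Worked example

```python
from cmmc import baseline_counts, stratify_by_baseline_median
from cmmc.commstant import flow_equivalent_percentage
from cmmc.datasets import FLOW_CALIBRATION_PAIRS, smm_cohort

cohort = smm_cohort()                       # 7 untreated SMM patients
high, low, median = stratify_by_baseline_median(baseline_counts(cohort))
print(median, len(high), len(low))
print(flow_equivalent_percentage(349, FLOW_CALIBRATION_PAIRS))
```

prints

```
327.0 4 3
0.02
```

— the baseline (earliest-enumeration) median of the SMM cohort is 327
CMMCs/4 mL, splitting the seven patients 4 high / 3 low (the patient exactly
at the median counts as high), and an absolute count of 349 corresponds to
0.02% by flow cytometry, a commonly used prognostic cut-off.

End-to-end on synthetic data (`python examples/06_survival_by_trajectory.py`):

```
PFS: HR = 4.61 (95% CI 3.46-6.14, truth 4.554), log-rank p = 3e-30
OS: HR = 7.50 (95% CI 5.15-10.90, truth 7.805), log-rank p = 7.7e-35
```

— classifying 500 simulated patients with the coMMstant rule and fitting Cox
models recovers the generator's true class hazard ratios.

The `examples/` directory holds one short script per capability; the `cmmc`
command-line tool (`cmmc simulate`, `cmmc classify`, `cmmc survival`,
`cmmc cna`, `cmmc run --config run.yaml`, …) wraps the same functions for
shell use. See `docs/methods.md` for models, parameter conventions and
limitations.

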