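# Methods

## The quantity being analysed

A CMMC enumeration is an absolute count of clonal plasma cells per 4 mL of
peripheral blood. Counts are non-negative integers, heavily overdispersed
(diagnosis values span 1 to tens of thousands) and, under therapy, dominated
by zeros. All longitudinal analysis is phase-driven: each enumeration
carries a treatment phase label (diagnosis, untreated_followup, induction,
consolidation, maintenance, progression), and analysis windows select
phases rather than clock times, because cohorts mix time-from-diagnosis and
time-from-treatment conventions. SMM rows keep time from diagnosis; when an
SMM patient progresses, progression-phase rows are re-anchored onto the same
per-patient clock so times stay strictly increasing.

## coMMstant trajectory classification

The index summarises whether a patient keeps releasing CMMCs under therapy.
Within the window (default phases: induction, consolidation, maintenance):

- **1** — at least two usable enumerations, every count ≥ 1;
- **0** — at least two usable enumerations, some count = 0;
- **indeterminate** — fewer than two usable enumerations; these patients are
  excluded from all group comparisons, and the exclusion count is reported.

Two published phrasings of the zero rule conflict: "consistently ≥ 1"
(any zero anywhere gives 0) versus "a zero within the first two
enumerations". Both are implemented (`rule="all_positive"`, the default,
and `rule="first_two"`); neither is guessed to be the intended one. A
series positive at the first two enumerations but zero later is 0 under the
default rule and 1 under the alternative.

Baseline stratification uses each patient's earliest enumeration,
regardless of phase. The split point is the sample median (mean of central
order statistics for even n) and a count exactly at the median joins the
high group — the convention that makes a 7-patient cohort with median 327
split 4/3 when 327 is itself a baseline value.

Flow equivalence: given calibration pairs (count_i, percent_i) measured on
the same samples by both assays, a count c maps to
mean_i(percent_i · c / count_i), rounded to two decimals. The conversion is
linear in c before rounding.

## Association statistics

Correlation matrices use pairwise-complete deletion; cells with fewer than
three complete pairs, or a constant variable, are flagged missing rather
than raising. Pearson p-values come from the t transform of r; Spearman
p-values use the t approximation for n > 10 and exact permutation
(full enumeration of pairings, batched) for n ≤ 10. Kruskal–Wallis uses
mid-ranks with tie correction and a chi-squared reference; all-tied input
returns H = 0, p = 1 by convention. The Fisher exact test is two-sided by
the probability-mass rule (sum of hypergeometric probabilities not
exceeding the observed table's, relative tolerance 1e-7); tests verify it
against brute-force enumeration for every table with N ≤ 40. No
multiple-testing correction is applied anywhere; all reports print raw
p-values and say so.

## Longitudinal count–biomarker model

The response is log(count + 1); the pseudo-count of 1 handles zeros and is
stated in the fit metadata. Fixed effects are the biomarker panel (default:
β2-microglobulin, albumin, κ/λ ratio, LDH, M-protein, total protein); a
per-patient random intercept absorbs intra-subject correlation. Fitting is
REML via statsmodels MixedLM; rows with any missing predictor are dropped
listwise, constant predictors are dropped with a flag. Reported quantities:
coefficients, multiplicative effects exp(β), random-intercept and residual
variances, and the median scaled residual (a location check on the fit). A
fixed-effects-only OLS fit is always attached for comparison; on REML
non-convergence it is returned as the flagged fallback. A count-likelihood
(generalized linear mixed) model is deliberately out of scope: the
reference analysis this reproduces is a Gaussian model on the transformed
response.

## MRD pairing and concordance

MRD milestones pair by phase window: post_induction with the patient's last
induction-phase enumeration, pre_maintenance with the last
consolidation-phase enumeration. A numeric fallback window
(`window_months`) exists but is off by default — milestones, not clock
distances, define contemporaneity. An undetectable MRD on a hemodiluted
aspirate is a possible false negative: the pair is kept but flagged
excluded, and never enters the concordance summary. Every MRD record is
exactly one of paired, excluded, or unpaired (conservation is tested).
CMMC detectability is count ≥ 1 per 4 mL — the assay's own unit; no volume
rescaling is attempted. Concordance is the fraction of usable pairs with
matching detectability. Per-patient MRD positivity (any detectable usable
measurement) is cross-tabulated against the coMMstant index with the Fisher
test; a degenerate margin (all patients positive or all negative) flags the
odds ratio as undefined instead of raising.

## Survival

Kaplan–Meier, log-rank and Cox are delegated to lifelines. Cox uses Efron
tie handling — months-resolution follow-up guarantees ties, and Efron is
the lower-bias standard choice — with Wald 95% intervals. Zero events in
one group makes the partial likelihood monotone; the estimate is returned
flagged with the CI bound at 0/infinity rather than crashing. Median
survival is the first time with S(t) ≤ 0.5 and is undefined when the curve
never reaches 0.5. Only unadjusted two-group contrasts are in scope.

## Single-cell copy-number clonality

Resolution is fixed at chromosome arms; focal/sub-arm events are out of
scope. States are del/neutral/gain/amp per (chrom, arm); amp and gain are
distinct states but one identity direction ("gain") for alteration calls,
del maps to "loss". Clonality categories generalise a 19-cell convention:
rare ⇔ n_cells ≤ 2 or fraction ≤ 0.11; clonal ⇔ fraction ≥ 0.89; subclonal
otherwise (the boundary between rare and subclonal is closed at 0.11 and
open above). An alteration is emerging when the bulk diagnostic profile
lacks it — neutral there or the opposite direction; opposite directions on
one arm are distinct events, which is how a bulk "mixed" signal decomposes
at single-cell level. Bulk-vs-cells overlap is Jaccard over (arm,
direction) sets, with the cell side restricted to majority calls
(fraction ≥ 0.5), since bulk reflects dominant clones. Main ploidy is the
mode of per-cell ploidies rounded to integers, ties broken toward the lower
ploidy with a tie flag.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions under
which every downstream stage is validated, and its defaults are frozen.

**Counts.** Given patient i at timepoint k with concurrent β2M b_ik,
phase index k and random intercept u_i ~ N(0, intercept_sd²):

    log mu_ik = baseline_log_mean + log(beta2m_effect) · (b_ik − 3.5)
                + treatment_log_reduction · k + u_i

and counts are negative binomial with mean mu_ik and size
count_dispersion. The 3.5 mg/L reference is the ISS I/II boundary, so
baseline_log_mean (default log 349, a typical diagnosis median) is the log
count of a reference-level patient at diagnosis. Defaults:
beta2m_effect = 5.5, treatment_log_reduction = −0.5 per phase step,
count_dispersion = 2 (strong overdispersion), intercept_sd = 0.6.

**Classes.** A fraction frac_persistent (default 0.375) of MM patients is
*persistent*: their post-baseline counts are floored at 1 (the class is
defined by continued detectability, so the floor is class semantics, not
noise). *Clearing* patients draw structural zeros at post-baseline
timepoints with probability clearance_prob (default 0.9); the zero
inflation is the device that realises the two trajectory classes. A
noise-free mode (deterministic_counts = True, typically with
clearance_prob = 1) replaces sampling by count = round(mu), making the
latent class exactly recoverable by the classifier — the basis of the
exactness check.

**Biomarkers.** No published marginal distributions exist for the panel;
each patient has a latent severity s_i ~ N(0,1) with fixed loadings chosen
as conventions: positive for β2M, CRP, M-protein, κ/λ ratio, BM plasma-cell
percentage; negative for albumin. β2M declines under therapy (more steeply
in the clearing class), M-protein and the κ/λ ratio decay geometrically
under treatment.

**Survival.** PFS and OS are exponential proportional hazards:
baseline_hazard_pfs = 0.02/month and baseline_hazard_os = 0.008/month for
clearing patients, multiplied by hr_pfs = 4.554 and hr_os = 7.805 for the
persistent class; administrative censoring at 18 months. The two endpoints
are *comonotone* — one uniform per patient inverted through both hazards —
which preserves each marginal exponential PH law exactly while guaranteeing
PFS ≤ OS (the OS hazard never exceeds the PFS hazard at these defaults) and
inducing realistic positive dependence between the endpoints.

**MRD.** Each MM patient gets measurements at the two milestones (when the
matching phase was sampled). Detectability is logistic in the concurrent
count, logit p = −1.2 + 1.1·log(1 + count); detected values are log-normal
around 10⁻³, clipped to [sensitivity, 3.22]; hemodilution flags are
independent Bernoulli(0.25).

**Response.** Best response is drawn from per-class category probabilities
— the reduced form of a proportional-odds model — calibrated so
P(≥ VGPR) = 0.40 in the persistent class and 0.76 in the clearing class
(with ≥ CR rates 0.13 and 0.60).

**What the generator does not emulate:** circadian oscillation of cell
release, informative censoring, dropout and irregular visit schedules,
measurement error in the biomarkers' co-timing, or any genomic sequence
process. Passing recovery tests therefore show the estimators are correct
under the stated model, not that real cohorts satisfy that model.

## Validation conditions and problem sizes

Parameter-recovery checks run 100 seeded replicates: Cox hazard ratios on
cohorts of 500 patients (median estimate within 10% of the true 4.554 /
7.805), and the longitudinal β2M effect on cohorts of 200 patients (median
multiplicative effect within 15% of 5.5). The mixed-model check is the
wider band because the fitted Gaussian-on-log model is a working
approximation to the generating zero-inflated negative binomial: structural
zeros at low β2M steepen, and the log(count+1) floor at small counts
flattens, the estimated slope — the two biases largely offset at the
default conditions but do not cancel exactly. The random-intercept variance
check uses an inflation-free, low-dispersion configuration where the
intercept is the only between-patient term, recovering intercept_sd² within
20%. Oracle-equivalence checks are exhaustive (Fisher vs hypergeometric
enumeration for all tables with N ≤ 40) or exact (Kaplan–Meier vs the
empirical survivor function on uncensored data; mixed-model β vs OLS β when
the variance component collapses to zero).

## Numerical conventions and degenerate inputs

Empty cells are the only missing-value representation in CSVs; thousands
separators are rejected by construction. Validation errors name the row and
column. Classification of degenerate series never raises (they map to
indeterminate). The pipeline expands one global seed into per-stage
SeedSequence substreams, so a run is bit-reproducible and adding a stage
does not change earlier stages' draws. Pipeline stages degrade gracefully:
a missing MRD table or single-cell input skips that stage with a logged
notice; any hard failure names the stage and keeps partial outputs.

## Known limitations

- Arm-level CNA resolution only; no inference from reads, no ploidy
  refitting.
- Survival: single binary covariate, no multivariable adjustment.
- The longitudinal model is Gaussian on a transformed count, not a count
  likelihood; its coefficients are biased for generating processes far from
  the defaults (heavier zero inflation, tiny counts throughout).
- The clonality thresholds generalise a small-cohort (n = 19) convention;
  with very large cell numbers the "≤ 2 cells" rare criterion becomes
  conservative relative to the fraction criterion.
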