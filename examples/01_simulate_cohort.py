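"""Generate a synthetic CMMC cohort and inspect its structure.

The generator produces patients (stage, response, survival), longitudinal
CMMC enumerations with biomarkers, and bone-marrow MRD measurements, plus a
ground-truth table with each patient's latent trajectory class.
"""
from cmmc import GeneratorConfig, generate_cohort

cohort, truth = generate_cohort(GeneratorConfig(n_patients=51, seed=1))

n_mm = sum(1 for p in cohort.patients if p.stage == "MM")
print(f"patients: {len(cohort.patients)} ({n_mm} MM, "
      f"{len(cohort.patients) - n_mm} SMM)")
print(f"enumerations: {len(cohort.timepoints)}, MRD records: {len(cohort.mrd)}")
mix = truth.patients[truth.patients.stage == "MM"].latent_class.value_counts()
print("latent class mix (MM):", dict(mix))
# ~37.5% of MM patients are 'persistent': their CMMCs stay detectable under
# therapy; 'clearing' patients drop to zero counts with 90% probability per
# post-baseline timepoint.

one = cohort.timepoints_of(cohort.patient_ids[0])
print("\nfirst patient's trajectory (time, phase, count, beta2m):")
for t in one:
    print(f"  {t.time_months:5.1f}  {t.phase:<13} {t.cmmc_count:>6}  {t.beta2m}")
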