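"""Compare survival between coMMstant groups: KM medians, log-rank, Cox HR.

Generated at the default conditions: true PFS hazard ratio 4.554 and OS
hazard ratio 7.805 for the persistent class, administrative censoring at
18 months.
"""
from cmmc import GeneratorConfig, generate_cohort, cox_hr, km_estimate
from cmmc.commstant import classify_cohort

cohort, _ = generate_cohort(GeneratorConfig(n_patients=500, seed=3))
results = classify_cohort(cohort)

for endpoint, truth_hr in (("pfs", 4.554), ("os", 7.805)):
    times, events, group = [], [], []
    for pid, r in results.items():
        if r.index not in ("1", "0"):
            continue
        p = cohort.patient(pid)
        times.append(getattr(p, f"{endpoint}_months"))
        events.append(getattr(p, f"{endpoint}_event"))
        group.append(1 if r.index == "1" else 0)
    est = cox_hr(times, events, group)
    km1 = km_estimate([t for t, g in zip(times, group) if g == 1],
                      [e for e, g in zip(events, group) if g == 1])
    km0 = km_estimate([t for t, g in zip(times, group) if g == 0],
                      [e for e, g in zip(events, group) if g == 0])
    print(f"{endpoint.upper()}: HR = {est.hazard_ratio:.2f} "
          f"(95% CI {est.ci_low:.2f}-{est.ci_high:.2f}, truth {truth_hr}), "
          f"log-rank p = {est.logrank_p:.2g}")
    print(f"  median survival: index1 = {km1.median}, index0 = {km0.median} "
          "months (None = never falls below 0.5 within follow-up)")
# An HR near truth shows the classifier plus Cox model recover the simulated
# excess risk of the persistently-releasing group.
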