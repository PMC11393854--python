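"""Stratify SMM patients at the median of their baseline CMMC counts.

Uses the bundled 7-patient untreated SMM table (20 longitudinal
enumerations). The baseline is each patient's earliest enumeration; a count
equal to the median joins the high group.
"""
from cmmc import baseline_counts, stratify_by_baseline_median
from cmmc.commstant import flow_equivalent_percentage
from cmmc.datasets import FLOW_CALIBRATION_PAIRS, smm_cohort

cohort = smm_cohort()
baselines = baseline_counts(cohort)
high, low, median = stratify_by_baseline_median(baselines)

print("baseline counts:", baselines)
print(f"median = {median:g} CMMCs / 4 mL")
print(f"high group ({len(high)}):", high)
print(f"low group  ({len(low)}):", low)
# The tie-at-median patient sits in the high group, giving a 4/3 split.

pct = flow_equivalent_percentage(349, FLOW_CALIBRATION_PAIRS)
print(f"\nflow-cytometry equivalent of 349 CMMCs: {pct}%")
# 0.02% is a widely used prognostic CMMC cut-off in flow-based studies.
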