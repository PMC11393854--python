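"""Trajectory classification and baseline stratification of CMMC counts.

The coMMstant index is a binary label on a patient's on-treatment CMMC
trajectory: index 1 for patients whose circulating cells stay detectable
(count >= 1 per 4 mL) at every usable enumeration, index 0 for patients whose
cells become undetectable. Patients with fewer than two usable enumerations
are indeterminate and excluded from group comparisons.

Two published phrasings of the zero rule coexist; both are implemented:

``all_positive`` (default)
    index 1 iff every in-window count >= 1 — any zero anywhere gives 0.
``first_two``
    index 0 only when a zero occurs within the first two in-window
    enumerations; later zeros do not flip the index.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .records import TimepointRecord, ValidationError

DEFAULT_WINDOW_PHASES = frozenset({"induction", "consolidation", "maintenance"})
RULES = ("all_positive", "first_two")


@dataclass(frozen=True)
class CoMMstantResult:
    patient_id: str
    index: str  # "1", "0" or "indeterminate"
    n_enumerations_used: int
    window: tuple[tuple[str, float], ...]  # (phase, time_months) of used rows


@dataclass(frozen=True)
class CalibrationPair:
    """One sample measured both by absolute count and by flow-cytometry %."""

    count: int
    percent: float

    def __post_init__(self):
        if self.count <= 0 or self.percent <= 0:
            raise ValidationError("calibration pair requires count > 0 and percent > 0")


def classify_commstant(
    timepoints: Sequence[TimepointRecord],
    window_phases: Iterable[str] = DEFAULT_WINDOW_PHASES,
    rule: str = "all_positive",
) -> CoMMstantResult:
    """Classify one patient's trajectory from their time-ordered enumerations.

    Only rows whose phase is in ``window_phases`` are used; biomarkers and
    out-of-window rows never influence the result.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    window_phases = frozenset(window_phases)
    if not timepoints:
        return CoMMstantResult("", "indeterminate", 0, ())
    pids = {t.patient_id for t in timepoints}
    if len(pids) > 1:
        raise ValidationError(f"timepoints from multiple patients: {sorted(pids)}")
    used = sorted(
        (t for t in timepoints if t.phase in window_phases),
        key=lambda t: t.time_months,
    )
    window = tuple((t.phase, t.time_months) for t in used)
    pid = timepoints[0].patient_id
    if len(used) < 2:
        return CoMMstantResult(pid, "indeterminate", len(used), window)
    counts = [t.cmmc_count for t in used]
    if rule == "all_positive":
        index = "1" if min(counts) >= 1 else "0"
    else:  # first_two
        index = "0" if 0 in counts[:2] else "1"
    return CoMMstantResult(pid, index, len(used), window)


def classify_cohort(
    cohort,
    window_phases: Iterable[str] = DEFAULT_WINDOW_PHASES,
    rule: str = "all_positive",
) -> dict[str, CoMMstantResult]:
    """coMMstant result per patient of a cohort (keyed by patient_id)."""
    return {
        pid: classify_commstant(cohort.timepoints_of(pid), window_phases, rule)
        for pid in cohort.patient_ids
    }


def stratify_by_baseline_median(
    baselines: Mapping[str, int],
) -> tuple[list[str], list[str], float]:
    """Split patients at the sample median of their baseline counts.

    Baseline = the patient's earliest enumeration. The median is the sample
    median (mean of the two central order statistics for even n). A count
    equal to the median goes to the high group.

    Returns (high_ids, low_ids, median), each id list sorted.
    """
    if not baselines:
        raise ValidationError("no baseline counts supplied")
    values = sorted(baselines.values())
    n = len(values)
    if n % 2:
        median = float(values[n // 2])
    else:
        median = (values[n // 2 - 1] + values[n // 2]) / 2.0
    high = sorted(pid for pid, c in baselines.items() if c >= median)
    low = sorted(pid for pid, c in baselines.items() if c < median)
    return high, low, median


def baseline_counts(cohort) -> dict[str, int]:
    """Earliest enumeration per patient, regardless of phase label."""
    out: dict[str, int] = {}
    for pid in cohort.patient_ids:
        tps = cohort.timepoints_of(pid)
        if tps:
            out[pid] = min(tps, key=lambda t: t.time_months).cmmc_count
    return out


def stratify_by_threshold_ever(
    cohort, threshold: float
) -> tuple[list[str], list[str]]:
    """Alternative stratifier: high = any enumeration strictly above threshold.

    The baseline-median split is primary; this variant classifies a patient
    high if their count exceeds ``threshold`` at least once over the whole
    disease course.
    """
    high, low = [], []
    for pid in cohort.patient_ids:
        tps = cohort.timepoints_of(pid)
        if not tps:
            continue
        (high if any(t.cmmc_count > threshold for t in tps) else low).append(pid)
    return sorted(high), sorted(low)


def flow_equivalent_percentage(
    count: int, pairs: Sequence[CalibrationPair]
) -> float:
    """Convert an absolute CMMC count to a flow-cytometry-equivalent percentage.

    Each calibration pair scales proportionally (percent_i * count / count_i);
    the estimates are averaged and rounded to two decimals. Linear in
    ``count`` before rounding.
    """
    if not pairs:
        raise ValidationError("at least one calibration pair is required")
    if count < 0:
        raise ValidationError("count must be >= 0")
    est = sum(p.percent * count / p.count for p in pairs) / len(pairs)
    return round(est, 2)
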