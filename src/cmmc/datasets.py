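"""Small published summary tables bundled for worked examples and checks.

These are desk-scale inputs printed in the study report this package
operationalises: the SMM longitudinal enumeration table, the three
CELLSEARCH-count / flow-cytometry-percentage calibration pairs, and the
per-patient single-cell recovery/QC yields.
"""
from __future__ import annotations

from .commstant import CalibrationPair
from .records import Cohort, PatientRecord, TimepointRecord

# (patient_id, disease phase at sampling, printed months, CMMC count per 4 mL).
# Progression ("MM") rows restart the printed clock at progression; the loader
# re-anchors them to max(SMM time) + printed + 1 so each patient keeps a single
# strictly increasing time axis (analysis windows are driven by phase, not time).
SMM_TABLE = [
    ("AIRC19_001", "SMM", 17, 22),
    ("AIRC19_001", "SMM", 21, 2),
    ("AIRC19_001", "SMM", 38, 52),
    ("AIRC19_021", "SMM", 2, 52),
    ("AIRC19_021", "SMM", 7, 159),
    ("AIRC19_021", "SMM", 13, 49),
    ("AIRC19_021", "SMM", 26, 138),
    ("AIRC19_075", "SMM", 8, 344),
    ("AIRC19_075", "SMM", 12, 656),
    ("AIRC19_075", "SMM", 16, 371),
    ("AIRC19_013", "SMM", 12, 24),
    ("AIRC19_013", "SMM", 23, 100),
    ("AIRC19_013", "MM", 1, 0),
    ("AIRC19_051", "SMM", 1, 976),
    ("AIRC19_051", "MM", 0, 960),
    ("AIRC19_054", "SMM", 1, 327),
    ("AIRC19_054", "MM", 0, 38),
    ("AIRC19_055", "SMM", 4, 2463),
    ("AIRC19_055", "SMM", 11, 390),
    ("AIRC19_055", "MM", 0, 619),
]

#: CELLSEARCH absolute count <-> flow-cytometry CMMC percentage, same samples
FLOW_CALIBRATION_PAIRS = [
    CalibrationPair(count=39940, percent=2.5),
    CalibrationPair(count=18588, percent=0.98),
    CalibrationPair(count=316, percent=0.019),
]

#: per-patient single-cell workup yields:
#: enumerated CMMCs, recovered single cells, cells passing WGA+sequencing QC,
#: cells with an aberrant copy-number profile
SINGLE_CELL_YIELDS = {
    "CMMC1": {"enumerated": 15, "recovered": 5, "qc_passed": 5, "aberrant": 3},
    "CMMC2": {"enumerated": 16, "recovered": 2, "qc_passed": 2, "aberrant": 2},
    "CMMC3": {"enumerated": 32, "recovered": 10, "qc_passed": 6, "aberrant": 6},
    "CMMC4": {"enumerated": 62, "recovered": 23, "qc_passed": 19, "aberrant": 19},
}


def smm_cohort() -> Cohort:
    """The 7-patient untreated SMM cohort (20 longitudinal enumerations)."""
    patient_ids: list[str] = []
    for pid, *_ in SMM_TABLE:
        if pid not in patient_ids:
            patient_ids.append(pid)
    timepoints = []
    for pid in patient_ids:
        rows = [r for r in SMM_TABLE if r[0] == pid]
        max_smm = max(t for _, ph, t, _ in rows if ph == "SMM")
        for _, disease_phase, months, count in rows:
            if disease_phase == "SMM":
                phase, t = "untreated_followup", float(months)
            else:
                phase, t = "progression", float(max_smm + months + 1)
            timepoints.append(
                TimepointRecord(
                    patient_id=pid, time_months=t, phase=phase, cmmc_count=count
                )
            )
    patients = [PatientRecord(patient_id=pid, stage="SMM") for pid in patient_ids]
    return Cohort(patients=patients, timepoints=timepoints)


def single_cell_redetection_rate() -> tuple[float, int, int]:
    """Overall redetection rate: recovered single cells over enumerated CMMCs.

    Returns (percentage, n_recovered, n_enumerated).
    """
    rec = sum(y["recovered"] for y in SINGLE_CELL_YIELDS.values())
    enum_ = sum(y["enumerated"] for y in SINGLE_CELL_YIELDS.values())
    return 100.0 * rec / enum_, rec, enum_


def aberrant_profile_rate() -> tuple[float, int, int]:
    """Fraction of QC-passing single cells with an aberrant CN profile.

    Returns (percentage, n_aberrant, n_qc_passed).
    """
    ab = sum(y["aberrant"] for y in SINGLE_CELL_YIELDS.values())
    qc = sum(y["qc_passed"] for y in SINGLE_CELL_YIELDS.values())
    return 100.0 * ab / qc, ab, qc
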