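import pytest

from cmmc.records import Cohort, MRDRecord, PatientRecord, TimepointRecord


def make_patient(pid="P1", stage="MM", **kw):
    return PatientRecord(patient_id=pid, stage=stage, **kw)


def make_tp(pid="P1", t=0.0, phase="induction", count=1, **kw):
    return TimepointRecord(
        patient_id=pid, time_months=t, phase=phase, cmmc_count=count, **kw
    )


@pytest.fixture
def small_cohort():
    """Two MM patients: one persistently detectable, one clearing; with MRD."""
    patients = [
        make_patient("P1", pfs_months=6.0, pfs_event=True, os_months=10.0,
                     os_event=True, best_response="PR"),
        make_patient("P2", pfs_months=18.0, pfs_event=False, os_months=18.0,
                     os_event=False, best_response="CR"),
    ]
    timepoints = [
        make_tp("P1", 0.0, "diagnosis", 250, beta2m=5.0),
        make_tp("P1", 3.0, "induction", 40, beta2m=4.2),
        make_tp("P1", 6.0, "consolidation", 12, beta2m=3.9),
        make_tp("P2", 0.0, "diagnosis", 400, beta2m=4.0),
        make_tp("P2", 3.0, "induction", 0, beta2m=2.5),
        make_tp("P2", 6.0, "consolidation", 0, beta2m=2.1),
    ]
    mrd = [
        MRDRecord("P1", "post_induction", 2e-3, True),
        MRDRecord("P1", "pre_maintenance", 1e-4, True),
        MRDRecord("P2", "post_induction", 0.0, False),
        MRDRecord("P2", "pre_maintenance", 0.0, False, hemodiluted=True),
    ]
    return Cohort(patients=patients, timepoints=timepoints, mrd=mrd)
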