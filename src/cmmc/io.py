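"""CSV readers/writers for cohort and copy-number tables.

Dialect: comma separator, period decimal mark, UTF-8, header row with exact
field names, empty cell = missing (never "NA" strings or thousands
separators). Readers validate on load and report the offending row.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional

from .records import (
    ARMS,
    BIOMARKERS,
    BulkProfile,
    CellProfile,
    CHROMS,
    Cohort,
    FormatError,
    MRDRecord,
    PatientRecord,
    ReferentialError,
    TimepointRecord,
    ValidationError,
)

PATIENT_COLUMNS = (
    "patient_id", "stage", "age_years", "sex", "iss", "r_iss", "best_response",
    "pfs_months", "pfs_event", "os_months", "os_event",
)
TIMEPOINT_COLUMNS = ("patient_id", "time_months", "phase", "cmmc_count") + BIOMARKERS
MRD_COLUMNS = (
    "patient_id", "timepoint", "mrd_value", "detectable", "hemodiluted", "sensitivity",
)
CELL_COLUMNS = ("cell_id", "patient_id", "chrom", "arm", "state", "ploidy")
BULK_COLUMNS = ("patient_id", "chrom", "arm", "state", "tumor_fraction", "ploidy")

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _opt(value: str) -> Optional[str]:
    return None if value is None or value.strip() == "" else value.strip()


def _opt_float(value: str, col: str, row: int) -> Optional[float]:
    v = _opt(value)
    if v is None:
        return None
    try:
        return float(v)
    except ValueError:
        raise FormatError(f"row {row}: column {col!r}: not a number: {v!r}") from None


def _opt_int(value: str, col: str, row: int) -> Optional[int]:
    v = _opt_float(value, col, row)
    if v is None:
        return None
    if not float(v).is_integer():
        raise ValidationError(f"row {row}: column {col!r}: not an integer: {v!r}")
    return int(v)


def _opt_bool(value: str, col: str, row: int) -> Optional[bool]:
    v = _opt(value)
    if v is None:
        return None
    low = v.lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise FormatError(f"row {row}: column {col!r}: not a boolean: {v!r}")


def _read_rows(path: Path, required: tuple[str, ...]) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s): {missing}")
        return list(reader)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float) and float(value).is_integer():
        return str(int(value))
    return str(value)


def read_cohort(
    patients_path, timepoints_path, mrd_path=None, strict: bool = True
) -> Cohort:
    """Read and validate the three cohort CSVs.

    Parameters
    ----------
    patients_path, timepoints_path : path
        Mandatory patient and enumeration tables.
    mrd_path : path, optional
        Bone-marrow MRD table; omit for cohorts without MRD monitoring.
    strict : bool
        If True (default) abort on the first invalid row; if False, collect
        all row errors and raise one combined error at the end.
    """
    errors: list[str] = []

    def handle(exc: Exception) -> None:
        if strict:
            raise exc
        errors.append(str(exc))

    patients: list[PatientRecord] = []
    for i, row in enumerate(_read_rows(Path(patients_path), PATIENT_COLUMNS), start=2):
        try:
            patients.append(
                PatientRecord(
                    patient_id=(_opt(row["patient_id"]) or ""),
                    stage=(_opt(row["stage"]) or ""),
                    age_years=_opt_int(row["age_years"], "age_years", i),
                    sex=_opt(row["sex"]),
                    iss=_opt(row["iss"]),
                    r_iss=_opt(row["r_iss"]),
                    best_response=_opt(row["best_response"]),
                    pfs_months=_opt_float(row["pfs_months"], "pfs_months", i),
                    pfs_event=_opt_bool(row["pfs_event"], "pfs_event", i),
                    os_months=_opt_float(row["os_months"], "os_months", i),
                    os_event=_opt_bool(row["os_event"], "os_event", i),
                )
            )
        except ValueError as exc:
            handle(type(exc)(f"{patients_path}: row {i}: {exc}"))

    timepoints: list[TimepointRecord] = []
    for i, row in enumerate(_read_rows(Path(timepoints_path), TIMEPOINT_COLUMNS), start=2):
        try:
            kwargs = {
                m: _opt_float(row[m], m, i) for m in BIOMARKERS
            }
            count = _opt_float(row["cmmc_count"], "cmmc_count", i)
            timepoints.append(
                TimepointRecord(
                    patient_id=(_opt(row["patient_id"]) or ""),
                    time_months=_opt_float(row["time_months"], "time_months", i),
                    phase=(_opt(row["phase"]) or ""),
                    cmmc_count=count,
                    **kwargs,
                )
            )
        except ValueError as exc:
            handle(type(exc)(f"{timepoints_path}: row {i}: {exc}"))

    mrd: list[MRDRecord] = []
    if mrd_path is not None:
        for i, row in enumerate(_read_rows(Path(mrd_path), MRD_COLUMNS), start=2):
            try:
                mrd.append(
                    MRDRecord(
                        patient_id=(_opt(row["patient_id"]) or ""),
                        timepoint=(_opt(row["timepoint"]) or ""),
                        mrd_value=_opt_float(row["mrd_value"], "mrd_value", i),
                        detectable=_opt_bool(row["detectable"], "detectable", i),
                        hemodiluted=_opt_bool(row["hemodiluted"], "hemodiluted", i)
                        or False,
                        sensitivity=_opt_float(row["sensitivity"], "sensitivity", i)
                        or 1e-5,
                    )
                )
            except ValueError as exc:
                handle(type(exc)(f"{mrd_path}: row {i}: {exc}"))

    if errors:
        raise ValidationError("; ".join(errors))
    return Cohort(patients=patients, timepoints=timepoints, mrd=mrd)


def write_cohort(cohort: Cohort, directory) -> dict[str, Path]:
    """Write patients/timepoints/mrd CSVs into ``directory``; returns the paths.

    Round-trips: ``read_cohort(**write_cohort(c))`` equals ``c`` field-for-field.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients_path": directory / "patients.csv",
        "timepoints_path": directory / "timepoints.csv",
        "mrd_path": directory / "mrd.csv",
    }
    with open(paths["patients_path"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PATIENT_COLUMNS)
        for p in cohort.patients:
            w.writerow([_fmt(getattr(p, c)) for c in PATIENT_COLUMNS])
    with open(paths["timepoints_path"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(TIMEPOINT_COLUMNS)
        for t in cohort.timepoints:
            w.writerow([_fmt(getattr(t, c)) for c in TIMEPOINT_COLUMNS])
    with open(paths["mrd_path"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(MRD_COLUMNS)
        for m in cohort.mrd:
            w.writerow([_fmt(getattr(m, c)) for c in MRD_COLUMNS])
    return paths


def read_cna_tables(cells_path, bulk_path) -> tuple[list[CellProfile], BulkProfile]:
    """Read per-cell and bulk arm-level copy-number CSVs.

    The cell table holds one row per (cell, chrom, arm) explicit state plus a
    per-cell ploidy column (repeated across that cell's rows); unlisted arms
    are neutral. The bulk table holds the diagnostic sample's states with its
    tumor_fraction and ploidy repeated per row.
    """
    cells_rows = _read_rows(Path(cells_path), CELL_COLUMNS)
    bulk_rows = _read_rows(Path(bulk_path), BULK_COLUMNS)

    by_cell: dict[str, CellProfile] = {}
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(cells_rows, start=2):
        cell_id = _opt(row["cell_id"]) or ""
        patient_id = _opt(row["patient_id"]) or ""
        chrom, arm = _opt(row["chrom"]) or "", _opt(row["arm"]) or ""
        state = _opt(row["state"]) or ""
        if chrom not in CHROMS or arm not in ARMS:
            raise FormatError(f"{cells_path}: row {i}: unknown region ({chrom}, {arm})")
        if state not in ("del", "neutral", "gain", "amp"):
            raise FormatError(
                f"{cells_path}: row {i}: unknown state token {state!r} "
                "(expected del/neutral/gain/amp)"
            )
        key = (cell_id, chrom, arm)
        if key in seen:
            raise ValidationError(
                f"{cells_path}: row {i}: duplicate (cell, arm) entry {key}"
            )
        seen.add(key)
        ploidy = _opt_float(row["ploidy"], "ploidy", i)
        prof = by_cell.get(cell_id)
        if prof is None:
            prof = CellProfile(
                cell_id=cell_id,
                patient_id=patient_id,
                states={},
                ploidy=ploidy if ploidy is not None else 2.0,
            )
            by_cell[cell_id] = prof
        prof.states[(chrom, arm)] = state

    if not bulk_rows:
        raise FormatError(f"{bulk_path}: empty bulk table")
    bulk_states: dict[tuple[str, str], str] = {}
    pid = tf = ploidy = None
    for i, row in enumerate(bulk_rows, start=2):
        pid = _opt(row["patient_id"]) or pid
        chrom, arm = _opt(row["chrom"]) or "", _opt(row["arm"]) or ""
        state = _opt(row["state"]) or ""
        if chrom not in CHROMS or arm not in ARMS:
            raise FormatError(f"{bulk_path}: row {i}: unknown region ({chrom}, {arm})")
        if state not in ("del", "neutral", "gain", "amp"):
            raise FormatError(f"{bulk_path}: row {i}: unknown state token {state!r}")
        if (chrom, arm) in bulk_states:
            raise ValidationError(f"{bulk_path}: row {i}: duplicate arm ({chrom}, {arm})")
        bulk_states[(chrom, arm)] = state
        tf = _opt_float(row["tumor_fraction"], "tumor_fraction", i) or tf
        ploidy = _opt_float(row["ploidy"], "ploidy", i) or ploidy
    bulk = BulkProfile(
        patient_id=pid or "",
        states=bulk_states,
        tumor_fraction=tf if tf is not None else 1.0,
        ploidy=ploidy if ploidy is not None else 2.0,
    )
    cells = sorted(by_cell.values(), key=lambda c: c.cell_id)
    return cells, bulk


def write_cna_tables(
    cells: list[CellProfile], bulk: BulkProfile, directory
) -> dict[str, Path]:
    """Write per-cell and bulk arm-level CSVs (inverse of read_cna_tables)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"cells_path": directory / "cells.csv", "bulk_path": directory / "bulk.csv"}
    with open(paths["cells_path"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CELL_COLUMNS)
        for cell in cells:
            for (chrom, arm), state in sorted(cell.states.items()):
                w.writerow([cell.cell_id, cell.patient_id, chrom, arm, state,
                            _fmt(cell.ploidy)])
    with open(paths["bulk_path"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(BULK_COLUMNS)
        for (chrom, arm), state in sorted(bulk.states.items()):
            w.writerow([bulk.patient_id, chrom, arm, state,
                        _fmt(bulk.tumor_fraction), _fmt(bulk.ploidy)])
    return paths
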