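"""Core record types for CMMC cohort analysis.

A cohort is a set of patients (stage, staging systems, response, survival),
their longitudinal CMMC enumerations with co-measured biochemical markers,
and optional bone-marrow MRD measurements. Single-cell copy-number data are
held separately as per-cell and bulk arm-level profiles.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

STAGES = ("SMM", "MM")
SEXES = ("F", "M")
ISS_STAGES = ("I", "II", "III")
RESPONSES = ("CR", "VGPR", "PR", "MR", "SD", "PD")
PHASES = (
    "diagnosis",
    "untreated_followup",
    "induction",
    "consolidation",
    "maintenance",
    "progression",
)
MRD_TIMEPOINTS = ("post_induction", "pre_maintenance")
CN_STATES = ("del", "neutral", "gain", "amp")
CHROMS = tuple(str(c) for c in range(1, 23)) + ("X", "Y")
ARMS = ("p", "q")

#: ordered from best to worst; ">= VGPR" means index <= RESPONSES.index("VGPR")
RESPONSE_ORDER = {r: i for i, r in enumerate(RESPONSES)}


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class FormatError(ValueError):
    """A file or table does not follow the expected schema/dialect."""


class ReferentialError(ValueError):
    """A child record references a patient_id absent from the patient table."""


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    if isinstance(x, str) and x.strip() == "":
        return True
    return False


@dataclass(frozen=True)
class PatientRecord:
    """One patient: disease stage, staging, best response and survival endpoints."""

    patient_id: str
    stage: str
    age_years: Optional[int] = None
    sex: Optional[str] = None
    iss: Optional[str] = None
    r_iss: Optional[str] = None
    best_response: Optional[str] = None
    pfs_months: Optional[float] = None
    pfs_event: Optional[bool] = None
    os_months: Optional[float] = None
    os_event: Optional[bool] = None

    def __post_init__(self):
        if _is_missing(self.patient_id):
            raise ValidationError("patient_id must not be missing")
        if self.stage not in STAGES:
            raise ValidationError(
                f"patient {self.patient_id}: stage {self.stage!r} not in {STAGES}"
            )
        for name, val, domain in (
            ("sex", self.sex, SEXES),
            ("iss", self.iss, ISS_STAGES),
            ("r_iss", self.r_iss, ISS_STAGES),
            ("best_response", self.best_response, RESPONSES),
        ):
            if val is not None and val not in domain:
                raise ValidationError(
                    f"patient {self.patient_id}: {name} {val!r} not in {domain}"
                )
        for name, val in (("pfs_months", self.pfs_months), ("os_months", self.os_months)):
            if val is not None and val < 0:
                raise ValidationError(f"patient {self.patient_id}: {name} < 0")
        if (
            self.pfs_months is not None
            and self.os_months is not None
            and self.pfs_months > self.os_months + 1e-9
        ):
            raise ValidationError(
                f"patient {self.patient_id}: pfs_months > os_months"
            )


#: biomarker columns of a timepoint row, in file order
BIOMARKERS = (
    "beta2m",
    "albumin",
    "calcium",
    "crp",
    "ldh",
    "m_protein",
    "kappa_lambda_ratio",
    "total_protein",
    "bm_pc_percent",
)


@dataclass(frozen=True)
class TimepointRecord:
    """One CMMC enumeration (absolute count per 4 mL PB) with co-measured markers."""

    patient_id: str
    time_months: float
    phase: str
    cmmc_count: int
    beta2m: Optional[float] = None
    albumin: Optional[float] = None
    calcium: Optional[float] = None
    crp: Optional[float] = None
    ldh: Optional[float] = None
    m_protein: Optional[float] = None
    kappa_lambda_ratio: Optional[float] = None
    total_protein: Optional[float] = None
    bm_pc_percent: Optional[float] = None

    def __post_init__(self):
        if _is_missing(self.patient_id):
            raise ValidationError("patient_id must not be missing")
        if self.phase not in PHASES:
            raise ValidationError(
                f"patient {self.patient_id}: phase {self.phase!r} not in {PHASES}"
            )
        if self.time_months is None or self.time_months < 0:
            raise ValidationError(
                f"patient {self.patient_id}: time_months must be a non-negative number"
            )
        c = self.cmmc_count
        if c is None or (isinstance(c, float) and not float(c).is_integer()) or int(c) < 0:
            raise ValidationError(
                f"patient {self.patient_id}: cmmc_count must be an integer >= 0, got {c!r}"
            )
        object.__setattr__(self, "cmmc_count", int(c))


@dataclass(frozen=True)
class MRDRecord:
    """One bone-marrow MRD measurement (NGS clonal-cell fraction).

    ``detectable`` follows the assay call at the stated sensitivity;
    ``hemodiluted`` flags peripheral-blood contamination of the aspirate, which
    invalidates an *undetectable* result (flagged for exclusion downstream, the
    record itself is kept).
    """

    patient_id: str
    timepoint: str
    mrd_value: float
    detectable: bool
    hemodiluted: bool = False
    sensitivity: float = 1e-5

    def __post_init__(self):
        if _is_missing(self.patient_id):
            raise ValidationError("patient_id must not be missing")
        if self.timepoint not in MRD_TIMEPOINTS:
            raise ValidationError(
                f"patient {self.patient_id}: mrd timepoint {self.timepoint!r} "
                f"not in {MRD_TIMEPOINTS}"
            )
        if self.mrd_value < 0:
            raise ValidationError(f"patient {self.patient_id}: mrd_value < 0")
        if self.detectable and self.mrd_value < self.sensitivity:
            raise ValidationError(
                f"patient {self.patient_id}: detectable MRD below sensitivity "
                f"{self.sensitivity:g}"
            )

    @property
    def excluded_hemodilution(self) -> bool:
        """Undetectable result on a hemodiluted aspirate: not interpretable."""
        return self.hemodiluted and not self.detectable


@dataclass
class Cohort:
    """Validated container: patients plus their longitudinal and MRD records."""

    patients: list[PatientRecord] = field(default_factory=list)
    timepoints: list[TimepointRecord] = field(default_factory=list)
    mrd: list[MRDRecord] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id(s): {dup}")
        known = set(ids)
        for kind, rows in (("timepoint", self.timepoints), ("mrd", self.mrd)):
            orphans = sorted({r.patient_id for r in rows} - known)
            if orphans:
                raise ReferentialError(
                    f"{kind} rows reference unknown patient_id(s): {orphans}"
                )
        seen: set[tuple[str, float]] = set()
        for tp in self.timepoints:
            key = (tp.patient_id, tp.time_months)
            if key in seen:
                raise ValidationError(
                    f"duplicated (patient_id, time_months) = {key}"
                )
            seen.add(key)
        self.timepoints.sort(key=lambda t: (t.patient_id, t.time_months))
        self.patients.sort(key=lambda p: p.patient_id)
        self.mrd.sort(key=lambda m: (m.patient_id, m.timepoint))

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def timepoints_of(self, patient_id: str) -> list[TimepointRecord]:
        return [t for t in self.timepoints if t.patient_id == patient_id]

    def mrd_of(self, patient_id: str) -> list[MRDRecord]:
        return [m for m in self.mrd if m.patient_id == patient_id]

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]


@dataclass
class CellProfile:
    """Arm-level copy-number states of one single cell.

    ``states`` maps (chrom, arm) -> one of del/neutral/gain/amp; arms not
    listed are neutral. ``ploidy`` is the fitted overall copy number.
    """

    cell_id: str
    patient_id: str
    states: dict[tuple[str, str], str] = field(default_factory=dict)
    ploidy: float = 2.0

    def __post_init__(self):
        if self.ploidy <= 0:
            raise ValidationError(f"cell {self.cell_id}: ploidy must be > 0")
        for (chrom, arm), state in self.states.items():
            if chrom not in CHROMS or arm not in ARMS:
                raise ValidationError(
                    f"cell {self.cell_id}: unknown region ({chrom}, {arm})"
                )
            if state not in CN_STATES:
                raise FormatError(
                    f"cell {self.cell_id}: unknown state token {state!r} "
                    f"(expected one of {CN_STATES})"
                )

    def state(self, chrom: str, arm: str) -> str:
        return self.states.get((chrom, arm), "neutral")


@dataclass
class BulkProfile:
    """Arm-level copy-number profile of the diagnostic bulk CD138+ sample."""

    patient_id: str
    states: dict[tuple[str, str], str] = field(default_factory=dict)
    tumor_fraction: float = 1.0
    ploidy: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValidationError("tumor_fraction must be in [0, 1]")
        if self.ploidy <= 0:
            raise ValidationError("ploidy must be > 0")
        for (chrom, arm), state in self.states.items():
            if chrom not in CHROMS or arm not in ARMS:
                raise ValidationError(f"bulk: unknown region ({chrom}, {arm})")
            if state not in CN_STATES:
                raise FormatError(f"bulk: unknown state token {state!r}")

    def state(self, chrom: str, arm: str) -> str:
        return self.states.get((chrom, arm), "neutral")

    def alterations(self) -> set[tuple[str, str, str]]:
        """Altered (chrom, arm, direction) with amp/gain collapsed to 'gain',
        del to 'loss'."""
        out = set()
        for (chrom, arm), state in self.states.items():
            if state in ("gain", "amp"):
                out.add((chrom, arm, "gain"))
            elif state == "del":
                out.add((chrom, arm, "loss"))
        return out
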