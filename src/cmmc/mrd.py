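"""Pairing of bone-marrow MRD measurements with contemporaneous CMMC counts.

Each MRD measurement is taken at a named treatment milestone
(post_induction or pre_maintenance) and is paired with the patient's CMMC
enumeration from the matching phase window: post_induction pairs with the
last induction-phase enumeration, pre_maintenance with the last
consolidation-phase enumeration. An undetectable MRD on a hemodiluted
aspirate is uninterpretable (possible false negative) and is flagged
excluded; it never enters the concordance summary. Every MRD record ends up
exactly one of paired, excluded, or unpaired (remainder report).

CMMC detectability is count >= 1 per 4 mL, the assay's unit of detection.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .commstant import CoMMstantResult
from .records import Cohort, MRDRecord, ValidationError
from .stats import fisher_exact_2x2

#: MRD milestone -> enumeration phase whose last row is the contemporaneous count
PHASE_WINDOW = {"post_induction": "induction", "pre_maintenance": "consolidation"}


@dataclass(frozen=True)
class PairedMeasurement:
    patient_id: str
    timepoint: str
    mrd_detectable: bool
    cmmc_detectable: bool
    mrd_value: float
    cmmc_count: int
    excluded_hemodilution: bool

    @property
    def concordant(self) -> bool:
        return self.mrd_detectable == self.cmmc_detectable


@dataclass
class PairingResult:
    pairs: list[PairedMeasurement]
    unpaired: list[MRDRecord]  # remainder report: no matching enumeration

    @property
    def usable(self) -> list[PairedMeasurement]:
        return [p for p in self.pairs if not p.excluded_hemodilution]


@dataclass
class ConcordanceSummary:
    n_pairs: int
    n_concordant: int
    fraction_concordant: float
    table: tuple[tuple[int, int], tuple[int, int]]
    """2x2 counts: rows MRD (detectable, undetectable) x cols CMMC
    (detectable, undetectable)."""


def pair_measurements(
    cohort: Cohort, window_months: Optional[float] = None
) -> PairingResult:
    """Pair every MRD record with its milestone-matched CMMC enumeration.

    With ``window_months`` set, an MRD record whose milestone phase has no
    enumeration instead pairs with the enumeration closest in time among the
    patient's rows within that many months of the milestone window's rows —
    disabled by default (pairing is by phase label).
    """
    pairs: list[PairedMeasurement] = []
    unpaired: list[MRDRecord] = []
    for m in cohort.mrd:
        tps = cohort.timepoints_of(m.patient_id)
        phase = PHASE_WINDOW[m.timepoint]
        in_window = [t for t in tps if t.phase == phase]
        match = max(in_window, key=lambda t: t.time_months) if in_window else None
        if match is None and window_months is not None and tps:
            on_treatment = [
                t for t in tps if t.phase in ("induction", "consolidation", "maintenance")
            ]
            if on_treatment:
                ref = max(t.time_months for t in on_treatment)
                near = [t for t in tps if abs(t.time_months - ref) <= window_months]
                match = max(near, key=lambda t: t.time_months) if near else None
        if match is None:
            unpaired.append(m)
            continue
        pairs.append(
            PairedMeasurement(
                patient_id=m.patient_id,
                timepoint=m.timepoint,
                mrd_detectable=m.detectable,
                cmmc_detectable=match.cmmc_count >= 1,
                mrd_value=m.mrd_value,
                cmmc_count=match.cmmc_count,
                excluded_hemodilution=m.excluded_hemodilution,
            )
        )
    return PairingResult(pairs=pairs, unpaired=unpaired)


def concordance(pairs: Sequence[PairedMeasurement]) -> ConcordanceSummary:
    """Detectability agreement over non-excluded pairs.

    Concordant = both detectable or both undetectable.
    """
    usable = [p for p in pairs if not p.excluded_hemodilution]
    if not usable:
        raise ValidationError("no usable (non-excluded) pairs")
    cells = [[0, 0], [0, 0]]
    for p in usable:
        cells[0 if p.mrd_detectable else 1][0 if p.cmmc_detectable else 1] += 1
    n = len(usable)
    n_conc = cells[0][0] + cells[1][1]
    return ConcordanceSummary(
        n_pairs=n,
        n_concordant=n_conc,
        fraction_concordant=n_conc / n,
        table=(tuple(cells[0]), tuple(cells[1])),
    )


def crosstab_commstant_mrd(
    results: dict[str, CoMMstantResult], pairs: Sequence[PairedMeasurement]
) -> dict:
    """Cross-tabulate coMMstant index against per-patient MRD positivity.

    A patient is MRD-positive if any of their non-excluded paired MRD
    measurements is detectable. Patients without a classified index (1/0) or
    without usable MRD pairs are omitted. Returns the 2x2 table
    (rows: index 1, 0; cols: MRD+, MRD-), the per-group positivity fractions
    and the Fisher exact result (odds ratio flagged None on a degenerate
    margin).
    """
    mrd_pos: dict[str, bool] = {}
    for p in pairs:
        if p.excluded_hemodilution:
            continue
        mrd_pos[p.patient_id] = mrd_pos.get(p.patient_id, False) or p.mrd_detectable
    table = [[0, 0], [0, 0]]
    for pid, res in results.items():
        if res.index not in ("1", "0") or pid not in mrd_pos:
            continue
        row = 0 if res.index == "1" else 1
        col = 0 if mrd_pos[pid] else 1
        table[row][col] += 1
    n1 = sum(table[0])
    n0 = sum(table[1])
    if n1 == 0 or n0 == 0:
        raise ValidationError("empty intersection of classified and MRD-measured patients")
    out = {
        "table": (tuple(table[0]), tuple(table[1])),
        "fraction_positive_index1": table[0][0] / n1,
        "fraction_positive_index0": table[1][0] / n0,
        "odds_ratio": None,
        "p_value": None,
        "degenerate_margin": False,
    }
    col_sums = (table[0][0] + table[1][0], table[0][1] + table[1][1])
    if 0 in col_sums:
        out["degenerate_margin"] = True  # all patients MRD+ or all MRD-: OR undefined
        return out
    odds, p = fisher_exact_2x2(table)
    out["odds_ratio"] = odds
    out["p_value"] = p
    return out
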