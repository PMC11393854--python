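"""Single-cell arm-level copy-number clonality analysis.

Per-cell states (del/neutral/gain/amp) are collapsed to a direction per
alteration identity — gain and amp both count as "gain", del as "loss" —
so an alteration is a (chrom, arm, direction) triple. Calls are classified
by the fraction of cells carrying them:

- rare:      at most 2 cells, or fraction <= 0.11
- clonal:    fraction >= 0.89
- subclonal: everything in between

An alteration is *emerging* when it is absent from the diagnostic bulk
profile (neutral there, or the opposite direction — opposite directions on
the same arm are genuinely distinct events, the bulk "mixed event"
signature). The bulk comparison uses majority calls (fraction >= 0.5) as the
cell-side set, since the bulk profile reflects dominant clones.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .records import BulkProfile, CellProfile, ValidationError

RARE_MAX_CELLS = 2
RARE_MAX_FRACTION = 0.11
CLONAL_MIN_FRACTION = 0.89


@dataclass(frozen=True)
class AlterationCall:
    alteration: tuple[str, str, str]  # (chrom, arm, direction in {gain, loss})
    n_cells: int
    n_total: int
    category: Optional[str] = None  # clonal | subclonal | rare
    emerging: Optional[bool] = None

    @property
    def fraction(self) -> float:
        return self.n_cells / self.n_total


def _direction(state: str) -> Optional[str]:
    if state in ("gain", "amp"):
        return "gain"
    if state == "del":
        return "loss"
    return None


def call_alterations(cells: Sequence[CellProfile]) -> list[AlterationCall]:
    """One call per (chrom, arm, direction) present in >= 1 cell."""
    if not cells:
        raise ValidationError("need >= 1 cell")
    pids = {c.patient_id for c in cells}
    if len(pids) > 1:
        raise ValidationError(f"cells from multiple patients: {sorted(pids)}")
    counts: Counter = Counter()
    for cell in cells:
        for (chrom, arm), state in cell.states.items():
            d = _direction(state)
            if d is not None:
                counts[(chrom, arm, d)] += 1
    n_total = len(cells)
    return [
        AlterationCall(alteration=alt, n_cells=n, n_total=n_total)
        for alt, n in sorted(counts.items())
    ]


def classify_clonality(
    calls: Sequence[AlterationCall], n_total: int
) -> list[AlterationCall]:
    """Attach a clonality category to each call; categories partition calls."""
    if n_total < 1:
        raise ValidationError("n_total must be >= 1")
    out = []
    for c in calls:
        frac = c.n_cells / n_total
        if c.n_cells <= RARE_MAX_CELLS or frac <= RARE_MAX_FRACTION:
            cat = "rare"
        elif frac >= CLONAL_MIN_FRACTION:
            cat = "clonal"
        else:
            cat = "subclonal"
        out.append(replace(c, n_total=n_total, category=cat))
    return out


def detect_emerging(
    calls: Sequence[AlterationCall], bulk: BulkProfile,
    patient_id: Optional[str] = None,
) -> list[AlterationCall]:
    """Flag calls absent from the bulk profile (by direction) as emerging."""
    if patient_id is not None and patient_id != bulk.patient_id:
        raise ValidationError(
            f"patient mismatch: cells {patient_id!r} vs bulk {bulk.patient_id!r}"
        )
    bulk_alts = bulk.alterations()
    return [replace(c, emerging=c.alteration not in bulk_alts) for c in calls]


@dataclass
class OverlapReport:
    shared: set[tuple[str, str, str]]
    cell_only: set[tuple[str, str, str]]
    bulk_only: set[tuple[str, str, str]]
    jaccard: float


def compare_bulk_cells(
    calls: Sequence[AlterationCall], bulk: BulkProfile,
    majority_fraction: float = 0.5,
) -> OverlapReport:
    """Set overlap between majority cell-level calls and the bulk alterations."""
    cell_set = {c.alteration for c in calls if c.fraction >= majority_fraction}
    bulk_set = bulk.alterations()
    union = cell_set | bulk_set
    shared = cell_set & bulk_set
    return OverlapReport(
        shared=shared,
        cell_only=cell_set - bulk_set,
        bulk_only=bulk_set - cell_set,
        jaccard=(len(shared) / len(union)) if union else 1.0,
    )


@dataclass
class PloidySummary:
    main_ploidy: int
    distribution: dict[int, int]  # rounded ploidy -> cell count
    tie: bool


def ploidy_summary(cells: Sequence[CellProfile]) -> PloidySummary:
    """Mode of rounded per-cell ploidies; ties break toward the lower ploidy."""
    if not cells:
        raise ValidationError("need >= 1 cell")
    rounded = [int(round(c.ploidy)) for c in cells]
    dist = dict(sorted(Counter(rounded).items()))
    top = max(dist.values())
    modes = [p for p, n in dist.items() if n == top]
    return PloidySummary(main_ploidy=min(modes), distribution=dist, tie=len(modes) > 1)


def analyze_cells(
    cells: Sequence[CellProfile], bulk: BulkProfile
) -> dict:
    """Full per-patient workup: calls with categories and emerging flags,
    bulk overlap, ploidy summary and clonality tallies."""
    calls = call_alterations(cells)
    calls = classify_clonality(calls, n_total=len(cells))
    calls = detect_emerging(calls, bulk, patient_id=cells[0].patient_id)
    tallies = Counter(c.category for c in calls)
    return {
        "calls": calls,
        "overlap": compare_bulk_cells(calls, bulk),
        "ploidy": ploidy_summary(cells),
        "clonality_tallies": dict(tallies),
        "n_emerging": sum(1 for c in calls if c.emerging),
    }
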