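"""Synthetic cohort generator with ground-truth labels.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be validated against known truth:

* two latent MM trajectory classes — *persistent* (circulating cells stay
  detectable under therapy) and *clearing* (counts drop to structural zeros
  soon after treatment starts);
* zero-inflated, overdispersed counts: negative binomial on a log-linear
  mean with a multiplicative beta-2-microglobulin effect, a per-phase
  treatment reduction and a patient random intercept; clearing-class
  patients draw structural zeros at post-baseline timepoints;
* exponential proportional-hazards PFS/OS with a class hazard ratio,
  administratively censored; the two endpoints are comonotone (one uniform
  per patient drives both), which preserves each marginal exponential PH
  distribution exactly while guaranteeing PFS <= OS;
* MRD detectability increasing in the concurrent true count;
* IMWG best response worse on average in the persistent class;
* untreated SMM patients with stable, uninflated counts and no MRD.

Identical configs (including seed) produce bit-identical cohorts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    Cohort,
    MRDRecord,
    PatientRecord,
    TimepointRecord,
    BulkProfile,
    CellProfile,
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


#: reference beta-2-microglobulin (mg/L); the ISS I/II boundary, so the
#: baseline log-mean is the log count of a patient at that marker level
B2M_REF = 3.5

#: best-response category probabilities per latent class (CR..PD), the
#: reduced form of a proportional-odds model on class: calibrated so
#: P(>=VGPR) = 0.40 for persistent and 0.76 for clearing patients
RESPONSE_PROBS = {
    "persistent": (0.1333, 0.2667, 0.35, 0.10, 0.10, 0.05),
    "clearing": (0.60, 0.16, 0.15, 0.04, 0.03, 0.02),
}
RESPONSE_LEVELS = ("CR", "VGPR", "PR", "MR", "SD", "PD")


@dataclass(frozen=True)
class GeneratorConfig:
    """All ground-truth parameters of the synthetic cohort."""

    n_patients: int = 51
    frac_mm: float = 44 / 51
    frac_persistent: float = 0.375
    n_timepoints: int = 4          # spaced 3 months
    count_dispersion: float = 2.0  # negative-binomial size
    baseline_log_mean: float = math.log(349.0)  # log count at b2m = B2M_REF
    beta2m_effect: float = 5.5     # multiplicative count change per b2m unit
    treatment_log_reduction: float = -0.5  # per phase step, <= 0
    clearance_prob: float = 0.9
    hr_pfs: float = 4.554
    hr_os: float = 7.805
    baseline_hazard_pfs: float = 0.02   # events/month, clearing class
    baseline_hazard_os: float = 0.008
    censor_horizon_months: float = 18.0
    mrd_sensitivity: float = 1e-5
    seed: int = 0
    # free structural parameters (conventions; no published marginals exist)
    intercept_sd: float = 0.6      # patient random intercept SD (log scale)
    b2m_severity_loading: float = 0.9
    b2m_noise_sd: float = 0.3
    b2m_decline_clearing: tuple[float, float] = (0.35, 0.65)  # per phase step
    b2m_decline_persistent: tuple[float, float] = (0.05, 0.25)
    hemodilution_prob: float = 0.25
    deterministic_counts: bool = False  # count = round(mu): noise-free mode

    def validate(self) -> None:
        for name in ("frac_mm", "frac_persistent", "clearance_prob",
                     "hemodilution_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("count_dispersion", "hr_pfs", "hr_os",
                     "baseline_hazard_pfs", "baseline_hazard_os"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if self.n_timepoints < 2:
            raise ConfigError("n_timepoints must be >= 2")
        if self.treatment_log_reduction > 0:
            raise ConfigError("treatment_log_reduction must be <= 0")
        if self.beta2m_effect <= 0:
            raise ConfigError("beta2m_effect must be > 0")


@dataclass
class GroundTruth:
    """True latent structure behind a generated cohort."""

    patients: pd.DataFrame       # patient_id, stage, latent_class, severity, ...
    linear_predictors: pd.DataFrame  # patient_id, time_months, eta, mu, structural_zero

    def latent_class_of(self, patient_id: str) -> str:
        row = self.patients.loc[self.patients.patient_id == patient_id]
        return str(row.latent_class.iloc[0])


#: MM phase schedule by timepoint index (3-month spacing)
def _phase_of(k: int) -> str:
    if k == 0:
        return "diagnosis"
    if k == 1:
        return "induction"
    if k == 2:
        return "consolidation"
    return "maintenance"


def _draw_count(rng, mu: float, size: float, deterministic: bool) -> int:
    if deterministic:
        return int(round(mu))
    p = size / (size + mu)
    return int(rng.negative_binomial(size, p))


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort and its ground truth from the config."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_patients
    if n == 0:
        return Cohort(), GroundTruth(
            patients=pd.DataFrame(
                columns=["patient_id", "stage", "latent_class", "severity",
                         "random_intercept", "b2m0"]
            ),
            linear_predictors=pd.DataFrame(
                columns=["patient_id", "time_months", "eta", "mu", "structural_zero"]
            ),
        )

    log_effect = math.log(config.beta2m_effect)
    n_mm = int(round(config.frac_mm * n))
    stages = ["MM"] * n_mm + ["SMM"] * (n - n_mm)

    patients: list[PatientRecord] = []
    timepoints: list[TimepointRecord] = []
    mrd_records: list[MRDRecord] = []
    truth_rows, eta_rows = [], []

    for i in range(n):
        pid = f"SYN{i + 1:04d}"
        stage = stages[i]
        severity = float(rng.normal())
        u_i = float(rng.normal(0.0, config.intercept_sd))
        persistent = bool(rng.random() < config.frac_persistent)
        latent_class = "persistent" if persistent else "clearing"
        b2m0 = max(
            0.8,
            B2M_REF
            + config.b2m_severity_loading * severity
            + float(rng.normal(0.0, config.b2m_noise_sd)),
        )
        lo, hi = (
            config.b2m_decline_persistent if persistent
            else config.b2m_decline_clearing
        )
        b2m_decline = float(rng.uniform(lo, hi))

        # correlated biomarkers: fixed loadings on latent severity
        # (positive for b2m, CRP, M-protein, kappa/lambda; negative for albumin)
        albumin0 = 4.0 - 0.35 * severity + float(rng.normal(0.0, 0.3))
        calcium0 = 9.4 + 0.5 * severity + float(rng.normal(0.0, 0.5))
        crp0 = float(np.exp(0.6 + 0.8 * severity + rng.normal(0.0, 0.4)))
        ldh0 = 200.0 + 40.0 * severity + float(rng.normal(0.0, 25.0))
        m_protein0 = max(0.0, 2.6 + 1.0 * severity + float(rng.normal(0.0, 0.7)))
        klr0 = float(np.exp(1.2 + 0.7 * severity + rng.normal(0.0, 0.5)))
        tprot0 = 7.2 + 0.6 * severity + float(rng.normal(0.0, 0.4))
        bmpc0 = float(np.clip(10.0 + 8.0 * severity + rng.normal(0.0, 4.0), 0.1, 95.0))

        own_counts: dict[float, int] = {}
        for k in range(config.n_timepoints):
            t = 3.0 * k
            if stage == "MM":
                phase = _phase_of(k)
                b2m = max(0.8, b2m0 - b2m_decline * k)
                m_protein = max(0.0, m_protein0 * (0.55 ** k))
                klr = 1.0 + (klr0 - 1.0) * (0.6 ** k)
                reduction = config.treatment_log_reduction * k
            else:
                phase = "diagnosis" if k == 0 else "untreated_followup"
                b2m = max(0.8, b2m0 + float(rng.normal(0.0, 0.15)))
                m_protein = max(0.0, m_protein0 + float(rng.normal(0.0, 0.1)))
                klr = klr0
                reduction = 0.0

            eta = (
                config.baseline_log_mean
                + log_effect * (b2m - B2M_REF)
                + reduction
                + u_i
            )
            mu = float(np.exp(eta))
            structural_zero = False
            if stage == "MM" and not persistent and k >= 1:
                structural_zero = bool(rng.random() < config.clearance_prob)
            if structural_zero:
                count = 0
            else:
                count = _draw_count(
                    rng, mu, config.count_dispersion, config.deterministic_counts
                )
                if stage == "MM" and persistent and k >= 1:
                    count = max(1, count)  # persistence floor: class semantics
            own_counts[t] = count
            timepoints.append(
                TimepointRecord(
                    patient_id=pid,
                    time_months=t,
                    phase=phase,
                    cmmc_count=count,
                    beta2m=round(b2m, 3),
                    albumin=round(albumin0 + float(rng.normal(0.0, 0.1)), 3),
                    calcium=round(calcium0 + float(rng.normal(0.0, 0.15)), 3),
                    crp=round(max(0.1, crp0 * float(np.exp(rng.normal(0.0, 0.2)))), 3),
                    ldh=round(max(50.0, ldh0 + float(rng.normal(0.0, 10.0))), 1),
                    m_protein=round(m_protein, 3),
                    kappa_lambda_ratio=round(max(0.01, klr), 3),
                    total_protein=round(tprot0 + float(rng.normal(0.0, 0.1)), 3),
                    bm_pc_percent=round(bmpc0, 2),
                )
            )
            eta_rows.append(
                {"patient_id": pid, "time_months": t, "eta": eta, "mu": mu,
                 "structural_zero": structural_zero}
            )

        # survival: comonotone exponential PH (one uniform, both endpoints)
        z = 1.0 if (stage == "MM" and persistent) else 0.0
        h_pfs = config.baseline_hazard_pfs * config.hr_pfs ** z
        h_os = config.baseline_hazard_os * config.hr_os ** z
        if stage == "SMM":
            h_pfs = config.baseline_hazard_pfs * 0.5
            h_os = config.baseline_hazard_os * 0.25
        u_surv = float(rng.uniform())
        u_surv = min(max(u_surv, 1e-12), 1 - 1e-12)
        t_pfs = -math.log(u_surv) / h_pfs
        t_os = -math.log(u_surv) / h_os
        t_os = max(t_os, t_pfs)
        horizon = config.censor_horizon_months
        pfs_event = t_pfs <= horizon
        os_event = t_os <= horizon
        pfs_months = min(t_pfs, horizon)
        os_months = min(t_os, horizon)

        if stage == "MM":
            probs = RESPONSE_PROBS[latent_class]
            best_response = str(rng.choice(RESPONSE_LEVELS, p=np.asarray(probs) /
                                           sum(probs)))
        else:
            best_response = None

        patients.append(
            PatientRecord(
                patient_id=pid,
                stage=stage,
                age_years=int(np.clip(round(61 + 6 * rng.normal()), 40, 85)),
                sex="M" if rng.random() < 0.59 else "F",
                iss=("III" if b2m0 > 5.5 else ("II" if b2m0 > 3.5 else "I")),
                r_iss=None,
                best_response=best_response,
                pfs_months=round(pfs_months, 3),
                pfs_event=bool(pfs_event),
                os_months=round(os_months, 3),
                os_event=bool(os_event),
            )
        )

        # MRD at the two milestones, when the matching phase was sampled
        if stage == "MM":
            milestones = []
            if config.n_timepoints >= 2:
                milestones.append(("post_induction", 1))
            if config.n_timepoints >= 3:
                milestones.append(("pre_maintenance", 2))
            for label, k in milestones:
                conc = own_counts[3.0 * k]
                p_det = 1.0 / (1.0 + math.exp(-(-1.2 + 1.1 * math.log1p(conc))))
                detectable = bool(rng.random() < p_det)
                if detectable:
                    value = float(
                        np.clip(10 ** rng.normal(-3.0, 1.0), config.mrd_sensitivity,
                                3.22)
                    )
                else:
                    value = 0.0
                mrd_records.append(
                    MRDRecord(
                        patient_id=pid,
                        timepoint=label,
                        mrd_value=value,
                        detectable=detectable,
                        hemodiluted=bool(rng.random() < config.hemodilution_prob),
                        sensitivity=config.mrd_sensitivity,
                    )
                )

        truth_rows.append(
            {
                "patient_id": pid,
                "stage": stage,
                "latent_class": latent_class,
                "severity": severity,
                "random_intercept": u_i,
                "b2m0": b2m0,
                "hazard_pfs": h_pfs,
                "hazard_os": h_os,
            }
        )

    cohort = Cohort(patients=patients, timepoints=timepoints, mrd=mrd_records)
    truth = GroundTruth(
        patients=pd.DataFrame(truth_rows),
        linear_predictors=pd.DataFrame(eta_rows),
    )
    return cohort, truth


@dataclass
class SingleCellTruth:
    """Construction record of a synthetic single-cell experiment."""

    subclone_of_cell: dict[str, int]  # -1 = base clone
    alteration_frequency: dict[tuple[str, str, str], int]
    emerging: set[tuple[str, str, str]]


def _parse_region(arm_label: str) -> tuple[str, str]:
    """'13q' -> ('13', 'q')."""
    chrom, arm = arm_label[:-1], arm_label[-1]
    if arm not in ("p", "q"):
        raise ConfigError(f"arm label must end in p or q: {arm_label!r}")
    return chrom, arm


def _state_of(direction: str) -> str:
    if direction == "gain":
        return "amp"
    if direction == "loss":
        return "del"
    raise ConfigError(f"direction must be gain or loss: {direction!r}")


def generate_single_cell_experiment(
    n_cells: int,
    bulk_alterations: set[tuple[str, str]],
    subclone_spec: Sequence[tuple[set[tuple[str, str]], float]] = (),
    emerging_spec: set[tuple[str, str, int]] = frozenset(),
    ploidy: float = 2.0,
    seed: int = 0,
    patient_id: str = "SYNSC01",
    tumor_fraction: float = 0.78,
) -> tuple[list[CellProfile], BulkProfile, SingleCellTruth]:
    """Construct a per-cell CNA table with known clonal structure.

    ``bulk_alterations``: {(arm_label, direction)} present in every cell and
    in the bulk profile. ``subclone_spec``: [(extra alteration set, mixing
    fraction)]; each cell is sampled from the mixture (leftover probability =
    base clone). ``emerging_spec``: {(arm_label, direction, target cell
    count)} placed in exactly that many cells, absent from the bulk.
    """
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    fractions = [f for _, f in subclone_spec]
    if any(f < 0 for f in fractions) or sum(fractions) > 1.0 + 1e-9:
        raise ConfigError("subclone mixing fractions must be >= 0 and sum <= 1")
    bulk_set = {(_parse_region(a), d) for a, d in bulk_alterations}
    emerging_set = {(_parse_region(a), d) for a, d, _ in emerging_spec}
    overlap = {(a[0] + a[1], d) for (a, d) in bulk_set & emerging_set}
    if overlap:
        raise ConfigError(f"emerging alterations overlap the bulk set: {overlap}")
    for _, _, target in emerging_spec:
        if not 0 <= target <= n_cells:
            raise ConfigError("emerging target cell count must be in [0, n_cells]")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    probs = list(fractions) + [1.0 - sum(fractions)]
    assignment = rng.choice(len(probs), size=n_cells, p=probs)

    cells: list[CellProfile] = []
    freq: dict[tuple[str, str, str], int] = {}
    subclone_of_cell: dict[str, int] = {}
    for ci in range(n_cells):
        cell_id = f"{patient_id}_c{ci + 1:03d}"
        sub = int(assignment[ci])
        subclone_of_cell[cell_id] = -1 if sub == len(subclone_spec) else sub
        states: dict[tuple[str, str], str] = {}
        alts = set(bulk_set)
        if sub < len(subclone_spec):
            alts |= {(_parse_region(a), d) for a, d in subclone_spec[sub][0]}
        for (chrom, arm), d in alts:
            states[(chrom, arm)] = _state_of(d)
            key = (chrom, arm, d)
            freq[key] = freq.get(key, 0) + 1
        cells.append(
            CellProfile(cell_id=cell_id, patient_id=patient_id, states=states,
                        ploidy=ploidy)
        )

    emerging_out: set[tuple[str, str, str]] = set()
    for arm_label, direction, target in sorted(emerging_spec):
        chrom, arm = _parse_region(arm_label)
        chosen = rng.choice(n_cells, size=target, replace=False)
        for ci in chosen:
            cells[int(ci)].states[(chrom, arm)] = _state_of(direction)
        key = (chrom, arm, direction)
        if target > 0:
            freq[key] = target
            emerging_out.add(key)

    bulk = BulkProfile(
        patient_id=patient_id,
        states={(chrom, arm): _state_of(d) for (chrom, arm), d in bulk_set},
        tumor_fraction=tumor_fraction,
        ploidy=ploidy,
    )
    truth = SingleCellTruth(
        subclone_of_cell=subclone_of_cell,
        alteration_frequency=freq,
        emerging=emerging_out,
    )
    return cells, bulk, truth
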