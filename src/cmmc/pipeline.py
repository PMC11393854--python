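"""End-to-end orchestration: simulate/load -> classify -> stats -> mrd ->
survival -> cna -> report.

One run config (YAML/JSON-compatible mapping) drives everything. The global
seed is expanded into per-stage substreams via SeedSequence.spawn, so adding
a stage never perturbs earlier stages' draws. Exclusion accounting (patients
without a classifiable index, hemodiluted MRD, unpairable MRD) is logged as
a first-class output, since group denominators hinge on it.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import cna as cna_mod
from . import io as io_mod
from .commstant import baseline_counts, classify_cohort, stratify_by_baseline_median
from .mrd import concordance, crosstab_commstant_mrd, pair_measurements
from .records import Cohort
from .simulate import GeneratorConfig, generate_cohort
from .stats import DEFAULT_PREDICTORS, fit_longitudinal_model
from .survival import cox_hr, km_estimate

logger = logging.getLogger("cmmc.pipeline")

_KNOWN_KEYS = {
    "simulate", "generator", "cohort_dir", "patients_path", "timepoints_path",
    "mrd_path", "cells_path", "bulk_path", "commstant_rule", "pairing_window_months",
    "endpoints", "predictors", "out_dir", "seed", "log_level", "io_strict",
}


@dataclass
class RunConfig:
    simulate: bool = True
    generator: dict = field(default_factory=dict)
    cohort_dir: Optional[str] = None
    patients_path: Optional[str] = None
    timepoints_path: Optional[str] = None
    mrd_path: Optional[str] = None
    cells_path: Optional[str] = None
    bulk_path: Optional[str] = None
    commstant_rule: str = "all_positive"
    pairing_window_months: Optional[float] = None
    endpoints: tuple[str, ...] = ("pfs", "os")
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    out_dir: str = "cmmc_run"
    seed: int = 0
    log_level: str = "INFO"
    io_strict: bool = True

    @classmethod
    def from_mapping(cls, mapping: dict[str, Any]) -> "RunConfig":
        unknown = set(mapping) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(mapping)
        if "endpoints" in kwargs:
            kwargs["endpoints"] = tuple(kwargs["endpoints"])
        if "predictors" in kwargs:
            kwargs["predictors"] = tuple(kwargs["predictors"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in sorted(obj) if True] if isinstance(
            obj, (set, frozenset)) else [_jsonable(v) for v in obj]
    if isinstance(obj, float) and (obj != obj):
        return None
    return obj


def _load_cohort(config: RunConfig) -> Cohort:
    if config.cohort_dir:
        d = Path(config.cohort_dir)
        mrd = d / "mrd.csv"
        return io_mod.read_cohort(
            d / "patients.csv", d / "timepoints.csv",
            mrd if mrd.exists() else None, strict=config.io_strict,
        )
    return io_mod.read_cohort(
        config.patients_path, config.timepoints_path, config.mrd_path,
        strict=config.io_strict,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run all applicable stages; write CSV/JSON outputs under out_dir.

    Returns the JSON-ready summary dict. Deterministic given config + seed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": config.seed}
    # per-stage substreams: appending stages never changes earlier draws
    streams = np.random.SeedSequence(config.seed).spawn(4)

    stage = "input"
    try:
        if config.simulate:
            gen_seed = int(streams[0].generate_state(1)[0] % (2**31))
            gen = GeneratorConfig(**{"seed": gen_seed, **config.generator})
            cohort, truth = generate_cohort(gen)
            io_mod.write_cohort(cohort, out / "cohort")
            truth.patients.to_csv(out / "ground_truth.csv", index=False)
            logger.info("simulate: %d patients, %d timepoints, %d mrd records",
                        len(cohort.patients), len(cohort.timepoints), len(cohort.mrd))
        else:
            cohort = _load_cohort(config)
            logger.info("load: %d patients, %d timepoints, %d mrd records",
                        len(cohort.patients), len(cohort.timepoints), len(cohort.mrd))
        summary["n_patients"] = len(cohort.patients)
        summary["n_timepoints"] = len(cohort.timepoints)
        summary["n_mrd_records"] = len(cohort.mrd)

        stage = "classify"
        results = classify_cohort(cohort, rule=config.commstant_rule)
        n1 = sum(1 for r in results.values() if r.index == "1")
        n0 = sum(1 for r in results.values() if r.index == "0")
        n_ind = sum(1 for r in results.values() if r.index == "indeterminate")
        summary["commstant"] = {
            "rule": config.commstant_rule, "n_index1": n1, "n_index0": n0,
            "n_indeterminate_excluded": n_ind,
        }
        logger.info("classify: index1=%d index0=%d indeterminate(excluded)=%d",
                    n1, n0, n_ind)
        with open(out / "commstant.csv", "w", encoding="utf-8") as fh:
            fh.write("patient_id,index,n_used\n")
            for pid, r in sorted(results.items()):
                fh.write(f"{pid},{r.index},{r.n_enumerations_used}\n")

        stage = "stratify"
        baselines = baseline_counts(cohort)
        if baselines:
            high, low, median = stratify_by_baseline_median(baselines)
            summary["baseline_stratification"] = {
                "median": median, "n_high": len(high), "n_low": len(low),
                "high": high, "low": low,
            }
            logger.info("stratify: median=%g high=%d low=%d",
                        median, len(high), len(low))

        stage = "longitudinal"
        try:
            fit = fit_longitudinal_model(cohort, predictors=config.predictors)
            summary["longitudinal"] = {
                "multiplicative_effects": fit.multiplicative_effects,
                "random_intercept_variance": fit.random_intercept_variance,
                "residual_variance": fit.residual_variance,
                "scaled_residual_median": fit.scaled_residual_median,
                "converged": fit.converged,
                "n_obs": fit.n_obs,
                "n_patients": fit.n_patients,
                "note": "p-values are raw; no multiple-testing correction applied",
            }
            (out / "longitudinal_fit.txt").write_text(fit.report(), encoding="utf-8")
        except Exception as exc:
            summary["longitudinal"] = {"skipped": str(exc)}
            logger.info("longitudinal: skipped (%s)", exc)

        stage = "mrd"
        if cohort.mrd:
            pairing = pair_measurements(cohort, config.pairing_window_months)
            usable = pairing.usable
            n_excl = sum(1 for p in pairing.pairs if p.excluded_hemodilution)
            logger.info("mrd: %d records -> %d paired (%d hemodilution-excluded), "
                        "%d unpaired", len(cohort.mrd), len(pairing.pairs), n_excl,
                        len(pairing.unpaired))
            summary["mrd"] = {
                "n_records": len(cohort.mrd),
                "n_paired": len(pairing.pairs),
                "n_excluded_hemodilution": n_excl,
                "n_unpaired": len(pairing.unpaired),
            }
            if usable:
                summ = concordance(pairing.pairs)
                summary["mrd"]["concordance"] = _jsonable(summ)
                try:
                    summary["mrd"]["commstant_crosstab"] = _jsonable(
                        crosstab_commstant_mrd(results, pairing.pairs)
                    )
                except Exception as exc:
                    summary["mrd"]["commstant_crosstab"] = {"skipped": str(exc)}
            with open(out / "mrd_pairs.csv", "w", encoding="utf-8") as fh:
                fh.write("patient_id,timepoint,mrd_detectable,cmmc_detectable,"
                         "mrd_value,cmmc_count,excluded_hemodilution\n")
                for p in pairing.pairs:
                    fh.write(f"{p.patient_id},{p.timepoint},{p.mrd_detectable},"
                             f"{p.cmmc_detectable},{p.mrd_value},{p.cmmc_count},"
                             f"{p.excluded_hemodilution}\n")
        else:
            summary["mrd"] = {"skipped": "no MRD table supplied"}
            logger.info("mrd: stage skipped, no MRD table supplied")

        stage = "survival"
        classified = {pid: r.index for pid, r in results.items()
                      if r.index in ("1", "0")}
        summary["survival"] = {}
        for endpoint in config.endpoints:
            times, events, group = [], [], []
            for pid, idx in classified.items():
                p = cohort.patient(pid)
                t = getattr(p, f"{endpoint}_months")
                e = getattr(p, f"{endpoint}_event")
                if t is None or e is None:
                    continue
                times.append(t)
                events.append(e)
                group.append(1 if idx == "1" else 0)
            if len(set(group)) < 2 or not any(events):
                summary["survival"][endpoint] = {"skipped": "need 2 groups and >=1 event"}
                continue
            est = cox_hr(times, events, group)
            for gi in (0, 1):
                curve = km_estimate(
                    [t for t, g in zip(times, group) if g == gi],
                    [e for e, g in zip(events, group) if g == gi],
                )
                with open(out / f"km_{endpoint}_index{gi}.csv", "w",
                          encoding="utf-8") as fh:
                    fh.write("time_months,survival,at_risk\n")
                    for t, s, r in zip(curve.times, curve.survival, curve.at_risk):
                        fh.write(f"{t},{s},{r}\n")
            summary["survival"][endpoint] = _jsonable(est)
            logger.info("survival[%s]: HR=%.3f (%.3f-%.3f) logrank p=%.4g",
                        endpoint, est.hazard_ratio, est.ci_low, est.ci_high,
                        est.logrank_p)

        stage = "cna"
        if config.cells_path and config.bulk_path:
            cells, bulk = io_mod.read_cna_tables(config.cells_path, config.bulk_path)
            report = cna_mod.analyze_cells(cells, bulk)
            summary["cna"] = {
                "n_cells": len(cells),
                "clonality_tallies": report["clonality_tallies"],
                "n_emerging": report["n_emerging"],
                "jaccard_bulk_overlap": report["overlap"].jaccard,
                "main_ploidy": report["ploidy"].main_ploidy,
                "ploidy_tie": report["ploidy"].tie,
            }
            with open(out / "cna_calls.csv", "w", encoding="utf-8") as fh:
                fh.write("chrom,arm,direction,n_cells,n_total,fraction,"
                         "category,emerging\n")
                for c in report["calls"]:
                    ch, arm, d = c.alteration
                    fh.write(f"{ch},{arm},{d},{c.n_cells},{c.n_total},"
                             f"{c.fraction:.4f},{c.category},{c.emerging}\n")
        else:
            summary["cna"] = {"skipped": "no single-cell tables supplied"}
            logger.info("cna: stage skipped, no single-cell tables supplied")
    except Exception:
        logger.exception("pipeline failed in stage %r", stage)
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(_jsonable(summary), fh, indent=2)
        raise

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(summary), fh, indent=2)
    return summary
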