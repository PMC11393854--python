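"""Kaplan–Meier estimation, log-rank comparison and Cox hazard ratios.

Estimation is delegated to lifelines (product-limit estimator, multivariate
log-rank, Cox partial likelihood with Efron tie handling — months-resolution
follow-up guarantees ties). Median survival uses the first time at which
S(t) <= 0.5 and is undefined (None) when the curve never reaches 0.5.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .records import ValidationError


@dataclass
class SurvivalCurve:
    times: np.ndarray          # ordered distinct observed times (0 first)
    survival: np.ndarray       # S(t) at those times
    at_risk: np.ndarray        # number at risk just before each time
    censor_times: np.ndarray   # times of censored subjects
    median: Optional[float]    # first time with S <= 0.5; None if never reached


@dataclass
class HazardEstimate:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    logrank_statistic: float
    logrank_p: float
    n_per_group: tuple[int, int]
    events_per_group: tuple[int, int]
    monotone_likelihood: bool = False  # zero events in a group: HR boundary


def _check(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValidationError("empty survival input")
    if t.shape != e.shape:
        raise ValidationError("times and events must have equal length")
    if np.any(t < 0):
        raise ValidationError("times must be >= 0")
    return t, e


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit survival curve for one sample of right-censored times."""
    t, e = _check(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(kmf.survival_function_.index)
        .to_numpy(dtype=float)
    )
    below = np.nonzero(surv <= 0.5 + 1e-12)[0]
    median = float(grid[below[0]]) if below.size else None
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(t[~e]),
        median=median,
    )


def logrank(groups: Sequence[tuple]) -> tuple[float, float]:
    """Log-rank (O-E) test across >= 2 groups of (times, events).

    Returns (chi-squared statistic on k-1 df, p). Identical groups give
    statistic 0, p = 1.
    """
    if len(groups) < 2:
        raise ValidationError("logrank requires >= 2 groups")
    ts, es, labels = [], [], []
    for gi, (t, e) in enumerate(groups):
        t, e = _check(t, e)
        ts.append(t)
        es.append(e)
        labels.append(np.full(t.shape, gi))
    t_all = np.concatenate(ts)
    e_all = np.concatenate(es)
    g_all = np.concatenate(labels)
    if not e_all.any():
        raise ValidationError("logrank requires >= 1 event overall")
    res = multivariate_logrank_test(t_all, g_all, e_all)
    stat = float(res.test_statistic)
    if not np.isfinite(stat):
        stat = 0.0
    p = float(res.p_value) if np.isfinite(res.p_value) else 1.0
    return stat, p


def cox_hr(times, events, group) -> HazardEstimate:
    """Cox proportional-hazards HR of group 1 vs group 0 (binary covariate).

    Efron tie handling; Wald 95% CI. With zero events in one group the
    partial likelihood is monotone: the estimate is flagged and the CI bound
    set to 0 or inf rather than raising.
    """
    t, e = _check(times, events)
    g = np.asarray(group, dtype=int)
    if set(np.unique(g)) - {0, 1}:
        raise ValidationError("group must be binary 0/1")
    n1, n0 = int((g == 1).sum()), int((g == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValidationError("both groups must contain >= 1 subject")
    ev1, ev0 = int(e[g == 1].sum()), int(e[g == 0].sum())
    if ev0 + ev1 == 0:
        raise ValidationError("cox_hr requires >= 1 event")
    lr_stat, lr_p = logrank([(t[g == 0], e[g == 0]), (t[g == 1], e[g == 1])])

    if ev0 == 0 or ev1 == 0:
        # monotone partial likelihood: report the boundary estimate
        hr = float("inf") if ev0 == 0 and ev1 > 0 else 0.0
        return HazardEstimate(
            hazard_ratio=hr,
            ci_low=0.0,
            ci_high=float("inf"),
            logrank_statistic=lr_stat,
            logrank_p=lr_p,
            n_per_group=(n0, n1),
            events_per_group=(ev0, ev1),
            monotone_likelihood=True,
        )
    df = pd.DataFrame({"t": t, "e": e.astype(int), "g": g})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="t", event_col="e")
    beta = float(cph.params_["g"])
    se = float(cph.standard_errors_["g"])
    return HazardEstimate(
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        logrank_statistic=lr_stat,
        logrank_p=lr_p,
        n_per_group=(n0, n1),
        events_per_group=(ev0, ev1),
    )
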