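"""Association statistics and the longitudinal count–biomarker model.

The longitudinal model regresses log(CMMC count + 1) on a biomarker panel
with a per-patient random intercept (Gaussian linear mixed model, REML) so
that repeated enumerations of the same patient do not masquerade as
independent observations. Coefficients are reported both on the log scale
and as multiplicative effects exp(beta) per unit of the predictor. A plain
fixed-effects OLS variant is fitted alongside for comparison.

No multiple-testing correction is applied anywhere; every p-value printed is
raw, and reports state so.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import Cohort, ValidationError


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: np.ndarray
    p: np.ndarray
    n_pairs: np.ndarray
    method: str

    def to_frame(self, which: str = "r") -> pd.DataFrame:
        mat = {"r": self.r, "p": self.p, "n": self.n_pairs}[which]
        return pd.DataFrame(mat, index=self.variables, columns=self.variables)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n (<= 10).

    Enumerates all n! pairings of the rank vectors in batches; the p-value is
    the fraction of permutations with |rho| at least the observed |rho|.
    """
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    obs = abs(np.dot(rx, ry))
    count = total = 0
    batch: list[tuple] = []

    def flush(batch):
        nonlocal count, total
        if not batch:
            return
        perm = np.asarray(batch)
        vals = np.abs(perm @ ry)
        count += int(np.sum(vals >= obs - 1e-12))
        total += len(batch)

    for p in itertools.permutations(rx):
        batch.append(p)
        if len(batch) >= 200_000:
            flush(batch)
            batch = []
    flush(batch)
    return count / total


def pairwise_correlations(
    table: pd.DataFrame, method: str = "pearson", min_pairs: int = 3
) -> CorrelationMatrix:
    """Pairwise-complete correlation matrix with p-values.

    Cells with fewer than ``min_pairs`` complete pairs, or involving a
    constant variable, are flagged as missing (NaN) rather than raising.
    Pearson p-values come from the t-distribution transform of r; Spearman
    p-values use the t approximation for n > 10 and exact permutation for
    n <= 10.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be pearson or spearman, got {method!r}")
    cols = list(table.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n_pairs = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            pair = table[[cols[i], cols[j]]].dropna()
            n = len(pair)
            n_pairs[i, j] = n_pairs[j, i] = n
            if n < min_pairs:
                continue
            x = pair.iloc[:, 0].to_numpy(dtype=float)
            y = pair.iloc[:, 1].to_numpy(dtype=float)
            if i == j:
                if np.std(x) > 0:
                    r[i, i] = 1.0
                    p[i, i] = 0.0
                continue
            if np.std(x) == 0 or np.std(y) == 0:
                continue  # constant variable: correlation undefined, flagged NaN
            if method == "pearson":
                res = sps.pearsonr(x, y)
                r[i, j] = r[j, i] = res.statistic
                p[i, j] = p[j, i] = res.pvalue
            else:
                res = sps.spearmanr(x, y)
                rho = float(res.statistic)
                r[i, j] = r[j, i] = rho
                if n <= 10:
                    pv = _spearman_exact_p(x, y, rho)
                else:
                    pv = float(res.pvalue)
                p[i, j] = p[j, i] = pv
    return CorrelationMatrix(cols, r, p, n_pairs, method)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis rank test across >= 2 groups (mid-ranks, tie-corrected).

    Returns (H, p) with p from chi-squared on k-1 degrees of freedom.
    Identical groups give H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValidationError("kruskal_wallis requires >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValidationError("kruskal_wallis groups must be non-empty")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # all observations tied: no evidence of any difference
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher exact test on a 2x2 table of non-negative integers.

    Two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's
    (probability-mass rule, relative tolerance 1e-7 on the comparison).
    Returns (sample odds ratio, p); the odds ratio is inf/nan on zero cells.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValidationError("table entries must be non-negative integers")
    if np.any(t.sum(axis=0) < 1) or np.any(t.sum(axis=1) < 1):
        raise ValidationError("all margins must be >= 1")
    a, b = t[0]
    c, d = t[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (a * d) / (b * c)
    res = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return float(odds), float(res.pvalue)


@dataclass
class LongitudinalFit:
    coefficients: dict[str, float]
    multiplicative_effects: dict[str, float] = field(init=False)
    std_errors: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    random_intercept_variance: float = 0.0
    residual_variance: float = 0.0
    scaled_residual_median: float = 0.0
    n_obs: int = 0
    n_patients: int = 0
    converged: bool = True
    dropped: list[str] = field(default_factory=list)
    fixed_effects_fit: Optional["LongitudinalFit"] = None
    transform: str = "log(cmmc_count + 1)"

    def __post_init__(self):
        self.multiplicative_effects = {
            k: float(np.exp(v)) for k, v in self.coefficients.items()
        }

    def report(self) -> str:
        lines = [
            f"Longitudinal model of {self.transform} "
            f"({self.n_obs} observations, {self.n_patients} patients)",
            f"  random intercept variance: {self.random_intercept_variance:.4g}",
            f"  residual variance:         {self.residual_variance:.4g}",
            f"  scaled residual median:    {self.scaled_residual_median:.4g}",
            "  predictor          beta      exp(beta)   p (raw, uncorrected)",
        ]
        for k, v in self.coefficients.items():
            pv = self.p_values.get(k, float("nan"))
            lines.append(
                f"  {k:<16} {v:>9.4f} {self.multiplicative_effects[k]:>10.3f}"
                f"   {pv:.4g}"
            )
        if self.dropped:
            lines.append(f"  dropped (constant/collinear): {', '.join(self.dropped)}")
        if not self.converged:
            lines.append("  WARNING: mixed model did not converge; "
                         "fixed-effects fallback reported")
        return "\n".join(lines)


DEFAULT_PREDICTORS = (
    "beta2m", "albumin", "kappa_lambda_ratio", "ldh", "m_protein", "total_protein",
)


def _ols_fit(df: pd.DataFrame, predictors: list[str]) -> LongitudinalFit:
    import statsmodels.api as sm

    X = sm.add_constant(df[predictors].to_numpy(dtype=float))
    res = sm.OLS(df["_y"].to_numpy(dtype=float), X).fit()
    names = ["intercept"] + predictors
    resid = res.resid
    scale = np.sqrt(res.scale) if res.scale > 0 else 1.0
    return LongitudinalFit(
        coefficients=dict(zip(names, res.params)),
        std_errors=dict(zip(names, res.bse)),
        p_values=dict(zip(names, res.pvalues)),
        random_intercept_variance=0.0,
        residual_variance=float(res.scale),
        scaled_residual_median=float(np.median(resid / scale)),
        n_obs=int(res.nobs),
        n_patients=df["patient_id"].nunique(),
    )


def fit_longitudinal_model(
    cohort: Cohort,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    response_transform: str = "log1p",
) -> LongitudinalFit:
    """Fit the mixed model of transformed CMMC counts on a biomarker panel.

    Rows with any missing predictor are dropped listwise. Constant predictors
    are dropped with a flag rather than producing a singular design. If REML
    fails to converge the fixed-effects OLS fit is still returned, flagged.
    """
    import statsmodels.api as sm

    rows = pd.DataFrame(
        [
            {
                "patient_id": t.patient_id,
                "cmmc_count": t.cmmc_count,
                **{p: getattr(t, p, None) for p in predictors},
            }
            for t in cohort.timepoints
        ]
    )
    if rows.empty:
        raise ValidationError("cohort has no timepoints")
    df = rows.dropna(subset=list(predictors)).copy()
    if response_transform != "log1p":
        raise ValueError("only the log1p response transform is supported")
    df["_y"] = np.log1p(df["cmmc_count"].astype(float))
    if df["patient_id"].nunique() < 2 or len(df) < 4:
        raise ValidationError(
            "need >= 2 observations for >= 2 patients after listwise deletion"
        )
    kept, dropped = [], []
    for p in predictors:
        if df[p].nunique() > 1:
            kept.append(p)
        else:
            dropped.append(p)
    if not kept:
        raise ValidationError("all predictors are constant")

    ols = _ols_fit(df, kept)
    ols.dropped = dropped

    endog = df["_y"].to_numpy(dtype=float)
    exog = sm.add_constant(df[kept].to_numpy(dtype=float))
    names = ["intercept"] + kept
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(endog, exog, groups=df["patient_id"].to_numpy())
            res = model.fit(reml=True)
        converged = bool(res.converged)
    except Exception:
        converged = False
        res = None
    if res is None:
        fit = LongitudinalFit(
            coefficients=dict(ols.coefficients),
            std_errors=dict(ols.std_errors),
            p_values=dict(ols.p_values),
            residual_variance=ols.residual_variance,
            scaled_residual_median=ols.scaled_residual_median,
            n_obs=ols.n_obs,
            n_patients=ols.n_patients,
            converged=False,
            dropped=dropped,
        )
    else:
        fe = np.asarray(res.fe_params, dtype=float)
        resid = np.asarray(res.resid, dtype=float)
        scale = np.sqrt(res.scale) if res.scale > 0 else 1.0
        re_var = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
        fit = LongitudinalFit(
            coefficients=dict(zip(names, fe)),
            std_errors=dict(zip(names, np.asarray(res.bse_fe, dtype=float))),
            p_values=dict(zip(names, np.asarray(res.pvalues, dtype=float)[: len(names)])),
            random_intercept_variance=re_var,
            residual_variance=float(res.scale),
            scaled_residual_median=float(np.median(resid / scale)),
            n_obs=len(df),
            n_patients=df["patient_id"].nunique(),
            converged=converged,
            dropped=dropped,
        )
    fit.fixed_effects_fit = ols
    return fit


def biomarker_table(cohort: Cohort, variables: Sequence[str]) -> pd.DataFrame:
    """Long table of log1p(count) plus biomarkers, one row per enumeration."""
    rows = []
    for t in cohort.timepoints:
        row = {"log_cmmc": float(np.log1p(t.cmmc_count))}
        for v in variables:
            row[v] = getattr(t, v, None)
        rows.append(row)
    return pd.DataFrame(rows)
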