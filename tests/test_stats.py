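"""Association statistics and the longitudinal mixed model."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from cmmc.records import Cohort, PatientRecord, TimepointRecord, ValidationError
from cmmc.simulate import GeneratorConfig, generate_cohort
from cmmc.stats import (
    fisher_exact_2x2,
    fit_longitudinal_model,
    kruskal_wallis,
    pairwise_correlations,
)


def fisher_p_oracle(table, rtol=1e-7):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    probs = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(probs[probs <= p_obs * (1 + rtol)].sum())


class TestCorrelations:
    def test_self_correlation_is_one(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [1.0, 2, 3, 4]})
        m = pairwise_correlations(df, "pearson")
        assert m.r[0, 0] == 1.0
        assert m.r[0, 1] == pytest.approx(1.0)

    def test_anticorrelation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [-1.0, -2, -3]})
        m = pairwise_correlations(df, "pearson")
        assert m.r[0, 1] == pytest.approx(-1.0)

    def test_quadratic_example(self):
        # x = 1,2,3 vs y = x^2: rank-perfect, pearson slightly below 1
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [1.0, 4, 9]})
        sp = pairwise_correlations(df, "spearman")
        assert sp.r[0, 1] == pytest.approx(1.0)
        pe = pairwise_correlations(df, "pearson")
        # hand computation: cov = 4, sd_x = 1, sd_y = sqrt(49/3)
        assert pe.r[0, 1] == pytest.approx(4 / np.sqrt(49 / 3), abs=1e-12)

    def test_pairwise_complete_deletion_and_counts(self):
        df = pd.DataFrame(
            {"x": [1.0, 2, 3, 4, np.nan], "y": [2.0, 1, 4, np.nan, 5]}
        )
        m = pairwise_correlations(df, "pearson")
        assert m.n_pairs[0, 1] == 3

    def test_constant_variable_flagged_not_raised(self):
        df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]})
        m = pairwise_correlations(df, "pearson")
        assert np.isnan(m.r[0, 1])

    def test_too_few_pairs_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2, np.nan], "y": [1.0, np.nan, 3]})
        m = pairwise_correlations(df, "pearson")
        assert np.isnan(m.r[0, 1]) and m.n_pairs[0, 1] == 1

    @settings(max_examples=20, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(-100, 100), st.integers(-100, 100)),
            min_size=5, max_size=12,
            unique_by=(lambda t: t[0], lambda t: t[1]),
        )
    )
    def test_spearman_invariant_under_monotone_transform(self, data):
        x = np.array([a for a, _ in data], dtype=float)
        y = np.array([b for _, b in data], dtype=float)
        m1 = pairwise_correlations(pd.DataFrame({"x": x, "y": y}), "spearman")
        # strictly monotone transforms preserve ranks exactly on integers
        m2 = pairwise_correlations(
            pd.DataFrame({"x": x**3, "y": 2.0 * y + 7.0}), "spearman"
        )
        assert m1.r[0, 1] == pytest.approx(m2.r[0, 1], abs=1e-12)
        assert m1.p[0, 1] == pytest.approx(m2.p[0, 1], abs=1e-9)

    def test_spearman_exact_small_sample_p(self):
        # n = 4, perfect monotone: exact two-sided permutation p = 2/4! = 1/12
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [10.0, 20, 30, 40]})
        m = pairwise_correlations(df, "spearman")
        assert m.p[0, 1] == pytest.approx(2 / 24)


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_hand_value(self):
        # ranks 1..6 split 1-3 / 4-6: H = 12/42*(12+75) - 21 = 27/7
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27 / 7, abs=1e-9)

    def test_group_order_irrelevant(self):
        g = [[1.5, 2, 9], [4, 5.5], [0, 7, 8]]
        h1, _ = kruskal_wallis(g)
        h2, _ = kruskal_wallis(g[::-1])
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_fewer_than_two_groups_errors(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValidationError):
            kruskal_wallis([[1, 2], []])


class TestFisherExact:
    def test_response_table(self):
        # 6/15 vs 19/25 high-quality responders
        odds, p = fisher_exact_2x2([[6, 9], [19, 6]])
        assert p == pytest.approx(0.0418, abs=5e-4)
        assert odds == pytest.approx((6 * 6) / (9 * 19))

    def test_balanced_table(self):
        odds, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_row_and_column_swap_symmetry(self):
        _, p = fisher_exact_2x2([[3, 7], [8, 2]])
        _, p_row = fisher_exact_2x2([[8, 2], [3, 7]])
        _, p_col = fisher_exact_2x2([[7, 3], [2, 8]])
        assert p == pytest.approx(p_row, abs=1e-12)
        assert p == pytest.approx(p_col, abs=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[1, -1], [2, 3]])

    def test_matches_enumeration_small_tables(self):
        # exhaustive over all tables with N <= 15 and non-degenerate margins
        n_max = 15
        for a in range(n_max + 1):
            for b in range(n_max + 1 - a):
                for c in range(n_max + 1 - a - b):
                    for d in range(n_max + 1 - a - b - c):
                        if min(a + b, c + d, a + c, b + d) < 1:
                            continue
                        _, p = fisher_exact_2x2([[a, b], [c, d]])
                        assert p == pytest.approx(
                            fisher_p_oracle([[a, b], [c, d]]), abs=1e-9
                        ), (a, b, c, d)


def cohort_from_frame(df):
    patients = [
        PatientRecord(patient_id=pid, stage="MM")
        for pid in df.patient_id.unique()
    ]
    tps = [
        TimepointRecord(
            patient_id=r.patient_id, time_months=float(r.t), phase="induction",
            cmmc_count=int(r.count), beta2m=r.beta2m,
            albumin=getattr(r, "albumin", None),
        )
        for r in df.itertuples()
    ]
    return Cohort(patients=patients, timepoints=tps)


class TestLongitudinalModel:
    def test_noise_free_construction_recovers_effect(self):
        # log1p(count) made exactly alpha + log(5.5)*b2m: effect = 5.5 to 1e-6,
        # and the mixed estimate equals the OLS oracle on the same rows
        rng = np.random.default_rng(7)
        rows = []
        for pid in range(12):
            for k in range(4):
                b2m = float(rng.uniform(1.0, 8.0))
                count = int(round(np.expm1(0.3 + np.log(5.5) * b2m)))
                b2m_star = float(np.log1p(count) - 0.3) / np.log(5.5)  # invert rounding
                rows.append(
                    {"patient_id": f"P{pid}", "t": 3.0 * k, "count": count,
                     "beta2m": b2m_star}
                )
        cohort = cohort_from_frame(pd.DataFrame(rows))
        fit = fit_longitudinal_model(cohort, predictors=["beta2m"])
        assert fit.multiplicative_effects["beta2m"] == pytest.approx(5.5, abs=1e-6)
        ols = fit.fixed_effects_fit
        assert fit.coefficients["beta2m"] == pytest.approx(
            ols.coefficients["beta2m"], abs=1e-6
        )
        assert fit.random_intercept_variance == pytest.approx(0.0, abs=1e-6)

    def test_constant_predictor_dropped_with_flag(self):
        rng = np.random.default_rng(3)
        rows = [
            {"patient_id": f"P{p}", "t": 3.0 * k,
             "count": int(rng.integers(0, 50)), "beta2m": 4.0,
             "albumin": float(rng.uniform(3, 5))}
            for p in range(6) for k in range(3)
        ]
        cohort = cohort_from_frame(pd.DataFrame(rows))
        fit = fit_longitudinal_model(cohort, predictors=["beta2m", "albumin"])
        assert "beta2m" in fit.dropped
        assert "beta2m" not in fit.coefficients

    def test_random_intercept_variance_recovery(self):
        # all-persistent, zero-inflation-free, low-noise config: the patient
        # random intercept is the only between-patient term left, so REML
        # should recover intercept_sd^2 (median over replicates within 20%)
        true_var = 0.6**2
        estimates = []
        for s in range(100):
            cfg = GeneratorConfig(
                n_patients=200, frac_mm=1.0, frac_persistent=1.0,
                clearance_prob=0.0, count_dispersion=50.0,
                treatment_log_reduction=0.0, seed=40_000 + s,
            )
            cohort, _ = generate_cohort(cfg)
            fit = fit_longitudinal_model(cohort, predictors=["beta2m"])
            estimates.append(fit.random_intercept_variance)
        med = float(np.median(estimates))
        assert abs(med - true_var) / true_var < 0.20

    def test_too_few_rows_errors(self):
        cohort = cohort_from_frame(
            pd.DataFrame(
                [{"patient_id": "P1", "t": 0.0, "count": 5, "beta2m": 3.0}]
            )
        )
        with pytest.raises(ValidationError):
            fit_longitudinal_model(cohort, predictors=["beta2m"])
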