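"""Synthetic cohort generator: determinism, moments, label recovery."""
import math

import numpy as np
import pytest

from cmmc.commstant import classify_cohort
from cmmc.simulate import ConfigError, GeneratorConfig, generate_cohort


class TestConfig:
    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(frac_persistent=1.5).validate()

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(count_dispersion=-1).validate()

    def test_positive_treatment_reduction_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(treatment_log_reduction=0.2).validate()


class TestGenerate:
    def test_zero_patients_gives_empty_cohort(self):
        cohort, truth = generate_cohort(GeneratorConfig(n_patients=0))
        assert cohort.patients == [] and cohort.timepoints == []
        assert truth.patients.empty

    def test_same_seed_identical_different_seed_different(self):
        cfg = GeneratorConfig(n_patients=20, seed=42)
        a, _ = generate_cohort(cfg)
        b, _ = generate_cohort(cfg)
        assert a.patients == b.patients
        assert a.timepoints == b.timepoints
        assert a.mrd == b.mrd
        c, _ = generate_cohort(GeneratorConfig(n_patients=20, seed=43))
        assert c.timepoints != a.timepoints

    def test_structure_counts(self):
        cfg = GeneratorConfig(n_patients=51, seed=0)
        cohort, truth = generate_cohort(cfg)
        assert len(cohort.patients) == 51
        n_mm = sum(1 for p in cohort.patients if p.stage == "MM")
        assert n_mm == round(51 * 44 / 51)
        assert len(cohort.timepoints) == 51 * 4
        # MRD only for MM patients, two milestones each
        assert len(cohort.mrd) == 2 * n_mm
        assert set(truth.patients.latent_class) <= {"persistent", "clearing"}

    def test_pfs_never_exceeds_os(self):
        cohort, _ = generate_cohort(GeneratorConfig(n_patients=200, seed=9))
        for p in cohort.patients:
            assert p.pfs_months <= p.os_months + 1e-9

    def test_class_mix_matches_fraction_in_expectation(self):
        cohort, truth = generate_cohort(GeneratorConfig(n_patients=2000, seed=3))
        mm = truth.patients[truth.patients.stage == "MM"]
        frac = (mm.latent_class == "persistent").mean()
        assert frac == pytest.approx(0.375, abs=0.03)

    def test_count_moments_match_analytic_values(self):
        # fixed linear predictor (no b2m effect, no treatment step, no random
        # intercept): clearing-class post-baseline counts are a zero-inflated
        # negative binomial with known zero mass and mean
        mu = math.exp(2.0)
        cfg = GeneratorConfig(
            n_patients=1000, frac_mm=1.0, frac_persistent=0.0,
            clearance_prob=0.9, count_dispersion=2.0, baseline_log_mean=2.0,
            beta2m_effect=1.0, treatment_log_reduction=0.0, intercept_sd=0.0,
            seed=77,
        )
        cohort, _ = generate_cohort(cfg)
        post = [t.cmmc_count for t in cohort.timepoints if t.time_months > 0]
        post = np.asarray(post)
        n = post.size
        k, pi = cfg.count_dispersion, cfg.clearance_prob
        p_zero = pi + (1 - pi) * (k / (k + mu)) ** k
        mean = (1 - pi) * mu
        var = (1 - pi) * (mu + mu**2 / k) + pi * (1 - pi) * mu**2
        # 4-standard-error Monte-Carlo bounds
        assert np.mean(post == 0) == pytest.approx(
            p_zero, abs=4 * math.sqrt(p_zero * (1 - p_zero) / n)
        )
        assert post.mean() == pytest.approx(mean, abs=4 * math.sqrt(var / n))

    def test_persistent_class_counts_always_detectable(self):
        cohort, truth = generate_cohort(
            GeneratorConfig(n_patients=300, frac_mm=1.0, seed=5)
        )
        persistent = set(
            truth.patients.loc[
                truth.patients.latent_class == "persistent", "patient_id"
            ]
        )
        for t in cohort.timepoints:
            if t.patient_id in persistent and t.time_months > 0:
                assert t.cmmc_count >= 1

    def test_biomarker_sign_pattern(self):
        # loadings: b2m, CRP, M-protein rise with severity; albumin falls
        cohort, truth = generate_cohort(GeneratorConfig(n_patients=800, seed=21))
        sev = truth.patients.set_index("patient_id").severity
        first = {t.patient_id: t for t in cohort.timepoints if t.time_months == 0}
        ids = list(first)
        s = np.array([sev[i] for i in ids])
        for marker, sign in (("beta2m", 1), ("crp", 1), ("m_protein", 1),
                             ("albumin", -1)):
            vals = np.array([getattr(first[i], marker) for i in ids])
            r = np.corrcoef(s, vals)[0, 1]
            assert sign * r > 0.3, marker

    def test_response_worse_in_persistent_class(self):
        cohort, truth = generate_cohort(GeneratorConfig(n_patients=1000, seed=8))
        cls = truth.patients.set_index("patient_id").latent_class
        good = {"CR", "VGPR"}
        rates = {}
        for label in ("persistent", "clearing"):
            ids = [p.patient_id for p in cohort.patients
                   if p.stage == "MM" and cls[p.patient_id] == label]
            n_good = sum(
                1 for pid in ids if cohort.patient(pid).best_response in good
            )
            rates[label] = n_good / len(ids)
        assert rates["persistent"] < rates["clearing"]
        assert rates["persistent"] == pytest.approx(6 / 15, abs=0.07)
        assert rates["clearing"] == pytest.approx(19 / 25, abs=0.07)

    def test_mrd_detectability_increases_with_count(self):
        cohort, _ = generate_cohort(GeneratorConfig(n_patients=1000, seed=13))
        counts = {(t.patient_id, t.time_months): t.cmmc_count
                  for t in cohort.timepoints}
        milestones = {"post_induction": 3.0, "pre_maintenance": 6.0}
        pos = {True: [], False: []}
        for m in cohort.mrd:
            conc = counts[(m.patient_id, milestones[m.timepoint])]
            pos[conc >= 1].append(m.detectable)
        assert np.mean(pos[True]) > np.mean(pos[False])


class TestClassifierRecovery:
    def test_noise_free_generator_output_recovers_latent_classes(self):
        cfg = GeneratorConfig(
            n_patients=400, clearance_prob=1.0, deterministic_counts=True,
            seed=12,
        )
        cohort, truth = generate_cohort(cfg)
        results = classify_cohort(cohort)
        cls = truth.patients.set_index("patient_id").latent_class
        checked = 0
        for pid, res in results.items():
            if res.index not in ("1", "0"):
                continue  # < 2 in-window enumerations (SMM patients)
            checked += 1
            expected = "1" if cls[pid] == "persistent" else "0"
            assert res.index == expected, pid
        assert checked == sum(1 for p in cohort.patients if p.stage == "MM")
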