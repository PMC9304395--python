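"""Gamma GLMM layer: PQL correctness against the plain-GLM oracle,
Wald-test algebra, calibration under null generators, and the shapes of
the variability / tissue-contrast / clinical / descriptive tables."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import mechamap as mm
from mechamap.glmm import RandomTerm, fit_gamma_pql
from mechamap.stiffness_stats import (MixedModelSpec, _wald_from_contrast,
                                      fit_gamma_glmm, wald_f_test)


def small_obs(seed=0, effects=None, n_patients=12, maps_per_patient=4,
              points=20):
    effects = effects or mm.EffectConfig()
    obs, cohort = mm.simulate_observations(
        n_patients=n_patients, maps_per_patient=maps_per_patient,
        points_per_map=points, effects=effects, seed=seed)
    return obs, cohort


class TestPQLEngine:
    def test_collapses_to_plain_gamma_glm(self, rng):
        # single patient, single map: no estimable random structure, so
        # PQL must agree with the ordinary gamma GLM (statsmodels oracle)
        n = 300
        x = rng.normal(size=n)
        y = rng.gamma(2.0, np.exp(0.5 + 0.8 * x) / 2.0)
        X = np.column_stack([np.ones(n), x])
        ours = fit_gamma_pql(y, X, [RandomTerm("patient",
                                               np.zeros(n, dtype=int), 1)])
        oracle = sm.GLM(y, X, family=sm.families.Gamma(
            sm.families.links.Log())).fit()
        assert np.max(np.abs(ours.beta - oracle.params)) < 1e-6
        assert ours.dropped_terms == ["patient"]

    def test_positive_response_required(self):
        X = np.ones((4, 1))
        with pytest.raises(ValueError):
            fit_gamma_pql(np.array([1.0, 2.0, 0.0, 3.0]), X, [])

    def test_scale_equivariance_kpa_vs_pa(self):
        obs, _ = small_obs(seed=3)
        spec = MixedModelSpec(fixed_terms=("tissue_type",),
                              random_terms=("patient", "map"))
        fit_kpa = fit_gamma_glmm(obs, spec)
        obs_pa = obs.copy()
        obs_pa["E_kPa"] = obs_pa["E_kPa"] * 1000.0
        fit_pa = fit_gamma_glmm(obs_pa, spec)
        slopes = [n for n in fit_kpa.params.index if n != "Intercept"]
        assert np.allclose(fit_kpa.params[slopes], fit_pa.params[slopes],
                           atol=1e-5)
        assert fit_pa.params["Intercept"] - fit_kpa.params["Intercept"] \
            == pytest.approx(np.log(1000.0), abs=1e-5)

    def test_random_variance_recovery_order(self):
        # strong patient spread, weak map spread: recovered variance
        # components should rank accordingly
        eff = mm.EffectConfig.null()
        eff = mm.EffectConfig(
            tissue_effects=eff.tissue_effects,
            clinical_effects=eff.clinical_effects,
            sd_patient=1.0, sd_map=0.05)
        obs, _ = small_obs(seed=5, effects=eff, n_patients=20, points=30)
        spec = MixedModelSpec(fixed_terms=(), random_terms=("patient",
                                                            "map"))
        fit = fit_gamma_glmm(obs, spec)
        assert fit.random_variances["patient"] > \
            fit.random_variances["map"]


class TestWaldAlgebra:
    def test_single_coefficient_f_equals_t_squared(self):
        obs, _ = small_obs(seed=1)
        obs = obs[obs.tissue_type.isin(["distal_normal", "stroma"])]
        spec = MixedModelSpec(fixed_terms=("tissue_type",),
                              random_terms=("patient", "map"))
        fit = fit_gamma_glmm(obs, spec)
        F, p = wald_f_test(fit, "tissue_type")
        t = float(fit.t_values["tissue_type[stroma]"])
        assert F == pytest.approx(t**2, rel=1e-9)

    def test_zero_coefficients_give_zero_f_and_p_one(self):
        beta = np.zeros(3)
        cov = np.eye(3)
        C = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        res = _wald_from_contrast(beta, cov, C, ddf=20)
        assert res["F"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_unknown_term_rejected(self):
        obs, _ = small_obs(seed=2)
        spec = MixedModelSpec(fixed_terms=("tissue_type",),
                              random_terms=("patient",))
        fit = fit_gamma_glmm(obs, spec)
        with pytest.raises(KeyError):
            wald_f_test(fit, "phase_of_moon")

    def test_power_increases_with_sample_size(self):
        # true log-fold 2.0 between two tissues: p should fall as the
        # number of patients grows (averaged over a seeded triple)
        eff = mm.EffectConfig.only(tissue={"stroma": 2.0})
        spec = MixedModelSpec(fixed_terms=("tissue_type",),
                              random_terms=("patient", "map"))
        mean_logp = []
        for n_pat in (4, 8, 16):
            logps = []
            for seed in (11, 12, 13):
                obs, _ = mm.simulate_observations(
                    n_patients=n_pat, maps_per_patient=2,
                    points_per_map=15, effects=eff,
                    tissue_allocation=("distal_normal", "stroma"),
                    seed=seed)
                fit = fit_gamma_glmm(obs, spec)
                _, p = wald_f_test(fit, "tissue_type")
                logps.append(np.log(max(p, 1e-300)))
            mean_logp.append(np.mean(logps))
        assert mean_logp[0] > mean_logp[1] > mean_logp[2]


class TestModelValidation:
    def test_map_nesting_enforced(self):
        obs, _ = small_obs(seed=4)
        obs.loc[obs.index[:10], "map_id"] = obs["map_id"].iloc[-1]
        with pytest.raises(ValueError, match="patients"):
            fit_gamma_glmm(obs, MixedModelSpec(
                fixed_terms=(), random_terms=("patient", "map")))

    def test_nonpositive_stiffness_rejected(self):
        obs, _ = small_obs(seed=4)
        obs.loc[obs.index[0], "E_kPa"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_gamma_glmm(obs, MixedModelSpec(
                fixed_terms=(), random_terms=("patient",)))

    def test_only_gamma_log_supported(self):
        with pytest.raises(ValueError):
            MixedModelSpec(family="poisson")


class TestTissueContrasts:
    def test_zero_variance_contrast_equals_log_mean_ratio(self):
        # balanced two-tissue data with no random spread: the contrast
        # must collapse to the log ratio of group means
        eff = mm.EffectConfig(
            tissue_effects={t: (1.1 if t == "stroma" else 0.0)
                            for t in mm.synthetic_cohort.TISSUE_TYPES},
            clinical_effects={k: 0.0
                              for k in mm.EffectConfig().clinical_effects},
            sd_patient=0.0, sd_map=0.0)
        obs, _ = mm.simulate_observations(
            n_patients=8, maps_per_patient=2, points_per_map=200,
            effects=eff, tissue_allocation=("distal_normal", "stroma"),
            seed=21)
        table, _ = mm.tissue_contrasts(obs, reference="normal",
                                       pooling="normal")
        means = obs.groupby("tissue_type")["E_kPa"].mean()
        expected = np.log(means["stroma"] / means["distal_normal"])
        beta = float(table.loc[table.tissue == "stroma", "beta"].iloc[0])
        assert beta == pytest.approx(expected, abs=1e-3)

    def test_sign_recovery_of_tissue_ordering(self):
        # stroma > tumor epithelium > normal on the log scale
        eff = mm.EffectConfig.only(tissue={"stroma": True,
                                           "tumor_epithelium": True,
                                           "mixed": True})
        hits = 0
        n_runs = 25
        for seed in range(n_runs):
            obs, _ = small_obs(seed=100 + seed, effects=eff,
                               n_patients=20, points=56)
            table, _ = mm.tissue_contrasts(obs)
            b = table.set_index("tissue")["beta"]
            hits += (b["stroma"] > b["tumor_epithelium"] > 0)
        assert hits / n_runs >= 0.9

    def test_null_generator_rarely_rejects(self):
        # identical means in all tissues: every contrast p > 0.05 in the
        # vast majority of null runs
        null = mm.EffectConfig.null()
        clean = 0
        n_runs = 100
        for seed in range(n_runs):
            obs, _ = small_obs(seed=500 + seed, effects=null)
            table, _ = mm.tissue_contrasts(obs)
            clean += bool((table["p"] > 0.05).all())
        assert clean / n_runs >= 0.85

    def test_missing_reference_is_error(self):
        obs, _ = small_obs(seed=6)
        with pytest.raises(ValueError, match="reference"):
            mm.tissue_contrasts(obs, reference="cartilage", pooling=None)

    def test_st_merged_pooling(self):
        obs, _ = small_obs(seed=7)
        table, _ = mm.tissue_contrasts(obs, reference="mixed",
                                       pooling="st_merged")
        assert set(table.tissue) == {"normal", "t_s_merged"}


class TestVariability:
    def test_patient_spread_detected(self):
        eff = mm.EffectConfig(
            tissue_effects={t: 0.0
                            for t in mm.synthetic_cohort.TISSUE_TYPES},
            clinical_effects={k: 0.0
                              for k in mm.EffectConfig().clinical_effects},
            sd_patient=1.0, sd_map=0.0)
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            obs, _ = mm.simulate_observations(
                n_patients=8, maps_per_patient=3, points_per_map=25,
                effects=eff, tissue_allocation=("stroma",),
                seed=300 + seed)
            table = mm.variability_analysis(obs, "stroma")
            p = float(table.loc[table.factor == "Patient", "p"].iloc[0])
            hits += p < 0.05
        assert hits / n_runs >= 0.8

    def test_null_generator_not_systematically_rejected(self):
        null = mm.EffectConfig.null()
        rej_map = rej_pat = 0
        n_runs = 25
        for seed in range(n_runs):
            obs, _ = mm.simulate_observations(
                n_patients=8, maps_per_patient=3, points_per_map=25,
                effects=mm.EffectConfig(
                    tissue_effects=null.tissue_effects,
                    clinical_effects=null.clinical_effects,
                    sd_patient=0.0, sd_map=0.0),
                tissue_allocation=("stroma",), seed=700 + seed)
            table = mm.variability_analysis(obs, "stroma").set_index(
                "factor")
            rej_map += float(table.loc["Map", "p"]) < 0.05
            rej_pat += float(table.loc["Patient", "p"]) < 0.05
        assert rej_map / n_runs <= 0.2
        assert rej_pat / n_runs <= 0.2

    def test_single_patient_inter_row_not_estimable(self):
        obs, _ = mm.simulate_observations(
            n_patients=1, maps_per_patient=3, points_per_map=20,
            tissue_allocation=("stroma",), seed=9)
        table = mm.variability_analysis(obs, "stroma").set_index("factor")
        assert np.isnan(table.loc["Patient", "F"])
        assert "single" in table.loc["Patient", "note"]


class TestClinical:
    def test_null_covariate_rarely_significant(self):
        null = mm.EffectConfig.null()
        betas, clean = [], 0
        n_runs = 40
        for seed in range(n_runs):
            obs, cohort = small_obs(seed=900 + seed, effects=null)
            table = mm.clinical_associations(obs, cohort,
                                             covariates=["mucinous"])
            if table.note.iloc[0]:
                clean += 1  # skipped constant covariate counts as clean
                continue
            betas.append(float(table.beta.iloc[0]))
            clean += float(table.p.iloc[0]) > 0.05
        assert clean / n_runs >= 0.85
        assert abs(np.median(betas)) < 0.2

    def test_constant_covariate_skipped(self):
        obs, cohort = small_obs(seed=10)
        cohort = cohort.copy()
        cohort["mucinous"] = True
        table = mm.clinical_associations(obs, cohort,
                                         covariates=["mucinous"])
        assert "skipped" in table.note.iloc[0]
        assert np.isnan(table.beta.iloc[0])

    def test_reported_map_counts(self):
        obs, cohort = small_obs(seed=11)
        table = mm.clinical_associations(obs, cohort,
                                         covariates=["stage_late"])
        late = cohort.loc[cohort.stage.isin(["III", "IV"]),
                          "patient_id"]
        tumor = obs[obs.tissue_type.isin(
            ("tumor_epithelium", "stroma", "mixed"))]
        expected = tumor.loc[tumor.patient_id.isin(late),
                             "map_id"].nunique()
        assert int(table.n_maps.iloc[0]) == expected


class TestDescriptives:
    def test_demo_cohort_percentages(self):
        summary = mm.descriptive_summary(mm.demo_cohort())
        cat = summary["categorical"].set_index(["variable", "level"])
        assert cat.loc[("sex", "Female"), "percentage"] == \
            pytest.approx(61.1, abs=0.05)
        assert cat.loc[("location", "Right colon"), "percentage"] == \
            pytest.approx(55.6, abs=0.05)
        assert mm.kras_among_ras_fraction(mm.demo_cohort()) == \
            pytest.approx(87.5)

    def test_empty_level_reports_zero(self):
        cohort = mm.demo_cohort()
        cohort = cohort[cohort.stage != "I"]
        cat = mm.descriptive_summary(cohort)["categorical"].set_index(
            ["variable", "level"])
        assert cat.loc[("stage", "I"), "count"] == 0
        assert cat.loc[("stage", "I"), "percentage"] == 0.0

    def test_missing_column_is_schema_error(self):
        with pytest.raises(KeyError, match="missing"):
            mm.descriptive_summary(mm.demo_cohort().drop(columns=["msi"]))
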