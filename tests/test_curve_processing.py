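"""Curve-processing chain: baseline removal, contact detection, indentation
kinematics, Hertz fitting and the three quality-control criteria."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import mechamap as mm
from mechamap.curve_processing import (APPROACH, ForceCurve,
                                       baseline_correct,
                                       detect_contact_point,
                                       compute_indentation, fit_hertz,
                                       qc_curve, process_map)
from mechamap.physics import hertz_force
from mechamap.synthetic_cohort import StiffnessGroundTruth


def _clean_curve(E=1000.0, noise=0.0, seed=0):
    cfg = mm.AcquisitionConfig(noise_sd=noise)
    return mm.simulate_force_curve(E, config=cfg, seed=seed), cfg


class TestBaseline:
    def test_constant_offset_removed_to_machine_precision(self):
        curve, cfg = _clean_curve()
        curve.force = curve.force + 50e-12
        base = baseline_correct(curve)
        z, f = base.curve.approach
        pre = f[z < cfg.pre_contact_travel - 0.1e-6]
        assert abs(pre.mean()) < 1e-15

    def test_linear_drift_removed_on_noiseless_input(self):
        curve, cfg = _clean_curve()
        curve.force = curve.force + 1e-12 / 1e-6 * curve.z  # 1 pN per um
        base = baseline_correct(curve)
        z, f = base.curve.approach
        pre = f[z < cfg.pre_contact_travel - 0.1e-6]
        assert np.max(np.abs(pre)) < 1e-15
        assert base.slope == pytest.approx(1e-6, rel=1e-3)  # N/m

    def test_drift_plus_noise_corrected_within_sampling_error(self):
        curve, cfg = _clean_curve(noise=20e-12, seed=9)
        curve.force = curve.force + 2e-12 / 1e-6 * curve.z
        base = baseline_correct(curve)
        z, f = base.curve.approach
        pre = f[z < cfg.pre_contact_travel - 0.1e-6]
        assert abs(pre.mean()) < 3 * 20e-12 / np.sqrt(len(pre))


class TestContactPoint:
    def test_noiseless_recovery_within_one_sample(self):
        curve, cfg = _clean_curve()
        cp = detect_contact_point(baseline_correct(curve).curve)
        assert cp.found and not cp.permanent
        assert abs(cp.z0 - cfg.pre_contact_travel) <= cfg.sample_spacing

    def test_permanent_contact_gives_sentinel(self):
        cfg = mm.AcquisitionConfig()
        curve = mm.simulate_force_curve(
            1000.0, config=cfg,
            artifact=mm.ArtifactSpec(kind="permanent_contact"), seed=2)
        cp = detect_contact_point(curve)
        assert cp.permanent and not np.isfinite(cp.z0)

    def test_monte_carlo_refined_contact_accuracy(self):
        # 500 noisy replicates of one clean geometry; the fit-refined z0
        # must land within 5 sample spacings of truth at the median
        cfg = mm.AcquisitionConfig()
        errors = []
        for seed in range(500):
            curve = mm.simulate_force_curve(1000.0, config=cfg, seed=seed)
            fit = mm.process_curve(curve, cfg).fit
            errors.append(abs(fit.z0 - cfg.pre_contact_travel))
        assert np.median(errors) < 5 * cfg.sample_spacing


class TestIndentation:
    def test_zero_force_means_depth_equals_travel(self):
        z = np.linspace(0, 5e-6, 200)
        curve = ForceCurve(z=z, force=np.zeros_like(z),
                           segment=np.array([APPROACH] * len(z)))
        d, f = compute_indentation(curve, 1e-6, 0.2)
        np.testing.assert_allclose(d, z[z >= 1e-6] - 1e-6, atol=1e-18)

    def test_single_point_hand_arithmetic(self):
        # z - z0 = 1.0 um, F = 0.1 nN, k = 0.2 N/m -> delta = 0.9995 um
        z = np.array([0.0, 2.0e-6])
        f = np.array([0.0, 0.1e-9])
        curve = ForceCurve(z=z, force=f,
                           segment=np.array([APPROACH, APPROACH]))
        d, _ = compute_indentation(curve, 1.0e-6, 0.2)
        assert d[-1] == pytest.approx(0.9995e-6, abs=1e-12)

    def test_stiff_cantilever_limit(self):
        curve, cfg = _clean_curve()
        z, f = curve.approach
        d, ff = compute_indentation(curve, cfg.pre_contact_travel, 1e9)
        sel = z >= cfg.pre_contact_travel
        np.testing.assert_allclose(
            np.sort(z[sel] - cfg.pre_contact_travel), d, atol=1e-11)

    def test_nonpositive_spring_constant_rejected(self):
        curve, _ = _clean_curve()
        with pytest.raises(ValueError):
            compute_indentation(curve, 1e-6, 0.0)


class TestHertzFit:
    R, NU = 5.1e-6, 0.5

    def _exact(self, E, n=200, dmax=2e-6):
        d = np.linspace(0, dmax, n)
        return d, hertz_force(d, E, self.R, self.NU)

    def test_exact_data_round_trip(self):
        d, f = self._exact(1000.0)
        fit = fit_hertz(d, f, self.R, self.NU)
        assert fit.converged
        assert fit.E == pytest.approx(1000.0, rel=1e-9)
        assert fit.rss < 1e-30

    def test_linearity_in_modulus(self):
        d, f = self._exact(1000.0)
        fit2 = fit_hertz(d, 2 * f, self.R, self.NU)
        assert fit2.E == pytest.approx(2000.0, rel=1e-9)

    def test_delta_max_respected_on_noiseless_data(self):
        d, f = self._exact(800.0, n=400, dmax=4e-6)
        fit_win = fit_hertz(d, f, self.R, self.NU, delta_max=2e-6)
        d2, f2 = d[d <= 2e-6], f[d <= 2e-6]
        fit_ref = fit_hertz(d2, f2, self.R, self.NU, delta_max=2e-6)
        assert fit_win.E == pytest.approx(fit_ref.E, rel=1e-9)
        assert fit_win.n_fit == fit_ref.n_fit

    def test_too_few_samples_is_nonconverged_not_error(self):
        d, f = self._exact(1000.0, n=4)
        fit = fit_hertz(d, f, self.R, self.NU)
        assert not fit.converged and "samples" in fit.reason

    def test_monte_carlo_median_relative_error(self):
        # 1000 noisy replicates at generator defaults, E = 1000 Pa
        cfg = mm.AcquisitionConfig()
        errors = []
        for seed in range(1000):
            curve = mm.simulate_force_curve(1000.0, config=cfg, seed=seed)
            fit = mm.process_curve(curve, cfg).fit
            errors.append(abs(fit.E - 1000.0) / 1000.0)
        assert np.median(errors) < 0.05

    def test_unit_safety_nm_pn_vs_si(self):
        # fitting data expressed in nm/pN (converted back to SI at the
        # declared boundary) must match fitting native SI arrays
        d, f = self._exact(1234.0)
        d_nm, f_pn = d * 1e9, f * 1e12
        fit_si = fit_hertz(d, f, self.R, self.NU)
        fit_conv = fit_hertz(d_nm * 1e-9, f_pn * 1e-12, self.R, self.NU)
        assert fit_conv.E == pytest.approx(fit_si.E, rel=1e-12)

    @given(E=st.floats(50, 5e4), scale=st.floats(1.1, 5.0),
           d1=st.floats(1e-8, 1e-6), d2=st.floats(1.1e-6, 3e-6))
    def test_forward_model_properties(self, E, scale, d1, d2):
        # F(0) = 0; strictly increasing in depth and modulus; linear in E
        assert hertz_force(0.0, E, self.R, self.NU) == 0.0
        f1 = hertz_force(d1, E, self.R, self.NU)
        f2 = hertz_force(d2, E, self.R, self.NU)
        assert f2 > f1 > 0
        assert hertz_force(d1, scale * E, self.R, self.NU) == \
            pytest.approx(scale * f1, rel=1e-12)


class TestCurveQC:
    def test_clean_curve_passes(self):
        curve, cfg = _clean_curve(noise=20e-12, seed=1)
        verdict = mm.process_curve(curve, cfg).qc
        assert verdict.passed

    def test_short_baseline_flags_ill_defined_contact(self):
        cfg = mm.AcquisitionConfig()
        curve = mm.simulate_force_curve(
            1000.0, config=cfg,
            artifact=mm.ArtifactSpec(kind="short_baseline"), seed=2)
        verdict = mm.process_curve(curve, cfg).qc
        assert verdict.ill_defined_contact
        assert not verdict.permanent_contact and not verdict.too_noisy

    def test_noise_threshold_arithmetic(self):
        # deterministic fixture: +-0.5 nN alternating on a flat baseline
        # has sd >= 0.5 nN = 0.25 * 2 nN, tripping the noise rule exactly
        curve, cfg = _clean_curve()
        wobble = 0.5e-9 * (-1.0) ** np.arange(len(curve.force))
        curve.force = curve.force + wobble
        base = baseline_correct(curve)
        cp = detect_contact_point(base.curve)
        verdict = qc_curve(base.curve, cp, cfg.force_trigger)
        assert verdict.too_noisy
        assert not verdict.permanent_contact
        assert not verdict.ill_defined_contact


class TestProcessMap:
    def _map_curves(self, kinds, cfg, E=1000.0):
        truth = StiffnessGroundTruth("P1", "M1", "stroma", np.log(E))
        curves = []
        for idx, kind in enumerate(kinds):
            r, c = divmod(idx, cfg.grid_n)
            curves.append(mm.simulate_force_curve(
                E, config=cfg, artifact=mm.ArtifactSpec(kind=kind),
                seed=idx, curve_id=f"c{idx}", grid_row=r, grid_col=c))
        return curves

    def test_all_clean_grid_fully_valid(self, acq_noiseless):
        curves = self._map_curves(["clean"] * 100, acq_noiseless)
        smap, results = process_map(curves, acq_noiseless)
        assert smap.n_valid == 100
        assert smap.exclusion_counts["clean"] == 100

    def test_all_permanent_contact_yields_empty_map(self, acq_noiseless):
        curves = self._map_curves(["permanent_contact"] * 100,
                                  acq_noiseless)
        smap, _ = process_map(curves, acq_noiseless)
        assert smap.n_valid == 0
        assert smap.exclusion_counts["permanent_contact"] == 100

    def test_mixture_tally_matches_injected_kinds(self, acq):
        kinds = (["clean"] * 80 + ["permanent_contact"] * 8
                 + ["short_baseline"] * 6 + ["high_noise"] * 6)
        curves = self._map_curves(kinds, acq)
        smap, _ = process_map(curves, acq)
        assert smap.n_valid == 80
        assert smap.exclusion_counts["permanent_contact"] == 8
        assert smap.exclusion_counts["ill_defined_contact"] == 6
        assert smap.exclusion_counts["too_noisy"] == 6

    def test_duplicate_grid_index_latest_wins(self, acq_noiseless, caplog):
        curves = self._map_curves(["clean"] * 2, acq_noiseless)
        curves[1].grid_row = curves[0].grid_row
        curves[1].grid_col = curves[0].grid_col
        with caplog.at_level("WARNING"):
            smap, _ = process_map(curves, acq_noiseless)
        assert smap.n_valid == 1
        assert any("duplicate" in r.message for r in caplog.records)
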