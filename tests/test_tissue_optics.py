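"""Ablation threshold/attenuation inference and THG slope fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from threephoton import tissue_optics as to


class TestW0Conversion:
    def test_numeric_oracle_cubed_gaussian(self):
        """Cube a sampled Gaussian, measure both widths, invert numerically."""
        w0_true = 1.7  # µm, arbitrary
        x = np.linspace(-6, 6, 200001)
        one_photon = np.exp(-2.0 * x**2 / w0_true**2)  # 1/e^2 radius w0
        three_photon = one_photon**3
        half = three_photon >= 0.5
        fwhm_3p = x[half][-1] - x[half][0]
        assert to.w0_from_three_photon_fwhm(fwhm_3p) == pytest.approx(w0_true, rel=1e-3)

    def test_paper_fwhm_value(self):
        assert to.w0_from_three_photon_fwhm(0.45) == pytest.approx(0.662, rel=1e-3)

    def test_inversion_and_linearity(self):
        assert to.w0_from_three_photon_fwhm(
            math.sqrt(2 * math.log(2)) / math.sqrt(3)
        ) == pytest.approx(1.0)
        assert to.w0_from_three_photon_fwhm(0.9) == pytest.approx(
            2 * to.w0_from_three_photon_fwhm(0.45)
        )
        with pytest.raises(ValueError):
            to.w0_from_three_photon_fwhm(0.0)


def synthetic_curve(e_th, delta_e, n=9, span=(0.4, 2.5), depth=150.0):
    e = np.linspace(span[0] * e_th, span[1] * e_th, n)
    return to.DamageCurve(depth=depth, energies=tuple(e),
                          damage_percent=tuple(to.damage_model(e, e_th, delta_e)))


class TestDamageThresholdFit:
    def test_recovers_generative_threshold(self):
        """Noiseless erf curve at the 150 µm measured threshold refits exactly."""
        fit = to.fit_damage_threshold(synthetic_curve(25.7, 4.0))
        assert fit.e_th_surface == pytest.approx(25.7, rel=1e-6)
        assert fit.delta_e == pytest.approx(4.0, rel=1e-6)
        assert fit.residual_norm < 1e-6

    def test_model_is_50_percent_at_threshold(self):
        fit = to.fit_damage_threshold(synthetic_curve(25.7, 4.0))
        assert to.damage_model(fit.e_th_surface, fit.e_th_surface, fit.delta_e) == 50.0

    def test_erf_limits(self):
        assert to.damage_model(1e-9, 25.7, 4.0) == pytest.approx(0.0, abs=1e-6)
        assert to.damage_model(1e9, 25.7, 4.0) == pytest.approx(100.0, abs=1e-6)

    @given(k=st.floats(0.2, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_energy_scale_equivariance(self, k):
        """Scaling all energies by k scales fitted E_th and dE by k."""
        base = to.fit_damage_threshold(synthetic_curve(20.0, 3.0))
        scaled = to.fit_damage_threshold(synthetic_curve(20.0 * k, 3.0 * k))
        assert scaled.e_th_surface == pytest.approx(k * base.e_th_surface, rel=1e-4)
        assert scaled.delta_e == pytest.approx(k * base.delta_e, rel=1e-4)

    def test_non_identifiable_curves_rejected(self):
        flat0 = to.DamageCurve(150.0, (1, 2, 3, 4), (0, 1, 2, 3))
        with pytest.raises(to.NonIdentifiableError):
            to.fit_damage_threshold(flat0)
        flat100 = to.DamageCurve(150.0, (1, 2, 3, 4), (99, 99, 100, 100))
        with pytest.raises(to.NonIdentifiableError):
            to.fit_damage_threshold(flat100)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            to.DamageCurve(150.0, (1, 2, 3), (0, 50, 100))  # too few
        with pytest.raises(ValueError):
            to.DamageCurve(150.0, (1, 3, 2, 4), (0, 20, 80, 100))  # not increasing
        with pytest.raises(ValueError):
            to.DamageCurve(150.0, (1, 2, 3, 4), (0, 20, 80, 120))  # out of range


class TestAttenuationFit:
    def test_round_trip_recovery(self, paper_like_model):
        """Thresholds generated from the model refit to <=0.1%."""
        depths = [150.0, 300.0, 450.0, 600.0]
        pts = [(z, to.threshold_energy_at_depth(paper_like_model, z)) for z in depths]
        fit = to.fit_attenuation(pts, w0=paper_like_model.w0)
        assert fit.extinction_length == pytest.approx(270.3, rel=1e-3)
        assert fit.threshold_fluence == pytest.approx(1.04, rel=1e-3)

    def test_two_point_slope_identity(self):
        l_ext = 200.0
        pts = [(100.0, 5.0), (100.0 + l_ext, 5.0 * math.e)]
        fit = to.fit_attenuation(pts, w0=1.0)
        assert fit.extinction_length == pytest.approx(l_ext, rel=1e-9)

    def test_threshold_scale_moves_fluence_not_length(self, paper_like_model):
        depths = [150.0, 300.0, 450.0, 600.0]
        pts = [(z, to.threshold_energy_at_depth(paper_like_model, z)) for z in depths]
        k = 3.0
        scaled = to.fit_attenuation([(z, k * e) for z, e in pts], w0=paper_like_model.w0)
        base = to.fit_attenuation(pts, w0=paper_like_model.w0)
        assert scaled.extinction_length == pytest.approx(base.extinction_length, rel=1e-9)
        assert scaled.threshold_fluence == pytest.approx(k * base.threshold_fluence, rel=1e-9)

    def test_stderr_shrinks_with_replication(self, rng):
        """Log-normal replicate noise: s.e. drops roughly as 1/sqrt(n)."""
        depths = np.array([150.0, 300.0, 450.0, 600.0])
        model = to.AttenuationModel(270.3, 1.04, 0.662)
        clean = {z: to.threshold_energy_at_depth(model, z) for z in depths}

        def fit_with_reps(n_rep):
            pts = [
                (z, clean[z] * rng.lognormal(0.0, 0.1))
                for z in depths
                for _ in range(n_rep)
            ]
            return to.fit_attenuation(pts, w0=0.662).stderr_extinction

        few = np.mean([fit_with_reps(2) for _ in range(30)])
        many = np.mean([fit_with_reps(8) for _ in range(30)])
        assert many < few
        assert many == pytest.approx(few / 2.0, rel=0.35)

    def test_rank_deficiency_rejected(self):
        with pytest.raises(to.NonIdentifiableError):
            to.fit_attenuation([(150.0, 10.0), (150.0, 12.0)], w0=1.0)


class TestDepthPrediction:
    def test_paper_predictions(self, paper_like_model):
        """Focal 15 nJ, 25.7 nJ at 150 µm, 130 nJ at 600 µm, all within 10%."""
        assert to.threshold_energy_at_depth(paper_like_model, 0.0) == pytest.approx(15.0, rel=0.1)
        assert to.threshold_energy_at_depth(paper_like_model, 150.0) == pytest.approx(25.7, rel=0.1)
        assert to.threshold_energy_at_depth(paper_like_model, 600.0) == pytest.approx(130.0, rel=0.1)

    def test_log_linear_growth(self, paper_like_model):
        e0 = to.threshold_energy_at_depth(paper_like_model, 0.0)
        e1 = to.threshold_energy_at_depth(paper_like_model, 270.3)
        assert e1 == pytest.approx(math.e * e0, rel=1e-9)
        z = np.linspace(0, 900, 10)
        e = [to.threshold_energy_at_depth(paper_like_model, zi) for zi in z]
        assert np.all(np.diff(e) > 0)
        assert np.allclose(np.diff(np.log(e)), np.diff(z) / 270.3)

    def test_fluence_inverts_threshold(self, paper_like_model):
        for z in (0.0, 150.0, 600.0):
            e = to.threshold_energy_at_depth(paper_like_model, z)
            assert to.fluence_at_focus(e, z, paper_like_model) == pytest.approx(1.04, rel=1e-9)
        assert to.fluence_at_focus(2.0, 100.0, paper_like_model) == pytest.approx(
            2 * to.fluence_at_focus(1.0, 100.0, paper_like_model), rel=1e-9
        )


class TestThgFit:
    @staticmethod
    def profile(l_exts=(242.0,), breaks=(), z_max=600.0, doubling=150.0):
        z = np.arange(0.0, z_max + 1, 25.0)
        edges = [0.0, *breaks, np.inf]
        z_eff = np.zeros_like(z)
        for i, zi in enumerate(z):
            acc, z0 = 0.0, 0.0
            for seg, l in enumerate(l_exts):
                hi = min(zi, edges[seg + 1])
                if hi > z0:
                    acc += (hi - z0) / l
                    z0 = hi
            z_eff[i] = acc
        p = 2.0 ** np.floor(z / doubling)
        s = 1e4 * p**3 * np.exp(-3 * z_eff)
        return to.ThgProfile(tuple(z), tuple(s), tuple(p), tuple(breaks))

    def test_cortex_segment_recovery(self):
        fits = to.fit_thg_attenuation(self.profile())
        assert len(fits) == 1
        assert fits[0].extinction_length == pytest.approx(242.0, rel=1e-6)

    def test_two_segment_recovery(self):
        fits = to.fit_thg_attenuation(self.profile((242.0, 107.0), breaks=(600.0,), z_max=800.0))
        assert [f.extinction_length for f in fits] == [
            pytest.approx(242.0, rel=1e-6),
            pytest.approx(107.0, rel=1e-6),
        ]

    def test_power_schedule_divides_out(self):
        """Constant vs doubling power schedule: identical fitted length."""
        a = to.fit_thg_attenuation(self.profile(doubling=150.0))[0]
        b = to.fit_thg_attenuation(self.profile(doubling=1e9))[0]
        assert a.extinction_length == pytest.approx(b.extinction_length, rel=1e-9)

    def test_flat_profile_reports_infinite_length(self):
        z = tuple(np.arange(0.0, 200.0, 25.0))
        p = tuple(np.ones(len(z)))
        s = tuple(np.full(len(z), 5.0))
        fits = to.fit_thg_attenuation(to.ThgProfile(z, s, p))
        assert math.isinf(fits[0].extinction_length)

    def test_photon_order_convention(self):
        """With constant power, order 1 vs 3 rescales the length by exactly 3."""
        prof = self.profile(doubling=1e9)
        l3 = to.fit_thg_attenuation(prof, photon_order=3)[0].extinction_length
        l1 = to.fit_thg_attenuation(prof, photon_order=1)[0].extinction_length
        assert l3 == pytest.approx(3 * l1, rel=1e-9)

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            to.ThgProfile((0.0, 50.0, 25.0), (1, 1, 1), (1, 1, 1))
        with pytest.raises(ValueError):
            to.ThgProfile((0.0, 25.0, 50.0), (1, -1, 1), (1, 1, 1))
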