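"""Registration, dF/F, epoch statistics, tuning fit and selectivity indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from threephoton import calcium as ca

DIRS = np.asarray(ca.DEFAULT_DIRECTIONS, dtype=float)


class TestProtocol:
    def test_epochs_and_counts(self):
        p = ca.StimulusProtocol.generate(seed=0)
        assert p.n_presentations == 120
        assert p.frames_per_trial == 48
        counts = np.bincount(np.asarray(p.order))
        assert np.all(counts == 10)

    def test_invalid_epochs_rejected(self):
        with pytest.raises(ValueError):
            ca.StimulusProtocol(static_pre=4.0)  # no longer sums to 12

    def test_generate_is_seed_deterministic(self):
        assert ca.StimulusProtocol.generate(seed=5) == ca.StimulusProtocol.generate(seed=5)
        assert ca.StimulusProtocol.generate(seed=5) != ca.StimulusProtocol.generate(seed=6)


class TestRegistration:
    @staticmethod
    def texture(rng, ny=48, nx=40):
        from scipy.ndimage import gaussian_filter
        return gaussian_filter(rng.random((ny, nx)), 2.0) * 100

    def test_identical_frames_zero_shift(self, rng):
        frame = self.texture(rng)
        movie = np.stack([frame] * 5)
        registered, shifts = ca.register_translation(movie)
        assert np.all(shifts == 0)
        np.testing.assert_allclose(registered, movie)

    def test_known_translation_recovered(self, rng):
        frame = self.texture(rng)
        shifted = np.roll(frame, (3, -2), axis=(0, 1))
        movie = np.stack([frame] * 6 + [shifted])
        _, shifts = ca.register_translation(movie)
        assert tuple(shifts[-1]) == (-3, 2)
        assert np.all(shifts[:-1] == 0)

    def test_noise_shifts_bounded_by_cap(self, rng):
        movie = rng.random((6, 40, 40))
        _, shifts = ca.register_translation(movie, max_shift_frac=0.1)
        assert np.all(np.abs(shifts) <= 4)

    def test_single_frame_identity_with_warning(self, rng):
        movie = rng.random((1, 16, 16))
        with pytest.warns(UserWarning):
            registered, shifts = ca.register_translation(movie)
        assert np.all(shifts == 0)
        np.testing.assert_allclose(registered, movie)


class TestDff:
    def test_constant_trace_all_zero(self):
        assert np.all(ca.compute_dff(np.full(500, 80.0)) == 0.0)

    def test_two_level_trace_mode_is_baseline(self, rng):
        raw = np.full(1000, 100.0)
        raw[rng.choice(1000, 100, replace=False)] = 200.0
        dff = ca.compute_dff(raw)
        assert dff.max() == pytest.approx(1.0, abs=0.05)
        assert np.median(dff) == pytest.approx(0.0, abs=0.05)

    def test_shift_equivariance_of_mode(self, rng):
        raw = 100.0 + 10.0 * rng.standard_normal(2000)
        f0 = ca._histogram_mode(raw)
        assert ca._histogram_mode(raw + 50.0) == pytest.approx(f0 + 50.0, abs=1.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            ca.compute_dff(np.full(100, -5.0) + np.r_[np.zeros(99), 1.0])


class TestEpochResponses:
    def test_zero_trace_gives_zero_pairs(self):
        p = ca.StimulusProtocol.generate(seed=1)
        static, drift = ca.epoch_responses(np.zeros(p.n_frames), p)
        assert np.all(static == 0) and np.all(drift == 0)

    def test_boxcar_lands_in_drift_epoch_of_its_direction(self):
        p = ca.StimulusProtocol.generate(seed=2)
        dff = np.zeros(p.n_frames)
        k = 17  # an arbitrary presentation
        fpt, fr = p.frames_per_trial, p.frame_rate
        pre_f, drift_f = int(3 * fr), int(6 * fr)
        dff[k * fpt + pre_f : k * fpt + pre_f + drift_f] = 0.8
        static, drift = ca.epoch_responses(dff, p)
        d_idx = p.order[k]
        trial = list(p.order[: k + 1]).count(d_idx) - 1
        assert drift[d_idx, trial] == pytest.approx(0.8)
        assert static[d_idx, trial] == 0.0
        assert drift.sum() == pytest.approx(0.8)

    def test_grouping_invariant_to_presentation_order(self, rng):
        """Same responses under a different recorded order group identically."""
        p1 = ca.StimulusProtocol.generate(seed=3)
        p2 = ca.StimulusProtocol.generate(seed=4)
        amps = rng.uniform(0, 1, 12)
        def render(p):
            dff = np.zeros(p.n_frames)
            fpt, fr = p.frames_per_trial, p.frame_rate
            pre_f, drift_f = int(3 * fr), int(6 * fr)
            for k, d in enumerate(p.order):
                dff[k * fpt + pre_f : k * fpt + pre_f + drift_f] = amps[d]
            return ca.epoch_responses(dff, p)
        s1, d1 = render(p1)
        s2, d2 = render(p2)
        np.testing.assert_allclose(np.sort(d1, axis=1), np.sort(d2, axis=1))

    def test_length_mismatch_rejected(self):
        p = ca.StimulusProtocol.generate(seed=5)
        with pytest.raises(ValueError):
            ca.epoch_responses(np.zeros(10), p)


class TestResponsiveness:
    def test_equal_epochs_unresponsive(self):
        static = np.zeros((12, 10))
        responsive, pvals = ca.classify_visually_responsive(static, static)
        assert not responsive
        assert np.all(pvals == 1.0)

    def test_strong_single_direction_is_responsive(self, rng):
        """Differences with mean 1, sd 0.1 over 10 trials: t ~ 31.6, p << alpha."""
        static = np.zeros((12, 10))
        drift = np.zeros((12, 10))
        drift[3] = 1.0 + 0.1 * rng.standard_normal(10)
        responsive, pvals = ca.classify_visually_responsive(static, drift)
        assert responsive
        assert pvals[3] < 1e-6
        # cross-check against the closed-form paired t statistic
        d = drift[3]
        t = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert pvals[3] == pytest.approx(2 * stats.t.sf(abs(t), df=9), rel=1e-9)

    def test_alpha_zero_never_responsive(self, rng):
        drift = rng.standard_normal((12, 10))
        responsive, _ = ca.classify_visually_responsive(np.zeros((12, 10)), drift, alpha=0.0)
        assert not responsive

    def test_constant_nonzero_difference_is_significant(self):
        static = np.zeros((1, 10))
        drift = np.ones((1, 10))
        responsive, pvals = ca.classify_visually_responsive(static, drift)
        assert responsive and pvals[0] == 0.0


class TestTuningFit:
    def test_exact_recovery_from_generative_curve(self):
        y = ca.tuning_model(DIRS, 90.0, 25.0, 0.1, 1.0, 0.5)
        fit = ca.fit_tuning(y, DIRS)
        assert fit.theta_p == pytest.approx(90.0, abs=1e-4)
        assert fit.sigma == pytest.approx(25.0, rel=1e-4)
        assert fit.r0 == pytest.approx(0.1, abs=1e-5)
        assert fit.rp == pytest.approx(1.0, abs=1e-5)
        assert fit.rn == pytest.approx(0.5, abs=1e-5)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert np.max(np.abs(fit.curve(DIRS) - y)) < 1e-6

    def test_rotation_equivariance(self):
        y = ca.tuning_model(DIRS, 60.0, 30.0, 0.0, 1.0, 0.3)
        y_rot = ca.tuning_model(DIRS, 90.0, 30.0, 0.0, 1.0, 0.3)
        f, f_rot = ca.fit_tuning(y, DIRS), ca.fit_tuning(y_rot, DIRS)
        assert ca.wrap_angle(f_rot.theta_p - f.theta_p - 30.0) == pytest.approx(0.0, abs=1e-3)

    def test_flat_curve_degenerate(self):
        fit = ca.fit_tuning(np.full(12, 0.7), DIRS)
        assert np.isnan(fit.r_squared)
        assert not ca.classify_orientation_selective(fit)

    def test_os_threshold_strict(self):
        good = ca.TuningFitResult(0, 25, 0, 1, 0, r_squared=1.0)
        border = ca.TuningFitResult(0, 25, 0, 1, 0, r_squared=0.6)
        assert ca.classify_orientation_selective(good)
        assert not ca.classify_orientation_selective(border)

    def test_non_finite_inputs_rejected(self):
        y = np.full(12, 0.5)
        y[3] = np.nan
        with pytest.raises(ValueError):
            ca.fit_tuning(y, DIRS)


def fit_for(y):
    return ca.fit_tuning(np.asarray(y, dtype=float), DIRS)


class TestSelectivityIndices:
    def test_two_opposite_lobes(self):
        """Equal response at 0 and 180 only: gOSI=1, OSI=1, DSI=0."""
        y = np.zeros(12)
        y[0] = y[6] = 1.0
        idx = ca.selectivity_indices(y, fit_for(y), DIRS)
        assert idx.gosi == pytest.approx(1.0, abs=1e-9)
        assert idx.osi == pytest.approx(1.0, abs=0.01)
        assert idx.dsi == pytest.approx(0.0, abs=0.01)

    def test_uniform_responses_all_zero(self):
        y = np.full(12, 0.5)
        idx = ca.selectivity_indices(y, fit_for(y), DIRS)
        assert idx.gosi == pytest.approx(0.0, abs=1e-12)
        assert idx.osi == pytest.approx(0.0, abs=0.01)
        assert idx.dsi == pytest.approx(0.0, abs=0.01)

    def test_single_direction_dsi_one(self):
        y = np.zeros(12)
        y[0] = 1.0
        idx = ca.selectivity_indices(y, fit_for(y), DIRS)
        assert idx.dsi == pytest.approx(1.0, abs=0.01)

    def test_zero_total_response_sentinel(self):
        y = np.zeros(12)
        idx = ca.selectivity_indices(y, ca.TuningFitResult(0, 25, 0, 0, 0, np.nan), DIRS)
        assert np.isnan(idx.gosi) and np.isnan(idx.osi) and np.isnan(idx.dsi)

    @given(st.lists(st.floats(0.0, 10.0), min_size=12, max_size=12), st.floats(0.1, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_scale_invariance(self, y, k):
        y = np.asarray(y)
        if y.sum() == 0:
            return
        fit = ca.TuningFitResult(
            theta_p=float(DIRS[np.argmax(y)]), sigma=30.0, r0=0.0,
            rp=float(y.max()), rn=0.0, r_squared=1.0,
        )
        a = ca.selectivity_indices(y, fit, DIRS)
        b = ca.selectivity_indices(k * y, ca.TuningFitResult(
            fit.theta_p, fit.sigma, 0.0, k * fit.rp, 0.0, 1.0), DIRS)
        assert 0.0 <= a.gosi <= 1.0 + 1e-12
        assert b.gosi == pytest.approx(a.gosi, abs=1e-9)
        assert b.osi == pytest.approx(a.osi, abs=1e-9)
        assert b.dsi == pytest.approx(a.dsi, abs=1e-9)

    def test_gosi_equals_one_only_for_single_orientation(self):
        y = np.zeros(12)
        y[0], y[6] = 1.0, 0.4  # theta and theta+180 only
        assert ca.selectivity_indices(y, fit_for(y), DIRS).gosi == pytest.approx(1.0)
        y[3] = 0.2  # any off-orientation response breaks equality
        assert ca.selectivity_indices(y, fit_for(y), DIRS).gosi < 1.0


class TestLayerAssignment:
    @pytest.mark.parametrize(
        "depth, label",
        [
            (50.0, "L1"),
            (200.0, "L2/3"),
            (400.0, "L4"),
            (500.0, "L5"),
            (700.0, "L6"),
            (800.0, ca.SUBPLATE_LABEL),
            (350.0, "L4"),  # boundary belongs to the deeper layer
            (750.0, ca.SUBPLATE_LABEL),
        ],
    )
    def test_default_table(self, depth, label):
        assert ca.assign_layer(depth) == label

    def test_custom_boundaries(self):
        assert ca.assign_layer(120.0, boundaries=((150.0, "upper"),)) == "upper"
        with pytest.raises(ValueError):
            ca.assign_layer(-1.0)
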