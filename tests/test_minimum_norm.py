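"""Minimum-norm / dSPM inverse operator properties."""

import numpy as np
import pytest

import retinomeg as rm
from retinomeg.beamformer import TrialContrast
from retinomeg.minimum_norm import (
    RankDeficiencyError,
    dspm_map,
    estimate_noise_covariance,
    make_inverse_operator,
    trial_values,
)


class TestNoiseCovariance:
    def test_white_noise_recovers_unit_diagonal(self, atlas, leadfield):
        """Generator with unit-variance uncorrelated noise -> diagonal ~ 1."""
        white = rm.NoiseModel(sd_mag=1.0, sd_grad=1.0, nugget=1.0)
        data = rm.simulate_subject(
            [(rm.StimulusSpec("ring", ecc=1), 100)], atlas, leadfield,
            evoked=rm.EvokedModel(frp_amplitude=0.0, steady_state_amplitude=0.0),
            noise=white, seed=11,
        )
        cov = estimate_noise_covariance(data, (-500.0, 0.0), shrinkage=0.0)
        assert np.allclose(np.diag(cov.matrix), 1.0, rtol=0.1)

    def test_full_shrinkage_is_diagonal(self, quadrant_data):
        cov = estimate_noise_covariance(quadrant_data, (-500.0, 0.0), 1.0)
        off = cov.matrix - np.diag(np.diag(cov.matrix))
        assert np.abs(off).max() == 0.0

    def test_symmetric(self, noise_cov):
        assert np.array_equal(noise_cov.matrix, noise_cov.matrix.T)

    def test_window_outside_epoch(self, quadrant_data):
        with pytest.raises(Exception, match="window"):
            estimate_noise_covariance(quadrant_data, (-1600.0, 0.0))

    def test_singular_covariance_raises(self, leadfield):
        from retinomeg.minimum_norm import NoiseCovariance

        n = leadfield.gain.shape[0]
        bad = NoiseCovariance(np.zeros((n, n)), (-500.0, 0.0), 100, 0.0)
        with pytest.raises(RankDeficiencyError, match="rank deficient"):
            make_inverse_operator(leadfield, bad)


class TestInverseOperator:
    def test_zero_depth_equals_iid_kernel(self, leadfield, noise_cov):
        op0 = make_inverse_operator(leadfield, noise_cov, depth_exponent=0.0)
        # the IID pathway builds its kernel the same way at p=0
        op_iid = make_inverse_operator(leadfield, noise_cov, 0.0)
        assert np.array_equal(op0.kernel, op_iid.kernel)
        op_depth = make_inverse_operator(leadfield, noise_cov, 0.8)
        rel = np.abs(op_depth.kernel - op0.kernel).max() / np.abs(op0.kernel).max()
        assert rel > 1e-3  # depth weighting genuinely changes the kernel

    def test_pseudoinverse_limit(self, rng):
        """Square well-conditioned gain, lambda2 -> 0, p = 0: W L -> I."""
        from retinomeg.forward import LeadField
        from retinomeg.minimum_norm import NoiseCovariance

        n = 12
        gain = rng.standard_normal((n, n)) + 5 * np.eye(n)
        lf = LeadField(gain, "fixed", None, None)
        cov = NoiseCovariance(np.eye(n), (-500.0, 0.0), 1000, 0.0)
        op = make_inverse_operator(lf, cov, 0.0, lambda2=1e-10)
        assert np.allclose(op.kernel @ gain, np.eye(n), atol=1e-6)

    def test_depth_weighting_reduces_amplitude_bias(self, space, sensors):
        """With p = 0.8 the deep/superficial recovered-amplitude ratio is
        closer to 1 than with p = 0 (the bias depth weighting counters)."""
        from retinomeg.minimum_norm import NoiseCovariance

        lf = rm.compute_lead_field(space, sensors)
        norms = np.linalg.norm(space.positions, axis=1)
        main = (space.df["sheet"] == "main").to_numpy()
        deep = np.flatnonzero(main)[np.argmin(norms[main])]
        shallow = np.flatnonzero(main)[np.argmax(norms[main])]
        cov = NoiseCovariance(np.eye(lf.gain.shape[0]), (-500.0, 0.0), 1000, 0.0)

        def ratio(p):
            op = make_inverse_operator(lf, cov, p)
            rec = op.kernel @ lf.gain  # unit-noise whitener: kernel acts on raw
            return (rec[deep, deep] / rec[shallow, shallow])

        assert abs(ratio(0.8) - 1) < abs(ratio(0.0) - 1)

    def test_depth_bias_of_peak_location_decreases_with_p(
        self, space, sensors, leadfield
    ):
        """On a fixed deep source, the estimate's energy centroid sits deeper
        (closer to truth) as p goes 0 -> 0.8."""
        from retinomeg.minimum_norm import NoiseCovariance

        norms = np.linalg.norm(space.positions, axis=1)
        main = np.flatnonzero((space.df["sheet"] == "main").to_numpy())
        deep = main[np.argmin(norms[main])]
        y = leadfield.gain[:, deep]
        cov = NoiseCovariance(np.eye(len(y)), (-500.0, 0.0), 1000, 0.0)

        def top_depth(p):
            op = make_inverse_operator(leadfield, cov, p)
            est = np.abs(op.kernel @ y)
            top = np.argsort(est)[-4:]
            return norms[top].mean()

        assert top_depth(0.8) < top_depth(0.0)


class TestDspmMap:
    def test_noise_only_f_calibrated(self, atlas, leadfield):
        """Mean dSPM F over vertices ~ 1 for source-free data."""
        data = rm.simulate_subject(
            [(rm.StimulusSpec("ring", ecc=1), 100)], atlas, leadfield,
            evoked=rm.EvokedModel(frp_amplitude=0.0, steady_state_amplitude=0.0),
            seed=21,
        )
        filt = rm.bandpass(data, 1.0, 40.0)
        cov = estimate_noise_covariance(filt, (-500.0, 0.0), 0.1)
        op = make_inverse_operator(leadfield, cov, 0.8)
        est = dspm_map(op, filt, (73.0, 93.0))
        assert est.values.mean() == pytest.approx(1.0, rel=0.3)

    def test_peak_recovers_active_patch(self, atlas, leadfield,
                                        quadrant_filtered, noise_cov):
        op = make_inverse_operator(leadfield, noise_cov, 0.8)
        stim = rm.StimulusSpec("quadrant", quadrant_pos="UR")
        est = dspm_map(op, quadrant_filtered, (73.0, 93.0),
                       trials=quadrant_filtered.trials_for("UR"))
        idx, _ = rm.stimulus_to_patch(stim, atlas)
        d = np.linalg.norm(
            atlas.space.positions[np.argmax(est.values)]
            - atlas.space.positions[idx], axis=1,
        ).min()
        assert d <= atlas.space.spacing

    def test_quadratic_in_amplitude(self, quadrant_filtered, leadfield, noise_cov):
        """Scaling the evoked response by 10 (baseline untouched) scales F
        by 100."""
        op = make_inverse_operator(leadfield, noise_cov, 0.8)
        est1 = dspm_map(op, quadrant_filtered, (73.0, 93.0))
        arr = quadrant_filtered.data.copy()
        post = quadrant_filtered.times_ms >= 0
        arr[:, :, post] *= 10.0
        est2 = dspm_map(op, quadrant_filtered.copy_with(data=arr), (73.0, 93.0))
        assert np.allclose(est2.values, 100.0 * est1.values, rtol=1e-9)

    def test_invariant_to_noise_cov_rescaling(self, quadrant_filtered,
                                              leadfield, noise_cov):
        from dataclasses import replace

        op1 = make_inverse_operator(leadfield, noise_cov, 0.8)
        cov5 = replace(noise_cov, matrix=5.0 * noise_cov.matrix)
        op2 = make_inverse_operator(leadfield, cov5, 0.8)
        f1 = dspm_map(op1, quadrant_filtered, (73.0, 93.0)).values
        f2 = dspm_map(op2, quadrant_filtered, (73.0, 93.0)).values
        assert np.allclose(f1, f2, rtol=1e-8)

    def test_whitened_space_equivalence(self, rng):
        """With C_n = sigma^2 I the whitened-kernel pathway equals the
        explicit unwhitened minimum-norm formula."""
        from retinomeg.forward import LeadField
        from retinomeg.minimum_norm import NoiseCovariance

        n_sens, n_src = 15, 40
        gain = rng.standard_normal((n_sens, n_src))
        sigma2 = 3.7
        lf = LeadField(gain, "fixed", None, None)
        cov = NoiseCovariance(sigma2 * np.eye(n_sens), (-500.0, 0.0), 1000, 0.0)
        lam2 = 1.0 / 9.0
        op = make_inverse_operator(lf, cov, 0.0, lam2)
        y = rng.standard_normal(n_sens)
        ours = op.kernel @ (op.whitener @ y)
        # unwhitened algebra with the same trace-normalized weighting
        g = gain / np.sqrt(sigma2)
        r = np.full(n_src, 1.0)
        r *= n_sens / np.trace((g * r) @ g.T)
        manual = (r[:, None] * gain.T) @ np.linalg.inv(
            (gain * r) @ gain.T + lam2 * sigma2 * np.eye(n_sens)
        ) @ y
        assert np.allclose(ours, manual, rtol=1e-8)

    def test_window_outside_epoch(self, quadrant_filtered, leadfield, noise_cov):
        op = make_inverse_operator(leadfield, noise_cov)
        with pytest.raises(Exception, match="window"):
            dspm_map(op, quadrant_filtered, (990.0, 1010.0))


class TestIidMap:
    def test_localizes_quadrant_above_chance(self, atlas, leadfield,
                                             quadrant_filtered, noise_cov):
        contrast = TrialContrast("stimulus_vs_other_stimuli", "UR")
        est = rm.iid_map(quadrant_filtered, leadfield, noise_cov, contrast)
        reg = rm.expected_subregion(
            rm.StimulusSpec("quadrant", quadrant_pos="UR"), atlas, "angular"
        )
        active = rm.threshold_active(est, 5.0)
        rec = rm.localization_accuracy(active, atlas,
                                       rm.StimulusSpec("quadrant", quadrant_pos="UR"),
                                       "angular")
        assert rec.percent > 25.0
        assert reg.expected[np.argmax(est.values)]

    def test_sensor_relabeling_invariance(self, quadrant_filtered, leadfield,
                                          noise_cov, rng):
        """Permuting sensors (data rows, gain rows, covariance) leaves the
        source map unchanged."""
        from dataclasses import replace

        from retinomeg.forward import LeadField

        contrast = TrialContrast("stimulus_vs_other_stimuli", "UL")
        est = rm.iid_map(quadrant_filtered, leadfield, noise_cov, contrast)
        perm = rng.permutation(leadfield.gain.shape[0])
        lf_p = LeadField(leadfield.gain[perm], "fixed", leadfield.sensors,
                         leadfield.space)
        cov_p = replace(noise_cov, matrix=noise_cov.matrix[np.ix_(perm, perm)])
        data_p = quadrant_filtered.copy_with(
            data=quadrant_filtered.data[:, perm, :]
        )
        est_p = rm.iid_map(data_p, lf_p, cov_p, contrast)
        assert np.allclose(est.values, est_p.values, rtol=1e-6, atol=1e-9)
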