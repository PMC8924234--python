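"""Monotonic and tuned response models: noiseless identifiability,
Monte-Carlo parameter recovery, cross-validation semantics."""

import numpy as np
import pytest

from numspec.response_models import (
    BASELINE_NUMEROSITY,
    CYCLE_LEN,
    HRFParams,
    MonotonicFit,
    StimulusSequence,
    build_sequence,
    choose_scaling,
    cross_validate,
    default_design_labels,
    default_mu_grid,
    default_sigma_grid,
    fit_monotonic,
    fit_tuned,
    hrf_kernel,
    pool_configurations,
    predicted_timecourse,
    tuned_amplitudes,
)
from numspec.simulate import SyntheticVoxelSpec, noiseless_prediction, simulate_voxel


class TestDesign:
    def test_cycle_structure(self):
        labels = default_design_labels()
        assert labels.size == CYCLE_LEN == 44
        assert (labels == BASELINE_NUMEROSITY).sum() == 16
        assert list(labels[:14]) == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6, 7, 7]
        assert list(labels[22:36]) == [7, 7, 6, 6, 5, 5, 4, 4, 3, 3, 2, 2, 1, 1]

    def test_build_sequence_identity_and_log(self):
        labels = default_design_labels()
        seq = build_sequence({int(n): float(n) for n in np.unique(labels)})
        np.testing.assert_array_equal(seq.values, labels.astype(float))
        seq_log = build_sequence({int(n): np.log(n) for n in np.unique(labels)})
        np.testing.assert_allclose(seq_log.values, np.log(labels))

    def test_missing_numerosity_rejected(self):
        with pytest.raises(KeyError):
            build_sequence({n: float(n) for n in range(1, 8)})  # lacks 20


class TestHrf:
    def test_canonical_shape(self):
        h = hrf_kernel()
        t = np.arange(h.size) * 2.1
        assert h.max() == pytest.approx(1.0)
        assert 4.0 <= t[np.argmax(h)] <= 7.0
        assert h.min() < 0  # undershoot
        assert t[np.argmin(h)] > t[np.argmax(h)]

    def test_truncation_keeps_l1_mass(self):
        short = hrf_kernel(HRFParams(duration=30.0))
        long = hrf_kernel(HRFParams(duration=60.0))
        lost = np.abs(long[short.size:]).sum()
        assert lost < 0.01 * np.abs(long).sum()

    def test_half_tr_sampling_interleaves(self):
        # every other fine sample falls on the coarse grid; each kernel
        # is unit-peak at its own sampling, so compare up to scale
        coarse = hrf_kernel(tr_s=2.1)
        fine = hrf_kernel(tr_s=1.05)
        sub = fine[::2]
        np.testing.assert_allclose(sub / sub.max(), coarse, rtol=1e-12)


class TestMonotonicFit:
    def test_noiseless_recovery(self):
        labels = default_design_labels()
        seq = build_sequence({int(n): float(n) for n in np.unique(labels)})
        pred = predicted_timecourse(np.log(seq.values))
        y = 3.5 * pred + 1.25
        fit = fit_monotonic(y, seq, "log")
        assert fit.beta == pytest.approx(3.5, abs=1e-6)
        assert fit.baseline == pytest.approx(1.25, abs=1e-6)
        assert fit.r2_fit == pytest.approx(1.0, abs=1e-9)

    def test_glm_matches_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        labels = default_design_labels()
        seq = build_sequence({int(n): float(n) for n in np.unique(labels)})
        pred = predicted_timecourse(np.log(seq.values))
        y = 2.0 * pred + 0.5 + 0.3 * rng.standard_normal(CYCLE_LEN)
        fit = fit_monotonic(y, seq, "log")
        betas = np.linspace(fit.beta - 0.5, fit.beta + 0.5, 41)
        bases = np.linspace(fit.baseline - 0.5, fit.baseline + 0.5, 41)
        sse = np.array([[((y - (b0 + b1 * pred)) ** 2).sum()
                         for b1 in betas] for b0 in bases])
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert bases[i] == pytest.approx(fit.baseline, abs=0.03)
        assert betas[j] == pytest.approx(fit.beta, abs=0.03)

    def test_beta_recovery_at_snr_one(self):
        """Over 200 simulated voxels at SNR 1, the mean estimated beta
        must sit within 3 standard errors of the generating value."""
        rng = np.random.default_rng(21)
        labels = default_design_labels()
        seq = build_sequence({int(n): float(n) for n in np.unique(labels)})
        pred = predicted_timecourse(np.log(seq.values))
        noise_sd = pred.std()  # SNR 1
        betas = []
        for _ in range(200):
            y = 1.0 * pred + noise_sd * rng.standard_normal(CYCLE_LEN)
            betas.append(fit_monotonic(y, seq, "log").beta)
        betas = np.array(betas)
        se = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean() - 1.0) < 3 * se

    def test_zero_variance_series_rejected(self):
        labels = default_design_labels()
        seq = build_sequence({int(n): float(n) for n in np.unique(labels)})
        with pytest.raises(ValueError):
            fit_monotonic(np.ones(CYCLE_LEN), seq)


class TestTunedFit:
    def test_noiseless_mu_recovery_within_grid_step(self):
        labels = default_design_labels()
        mu_grid = default_mu_grid()
        y = predicted_timecourse(tuned_amplitudes(labels, 3.0, 0.3))
        fit = fit_tuned(y, labels)
        step = np.diff(np.log(mu_grid)).max()
        assert abs(np.log(fit.mu) - np.log(3.0)) <= step + 1e-12
        assert fit.r2_fit > 0.999

    def test_mu_recovery_rmse_at_snr_one(self):
        """log-mu recovery RMSE below 0.5 log-units over 200 voxels."""
        rng = np.random.default_rng(31)
        labels = default_design_labels()
        errs = []
        for _ in range(200):
            mu = rng.uniform(1.5, 6.0)
            sig = rng.uniform(0.2, 0.8)
            signal = predicted_timecourse(tuned_amplitudes(labels, mu, sig))
            y = signal + signal.std() * rng.standard_normal(CYCLE_LEN)
            fit = fit_tuned(y, labels)
            errs.append(np.log(fit.mu) - np.log(mu))
        rmse = np.sqrt(np.mean(np.square(errs)))
        assert rmse < 0.5

    def test_monotonic_input_pins_mu_at_grid_boundary(self):
        labels = default_design_labels()
        y = predicted_timecourse(np.log(labels.astype(float)))
        fit = fit_tuned(y, labels)
        mu_grid = default_mu_grid()
        assert fit.mu in (pytest.approx(mu_grid[0]), pytest.approx(mu_grid[-1]))

    def test_empty_grid_rejected(self):
        labels = default_design_labels()
        with pytest.raises(ValueError):
            fit_tuned(np.zeros(CYCLE_LEN), labels, mu_grid=np.array([]))


class TestChooseScaling:
    def _population(self, rng, mode, n=30):
        labels = default_design_labels()
        seq = build_sequence({int(x): float(x) for x in np.unique(labels)})
        vals = np.log(seq.values) if mode == "log" else seq.values
        pred = predicted_timecourse(vals)
        fits_log, fits_lin = [], []
        for _ in range(n):
            y = pred + 0.5 * pred.std() * rng.standard_normal(CYCLE_LEN)
            fits_log.append(fit_monotonic(y, seq, "log"))
            fits_lin.append(fit_monotonic(y, seq, "linear"))
        return fits_log, fits_lin

    def test_log_generated_population_chooses_log(self, rng):
        assert choose_scaling(*self._population(rng, "log")) == "log"

    def test_linear_generated_population_chooses_linear(self, rng):
        assert choose_scaling(*self._population(rng, "linear")) == "linear"

    def test_tie_goes_to_log(self):
        f = [MonotonicFit(1.0, 0.0, "log", 0.5)] * 3
        g = [MonotonicFit(1.0, 0.0, "linear", 0.5)] * 3
        assert choose_scaling(f, g) == "log"


class TestCrossValidation:
    def test_identical_halves_reproduce_fit(self):
        labels = default_design_labels()
        seq = build_sequence({int(n): float(n) for n in np.unique(labels)})
        y = 2.0 * predicted_timecourse(np.log(seq.values)) + 1.0
        fit = fit_monotonic(y, seq, "log")
        r2cv = cross_validate(fit, y, seq)
        assert r2cv == pytest.approx(fit.r2_fit, abs=1e-12)

    def test_noise_degrades_cv_on_average(self):
        rng = np.random.default_rng(41)
        labels = default_design_labels()
        seq = build_sequence({int(n): float(n) for n in np.unique(labels)})
        pred = predicted_timecourse(np.log(seq.values))
        gaps = []
        for _ in range(50):
            a = pred + pred.std() * rng.standard_normal(CYCLE_LEN)
            b = pred + pred.std() * rng.standard_normal(CYCLE_LEN)
            fit = fit_monotonic(a, seq, "log")
            gaps.append(fit.r2_fit - cross_validate(fit, b, seq))
        assert np.mean(gaps) > 0

    def test_opposite_sign_half_clamps_beta(self):
        labels = default_design_labels()
        seq = build_sequence({int(n): float(n) for n in np.unique(labels)})
        pred = predicted_timecourse(np.log(seq.values))
        fit = fit_monotonic(2.0 * pred + 1.0, seq, "log")
        r2cv = cross_validate(fit, -2.0 * pred + 1.0, seq)
        assert r2cv <= 0.0 + 1e-12


class TestPooling:
    def test_equal_variances_reduce_to_mean(self):
        assert pool_configurations([0.2, 0.4], [3.0, 3.0]) == pytest.approx(0.3)

    def test_large_variance_configuration_dominates(self):
        pooled = pool_configurations([0.9, 0.1], [10.0, 1.0])
        assert pooled == pytest.approx((0.9 * 10 + 0.1) / 11)

    def test_matches_concatenated_residual_oracle(self):
        rng = np.random.default_rng(51)
        labels = default_design_labels()
        seq = build_sequence({int(n): float(n) for n in np.unique(labels)})
        pred = predicted_timecourse(np.log(seq.values))
        r2s, variances, sse_total, sst_total = [], [], 0.0, 0.0
        for amp in (1.0, 4.0):
            y = amp * pred + amp * 0.6 * pred.std() * rng.standard_normal(CYCLE_LEN)
            fit = fit_monotonic(y, seq, "log")
            sst = ((y - y.mean()) ** 2).sum()
            r2s.append(fit.r2_fit)
            variances.append(sst)
            sse_total += (1 - fit.r2_fit) * sst
            sst_total += sst
        oracle = 1 - sse_total / sst_total
        assert pool_configurations(r2s, variances) == pytest.approx(oracle,
                                                                    rel=1e-12)
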