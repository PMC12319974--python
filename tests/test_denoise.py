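"""Thermal denoising: noise estimation, the Monte-Carlo singular-value edge,
hard thresholding, and full-run behavior."""

import numpy as np
import pytest

import mepfm as m
from mepfm.denoise import THEORETICAL_FACTOR


class TestNoiseEstimate:
    def test_sigma_recovered_from_noise_frames(self, adult_run):
        _, series, _, _ = adult_run
        est = m.estimate_noise_sigma(series)
        assert est.source == "noise_frames"
        assert abs(est.sigma - 25.0) / 25.0 < 0.02

    def test_magnitude_only_rayleigh_route(self, adult_run):
        _, series, _, _ = adult_run
        mag_only = m.MultiEchoSeries(
            magnitude=series.magnitude.copy(),
            echo_times=series.echo_times,
            tr=series.tr,
            n_noise_frames=series.n_noise_frames,
        )
        est = m.estimate_noise_sigma(mag_only)
        assert abs(est.sigma - 25.0) / 25.0 < 0.02

    def test_theoretical_fallback_records_factor(self, adult_run):
        _, series, _, _ = adult_run
        est = m.estimate_noise_sigma(series, theoretical=True)
        assert est.source == "theoretical"
        assert est.theoretical_factor == pytest.approx(1 / np.sqrt(2))

    def test_no_noise_frames_requires_explicit_fallback(self, adult_run):
        _, series, _, _ = adult_run
        sig = series.signal_frames()
        with pytest.raises(ValueError, match="noise frames"):
            m.estimate_noise_sigma(sig)

    def test_zero_variance_noise_frames_degenerate(self):
        mag = np.ones((1, 6, 6, 6, 10))
        s = m.MultiEchoSeries(
            magnitude=mag, echo_times=(30.0,), tr=1.0, n_noise_frames=3
        )
        s.magnitude[..., -3:] = 0.0
        with pytest.raises(ValueError):
            m.estimate_noise_sigma(s)


class TestSingularValueEdge:
    def test_matches_asymptotic_edge(self):
        # per-channel SD 1 => entry SD sqrt(2); edge = sqrt(2)(sqrt(m)+sqrt(n))
        for mm, nn in [(100, 100), (125, 50), (216, 80)]:
            tau = m.noise_singular_value_edge(mm, nn, 1.0, mc_draws=10, seed=0)
            edge = np.sqrt(2.0) * (np.sqrt(mm) + np.sqrt(nn))
            assert abs(tau - edge) / edge < 0.05

    def test_zero_sigma_gives_zero(self):
        assert m.noise_singular_value_edge(50, 50, 0.0) == 0.0

    def test_scale_equivariance(self):
        t1 = m.noise_singular_value_edge(60, 40, 1.5, mc_draws=5, seed=3)
        t2 = m.noise_singular_value_edge(60, 40, 3.0, mc_draws=5, seed=3)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_deterministic_given_seed(self):
        a = m.noise_singular_value_edge(50, 30, 2.0, mc_draws=4, seed=9)
        b = m.noise_singular_value_edge(50, 30, 2.0, mc_draws=4, seed=9)
        assert a == b

    def test_rejects_bad_args(self):
        with pytest.raises(ValueError):
            m.noise_singular_value_edge(1, 50, 1.0)
        with pytest.raises(ValueError):
            m.noise_singular_value_edge(50, 50, 1.0, mc_draws=0)


class TestDenoisePatch:
    def test_strong_low_rank_signal_preserved(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal((125, 1))
        v = rng.standard_normal((1, 50))
        x = (100.0 * u @ v).astype(complex)
        tau = m.noise_singular_value_edge(125, 50, 1.0, mc_draws=5, seed=0)
        out = m.denoise_patch(x, tau)
        assert np.linalg.norm(out - x) / np.linalg.norm(x) < 1e-10

    def test_pure_noise_mostly_removed_at_edge(self):
        rng = np.random.default_rng(1)
        tau = m.noise_singular_value_edge(125, 50, 1.0, mc_draws=20, seed=2)
        kept = []
        for _ in range(100):
            g = rng.standard_normal((125, 50)) + 1j * rng.standard_normal((125, 50))
            kept.append(np.linalg.norm(m.denoise_patch(g, tau)) / np.linalg.norm(g))
        assert np.mean(kept) < 0.15

    def test_tau_zero_is_identity(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((20, 10)).astype(complex)
        assert np.array_equal(m.denoise_patch(x, 0.0), x)

    def test_nonfinite_rejected(self):
        x = np.full((4, 4), np.nan, dtype=complex)
        with pytest.raises(ValueError):
            m.denoise_patch(x, 1.0)


class TestNordicRun:
    def test_tsnr_gain_on_noisy_run(self, adult_run, denoised_adult_run, small_net):
        _, series, _, _ = adult_run
        den, _ = denoised_adult_run
        t2_raw = m.fit_t2star(series, mask=small_net.brain_mask)
        t2_den = m.fit_t2star(den, mask=small_net.brain_mask)
        tsnr_raw = m.tsnr_map(m.optimal_combine(series, t2_raw))
        tsnr_den = m.tsnr_map(m.optimal_combine(den, t2_den))
        gm = small_net.gray_mask
        gain = tsnr_den.values[gm].mean() / tsnr_raw.values[gm].mean() - 1
        assert gain > 0.10
        assert (tsnr_den.values[gm] > tsnr_raw.values[gm]).mean() > 0.95

    def test_noiseless_input_passes_through(self, noiseless_run):
        _, series, _, _ = noiseless_run
        noise = m.NoiseEstimate(sigma=1e-9, source="theoretical")
        den, _ = m.nordic_denoise_run(
            series, m.PatchConfig(patch_shape=(4, 4, 4), stride=2), noise
        )
        ref = np.abs(series.magnitude).max()
        assert np.abs(den.magnitude - series.magnitude).max() / ref < 1e-8

    def test_denoised_path_closer_to_noiseless_truth(self, small_net):
        """Denoise-then-combine beats combine-raw against the noiseless run."""
        acq = m.AcquisitionParams(
            echo_times=(14.2, 38.93, 63.66, 88.39, 113.12),
            n_frames=60,
            grid_shape=(16, 16, 16),
            n_noise_frames=3,
        )
        tissue = m.make_tissue_maps(m.TISSUE_PRESETS["adult"], (16, 16, 16), seed=42)
        kw = dict(resp_amplitude=0.0, drift_amplitude=0.0, motion_spike_prob=0.0,
                  motion_artifact_frac=0.0)
        clean_noise = m.NoiseAndMotionModel(thermal_sigma=0.0, **kw)
        noisy_noise = m.NoiseAndMotionModel(thermal_sigma=25.0, **kw)
        s_clean, _, _ = m.simulate_run(acq, tissue, small_net, clean_noise, seed=5)
        s_noisy, _, _ = m.simulate_run(acq, tissue, small_net, noisy_noise, seed=5)
        t2_true = m.fit_t2star(s_clean, mask=small_net.brain_mask)
        target = m.optimal_combine(s_clean, t2_true).magnitude
        den, _ = m.nordic_denoise_run(
            s_noisy, m.PatchConfig(patch_shape=(5, 5, 5), stride=3, seed=0)
        )
        bm = small_net.brain_mask
        err_raw = np.linalg.norm(
            m.optimal_combine(s_noisy, t2_true).magnitude[0][bm] - target[0][bm]
        )
        err_den = np.linalg.norm(
            m.optimal_combine(den, t2_true).magnitude[0][bm] - target[0][bm]
        )
        assert err_den < err_raw

    def test_mean_preserved_on_high_snr_data(self, small_net):
        acq = m.AcquisitionParams(
            echo_times=(14.2, 38.93, 63.66),
            n_frames=40,
            grid_shape=(16, 16, 16),
            n_noise_frames=3,
        )
        noise = m.NoiseAndMotionModel(thermal_sigma=5.0)
        series, _, truth = m.simulate_run(
            acq, m.TISSUE_PRESETS["adult"], small_net, noise, seed=6
        )
        den, _ = m.nordic_denoise_run(
            series, m.PatchConfig(patch_shape=(5, 5, 5), stride=3, seed=0)
        )
        bm = small_net.brain_mask
        d_mean = den.signal_frames().magnitude[:, bm, :].mean(axis=-1)
        r_mean = series.signal_frames().magnitude[:, bm, :].mean(axis=-1)
        assert np.abs(d_mean - r_mean).max() / truth.s0_map.mean() < 0.01

    def test_noise_frames_passed_through_untouched(self, adult_run, denoised_adult_run):
        _, series, _, _ = adult_run
        den, _ = denoised_adult_run
        assert np.array_equal(
            den.magnitude[..., -3:], series.magnitude[..., -3:]
        )

    def test_variance_selectivity_on_noise_region(self, adult_run, denoised_adult_run,
                                                  small_net):
        """Outside the brain (pure noise) most temporal variance is removed."""
        _, series, _, _ = adult_run
        den, _ = denoised_adult_run
        outside = ~small_net.brain_mask
        var_raw = series.signal_frames().magnitude[0][outside].var(axis=-1).mean()
        var_den = den.signal_frames().magnitude[0][outside].var(axis=-1).mean()
        assert var_den <= 0.25 * var_raw

    def test_nonoverlapping_tiling_covers_each_voxel_once(self):
        """stride = patch edge with an exactly tiling grid: denoising with
        τ=0 reproduces the input bit-for-bit (each voxel in one patch)."""
        rng = np.random.default_rng(3)
        mag = rng.random((1, 8, 8, 8, 6)) + 1.0
        ph = rng.uniform(-np.pi, np.pi, mag.shape)
        s = m.MultiEchoSeries(magnitude=mag, phase=ph, echo_times=(30.0,), tr=1.0)
        noise = m.NoiseEstimate(sigma=1e-300, source="theoretical")
        den, qc = m.nordic_denoise_run(
            s, m.PatchConfig(patch_shape=(4, 4, 4), stride=4), noise
        )
        assert np.allclose(den.magnitude, mag, atol=1e-10)

    def test_magnitude_only_mode_flagged(self, adult_run):
        _, series, _, _ = adult_run
        mag_only = m.MultiEchoSeries(
            magnitude=series.magnitude[:1],
            echo_times=series.echo_times[:1],
            tr=series.tr,
            n_noise_frames=series.n_noise_frames,
        )
        _, qc = m.nordic_denoise_run(
            mag_only, m.PatchConfig(patch_shape=(5, 5, 5), stride=5)
        )
        assert qc["magnitude_only"] is True

    def test_spatial_precision_impulse_preserved(self, small_net):
        """Denoising must not blur voxel-scale structure: a single-voxel S0
        impulse keeps its contrast against the neighborhood in the denoised
        temporal mean."""
        grid = (16, 16, 16)
        t2s = np.full(grid, 50.0)
        s0 = np.full(grid, 1000.0)
        s0[8, 8, 8] = 2000.0  # sharp feature
        acq = m.AcquisitionParams(
            echo_times=(14.2, 38.93), n_frames=40, grid_shape=grid,
            n_noise_frames=3,
        )
        net0 = m.NetworkModel(small_net.node_assignment, small_net.neural_cov, 0.0)
        noise = m.NoiseAndMotionModel(
            thermal_sigma=10.0, resp_amplitude=0.0, drift_amplitude=0.0,
            motion_spike_prob=0.0, motion_artifact_frac=0.0,
        )
        series, _, _ = m.simulate_run(acq, (t2s, s0), net0, noise, seed=8)
        den, _ = m.nordic_denoise_run(
            series, m.PatchConfig(patch_shape=(5, 5, 5), stride=3, seed=0)
        )
        mean = den.signal_frames().magnitude[0].mean(axis=-1)
        peak = mean[8, 8, 8]
        nbrs = np.array([mean[7, 8, 8], mean[9, 8, 8], mean[8, 7, 8],
                         mean[8, 9, 8], mean[8, 8, 7], mean[8, 8, 9]])
        true_peak = 1000.0 * np.exp(-14.2 / 50.0)  # impulse excess at echo 1
        # contrast preserved within 5%; no leakage into neighbors beyond 5%
        assert abs(peak - nbrs.mean() - true_peak) / true_peak < 0.05
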