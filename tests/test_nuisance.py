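"""Confound construction, cleaning, and connectivity."""

import numpy as np
import pytest

import mepfm as m
from mepfm.motion import CensorMask


def _masks(grid):
    g = np.zeros(grid, dtype=bool)
    w = np.zeros(grid, dtype=bool)
    c = np.zeros(grid, dtype=bool)
    g[1:-1, 1:-1, 1:-1] = True
    w[2:4, 2:4, 2:4] = True
    c[0] = True
    return {"global": g, "wm": w, "csf": c}


def _zero_motion(T, tr=1.761):
    return m.MotionTrace(np.zeros((T, 3)), np.zeros((T, 3)), tr=tr)


def _all_retained(T, threshold=0.3):
    return CensorMask(fd=np.zeros(T), threshold=threshold,
                      retained=np.ones(T, dtype=bool))


class TestBuildConfounds:
    def test_exactly_36_named_columns(self):
        rng = np.random.default_rng(0)
        data = rng.random((6, 6, 6, 20))
        conf = m.build_confounds(data, _masks((6, 6, 6)), _zero_motion(20))
        assert conf.values.shape == (20, 36)
        assert len(conf.names) == 36
        assert len(set(conf.names)) == 36

    def test_linear_motion_gives_unit_derivative_and_squared_quadratic(self):
        T = 15
        trans = np.zeros((T, 3))
        trans[:, 0] = np.arange(T, dtype=float)
        motion = m.MotionTrace(trans, np.zeros((T, 3)), tr=1.0)
        data = np.ones((6, 6, 6, T))
        conf = m.build_confounds(data, _masks((6, 6, 6)), motion)
        i_x = conf.names.index("trans_x")
        i_dx = conf.names.index("trans_x_derivative1")
        i_x2 = conf.names.index("trans_x_power2")
        assert np.array_equal(conf.values[:, i_x], np.arange(T))
        assert conf.values[0, i_dx] == 0.0
        assert np.allclose(conf.values[1:, i_dx], 1.0)
        assert np.array_equal(conf.values[:, i_x2], np.arange(T) ** 2.0)

    def test_constant_data_zero_motion_gives_zero_derivatives(self):
        data = np.full((6, 6, 6, 10), 7.0)
        conf = m.build_confounds(data, _masks((6, 6, 6)), _zero_motion(10))
        deriv_cols = [i for i, n in enumerate(conf.names) if "derivative" in n]
        assert np.allclose(conf.values[:, deriv_cols], 0.0)

    def test_empty_mask_rejected(self):
        masks = _masks((6, 6, 6))
        masks["csf"] = np.zeros((6, 6, 6), dtype=bool)
        with pytest.raises(ValueError, match="csf"):
            m.build_confounds(np.ones((6, 6, 6, 5)), masks, _zero_motion(5))


class TestCleanTimeseries:
    tr = 1.761

    def test_out_of_band_sinusoid_attenuated(self):
        T = 400
        t = np.arange(T) * self.tr
        rng = np.random.default_rng(1)
        data = np.zeros((4, 4, 4, T))
        sig = np.sin(2 * np.pi * 0.2 * t)  # 0.2 Hz, above the 0.08 Hz edge
        data[2, 2, 2] = sig
        data += 0.001 * rng.standard_normal(data.shape)
        conf = m.ConfoundMatrix(values=np.zeros((T, 1)), names=["null"])
        cleaned = m.clean_timeseries(
            data, conf, _all_retained(T), band=(0.009, 0.08), tr=self.tr
        )
        out = cleaned[2, 2, 2] - cleaned[2, 2, 2].mean()
        mid = slice(40, T - 40)  # steady-state response, clear of edge transients
        assert np.abs(out[mid]).max() < 0.1 * np.abs(sig[mid]).max()

    def test_residuals_orthogonal_to_filtered_confounds(self):
        T = 200
        rng = np.random.default_rng(2)
        data = rng.standard_normal((5, 5, 5, T))
        motion = m.MotionTrace(
            rng.normal(0, 0.05, (T, 3)), rng.normal(0, 0.001, (T, 3)), tr=self.tr
        )
        conf = m.build_confounds(data, _masks((5, 5, 5)), motion)
        cleaned = m.clean_timeseries(data, conf, _all_retained(T), tr=self.tr)
        from mepfm.nuisance import _bandpass

        conf_f = _bandpass(conf.values, (0.009, 0.08), self.tr)
        resid = cleaned.reshape(-1, T) - cleaned.reshape(-1, T).mean(
            axis=1, keepdims=True
        )
        dots = np.abs(resid @ conf_f)
        norms = np.linalg.norm(resid, axis=1)[:, None] * np.linalg.norm(
            conf_f, axis=0
        )[None, :]
        assert (dots <= 1e-8 * np.maximum(norms, 1e-30)).all()

    def test_injected_confound_removed(self):
        T = 300
        rng = np.random.default_rng(3)
        resp = np.sin(2 * np.pi * 0.05 * np.arange(T) * self.tr)
        data = rng.standard_normal((4, 4, 4, T))
        data[1, 1, 1] += 5.0 * resp
        conf = m.ConfoundMatrix(values=resp[:, None], names=["resp"])
        cleaned = m.clean_timeseries(data, conf, _all_retained(T), tr=self.tr)
        from mepfm.nuisance import _bandpass

        used = _bandpass(resp[:, None], (0.009, 0.08), self.tr)[:, 0]
        r = np.corrcoef(cleaned[1, 1, 1], used)[0, 1]
        assert abs(r) < 0.01

    def test_cleaning_improves_connectivity_recovery(self, cleaned_node_runs):
        """Confound regression + bandpass brings the parcel matrix closer to
        the generator's network correlation ground truth than raw data."""
        net = cleaned_node_runs["net"]
        grid = net.node_assignment.shape
        masks = {"global": net.brain_mask, "wm": net.wm_mask, "csf": net.csf_mask}
        acq = m.AcquisitionParams(
            echo_times=(37.0,), n_frames=400, grid_shape=grid, tr=1.761
        )
        tissue = m.make_tissue_maps(m.TISSUE_PRESETS["adult"], grid, seed=99)
        noise = m.NoiseAndMotionModel(thermal_sigma=8.0, motion_spike_prob=0.05)
        truthC = net.true_connectivity()
        off = ~np.eye(net.n_networks, dtype=bool)
        wins = 0
        for seed in (30, 31, 32):
            series, motion, _ = m.simulate_run(acq, tissue, net, noise, seed=seed)
            data = series.signal_frames().magnitude[0]
            fd = m.framewise_displacement(motion)
            c_hi, c_lo = m.censor(fd, 0.3), m.censor(fd, 0.2)
            conf = m.build_confounds(data, masks, motion)
            cleaned = m.clean_timeseries(data, conf, c_hi, tr=acq.tr)
            r_clean = m.connectivity(cleaned, net.node_assignment, c_lo).values
            r_raw = m.connectivity(data, net.node_assignment, c_lo).values
            cc = np.corrcoef(r_clean[off], truthC[off])[0, 1]
            cr = np.corrcoef(r_raw[off], truthC[off])[0, 1]
            wins += cc > cr
        assert wins >= 2

    def test_all_frames_censored_rejected(self):
        T = 10
        data = np.ones((3, 3, 3, T))
        conf = m.ConfoundMatrix(values=np.zeros((T, 1)), names=["null"])
        mask = CensorMask(fd=np.ones(T), threshold=0.3,
                          retained=np.zeros(T, dtype=bool))
        with pytest.raises(ValueError):
            m.clean_timeseries(data, conf, mask, tr=self.tr)


class TestConnectivity:
    def test_duplicated_node_series_correlate_perfectly(self):
        rng = np.random.default_rng(4)
        ts = rng.standard_normal(100)
        data = np.zeros((2, 1, 1, 100))
        data[0, 0, 0] = ts
        data[1, 0, 0] = ts
        cm = m.connectivity(data, np.ones((2, 1, 1), dtype=bool))
        assert cm.values[0, 1] == pytest.approx(1.0)

    def test_large_sample_matches_ground_truth(self, small_net):
        """Parcel matrix from a long noiseless run reproduces the network
        correlations (parcel averaging cancels voxel-level noise)."""
        grid = (10, 10, 10)
        net = m.make_network_model(grid)
        acq = m.AcquisitionParams(
            echo_times=(37.0,), n_frames=10_000, grid_shape=grid, n_noise_frames=0
        )
        noise = m.NoiseAndMotionModel(
            thermal_sigma=0.0, resp_amplitude=0.0, drift_amplitude=0.0,
            motion_spike_prob=0.0, motion_artifact_frac=0.0,
        )
        series, _, truth = m.simulate_run(
            acq, m.TISSUE_PRESETS["adult"], net, noise, seed=5
        )
        data = series.signal_frames().magnitude[0]
        cm = m.connectivity(data, net.node_assignment)
        # small-ΔR2* linearization leaves a slight attenuation; LLN noise on
        # smoothed series adds ~0.02 — allow both
        assert np.abs(cm.values - truth.true_connectivity).max() < 0.05

    def test_parcel_matrix_symmetric_unit_diagonal(self, cleaned_node_runs):
        net = cleaned_node_runs["net"]
        series, mask = cleaned_node_runs["parcel"][0]
        data = series[:, None, None, :]
        cm = m.connectivity(data, np.ones((net.n_networks, 1, 1), dtype=bool))
        assert np.allclose(cm.values, cm.values.T)
        assert np.allclose(np.diag(cm.values), 1.0)
        assert np.abs(cm.values).max() <= 1.0

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((3, 1, 1, 80))
        cm1 = m.connectivity(data.copy(), np.ones((3, 1, 1), dtype=bool))
        data[0, 0, 0] = 5.0 * data[0, 0, 0] - 17.0
        cm2 = m.connectivity(data, np.ones((3, 1, 1), dtype=bool))
        assert np.allclose(cm1.values, cm2.values, atol=1e-12)

    def test_censored_frames_never_used(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((3, 1, 1, 60))
        fd = np.zeros(60)
        fd[10:20] = 1.0
        mask = m.censor(fd, 0.2)
        cm1 = m.connectivity(data.copy(), np.ones((3, 1, 1), dtype=bool), mask)
        data[..., 10:20] = rng.standard_normal((3, 1, 1, 10))  # permute censored
        cm2 = m.connectivity(data, np.ones((3, 1, 1), dtype=bool), mask)
        assert np.array_equal(cm1.values, cm2.values)

    def test_constant_node_flagged_not_nan(self):
        data = np.zeros((2, 1, 1, 50))
        data[0, 0, 0] = np.random.default_rng(8).standard_normal(50)
        data[1, 0, 0] = 3.0  # constant
        cm = m.connectivity(data, np.ones((2, 1, 1), dtype=bool))
        assert not np.isnan(cm.values).any()
        assert cm.undefined_nodes.tolist() == [False, True]

    def test_fisher_z_transform_applied(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((3, 1, 1, 200))
        r = m.connectivity(data.copy(), np.ones((3, 1, 1), dtype=bool))
        z = m.connectivity(data, np.ones((3, 1, 1), dtype=bool), fisher_z=True)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(z.values[off], np.arctanh(r.values[off]))
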