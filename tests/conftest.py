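"""Shared fixtures: small synthetic runs reused across test modules."""

import numpy as np
import pytest

import mepfm as m

TE5 = (14.2, 38.93, 63.66, 88.39, 113.12)


@pytest.fixture(scope="session")
def small_net():
    return m.make_network_model((16, 16, 16))


@pytest.fixture(scope="session")
def adult_run(small_net):
    """Noisy 5-echo adult run on a 16^3 grid: the workhorse fixture."""
    acq = m.AcquisitionParams(
        echo_times=TE5, n_frames=80, grid_shape=(16, 16, 16), n_noise_frames=3
    )
    noise = m.NoiseAndMotionModel(thermal_sigma=25.0)
    series, motion, truth = m.simulate_run(
        acq, m.TISSUE_PRESETS["adult"], small_net, noise, seed=202
    )
    return acq, series, motion, truth


@pytest.fixture(scope="session")
def noiseless_run(small_net):
    """Pure monoexponential decay: no noise, no BOLD, no physio, no spikes."""
    acq = m.AcquisitionParams(
        echo_times=TE5, n_frames=12, grid_shape=(16, 16, 16), n_noise_frames=0
    )
    net0 = m.NetworkModel(small_net.node_assignment, small_net.neural_cov, 0.0)
    noise = m.NoiseAndMotionModel(
        thermal_sigma=0.0,
        resp_amplitude=0.0,
        drift_amplitude=0.0,
        motion_spike_prob=0.0,
        motion_artifact_frac=0.0,
    )
    series, motion, truth = m.simulate_run(
        acq, m.TISSUE_PRESETS["adult"], net0, noise, seed=7
    )
    return acq, series, motion, truth


@pytest.fixture(scope="session")
def denoised_adult_run(adult_run):
    acq, series, motion, truth = adult_run
    den, qc = m.nordic_denoise_run(
        series, m.PatchConfig(patch_shape=(5, 5, 5), stride=3, seed=0)
    )
    return den, qc


@pytest.fixture(scope="session")
def cleaned_node_runs():
    """Four cleaned single-echo runs of one synthetic subject, as parcel and
    dense node series with FC censor masks. Shared tissue maps across runs."""
    grid = (14, 14, 14)
    net = m.make_network_model(grid)
    masks = {"global": net.brain_mask, "wm": net.wm_mask, "csf": net.csf_mask}
    acq = m.AcquisitionParams(
        echo_times=(37.0,), n_frames=400, grid_shape=grid, tr=1.761
    )
    noise = m.NoiseAndMotionModel(thermal_sigma=8.0, motion_spike_prob=0.05)
    tissue = m.make_tissue_maps(m.TISSUE_PRESETS["adult"], grid, seed=99)
    labels = net.node_assignment
    rng = np.random.default_rng(0)
    dense_idx = np.sort(
        rng.choice(np.flatnonzero(net.gray_mask.ravel()), 300, replace=False)
    )
    parcel_runs, dense_runs = [], []
    for r in range(4):
        series, motion, truth = m.simulate_run(acq, tissue, net, noise, seed=10 + r)
        data = series.signal_frames().magnitude[0]
        fd = m.framewise_displacement(motion)
        c_hi, c_lo = m.censor(fd, 0.3), m.censor(fd, 0.2)
        conf = m.build_confounds(data, masks, motion)
        cleaned = m.clean_timeseries(data, conf, c_hi, tr=acq.tr)
        parcel = np.stack(
            [cleaned[labels == k + 1].mean(axis=0) for k in range(net.n_networks)]
        )
        parcel_runs.append((parcel, c_lo))
        dense_runs.append((cleaned.reshape(-1, acq.n_frames)[dense_idx], c_lo))
    return {"parcel": parcel_runs, "dense": dense_runs, "net": net, "tr": acq.tr}
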