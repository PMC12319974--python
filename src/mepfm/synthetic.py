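"""Synthetic multi-echo BOLD generator with known ground truth.

The generator emulates the statistical structure a multi-echo resting-state
analysis rests on: voxelwise monoexponential decay across echoes with
age-specific T2* distributions, BOLD fluctuations entering through R2*
modulation (so fractional signal change scales with echo time), additive
complex Gaussian thermal noise, respiratory-band physiological noise, slow
drift, motion spikes producing a controllable framewise-displacement trace,
and trailing pure-noise frames.

Signal model, per echo ``e``, frame ``t``, voxel ``v``::

    S(e, t, v) = S0(v) * exp(-TE_e * (1/T2*(v) + dR2*(v, t))) + physio(v, t)
    dR2*(v, t) = -amplitude * z(net(v), t)        [amplitude in 1/s]

with ``z`` a set of standardized network time series carrying a known
covariance. In the small-fluctuation regime the fractional BOLD signal change
is approximately ``TE_e * amplitude * z``, i.e. linear in echo time — the
property optimal echo combination exploits. Complex Gaussian noise is added
independently to real and imaginary channels before taking the magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .acquisition import AcquisitionParams, TissuePreset
from .motion import MotionTrace
from .series import MultiEchoSeries

__all__ = [
    "NetworkModel",
    "NoiseAndMotionModel",
    "GroundTruth",
    "make_tissue_maps",
    "make_network_model",
    "simulate_run",
    "extract_echo",
]

# node_assignment codes: 0 outside brain, -1 white matter, -2 CSF, 1..K networks
_WM, _CSF = -1, -2


@dataclass
class NetworkModel:
    """Ground-truth network structure for connectivity tests.

    ``node_assignment`` labels every voxel: 0 outside the brain, -1 white
    matter, -2 CSF, and 1..K for gray-matter functional networks.
    ``neural_cov`` is the K-by-K covariance of the latent network time series;
    its correlation form is the ground-truth connectivity.
    """

    node_assignment: np.ndarray
    neural_cov: np.ndarray
    delta_r2s_amplitude: float = 0.2  # 1/s; ~1% BOLD at TE ~ 50 ms

    def __post_init__(self) -> None:
        self.node_assignment = np.asarray(self.node_assignment, dtype=int)
        self.neural_cov = np.asarray(self.neural_cov, dtype=float)
        C = self.neural_cov
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("neural_cov must be square")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("neural_cov must be symmetric")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("neural_cov must be positive semi-definite")
        k = C.shape[0]
        labels = self.node_assignment
        if labels.max(initial=0) > k:
            raise ValueError("node_assignment refers to undefined networks")
        if self.delta_r2s_amplitude < 0:
            raise ValueError("delta_r2s_amplitude must be >= 0")

    @property
    def n_networks(self) -> int:
        return self.neural_cov.shape[0]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.node_assignment != 0

    @property
    def gray_mask(self) -> np.ndarray:
        return self.node_assignment > 0

    @property
    def wm_mask(self) -> np.ndarray:
        return self.node_assignment == _WM

    @property
    def csf_mask(self) -> np.ndarray:
        return self.node_assignment == _CSF

    def true_connectivity(self) -> np.ndarray:
        """Correlation form of ``neural_cov``."""
        d = np.sqrt(np.diag(self.neural_cov))
        return self.neural_cov / np.outer(d, d)


@dataclass
class NoiseAndMotionModel:
    """Noise, physiology and motion settings for one simulated run.

    thermal_sigma is the per-channel (real/imaginary) SD of the complex
    Gaussian noise. Respiration is a sinusoid in the stated breaths-per-minute
    band added to the signal and, at small amplitude, to the motion
    parameters, so the band-stop motion filter has a real target. Motion
    spikes displace the head by ``motion_spike_mm`` within one frame and add a
    transient signal artifact, so spike frames exceed censoring thresholds.
    """

    thermal_sigma: float = 20.0
    resp_freq_bpm: float = 15.0
    resp_amplitude: float = 0.01  # fraction of S0
    drift_amplitude: float = 0.01  # fraction of S0
    motion_spike_prob: float = 0.05
    motion_spike_mm: float = 0.6
    motion_artifact_frac: float = 0.05  # signal blip on spike frames, ×S0
    fd_baseline_mm: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "thermal_sigma",
            "resp_amplitude",
            "drift_amplitude",
            "motion_spike_mm",
            "motion_artifact_frac",
            "fd_baseline_mm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.motion_spike_prob <= 1.0:
            raise ValueError("motion_spike_prob must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    t2star_map: np.ndarray  # ms per voxel
    s0_map: np.ndarray
    neural_timeseries: np.ndarray  # (n_networks, n_frames), standardized
    true_connectivity: np.ndarray  # (n_networks, n_networks) correlations
    fd_true: np.ndarray  # mm per frame, fd_true[0] = 0
    spike_frames: np.ndarray  # boolean per frame
    delta_r2star: np.ndarray | None = None  # (x, y, z, t) in 1/ms, optional
    phase_map: np.ndarray | None = None


def _smooth_unit_field(shape, rng, sigma=1.0):
    """Gaussian-smoothed iid field, re-standardized to zero mean / unit SD."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def make_tissue_maps(
    preset: TissuePreset,
    grid_shape: tuple[int, int, int],
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample spatially correlated T2* (ms) and S0 maps for one age group.

    The T2* field has the preset's marginal mean and SD (Gaussian, clipped to
    the preset bounds) with mild spatial autocorrelation from a 1-voxel-SD
    Gaussian kernel. Deterministic given ``seed``.
    """
    if any(s < 1 for s in grid_shape):
        raise ValueError("grid_shape must be positive")
    rng = np.random.default_rng(seed)
    t2s = preset.t2star_mean + preset.t2star_sd * _smooth_unit_field(grid_shape, rng)
    np.clip(t2s, *preset.t2star_bounds, out=t2s)
    s0 = preset.s0_mean * (1.0 + 0.1 * _smooth_unit_field(grid_shape, rng))
    np.clip(s0, 0.1 * preset.s0_mean, None, out=s0)
    return t2s, s0


def make_network_model(
    grid_shape: tuple[int, int, int],
    n_networks: int = 6,
    delta_r2s_amplitude: float = 0.2,
    base_corr: float = 0.2,
    paired_corr: float = 0.6,
) -> NetworkModel:
    """Default brain geometry and network covariance on a cubic grid.

    An ellipsoidal brain mask is split into a thin CSF shell, a deep
    white-matter core, and a gray-matter ribbon partitioned into
    ``n_networks`` slabs. Consecutive network pairs (1–2, 3–4, ...) carry
    strong couplings of alternating sign and decreasing magnitude
    (``paired_corr``, −5/6·``paired_corr``, ``paired_corr``/2, cycling),
    plus two weak ±``base_corr`` cross-links — a mixed-sign structure like
    real functional connectomes, where networks both correlate and
    anti-correlate. The resulting correlation matrix is the ground truth
    for connectivity and reliability tests.
    """
    nx, ny, nz = grid_shape
    idx = np.indices(grid_shape, dtype=float)
    c = [(n - 1) / 2 for n in grid_shape]
    semi = [0.48 * n for n in grid_shape]
    r2 = sum(((idx[i] - c[i]) / semi[i]) ** 2 for i in range(3))
    labels = np.zeros(grid_shape, dtype=int)
    brain = r2 <= 1.0
    labels[(r2 > 0.78) & brain] = _CSF
    labels[r2 <= 0.18] = _WM
    gray = brain & (labels == 0)
    # partition gray ribbon into slabs along x, then wrap into n_networks
    gx = idx[0][gray]
    edges = np.quantile(gx, np.linspace(0, 1, n_networks + 1))
    edges[-1] += 1.0
    net = np.searchsorted(edges, gx, side="right")
    net = np.clip(net, 1, n_networks)
    labels[gray] = net

    C = np.eye(n_networks)
    mags = [paired_corr, -paired_corr * 5.0 / 6.0, paired_corr / 2.0]
    for p, a in enumerate(range(0, n_networks - 1, 2)):
        C[a, a + 1] = C[a + 1, a] = mags[p % 3]
    if n_networks >= 3:
        C[0, 2] = C[2, 0] = base_corr
    if n_networks >= 5:
        C[1, 4] = C[4, 1] = -base_corr
    if np.linalg.eigvalsh(C).min() < 1e-8:
        raise ValueError("default covariance not positive definite")
    return NetworkModel(labels, C, delta_r2s_amplitude)


def _network_timeseries(cov, n_frames, rng, temporal_sigma=2.0):
    """Standardized network series with the given covariance structure.

    White Gaussian draws are colored with the Cholesky factor, temporally
    smoothed to confine power to low frequencies (BOLD-like), and
    re-standardized per network — which preserves cross-correlations.
    """
    k = cov.shape[0]
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
    z = L @ rng.standard_normal((k, n_frames))
    if temporal_sigma > 0:
        z = ndimage.gaussian_filter1d(z, sigma=temporal_sigma, axis=1, mode="wrap")
    z -= z.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return z / sd


def _motion_trace(acq, noise, rng):
    """FD-exact motion parameters: per-frame displacement deltas whose L1
    norm (translations + 50 mm × rotations) equals the designed FD."""
    T = acq.n_frames
    fd = noise.fd_baseline_mm * np.abs(rng.standard_normal(T))
    spikes = rng.random(T) < noise.motion_spike_prob
    spikes[0] = False
    fd[spikes] = noise.motion_spike_mm * (1.0 + 0.2 * rng.random(spikes.sum()))
    fd[0] = 0.0

    # allocate each frame's displacement across the 6 parameters
    w = rng.dirichlet(np.ones(6), size=T)
    sign = rng.choice([-1.0, 1.0], size=(T, 6))
    deltas = w * sign * fd[:, None]
    deltas[:, 3:] /= 50.0  # rotations in radians; FD counts them ×50 mm
    params = np.cumsum(deltas, axis=0)

    # small respiratory wobble in translation y; adds ~2π·f·TR·amp per frame
    t_sec = np.arange(T) * acq.tr
    resp_hz = noise.resp_freq_bpm / 60.0
    params[:, 1] += 0.008 * np.sin(2 * np.pi * resp_hz * t_sec)
    trace = MotionTrace(
        translations=params[:, :3], rotations=params[:, 3:], tr=acq.tr
    )
    return trace, fd, spikes


def simulate_run(
    acq: AcquisitionParams,
    tissue: TissuePreset | tuple[np.ndarray, np.ndarray],
    network: NetworkModel,
    noise: NoiseAndMotionModel,
    seed: int | None = None,
) -> tuple[MultiEchoSeries, MotionTrace, GroundTruth]:
    """Simulate one multi-echo BOLD run.

    Parameters
    ----------
    tissue
        Either a :class:`TissuePreset` (maps are sampled from it) or a
        precomputed ``(t2star_map, s0_map)`` pair in ms / signal units.
    seed
        Overrides ``noise.seed`` when given. Identical seeds give
        bit-identical outputs.

    Returns
    -------
    series, motion, truth
        The noisy magnitude+phase series (with ``acq.n_noise_frames``
        trailing noise-only frames), the motion-parameter trace for the
        signal frames, and the generator's ground truth.
    """
    if seed is None:
        seed = noise.seed
    rng = np.random.default_rng(seed)
    grid = acq.grid_shape
    if isinstance(tissue, TissuePreset):
        t2s, s0 = make_tissue_maps(
            tissue, grid, int(rng.integers(0, 2**31 - 1))
        )
    else:
        t2s, s0 = (np.asarray(a, dtype=float) for a in tissue)
    if t2s.shape != grid or s0.shape != grid:
        raise ValueError("tissue maps do not match acq.grid_shape")
    if network.node_assignment.shape != grid:
        raise ValueError("network.node_assignment does not match acq.grid_shape")
    if max(acq.echo_times) > 5.0 * t2s.max():
        warnings.warn(
            "longest echo time exceeds 5× max T2*: late-echo signal underflows",
            RuntimeWarning,
            stacklevel=2,
        )

    T, E = acq.n_frames, acq.n_echoes
    labels = network.node_assignment
    brain = network.brain_mask
    gray = network.gray_mask

    z = _network_timeseries(network.neural_cov, T, rng)  # (K, T)
    amp_ms = network.delta_r2s_amplitude / 1000.0  # 1/s -> 1/ms
    # ΔR2*(v, t) = -amp · z(net(v), t); zero outside gray matter
    dr2s = np.zeros(grid + (T,))
    for k in range(network.n_networks):
        vox = labels == (k + 1)
        if vox.any():
            dr2s[vox] = -amp_ms * z[k]

    trace, fd, spikes = _motion_trace(acq, noise, rng)

    t_sec = np.arange(T) * acq.tr
    resp_hz = noise.resp_freq_bpm / 60.0
    resp_phase = np.pi * _smooth_unit_field(grid, rng, sigma=3.0)
    resp = np.sin(2 * np.pi * resp_hz * t_sec[None, :] + resp_phase[brain][:, None])
    drift = np.linspace(-1.0, 1.0, T)

    phase_map = 0.25 * np.pi * _smooth_unit_field(grid, rng, sigma=2.0)

    r20 = 1.0 / t2s  # 1/ms
    total = T + acq.n_noise_frames
    mag = np.empty((E,) + grid + (total,))
    ph = np.empty_like(mag)
    for e, te in enumerate(acq.echo_times):
        sig = np.zeros(grid + (T,))
        decay = s0 * np.exp(-te * r20)  # (x, y, z)
        sig[brain] = decay[brain][:, None] * np.exp(
            -te * dr2s[brain]
        )
        # additive physiological terms, scaled by S0
        s0_brain = s0[brain][:, None]
        sig[brain] += noise.resp_amplitude * s0_brain * resp
        sig[brain] += noise.drift_amplitude * s0_brain * drift[None, :]
        if spikes.any() and noise.motion_artifact_frac > 0:
            sig[brain] += (
                noise.motion_artifact_frac * s0_brain * spikes[None, :].astype(float)
            )
        full = np.zeros(grid + (total,))
        full[..., :T] = sig
        cplx = full * np.exp(1j * phase_map[..., None])
        if noise.thermal_sigma > 0:
            cplx = cplx + noise.thermal_sigma * (
                rng.standard_normal(cplx.shape)
                + 1j * rng.standard_normal(cplx.shape)
            )
        mag[e] = np.abs(cplx)
        ph[e] = np.angle(cplx)

    series = MultiEchoSeries(
        magnitude=mag,
        phase=ph,
        echo_times=acq.echo_times,
        tr=acq.tr,
        n_noise_frames=acq.n_noise_frames,
        voxel_size=acq.voxel_size,
    )
    truth = GroundTruth(
        t2star_map=t2s,
        s0_map=s0,
        neural_timeseries=z,
        true_connectivity=network.true_connectivity(),
        fd_true=fd,
        spike_frames=spikes,
        delta_r2star=dr2s,
        phase_map=phase_map,
    )
    return series, trace, truth


def extract_echo(series: MultiEchoSeries, echo_index: int) -> MultiEchoSeries:
    """Single echo of a multi-echo series (0-based), metadata preserved.

    Used for single-echo control analyses (e.g. comparing the second echo
    alone against the combined series).
    """
    return series.echo(echo_index)
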