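"""Temporal SNR, percent-difference comparisons, and Gaussian-ACF smoothness
(FWHM) estimation and matching.

tSNR is the voxelwise temporal mean divided by the temporal SD, computed on
un-censored signal frames (noise frames excluded) and averaged across
low-motion runs. Smoothness is summarized as the FWHM of the Gaussian kernel
whose application to white noise would produce the observed lag-1 spatial
autocorrelation of the detrended residuals (Forman-style kernel-equivalent
convention); unsmoothed white noise reports the one-voxel resolution floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .series import MultiEchoSeries

logger = logging.getLogger(__name__)

__all__ = [
    "TsnrMap",
    "SmoothnessEstimate",
    "tsnr_map",
    "average_tsnr",
    "percent_difference",
    "estimate_fwhm",
    "smooth_to_fwhm",
]

_FWHM_PER_SIGMA = np.sqrt(8.0 * np.log(2.0))


@dataclass
class TsnrMap:
    """Voxelwise tSNR with a validity mask for zero-variance voxels."""

    values: np.ndarray
    defined: np.ndarray
    runs_used: list[int] | None = None
    condition_label: str = ""

    def summary(self, mask: np.ndarray | None = None) -> tuple[float, float]:
        """Mean and SD of tSNR over defined in-mask voxels.

        The SD is across brain locations, not runs — the convention used
        for per-condition tSNR tables.
        """
        sel = self.defined if mask is None else (self.defined & mask)
        if not sel.any():
            raise ValueError("no defined voxels in mask")
        vals = self.values[sel]
        return float(vals.mean()), float(vals.std())


@dataclass
class SmoothnessEstimate:
    """Global kernel-equivalent FWHM in mm with per-axis diagnostics.

    ``fwhm`` is floored at one voxel (the sampling resolution);
    ``fwhm_unfloored`` keeps the raw model value (0 for uncorrelated noise)
    and is what kernel-matching arithmetic should use.
    """

    fwhm: float
    per_axis_fwhm: tuple[float, float, float]
    acf_r1: tuple[float, float, float]
    fwhm_unfloored: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")


def tsnr_map(
    series: MultiEchoSeries | np.ndarray,
    exclude_noise_frames: bool = True,
    condition_label: str = "",
) -> TsnrMap:
    """Voxelwise temporal mean / temporal SD.

    No motion censoring is applied (run selection handles motion); trailing
    noise frames are excluded. Voxels with zero temporal SD are flagged
    undefined rather than producing infinities.
    """
    if isinstance(series, MultiEchoSeries):
        data = (series.signal_frames() if exclude_noise_frames else series).magnitude
        if data.shape[0] != 1:
            raise ValueError("tSNR is defined for a single (combined) series")
        data = data[0]
    else:
        data = np.asarray(series, dtype=float)
    if data.ndim != 4 or data.shape[-1] < 2:
        raise ValueError("need a 4D series with at least 2 frames")
    mean = data.mean(axis=-1)
    sd = data.std(axis=-1)
    defined = sd > 0
    values = np.zeros_like(mean)
    values[defined] = mean[defined] / sd[defined]
    return TsnrMap(values=values, defined=defined, condition_label=condition_label)


def average_tsnr(
    maps: list[TsnrMap],
    runs_used: list[int] | None = None,
    condition_label: str = "",
) -> TsnrMap:
    """Voxelwise mean tSNR across qualifying runs.

    Callers pass the maps of runs selected by the >90 % low-motion rule.
    A voxel is defined in the average when it is defined in every run.
    """
    if not maps:
        raise ValueError("no runs to average")
    stack = np.stack([m.values for m in maps])
    defined = np.logical_and.reduce([m.defined for m in maps])
    return TsnrMap(
        values=stack.mean(axis=0),
        defined=defined,
        runs_used=runs_used,
        condition_label=condition_label,
    )


def percent_difference(m_before: float, m_after: float) -> float:
    """100·(after − before)/before, rounded to 2 decimals.

    Note the formula is directional: swapping the arguments does not just
    flip the sign.
    """
    if m_before <= 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * (m_after - m_before) / m_before, 2)


def _lag1_spatial_corr(resid: np.ndarray, mask: np.ndarray, axis: int) -> float:
    """Correlation of residuals between neighboring voxels along one axis,
    pooled over frames."""
    sl_a = [slice(None)] * 3
    sl_b = [slice(None)] * 3
    sl_a[axis] = slice(None, -1)
    sl_b[axis] = slice(1, None)
    pair_mask = mask[tuple(sl_a)] & mask[tuple(sl_b)]
    a = resid[tuple(sl_a)][pair_mask]
    b = resid[tuple(sl_b)][pair_mask]
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a**2).sum() * (b**2).sum())
    return float((a * b).sum() / den) if den > 0 else 0.0


def estimate_fwhm(
    series: np.ndarray,
    mask: np.ndarray | None = None,
    voxel_size: float = 2.0,
) -> SmoothnessEstimate:
    """Kernel-equivalent FWHM from the lag-1 spatial ACF of detrended data.

    Each voxel's series is linearly detrended; the lag-1 neighbor
    correlation r1 along each axis, modeled as the ACF of Gaussian-smoothed
    white noise r(d) = exp(−d²/(4σ²)), gives the smoothing-kernel width
    σ = d/√(−4·ln r1) and FWHM = √(8 ln 2)·σ. Estimates are floored at one
    voxel (the sampling resolution) and averaged across axes.
    """
    data = np.asarray(series, dtype=float)
    if data.ndim != 4:
        raise ValueError("series must be 4D")
    if min(data.shape[:3]) < 8:
        raise ValueError("grid must be at least 8 voxels per axis")
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    if mask.sum() < 16:
        raise ValueError("degenerate mask")
    T = data.shape[-1]
    t = np.arange(T)
    t = (t - t.mean()) / t.std()
    mean = data.mean(axis=-1, keepdims=True)
    slope = (data * t).mean(axis=-1, keepdims=True)
    resid = data - mean - slope * t

    fwhms, raw_fwhms, r1s = [], [], []
    for axis in range(3):
        r1 = _lag1_spatial_corr(resid, mask, axis)
        r1s.append(r1)
        if r1 <= 0:
            raw = 0.0  # uncorrelated: no measurable intrinsic smoothness
        else:
            raw = _FWHM_PER_SIGMA * voxel_size / np.sqrt(-4.0 * np.log(r1))
        raw_fwhms.append(raw)
        fwhms.append(max(raw, voxel_size))  # resolution floor
    return SmoothnessEstimate(
        fwhm=float(np.mean(fwhms)),
        per_axis_fwhm=tuple(fwhms),
        acf_r1=tuple(r1s),
        fwhm_unfloored=float(np.mean(raw_fwhms)),
    )


def smooth_to_fwhm(
    series: np.ndarray,
    target_fwhm: float,
    voxel_size: float = 2.0,
    current_fwhm: float | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian-smooth a 4D series up to a target global FWHM (mm).

    The added kernel width follows quadrature addition of Gaussian widths,
    σ_add = √(σ_target² − σ_current²); the current smoothness is estimated
    from the data when not supplied. Raises if the target is below the
    current estimate.
    """
    data = np.asarray(series, dtype=float)
    if current_fwhm is None:
        est = estimate_fwhm(data, mask=mask, voxel_size=voxel_size)
        if target_fwhm < est.fwhm:
            raise ValueError(
                f"target FWHM {target_fwhm} below current estimate {est.fwhm:.2f}"
            )
        # quadrature arithmetic uses the unfloored intrinsic smoothness
        current_fwhm = est.fwhm_unfloored
    elif target_fwhm < current_fwhm:
        raise ValueError(
            f"target FWHM {target_fwhm} below current estimate {current_fwhm:.2f}"
        )
    sigma_t = target_fwhm / _FWHM_PER_SIGMA
    sigma_c = current_fwhm / _FWHM_PER_SIGMA
    sigma_add_vox = np.sqrt(max(sigma_t**2 - sigma_c**2, 0.0)) / voxel_size
    if sigma_add_vox == 0.0:
        return data.copy()
    out = np.empty_like(data)
    for f in range(data.shape[-1]):
        out[..., f] = ndimage.gaussian_filter(data[..., f], sigma=sigma_add_vox)
    return out
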