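"""Voxelwise T2*/S0 estimation and T2*-weighted optimal echo combination.

The decay of the temporal-mean signal across echoes is modeled as
monoexponential, ``S̄(TE) = S0·exp(−TE/T2*)``, fit by ordinary least squares
on the log signal. Echoes are then combined with the standard
contrast-optimal weights

    w_e ∝ TE_e · exp(−TE_e / T2*),   normalized to sum 1,

which up-weight the echoes closest to the local T2*. Because infant cortex
has much longer T2* than adult cortex, the weight mass shifts toward later
echoes in infants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import MultiEchoSeries

__all__ = [
    "T2StarMap",
    "fit_t2star",
    "weights_at_t2star",
    "optimal_combine",
    "weight_summary",
]

DEFAULT_T2S_BOUNDS = (2.0, 500.0)


@dataclass
class T2StarMap:
    """Voxelwise T2* (ms), S0, R2* (1/s) and fit diagnostics.

    ``valid`` marks voxels where at least two echoes were usable;
    ``n_echoes_used`` records how many trailing echoes had to be dropped for
    non-positive mean signal. R2* = 1000/T2* with T2* in ms.
    """

    t2star: np.ndarray
    s0: np.ndarray
    fit_rmse: np.ndarray
    n_echoes_used: np.ndarray
    valid: np.ndarray
    bounds: tuple[float, float] = DEFAULT_T2S_BOUNDS

    @property
    def r2star(self) -> np.ndarray:
        """Transverse relaxation rate in 1/s (iron-sensitive tissue measure)."""
        with np.errstate(divide="ignore"):
            return np.where(self.t2star > 0, 1000.0 / self.t2star, np.inf)


def fit_t2star(
    series: MultiEchoSeries,
    mask: np.ndarray | None = None,
    bounds: tuple[float, float] = DEFAULT_T2S_BOUNDS,
    noise_sigma: float | str | None = "auto",
) -> T2StarMap:
    """Log-linear monoexponential fit of the temporal-mean decay curve.

    Per voxel, OLS of log S̄(TE) on TE gives slope −1/T2* and intercept
    log S0. Voxels with any non-positive mean signal drop trailing echoes
    until all used means are positive; voxels left with fewer than two
    usable echoes are flagged invalid (T2* at the upper bound). T2* is
    clipped to ``bounds``. Noise frames are excluded.

    Magnitude data carry a Rician noise floor that inflates the mean of
    low-SNR late echoes and would bias T2* upward, so when a thermal noise
    level is available the fit uses the noise-floor-corrected mean
    √(⟨mag²⟩ − 2σ²) instead of ⟨mag⟩ (the second moment of a Rician with
    per-channel SD σ is S² + 2σ²). ``noise_sigma="auto"`` estimates σ from
    the series' noise frames when present; pass a number to fix it or
    None/0 to disable the correction.
    """
    if series.n_echoes < 2:
        raise ValueError("at least two echoes are required")
    te = np.asarray(series.echo_times)
    sigma = 0.0
    if noise_sigma == "auto":
        if series.n_noise_frames >= 1:
            from .denoise import estimate_noise_sigma

            try:
                sigma = estimate_noise_sigma(series).sigma
            except ValueError:  # degenerate (e.g. noiseless) noise frames
                sigma = 0.0
    elif noise_sigma:
        sigma = float(noise_sigma)
    sig = series.signal_frames().magnitude
    if sigma > 0:
        power = (sig**2).mean(axis=-1) - 2.0 * sigma**2
        mean_sig = np.sqrt(np.clip(power, 0.0, None))
    else:
        mean_sig = sig.mean(axis=-1)  # (E, x, y, z)
    grid = series.grid_shape
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    flat = mean_sig.reshape(series.n_echoes, -1).T  # (V, E)
    in_mask = mask.ravel()
    E = series.n_echoes

    t2s = np.full(flat.shape[0], bounds[1])
    s0 = np.zeros(flat.shape[0])
    rmse = np.zeros(flat.shape[0])
    n_used = np.zeros(flat.shape[0], dtype=int)
    valid = np.zeros(flat.shape[0], dtype=bool)

    pos = flat > 0
    # usable echo count per voxel: longest positive prefix
    prefix = np.where(pos.cumprod(axis=1).astype(bool), 1, 0).sum(axis=1)
    for n in range(2, E + 1):
        vox = in_mask & (prefix == n) if n < E else in_mask & (prefix >= E)
        if not vox.any():
            continue
        x = te[:n]
        y = np.log(flat[vox][:, :n])
        A = np.vstack([np.ones(n), x]).T
        coef, *_ = np.linalg.lstsq(A, y.T, rcond=None)
        intercept, slope = coef
        resid = y.T - A @ coef
        with np.errstate(divide="ignore"):
            t2 = np.where(slope < 0, -1.0 / slope, bounds[1])
        t2s[vox] = np.clip(t2, *bounds)
        s0[vox] = np.exp(intercept)
        rmse[vox] = np.sqrt(np.mean(resid**2, axis=0))
        n_used[vox] = n
        valid[vox] = True

    return T2StarMap(
        t2star=t2s.reshape(grid),
        s0=s0.reshape(grid),
        fit_rmse=rmse.reshape(grid),
        n_echoes_used=n_used.reshape(grid),
        valid=(valid & in_mask).reshape(grid),
        bounds=bounds,
    )


def weights_at_t2star(echo_times, t2star) -> np.ndarray:
    """Normalized optimal-combination weights w_e ∝ TE_e·exp(−TE_e/T2*).

    ``t2star`` may be a scalar (ms) or an array; the echo axis is prepended
    for array input. Weights sum to 1 along the echo axis.
    """
    te = np.asarray(echo_times, dtype=float)
    if (te <= 0).any():
        raise ValueError("echo times must be positive")
    t2s = np.asarray(t2star, dtype=float)
    if (t2s <= 0).any():
        raise ValueError("t2star must be positive")
    shape = (te.size,) + (1,) * t2s.ndim
    w = te.reshape(shape) * np.exp(-te.reshape(shape) / t2s[None])
    w = w / w.sum(axis=0, keepdims=True)
    return w if t2s.ndim else w.ravel()


def optimal_combine(
    series: MultiEchoSeries,
    t2smap: T2StarMap,
    mask: np.ndarray | None = None,
) -> MultiEchoSeries:
    """T2*-weighted combination of a multi-echo series into a single series.

    combined(v, t) = Σ_e w_e(v)·S_e(v, t) with weights from the run-average
    T2* map. Voxels with an invalid fit fall back to equal weights. The
    combined series keeps the TR, noise frames and voxel size; its nominal
    echo time is the weight-averaged TE.
    """
    if series.grid_shape != t2smap.t2star.shape:
        raise ValueError("T2* map does not match the series grid")
    te = np.asarray(series.echo_times)
    w = weights_at_t2star(te, t2smap.t2star)  # (E, x, y, z)
    eq = np.full_like(w, 1.0 / series.n_echoes)
    w = np.where(t2smap.valid[None], w, eq)
    if mask is not None:
        w = np.where(mask[None], w, eq)
    combined = np.einsum("exyz,exyzt->xyzt", w, series.magnitude)
    te_eff = float((w.mean(axis=(1, 2, 3)) * te).sum())
    return MultiEchoSeries(
        magnitude=combined[None],
        echo_times=(te_eff,),
        tr=series.tr,
        n_noise_frames=series.n_noise_frames,
        voxel_size=series.voxel_size,
    )


def weight_summary(
    t2smap: T2StarMap,
    echo_times,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-echo weight distribution summary across a mask.

    Rows: mean, median, SD, 5th and 95th percentile of the voxelwise
    normalized weights; one column per echo, plus the matching T2*
    statistic. Mirrors the standard per-subject echo-weighting table.
    """
    if mask is None:
        mask = t2smap.valid
    else:
        mask = np.asarray(mask, dtype=bool) & t2smap.valid
    if not mask.any():
        raise ValueError("empty mask")
    t2s = t2smap.t2star[mask]
    w = weights_at_t2star(echo_times, t2s)  # (E, V)
    te = np.asarray(echo_times)
    rows = {
        "mean": (t2s.mean(), w.mean(axis=1)),
        "median": (np.median(t2s), np.median(w, axis=1)),
        "SD": (t2s.std(), w.std(axis=1)),
        "5th pct": (np.percentile(t2s, 5), np.percentile(w, 5, axis=1)),
        "95th pct": (np.percentile(t2s, 95), np.percentile(w, 95, axis=1)),
    }
    data = {
        "T2*": [rows[r][0] for r in rows],
    }
    for e in range(te.size):
        data[f"e{e + 1}"] = [rows[r][1][e] for r in rows]
    return pd.DataFrame(data, index=list(rows))
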