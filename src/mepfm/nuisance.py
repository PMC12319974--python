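"""36-parameter confound regression, censored-frame interpolation, bandpass
filtering, and dense/parcellated functional connectivity.

The confound model is the standard 36-parameter set: six rigid-body motion
parameters, mean global / white-matter / CSF signals, the backward-difference
temporal derivatives of those nine, and the elementwise squares of all
eighteen. Cleaning follows the sequence interpolate → bandpass → regress,
with the same zero-phase Butterworth filter applied to data and confounds, so
censored motion spikes cannot leak through the filter and confound/band
mismatch cannot reintroduce nuisance frequencies. Frames censored at the
stricter FC threshold are excluded again when correlations are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .motion import CensorMask, MotionTrace

logger = logging.getLogger(__name__)

__all__ = [
    "ConfoundMatrix",
    "ConnectivityMatrix",
    "build_confounds",
    "clean_timeseries",
    "connectivity",
]


@dataclass
class ConfoundMatrix:
    """36 named nuisance regressors (columns) by frames (rows)."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be (frames, n_regressors)")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class ConnectivityMatrix:
    """Node-by-node Pearson correlations with retained-frame provenance."""

    values: np.ndarray
    node_kind: str  # "dense" or "parcel"
    n_frames_used: int
    fd_threshold: float | None = None
    fisher_z: bool = False
    undefined_nodes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")


def _backward_diff(x: np.ndarray) -> np.ndarray:
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d  # derivative at frame 1 is 0 by convention


def build_confounds(
    data: np.ndarray,
    tissue_masks: dict[str, np.ndarray],
    motion: MotionTrace,
) -> ConfoundMatrix:
    """Assemble the 36-parameter confound matrix.

    ``data`` is (x, y, z, t); ``tissue_masks`` must provide boolean masks
    under the keys ``global``, ``wm`` and ``csf``. Column order: 6 motion,
    3 tissue means, their 9 derivatives, then the squares of all 18.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("data must be 4D (x, y, z, t)")
    T = data.shape[-1]
    if motion.n_frames != T:
        raise ValueError("motion trace length does not match data frames")
    base_cols, names = [], []
    mp = motion.as_array()
    for i, nm in enumerate(
        ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    ):
        base_cols.append(mp[:, i])
        names.append(nm)
    for key in ("global", "wm", "csf"):
        if key not in tissue_masks:
            raise ValueError(f"missing tissue mask {key!r}")
        m = np.asarray(tissue_masks[key], dtype=bool)
        if not m.any():
            raise ValueError(f"tissue mask {key!r} is empty")
        base_cols.append(data[m].mean(axis=0))
        names.append(f"{key}_signal")
    base = np.column_stack(base_cols)  # (T, 9)
    deriv = np.column_stack([_backward_diff(base[:, i]) for i in range(9)])
    eighteen = np.hstack([base, deriv])
    values = np.hstack([eighteen, eighteen**2])
    names18 = names + [f"{n}_derivative1" for n in names]
    names36 = names18 + [f"{n}_power2" for n in names18]
    return ConfoundMatrix(values=values, names=names36)


def _interpolate_censored(x: np.ndarray, retained: np.ndarray) -> np.ndarray:
    """Linear interpolation over censored frames, edges held constant.

    ``x`` is (frames, ...); operates along the first axis.
    """
    if retained.all():
        return x
    if not retained.any():
        raise ValueError("all frames censored; nothing to interpolate from")
    t = np.arange(x.shape[0])
    good = np.flatnonzero(retained)
    out = x.copy()
    flat = out.reshape(x.shape[0], -1)
    src = flat[good]
    bad = np.flatnonzero(~retained)
    for j in range(flat.shape[1]):
        flat[bad, j] = np.interp(t[bad], good, src[:, j])
    return out


def _bandpass(x: np.ndarray, band: tuple[float, float], tr: float) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the first axis."""
    lo, hi = band
    nyq = 0.5 / tr
    if not 0 < lo < hi < nyq:
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    b, a = sps.butter(2, [lo / nyq, hi / nyq], btype="bandpass")
    return sps.filtfilt(b, a, x, axis=0)


def clean_timeseries(
    data: np.ndarray,
    confounds: ConfoundMatrix,
    censor_hi: CensorMask,
    band: tuple[float, float] = (0.009, 0.08),
    tr: float = 1.761,
) -> np.ndarray:
    """Interpolate, bandpass, and regress confounds from a 4D series.

    Steps: (1) frames censored at the high-motion threshold (FD 0.3 mm) are
    replaced by linear interpolation from the nearest retained frames in both
    the data and the confound columns; (2) a zero-phase Butterworth bandpass
    (default 0.009-0.08 Hz) is applied identically to data and confounds;
    (3) voxelwise OLS residuals against the filtered confounds are returned
    with the voxel temporal mean restored.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("data must be 4D (x, y, z, t)")
    T = data.shape[-1]
    if confounds.n_frames != T or censor_hi.n_frames != T:
        raise ValueError("confounds/censor mask length mismatch")
    grid = data.shape[:3]
    ts = data.reshape(-1, T).T  # (T, V)
    ts = _interpolate_censored(ts, censor_hi.retained)
    conf = _interpolate_censored(confounds.values, censor_hi.retained)
    ts_f = _bandpass(ts, band, tr)
    conf_f = _bandpass(conf, band, tr)
    mean = ts.mean(axis=0, keepdims=True)
    design = np.column_stack([np.ones(T), conf_f])
    beta, *_ = np.linalg.lstsq(design, ts_f, rcond=None)
    resid = ts_f - design @ beta
    cleaned = (resid + mean).T.reshape(grid + (T,))
    return cleaned


def connectivity(
    cleaned: np.ndarray,
    nodes: np.ndarray,
    censor_lo: CensorMask | None = None,
    fisher_z: bool = False,
) -> ConnectivityMatrix:
    """Pearson connectivity across retained frames.

    ``nodes`` is either a boolean mask (dense mode: every in-mask voxel is a
    node) or an integer label volume (parcel mode: voxel series are averaged
    within each positive label first). Correlations use only frames retained
    by ``censor_lo`` (the FC censoring mask, FD 0.2 mm). Nodes with constant
    series are flagged in ``undefined_nodes`` and their rows/columns set to 0
    rather than NaN-propagated.
    """
    cleaned = np.asarray(cleaned, dtype=float)
    nodes = np.asarray(nodes)
    T = cleaned.shape[-1]
    if censor_lo is not None:
        if censor_lo.n_frames != T:
            raise ValueError("censor mask length mismatch")
        keep = censor_lo.retained
    else:
        keep = np.ones(T, dtype=bool)
    if keep.sum() < 2:
        raise ValueError("need at least 2 retained frames")
    if nodes.dtype == bool:
        series = cleaned[nodes][:, keep]  # (N, T_kept)
        node_kind = "dense"
    else:
        labels = np.unique(nodes[nodes > 0])
        series = np.stack(
            [cleaned[nodes == lab][:, keep].mean(axis=0) for lab in labels]
        )
        node_kind = "parcel"
    series = series - series.mean(axis=1, keepdims=True)
    sd = series.std(axis=1)
    undefined = sd == 0
    if undefined.any():
        logger.warning("%d node(s) have constant series; flagged", undefined.sum())
    sd_safe = np.where(undefined, 1.0, sd)
    z = series / sd_safe[:, None]
    r = (z @ z.T) / keep.sum()
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    r[undefined, :] = 0.0
    r[:, undefined] = 0.0
    if fisher_z:
        with np.errstate(divide="ignore"):
            r = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    return ConnectivityMatrix(
        values=r,
        node_kind=node_kind,
        n_frames_used=int(keep.sum()),
        fd_threshold=None if censor_lo is None else censor_lo.threshold,
        fisher_z=fisher_z,
        undefined_nodes=undefined,
    )
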