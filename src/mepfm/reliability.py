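"""Permuted split-half reliability of connectivity matrices vs data amount.

A subject's runs are split in half; the connectivity matrix from increasing
consecutive amounts of one half is compared, node by node, against the matrix
from the entire held-out half. Because run quality varies within and across
sessions, the run order is randomly permuted (default 100 times) and the mean
and SD of the curve across permutations reported. Reliability at a grid point
is the average over nodes of the Pearson correlation between each node's
connectivity row in the two matrices, diagonal excluded.

Note the absolute values of such curves also depend on how much held-out data
anchors them: more held-out data raises the whole curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .motion import CensorMask

logger = logging.getLogger(__name__)

__all__ = [
    "ReliabilityCurve",
    "split_half_reliability",
    "reliability_equivalent_minutes",
]


@dataclass
class ReliabilityCurve:
    """Mean ± SD reliability at each data amount across permutations."""

    minutes_grid: np.ndarray
    mean_r: np.ndarray
    sd_r: np.ndarray
    n_permutations: int
    node_kind: str = "dense"
    node_reliability: np.ndarray | None = None  # per-node map at max data

    def __post_init__(self) -> None:
        self.minutes_grid = np.asarray(self.minutes_grid, dtype=float)
        self.mean_r = np.asarray(self.mean_r, dtype=float)
        self.sd_r = np.asarray(self.sd_r, dtype=float)
        if not (np.diff(self.minutes_grid) > 0).all():
            raise ValueError("minutes_grid must be strictly increasing")
        if (np.abs(self.mean_r) > 1 + 1e-12).any() or (self.sd_r < 0).any():
            raise ValueError("invalid reliability values")


def _corr_matrix(series: np.ndarray) -> np.ndarray:
    """Pearson correlations across columns of an (N, T) array."""
    z = series - series.mean(axis=1, keepdims=True)
    sd = z.std(axis=1)
    sd[sd == 0] = 1.0
    z /= sd[:, None]
    r = (z @ z.T) / series.shape[1]
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def _row_reliability(a: np.ndarray, b: np.ndarray, fisher_z: bool) -> np.ndarray:
    """Per-node Pearson correlation of connectivity rows, diagonal excluded."""
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    ra = a[off].reshape(n, n - 1)
    rb = b[off].reshape(n, n - 1)
    if fisher_z:
        ra = np.arctanh(np.clip(ra, -1 + 1e-15, 1 - 1e-15))
        rb = np.arctanh(np.clip(rb, -1 + 1e-15, 1 - 1e-15))
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    out = np.full(n, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def _retained_series(run, mask: CensorMask | None) -> np.ndarray:
    """Retained frames of one run, demeaned per node.

    Runs are demeaned before concatenation so between-run offset
    differences cannot masquerade as correlation structure.
    """
    run = np.asarray(run, dtype=float)
    if run.ndim != 2:
        raise ValueError("each run must be a (nodes, frames) array")
    if mask is not None:
        if mask.n_frames != run.shape[1]:
            raise ValueError("censor mask length does not match run frames")
        run = run[:, mask.retained]
    return run - run.mean(axis=1, keepdims=True)


def split_half_reliability(
    runs: list[np.ndarray | tuple[np.ndarray, CensorMask | None]],
    minutes_grid,
    tr: float,
    n_permutations: int = 100,
    seed: int = 0,
    node_kind: str = "dense",
    fisher_z: bool = False,
) -> ReliabilityCurve:
    """Permuted split-half reliability curve for one subject.

    Parameters
    ----------
    runs
        Cleaned node-by-frame series, optionally paired with a
        :class:`CensorMask` (FD 0.2 mm) whose retained frames are used.
    minutes_grid
        Data amounts (minutes) at which the growing half is evaluated;
        converted to frames as floor(m·60/TR) of retained frames. Grid
        points exceeding the available data are dropped with a warning.
    tr
        Repetition time in seconds.
    n_permutations
        Random run-order permutations (seeded); mean and SD of the curve
        are taken across them.

    With an odd number of runs the extra run goes to the held-out half.
    """
    mats = []
    for item in runs:
        if isinstance(item, tuple):
            mats.append(_retained_series(*item))
        else:
            mats.append(_retained_series(item, None))
    if len(mats) < 2:
        raise ValueError("at least two runs are required for a split half")
    n_nodes = mats[0].shape[0]
    if any(m.shape[0] != n_nodes for m in mats):
        raise ValueError("all runs must share the node set")
    minutes_grid = np.sort(np.asarray(minutes_grid, dtype=float))
    n_half = len(mats) // 2  # growing half; extra run is held out
    frames_half = None
    rng = np.random.default_rng(seed)

    per_perm = []
    node_rel_acc = np.zeros(n_nodes)
    n_rel = 0
    for _ in range(n_permutations):
        order = rng.permutation(len(mats))
        half_a = np.concatenate([mats[i] for i in order[:n_half]], axis=1)
        half_b = np.concatenate([mats[i] for i in order[n_half:]], axis=1)
        if frames_half is None:
            frames_half = half_a.shape[1]
        ref = _corr_matrix(half_b)
        row = []
        for m in minutes_grid:
            nf = int(np.floor(m * 60.0 / tr))
            if nf < 2 or nf > half_a.shape[1]:
                row.append(np.nan)
                continue
            node_r = _row_reliability(_corr_matrix(half_a[:, :nf]), ref, fisher_z)
            row.append(float(np.nanmean(node_r)))
            if nf == half_a.shape[1] or m == minutes_grid[-1]:
                last_node_r = node_r
        per_perm.append(row)
        if "last_node_r" in locals():
            node_rel_acc += np.nan_to_num(last_node_r)
            n_rel += 1
    arr = np.asarray(per_perm)  # (perms, grid)
    keep = ~np.isnan(arr).all(axis=0)
    if not keep.all():
        logger.warning(
            "dropping %d grid point(s) exceeding available retained data",
            int((~keep).sum()),
        )
    if not keep.any():
        raise ValueError("no grid point is attainable with the available data")
    mean_r = np.nanmean(arr[:, keep], axis=0)
    sd_r = np.nanstd(arr[:, keep], axis=0)
    return ReliabilityCurve(
        minutes_grid=minutes_grid[keep],
        mean_r=np.clip(mean_r, -1.0, 1.0),
        sd_r=sd_r,
        n_permutations=n_permutations,
        node_kind=node_kind,
        node_reliability=node_rel_acc / n_rel if n_rel else None,
    )


def reliability_equivalent_minutes(
    curve: ReliabilityCurve, target: float
) -> float | None:
    """Minutes at which ``curve`` first reaches ``target`` reliability.

    Linear interpolation between grid points; returns None when the target
    is never reached. Used to express one condition's reliability budget in
    another condition's scan time (e.g. "the 70-minute single-echo value is
    reached in 10-15 minutes").
    """
    m, r = curve.minutes_grid, curve.mean_r
    if r[0] >= target:
        return float(m[0])
    for i in range(1, len(m)):
        if r[i] >= target:
            lo_m, hi_m, lo_r, hi_r = m[i - 1], m[i], r[i - 1], r[i]
            if hi_r == lo_r:
                return float(hi_m)
            return float(lo_m + (target - lo_r) * (hi_m - lo_m) / (hi_r - lo_r))
    return None
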