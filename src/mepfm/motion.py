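"""Framewise displacement, respiratory band-stop filtering, frame censoring,
and run-level inclusion rules.

Conventions follow the common volumetric resting-state QC practice: FD is the
sum of absolute backward differences of the six rigid-body parameters, with
rotations converted to arc length on a 50 mm sphere; the first frame has
FD = 0 and is always retained. Threshold semantics are strict exactly as
stated: frames with FD > threshold are censored, runs with > 90 % low-motion
frames qualify for tSNR averaging, runs with < 30 % retained at FD 0.3 mm are
excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "MotionTrace",
    "CensorMask",
    "framewise_displacement",
    "bandstop_motion",
    "censor",
    "select_runs",
]


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per frame.

    translations in mm (x, y, z), rotations in radians (x, y, z); one row per
    BOLD signal frame (noise frames carry no motion estimate).
    """

    translations: np.ndarray  # (T, 3) mm
    rotations: np.ndarray  # (T, 3) radians
    tr: float

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be (T, 3)")
        if not (np.isfinite(self.translations).all() and np.isfinite(self.rotations).all()):
            raise ValueError("motion parameters must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_frames(self) -> int:
        return self.translations.shape[0]

    def as_array(self) -> np.ndarray:
        """(T, 6) array: 3 translations then 3 rotations."""
        return np.hstack([self.translations, self.rotations])


@dataclass
class CensorMask:
    """FD series with the boolean retained-frame mask at one threshold."""

    fd: np.ndarray
    threshold: float
    retained: np.ndarray

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.fd.shape != self.retained.shape:
            raise ValueError("fd and retained must have the same length")

    @property
    def n_frames(self) -> int:
        return self.fd.size

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def pct_retained(self) -> float:
        return 100.0 * self.n_retained / self.n_frames


def framewise_displacement(motion: MotionTrace, head_radius: float = 50.0) -> np.ndarray:
    """Per-frame FD in mm: Σ|Δtranslation| + head_radius·Σ|Δrotation|.

    Backward differences; FD of the first frame is defined as 0.
    """
    p = motion.as_array()
    d = np.abs(np.diff(p, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def bandstop_motion(
    motion: MotionTrace, band_bpm: tuple[float, float]
) -> MotionTrace:
    """Zero-phase band-stop (notch) filter on all six motion parameters.

    The band is given in breaths per minute and converted to Hz as bpm/60;
    a second-order Butterworth band-stop is applied forward and backward
    (``filtfilt``). If the lower band edge reaches the Nyquist frequency of
    the sampling rate 1/TR — as happens for fast-breathing infants at long
    TRs — filtering is skipped with a logged reason and the trace is returned
    unchanged.
    """
    lo_bpm, hi_bpm = band_bpm
    if not 0 < lo_bpm < hi_bpm:
        raise ValueError("band must satisfy 0 < low < high")
    nyq = 0.5 / motion.tr
    lo, hi = lo_bpm / 60.0, hi_bpm / 60.0
    if lo >= nyq:
        logger.warning(
            "respiratory band (%.3f-%.3f Hz) at/above Nyquist %.3f Hz; "
            "band-stop filter skipped",
            lo,
            hi,
            nyq,
        )
        return motion
    hi = min(hi, 0.999 * nyq)
    b, a = sps.butter(2, [lo / nyq, hi / nyq], btype="bandstop")
    params = sps.filtfilt(b, a, motion.as_array(), axis=0)
    return replace(motion, translations=params[:, :3], rotations=params[:, 3:])


def censor(fd: np.ndarray, threshold: float) -> CensorMask:
    """Retained-frame mask: frames with FD > threshold are censored (strict)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fd = np.asarray(fd, dtype=float)
    retained = fd <= threshold
    if fd.size:
        retained = retained.copy()
        retained[0] = True  # first frame has FD 0 by convention
    return CensorMask(fd=fd, threshold=threshold, retained=retained)


def select_runs(masks: list[CensorMask], rule: str) -> list[int]:
    """Run-level inclusion rules, applied to FD-0.3 censor masks.

    ``tsnr_averaging`` keeps runs with strictly more than 90 % low-motion
    frames; ``infant_inclusion`` drops runs with strictly less than 30 %
    retained frames. Returns the kept run indices (0-based).
    """
    if not masks:
        raise ValueError("at least one run required")
    pct = np.array([m.pct_retained for m in masks])
    if rule == "tsnr_averaging":
        kept = np.flatnonzero(pct > 90.0)
    elif rule == "infant_inclusion":
        kept = np.flatnonzero(pct >= 30.0)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if kept.size == 0:
        logger.warning("no runs qualify under rule %r", rule)
    return kept.tolist()
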