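"""Acquisition metadata and age-specific tissue presets.

Echo times and T2* are in milliseconds throughout the package; TR in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AcquisitionParams:
    """Protocol-level metadata for one multi-echo BOLD run.

    Parameters
    ----------
    echo_times : tuple of float
        Echo times in ms, strictly increasing and positive.
    tr : float
        Repetition time in seconds.
    n_frames : int
        Number of BOLD frames carrying signal (noise frames excluded).
    n_noise_frames : int
        Frames appended at the end of the run acquired without excitation;
        they contain thermal noise only and drive the empirical noise
        estimate used by the denoiser.
    grid_shape : tuple of int
        Spatial matrix size (3 positive integers).
    voxel_size : float
        Isotropic voxel edge in mm.
    """

    echo_times: tuple[float, ...]
    tr: float = 1.761
    n_frames: int = 120
    n_noise_frames: int = 3
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 2.0

    def __post_init__(self) -> None:
        te = tuple(float(t) for t in self.echo_times)
        if len(te) < 1 or any(t <= 0 for t in te):
            raise ValueError("echo_times must be positive")
        if any(b <= a for a, b in zip(te, te[1:])):
            raise ValueError("echo_times must be strictly increasing")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_noise_frames < 0:
            raise ValueError("n_noise_frames must be >= 0")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.tr <= 0 or self.voxel_size <= 0:
            raise ValueError("tr and voxel_size must be positive")
        object.__setattr__(self, "echo_times", te)
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr


#: The five-echo protocol with three trailing noise frames.
FIVE_ECHO = AcquisitionParams(
    echo_times=(14.2, 38.93, 63.66, 88.39, 113.12),
    tr=1.761,
    n_noise_frames=3,
)


@dataclass(frozen=True)
class TissuePreset:
    """Marginal T2* distribution for one age group.

    T2* is sampled from a truncated normal with the given mean/SD and clipped
    to ``t2star_bounds``. Infant cortex has markedly longer and more variable
    T2* than adult cortex, which shifts optimal echo weighting toward later
    echoes.
    """

    label: str
    t2star_mean: float
    t2star_sd: float
    t2star_bounds: tuple[float, float] = (5.0, 200.0)
    s0_mean: float = 1000.0

    def __post_init__(self) -> None:
        lo, hi = self.t2star_bounds
        if not (lo < self.t2star_mean < hi):
            raise ValueError("t2star_mean must lie inside t2star_bounds")
        if self.t2star_sd <= 0:
            raise ValueError("t2star_sd must be positive")
        if hi <= lo:
            raise ValueError("degenerate t2star_bounds")
        if self.s0_mean <= 0:
            raise ValueError("s0_mean must be positive")


# Cortical T2* at 3 T: mean/SD by age group.
TISSUE_PRESETS: dict[str, TissuePreset] = {
    "adult": TissuePreset("adult", 48.89, 12.23),
    "child": TissuePreset("child", 59.34, 13.96),
    "infant": TissuePreset("infant", 93.84, 27.04),
}
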