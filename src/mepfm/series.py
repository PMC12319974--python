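"""The central multi-echo signal container."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class MultiEchoSeries:
    """Per-echo 4D magnitude (and optionally phase) data plus metadata.

    Arrays are indexed ``(echo, x, y, z, t)``. The last ``n_noise_frames``
    frames along the time axis carry thermal noise only (no excitation);
    every analysis stage must exclude them from signal statistics.
    """

    magnitude: np.ndarray
    echo_times: tuple[float, ...]
    tr: float
    n_noise_frames: int = 0
    phase: np.ndarray | None = None
    voxel_size: float = 2.0

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.magnitude.ndim == 4:  # single echo without leading axis
            self.magnitude = self.magnitude[None]
        if self.magnitude.ndim != 5:
            raise ValueError("magnitude must be (echo, x, y, z, t)")
        self.echo_times = tuple(float(t) for t in self.echo_times)
        if self.magnitude.shape[0] != len(self.echo_times):
            raise ValueError("echo axis does not match echo_times")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)
            if self.phase.shape != self.magnitude.shape:
                raise ValueError("phase shape must match magnitude")
        if self.n_noise_frames < 0 or self.n_noise_frames >= self.magnitude.shape[-1]:
            raise ValueError("invalid n_noise_frames")

    @property
    def n_echoes(self) -> int:
        return self.magnitude.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape[1:4]

    @property
    def n_frames_total(self) -> int:
        return self.magnitude.shape[-1]

    @property
    def n_frames(self) -> int:
        """Signal frames only (noise frames excluded)."""
        return self.n_frames_total - self.n_noise_frames

    def signal_frames(self) -> "MultiEchoSeries":
        """The series restricted to the signal frames."""
        if self.n_noise_frames == 0:
            return self
        sl = slice(0, self.n_frames)
        return replace(
            self,
            magnitude=self.magnitude[..., sl],
            phase=None if self.phase is None else self.phase[..., sl],
            n_noise_frames=0,
        )

    def noise_frames(self) -> "MultiEchoSeries":
        """Only the trailing noise frames (raises if there are none)."""
        if self.n_noise_frames == 0:
            raise ValueError("series has no noise frames")
        sl = slice(self.n_frames, None)
        return replace(
            self,
            magnitude=self.magnitude[..., sl],
            phase=None if self.phase is None else self.phase[..., sl],
            n_noise_frames=0,
        )

    def complex_data(self) -> np.ndarray:
        """magnitude·exp(i·phase); requires phase."""
        if self.phase is None:
            raise ValueError("series has no phase data")
        return self.magnitude * np.exp(1j * self.phase)

    def echo(self, echo_index: int) -> "MultiEchoSeries":
        """Single-echo sub-series (0-based index)."""
        if not 0 <= echo_index < self.n_echoes:
            raise IndexError(
                f"echo_index {echo_index} out of range for {self.n_echoes} echoes"
            )
        return replace(
            self,
            magnitude=self.magnitude[echo_index : echo_index + 1],
            phase=None
            if self.phase is None
            else self.phase[echo_index : echo_index + 1],
            echo_times=(self.echo_times[echo_index],),
        )
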