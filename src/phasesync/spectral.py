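"""Continuous Morlet wavelet transform of ROI time courses.

The wavelet at frequency f carries n = f / cycles_divisor cycles, i.e. a
Gaussian envelope with sigma_t = n / (2 * pi * f) seconds, and is
normalized to unit L2 energy.  With the default divisor of 7 the cycle
count runs from 8/7 = 1.14 at 8 Hz to 80/7 = 11.43 at 80 Hz.  Only the
coefficient phase enters the connectivity stage, so the amplitude
normalization choice is inconsequential downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.signal import fftconvolve

from .epochs import EpochArray
from .exceptions import FrequencyGridError

__all__ = ["FrequencyGrid", "TFCube", "build_frequency_grid", "morlet_transform", "morlet_wavelet"]


@dataclass
class FrequencyGrid:
    """Arithmetic grid of wavelet center frequencies with a cycle schedule."""

    start: float = 8.0
    stop: float = 80.0
    step: float = 3.0
    cycles_divisor: float = 7.0

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise FrequencyGridError("start must be <= stop")
        if self.step <= 0:
            raise FrequencyGridError("step must be > 0")
        span = self.stop - self.start
        n_steps = span / self.step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise FrequencyGridError(
                f"span {span} Hz is not divisible by step {self.step} Hz: grid ambiguous"
            )
        if self.cycles_divisor <= 0:
            raise FrequencyGridError("cycles_divisor must be > 0")

    @property
    def frequencies(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    def cycles(self, frequency: float | np.ndarray) -> float | np.ndarray:
        return frequency / self.cycles_divisor

    def __len__(self) -> int:
        return len(self.frequencies)


def build_frequency_grid(
    start: float = 8.0, stop: float = 80.0, step: float = 3.0, cycles_divisor: float = 7.0
) -> FrequencyGrid:
    """Validated arithmetic frequency grid, inclusive of both endpoints."""
    return FrequencyGrid(start=start, stop=stop, step=step, cycles_divisor=cycles_divisor)


@dataclass
class TFCube:
    """Complex wavelet coefficients, trials x ROIs x frequencies x samples."""

    coefficients: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    rois: list[str]
    boundary: np.ndarray = field(default=None)  # type: ignore[assignment]
    sfreq: float = 1000.0

    def __post_init__(self) -> None:
        if self.boundary is None:
            self.boundary = np.zeros(
                (len(self.freqs), len(self.times)), dtype=bool
            )

    @property
    def n_trials(self) -> int:
        return self.coefficients.shape[0]

    def roi_index(self, label: str) -> int:
        from .exceptions import UnknownROIError

        try:
            return self.rois.index(label)
        except ValueError:
            raise UnknownROIError(f"ROI {label!r} not in {self.rois}") from None

    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("coefficients", data=self.coefficients)
            f.create_dataset("freqs", data=self.freqs)
            f.create_dataset("times", data=self.times)
            f.create_dataset("boundary", data=self.boundary)
            f.attrs["sfreq"] = self.sfreq
            f.create_dataset("rois", data=np.array(self.rois, dtype=h5py.string_dtype()))

    @classmethod
    def from_hdf5(cls, path: str) -> "TFCube":
        with h5py.File(path, "r") as f:
            return cls(
                coefficients=f["coefficients"][()],
                freqs=f["freqs"][()],
                times=f["times"][()],
                rois=[r.decode() if isinstance(r, bytes) else str(r) for r in f["rois"][()]],
                boundary=f["boundary"][()],
                sfreq=float(f.attrs["sfreq"]),
            )


def morlet_wavelet(
    frequency: float, sfreq: float, n_cycles: float, n_sigmas: float = 4.0
) -> np.ndarray:
    """Complex Morlet wavelet, unit L2 norm, odd length covering +-n_sigmas."""
    sigma_t = n_cycles / (2 * np.pi * frequency)
    half = max(1, int(np.ceil(n_sigmas * sigma_t * sfreq)))
    t = np.arange(-half, half + 1) / sfreq
    wav = np.exp(2j * np.pi * frequency * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return wav / np.linalg.norm(wav)


def morlet_transform(epochs: EpochArray, grid: FrequencyGrid) -> TFCube:
    """Morlet CWT of every trial x ROI trace on the grid frequencies.

    Convolution uses zero padding; output is aligned to the input time
    axis.  ``boundary[f, t]`` flags samples within one wavelet
    half-support of either epoch edge, where zero padding leaks in.
    """
    freqs = grid.frequencies
    nyquist = epochs.sfreq / 2.0
    if freqs.max() >= nyquist:
        raise FrequencyGridError(
            f"max frequency {freqs.max()} Hz >= Nyquist {nyquist} Hz"
        )
    n_trials, n_rois, n_samples = epochs.data.shape
    coeffs = np.empty((n_trials, n_rois, len(freqs), n_samples), dtype=np.complex128)
    boundary = np.zeros((len(freqs), n_samples), dtype=bool)
    flat = epochs.data.reshape(n_trials * n_rois, n_samples)
    for fi, f in enumerate(freqs):
        wav = morlet_wavelet(f, epochs.sfreq, grid.cycles(f))
        if len(wav) > n_samples:
            raise FrequencyGridError(
                f"wavelet support ({len(wav)} samples) exceeds epoch length "
                f"({n_samples}) at {f} Hz"
            )
        conv = fftconvolve(flat, wav[None, :], mode="same", axes=1)
        coeffs[:, :, fi, :] = conv.reshape(n_trials, n_rois, n_samples)
        half = len(wav) // 2
        boundary[fi, :half] = True
        if half > 0:
            boundary[fi, -half:] = True
    return TFCube(
        coefficients=coeffs,
        freqs=freqs,
        times=epochs.times.copy(),
        rois=list(epochs.rois),
        boundary=boundary,
        sfreq=epochs.sfreq,
    )
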