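"""Across-trial WPLI per ROI pair x frequency x time, with window averaging.

WPLI(f, t) = |sum_k Im X_k(f, t)| / sum_k |Im X_k(f, t)| over trials k,
where X is the complex cross-spectrum between a pair of ROIs.  A zero
denominator (all imaginary parts exactly zero) yields NaN — "undefined"
is a different claim from 0, which encodes random phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import h5py
import numpy as np
import pandas as pd

from .exceptions import InsufficientTrialsError, WindowError
from .spectral import TFCube

__all__ = ["SyncMap", "cross_spectrum", "wpli", "window_average", "compute_syncmap"]


@dataclass
class SyncMap:
    """WPLI values indexed by ROI pair x frequency x 10-ms window."""

    wpli: np.ndarray  # (n_pairs, n_freqs, n_windows), NaN = undefined
    pairs: list[tuple[str, str]]
    freqs: np.ndarray
    window_starts: np.ndarray  # ms, left edges
    window_width: float = 10.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        defined = self.wpli[np.isfinite(self.wpli)]
        if defined.size and (defined.min() < -1e-12 or defined.max() > 1 + 1e-12):
            raise ValueError("WPLI values must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pi, pair in enumerate(self.pairs):
            for fi, f in enumerate(self.freqs):
                for wi, w0 in enumerate(self.window_starts):
                    rows.append(
                        {
                            **self.meta,
                            "pair": f"{pair[0]}--{pair[1]}",
                            "frequency": float(f),
                            "window_start": float(w0),
                            "wpli": float(self.wpli[pi, fi, wi]),
                        }
                    )
        return pd.DataFrame(rows)

    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("wpli", data=self.wpli)
            f.create_dataset("freqs", data=self.freqs)
            f.create_dataset("window_starts", data=self.window_starts)
            f.attrs["window_width"] = self.window_width
            pair_labels = [f"{a}--{b}" for a, b in self.pairs]
            f.create_dataset("pairs", data=np.array(pair_labels, dtype=h5py.string_dtype()))
            for k, v in self.meta.items():
                f.attrs[f"meta_{k}"] = v


def cross_spectrum(tf: TFCube, pair: tuple[str, str]) -> np.ndarray:
    """Per-trial cross-spectrum A * conj(B): (n_trials, n_freqs, n_samples)."""
    ia = tf.roi_index(pair[0])
    ib = tf.roi_index(pair[1])
    return tf.coefficients[:, ia] * np.conj(tf.coefficients[:, ib])


def wpli(cross: np.ndarray, axis: int = 0) -> np.ndarray:
    """Weighted phase lag index over the trial axis.

    Returns values in [0, 1]; entries where the denominator is exactly
    zero are NaN (undefined), not 0.
    """
    cross = np.asarray(cross)
    if cross.shape[axis] < 2:
        raise InsufficientTrialsError("WPLI requires at least 2 trials")
    im = np.imag(cross)
    num = np.abs(im.sum(axis=axis))
    den = np.abs(im).sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out


def window_average(
    values: np.ndarray,
    times: np.ndarray,
    time_range: tuple[float, float] = (50.0, 200.0),
    width: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Average per-sample values into fixed-width bins over [t0, t1) ms.

    ``values`` has time as its last axis, aligned with ``times``.  NaN
    samples are excluded from each bin mean; a bin is NaN only when all
    its samples are NaN.  Returns (binned values, bin left edges).
    """
    t0, t1 = time_range
    span = t1 - t0
    n_bins = span / width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise WindowError(f"range {time_range} not divisible into {width} ms bins")
    n_bins = int(round(n_bins))
    dt = np.median(np.diff(times))
    per_bin = width / dt
    if abs(per_bin - round(per_bin)) > 1e-6:
        raise WindowError(
            f"bin width {width} ms is not a whole number of samples (dt={dt} ms)"
        )
    edges = t0 + width * np.arange(n_bins + 1)
    out_shape = values.shape[:-1] + (n_bins,)
    out = np.full(out_shape, np.nan)
    for b in range(n_bins):
        mask = (times >= edges[b] - 1e-9) & (times < edges[b + 1] - 1e-9)
        if not mask.any():
            raise WindowError(f"bin [{edges[b]}, {edges[b+1]}) ms holds no samples")
        chunk = values[..., mask]
        defined = np.isfinite(chunk)
        n_def = defined.sum(axis=-1)
        sums = np.where(defined, chunk, 0.0).sum(axis=-1)
        out[..., b] = np.where(n_def > 0, sums / np.maximum(n_def, 1), np.nan)
    return out, edges[:-1]


def compute_syncmap(
    tf: TFCube,
    pairs: list[tuple[str, str]] | None = None,
    time_range: tuple[float, float] = (50.0, 200.0),
    width: float = 10.0,
    meta: dict | None = None,
) -> SyncMap:
    """Per-sample WPLI for every pair, then 10-ms window averages."""
    if pairs is None:
        pairs = list(combinations(tf.rois, 2))
    binned = []
    for pair in pairs:
        per_sample = wpli(cross_spectrum(tf, pair), axis=0)  # (freqs, samples)
        vals, starts = window_average(per_sample, tf.times, time_range, width)
        binned.append(vals)
    return SyncMap(
        wpli=np.stack(binned, axis=0),
        pairs=list(pairs),
        freqs=tf.freqs.copy(),
        window_starts=starts,
        window_width=width,
        meta=meta or {},
    )
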