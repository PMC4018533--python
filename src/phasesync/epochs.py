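"""Epoch container: one subject's trials x ROIs x samples with metadata.

``EpochArray`` is the unit of all downstream computation.  Time is in
milliseconds throughout, with the epoch covering the half-open interval
``[tmin, tmin + n_samples * 1000 / sfreq)`` so a [-200, +500) ms epoch at
1000 Hz holds exactly 700 samples and t = 0 falls on sample index 200.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .exceptions import UnknownROIError, WindowError

__all__ = ["EpochArray"]


@dataclass
class EpochArray:
    """Real-valued epochs for a single subject.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_rois, n_samples)
        ROI time courses.
    sfreq : float
        Sampling rate in Hz.
    tmin : float
        Time of the first sample in ms relative to stimulus onset.
    rois : list of str
        Unique ROI labels, one per data row.
    trials : pandas.DataFrame
        One row per trial; columns typically include ``trial_id``,
        ``condition`` and ``stimulus``.
    aux : ndarray, shape (n_trials, n_samples), optional
        A single auxiliary channel (e.g. an EOG stand-in) used only by
        amplitude-based trial rejection.
    """

    data: np.ndarray
    sfreq: float
    tmin: float
    rois: list[str]
    trials: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    aux: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_rois, n_samples)")
        if len(self.rois) != self.data.shape[1]:
            raise ValueError("number of ROI labels must match data rows")
        if len(set(self.rois)) != len(self.rois):
            raise ValueError("ROI labels must be unique")
        if self.trials is None:
            self.trials = pd.DataFrame({"trial_id": np.arange(self.data.shape[0])})
        if len(self.trials) != self.data.shape[0]:
            raise ValueError("trial table length must match number of trials")
        if self.aux is not None:
            self.aux = np.asarray(self.aux, dtype=np.float64)
            if self.aux.shape != (self.data.shape[0], self.data.shape[2]):
                raise ValueError("aux must be (n_trials, n_samples)")

    # ------------------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.tmin + np.arange(self.n_samples) * 1000.0 / self.sfreq

    # ------------------------------------------------------------------
    def roi_index(self, label: str) -> int:
        try:
            return self.rois.index(label)
        except ValueError:
            raise UnknownROIError(
                f"ROI {label!r} not in {self.rois}"
            ) from None

    def time_mask(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Boolean mask of samples in the half-open interval [start, stop) ms."""
        t = self.times
        mask = (t >= start_ms - 1e-9) & (t < stop_ms - 1e-9)
        if not mask.any():
            raise WindowError(f"window [{start_ms}, {stop_ms}) ms holds no samples")
        return mask

    def select_trials(self, index: np.ndarray) -> "EpochArray":
        """New EpochArray restricted to the given trial indices (order kept)."""
        index = np.asarray(index)
        return EpochArray(
            data=self.data[index],
            sfreq=self.sfreq,
            tmin=self.tmin,
            rois=list(self.rois),
            trials=self.trials.iloc[index].reset_index(drop=True),
            aux=None if self.aux is None else self.aux[index],
        )

    # ------------------------------------------------------------------
    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            f.attrs["sfreq"] = self.sfreq
            f.attrs["tmin"] = self.tmin
            f.create_dataset(
                "rois", data=np.array(self.rois, dtype=h5py.string_dtype())
            )
            if self.aux is not None:
                f.create_dataset("aux", data=self.aux)
            grp = f.create_group("trials")
            for col in self.trials.columns:
                values = self.trials[col].to_numpy()
                if values.dtype == object:
                    values = values.astype(h5py.string_dtype())
                grp.create_dataset(col, data=values)

    @classmethod
    def from_hdf5(cls, path: str) -> "EpochArray":
        with h5py.File(path, "r") as f:
            rois = [r.decode() if isinstance(r, bytes) else str(r) for r in f["rois"][()]]
            trial_cols = {}
            for col in f["trials"]:
                vals = f["trials"][col][()]
                if vals.dtype.kind in "SO":
                    vals = np.array([v.decode() if isinstance(v, bytes) else v for v in vals])
                trial_cols[col] = vals
            return cls(
                data=f["data"][()],
                sfreq=float(f.attrs["sfreq"]),
                tmin=float(f.attrs["tmin"]),
                rois=rois,
                trials=pd.DataFrame(trial_cols),
                aux=f["aux"][()] if "aux" in f else None,
            )
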