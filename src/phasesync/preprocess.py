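"""Epoch-level cleaning: baseline correction, amplitude rejection, equalization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import EpochArray
from .exceptions import AllTrialsRejectedError, WindowError

__all__ = [
    "RejectionCriteria",
    "baseline_correct",
    "reject_trials",
    "equalize_trial_counts",
]


@dataclass
class RejectionCriteria:
    """Amplitude thresholds for trial rejection.

    ``signal_threshold`` applies to baseline-corrected ROI traces,
    ``aux_threshold`` to the raw auxiliary channel.
    """

    signal_threshold: float = np.inf
    aux_threshold: float = np.inf
    baseline_window: tuple[float, float] = (-200.0, 0.0)

    def __post_init__(self) -> None:
        if self.signal_threshold <= 0 or self.aux_threshold <= 0:
            raise ValueError("thresholds must be > 0")


def baseline_correct(
    epochs: EpochArray, baseline_window: tuple[float, float] = (-200.0, 0.0)
) -> EpochArray:
    """Subtract the per-trial, per-ROI mean over the baseline window."""
    if baseline_window[1] <= baseline_window[0]:
        raise WindowError("baseline window is empty")
    mask = epochs.time_mask(*baseline_window)
    means = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochArray(
        data=epochs.data - means,
        sfreq=epochs.sfreq,
        tmin=epochs.tmin,
        rois=list(epochs.rois),
        trials=epochs.trials.copy(),
        aux=None if epochs.aux is None else epochs.aux.copy(),
    )


def reject_trials(
    epochs: EpochArray, criteria: RejectionCriteria
) -> tuple[EpochArray, pd.DataFrame]:
    """Drop trials whose peak amplitude exceeds the criteria.

    A trial is rejected iff the maximum absolute baseline-corrected
    amplitude on any ROI exceeds ``signal_threshold``, or the raw aux
    channel exceeds ``aux_threshold``.  Returns the retained epochs and a
    log with one row per rejected (trial, channel) exceedance.
    """
    corrected = baseline_correct(epochs, criteria.baseline_window)
    peaks = np.abs(corrected.data).max(axis=2)  # trials x rois
    log_rows = []
    bad = np.zeros(epochs.n_trials, dtype=bool)
    for t, r in zip(*np.where(peaks > criteria.signal_threshold)):
        bad[t] = True
        log_rows.append(
            {
                "trial_id": int(epochs.trials["trial_id"].iloc[t]),
                "channel": epochs.rois[r],
                "peak": float(peaks[t, r]),
                "threshold": criteria.signal_threshold,
                "reason": "signal_amplitude",
            }
        )
    if epochs.aux is not None:
        aux_peaks = np.abs(epochs.aux).max(axis=1)
        for t in np.where(aux_peaks > criteria.aux_threshold)[0]:
            bad[t] = True
            log_rows.append(
                {
                    "trial_id": int(epochs.trials["trial_id"].iloc[t]),
                    "channel": "aux",
                    "peak": float(aux_peaks[t]),
                    "threshold": criteria.aux_threshold,
                    "reason": "aux_amplitude",
                }
            )
    if bad.all():
        raise AllTrialsRejectedError("every trial exceeded the rejection criteria")
    log = pd.DataFrame(
        log_rows, columns=["trial_id", "channel", "peak", "threshold", "reason"]
    )
    return epochs.select_trials(np.where(~bad)[0]), log


def equalize_trial_counts(
    groups: list[EpochArray], seed: int = 0
) -> list[EpochArray]:
    """Subsample every group to the minimum group size.

    Sampling is uniform without replacement with the given seed; the
    surviving trials keep their original order.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to equalize")
    sizes = [g.n_trials for g in groups]
    if min(sizes) == 0:
        raise ValueError("groups must be non-empty")
    target = min(sizes)
    rng = np.random.default_rng(seed)
    out = []
    for g in groups:
        if g.n_trials == target:
            out.append(g)
        else:
            keep = np.sort(rng.choice(g.n_trials, size=target, replace=False))
            out.append(g.select_trials(keep))
    return out
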