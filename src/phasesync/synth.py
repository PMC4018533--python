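"""Synthetic multi-subject epoch generator with known ground-truth coupling.

Each ROI trace is a sum of three ingredients:

* 1/f background noise (spectrally shaped white noise, unit variance),
* an optional evoked component — a damped 10 Hz cosine with identical
  phase on every trial, time-locked to stimulus onset, and
* induced coupled components — a source oscillator with a fresh uniform
  random phase per trial injected into both ROIs of a coupling, the
  second copy delayed by a physical conduction delay derived from the
  requested phase lag, gated to a post-onset window with cosine ramps.

Because the induced phase is random across trials but the *lag* between
the two ROIs is fixed, across-trial WPLI detects the coupling while
trial-shuffle surrogates destroy it — mirroring the evoked/induced
distinction the downstream surrogate test relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import EpochArray
from .exceptions import UnknownROIError, WindowError

__all__ = [
    "StudyDesign",
    "CouplingSpec",
    "BehavioralSpec",
    "generate_subject",
    "generate_cohort",
    "one_over_f_noise",
]

_DEFAULT_ROIS = [
    f"{roi}-{hemi}"
    for hemi in ("lh", "rh")
    for roi in ("AC", "TPJ", "vPMC", "dPMC", "MC")
]


@dataclass
class StudyDesign:
    """Experimental design: cells, trial counts, epoch timing."""

    n_subjects: int = 20
    conditions: list[str] = field(default_factory=lambda: ["passive", "active"])
    stimulus_types: list[str] = field(default_factory=lambda: ["intact", "noisy"])
    tokens: list[str] = field(default_factory=lambda: ["pa", "ta"])
    trials_per_cell: int = 75
    rois: list[str] = field(default_factory=lambda: list(_DEFAULT_ROIS))
    epoch_window: tuple[float, float] = (-200.0, 500.0)
    sampling_rate: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for labels, what in (
            (self.conditions, "conditions"),
            (self.stimulus_types, "stimulus_types"),
            (self.tokens, "tokens"),
            (self.rois, "rois"),
        ):
            if len(set(labels)) != len(labels):
                raise ValueError(f"{what} labels must be unique")
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")
        if self.epoch_window[1] <= self.epoch_window[0]:
            raise ValueError("epoch_window must be increasing")

    @property
    def n_samples(self) -> int:
        """Half-open [tmin, tmax) convention: span(ms) * rate / 1000 samples."""
        span = self.epoch_window[1] - self.epoch_window[0]
        return int(round(span * self.sampling_rate / 1000.0))

    @property
    def trials_per_condition(self) -> int:
        """75 x 4 by default: trials_per_cell x stimulus types x tokens."""
        return self.trials_per_cell * len(self.stimulus_types) * len(self.tokens)

    @property
    def n_trials(self) -> int:
        return self.trials_per_condition * len(self.conditions)

    def trial_table(self) -> pd.DataFrame:
        rows = []
        tid = 0
        for cond in self.conditions:
            for stim in self.stimulus_types:
                for tok in self.tokens:
                    for _ in range(self.trials_per_cell):
                        rows.append(
                            {
                                "trial_id": tid,
                                "condition": cond,
                                "stimulus": stim,
                                "token": tok,
                            }
                        )
                        tid += 1
        return pd.DataFrame(rows)


@dataclass
class CouplingSpec:
    """Band-limited induced coupling between an ordered ROI pair.

    The second ROI receives the source delayed by
    ``phase_lag / (2 * pi * center_frequency)`` seconds (a conduction
    delay), plus ``direction_lag`` ms when ``directed``.
    """

    roi_pair: tuple[str, str]
    center_frequency: float
    phase_lag: float = np.pi / 2
    coupling_window: tuple[float, float] = (50.0, 200.0)
    coupling_strength: float = 1.0
    directed: bool = False
    direction_lag: float = 0.0
    conditions: tuple[str, ...] | None = None  # None = all cells
    stimulus_types: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be >= 0")
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be > 0")

    @property
    def delay_ms(self) -> float:
        """Total A->B delay in ms (phase lag as conduction delay + directed lag)."""
        base = self.phase_lag / (2 * np.pi * self.center_frequency) * 1000.0
        return base + (self.direction_lag if self.directed else 0.0)


@dataclass
class BehavioralSpec:
    """Linear map from subject coupling gain to identification accuracy."""

    base_accuracy: float = 0.55
    accuracy_slope: float = 0.15
    noise_sd: float = 0.03


# ----------------------------------------------------------------------
def one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, ...], sfreq: float
) -> np.ndarray:
    """1/f noise over the trailing axis, unit variance.

    White Gaussian noise is shaped in the frequency domain with amplitude
    proportional to f**-0.5 (power ~ 1/f) for f >= 1 Hz and flat below;
    the DC bin is zeroed.  Each leading-axis slice is independent.
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    scale = np.ones_like(freqs)
    above = freqs >= 1.0
    scale[above] = freqs[above] ** -0.5
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _evoked_component(times_ms: np.ndarray) -> np.ndarray:
    """Damped 10 Hz cosine, onset +50 ms, 50 ms decay constant."""
    t = (times_ms - 50.0) / 1000.0
    active = t >= 0
    out = np.zeros_like(times_ms, dtype=float)
    out[active] = np.cos(2 * np.pi * 10.0 * t[active]) * np.exp(-t[active] / 0.050)
    return out


def _gate(times_ms: np.ndarray, window: tuple[float, float], ramp_ms: float = 10.0) -> np.ndarray:
    """Smooth gate: 1 inside window, cosine ramps of ramp_ms at the edges."""
    t0, t1 = window
    out = np.zeros_like(times_ms, dtype=float)
    inside = (times_ms >= t0) & (times_ms < t1)
    out[inside] = 1.0
    rise = (times_ms >= t0 - ramp_ms) & (times_ms < t0)
    out[rise] = 0.5 * (1 + np.cos(np.pi * (t0 - times_ms[rise]) / ramp_ms))
    fall = (times_ms >= t1) & (times_ms < t1 + ramp_ms)
    out[fall] = 0.5 * (1 + np.cos(np.pi * (times_ms[fall] - t1) / ramp_ms))
    return out


def _validate_couplings(
    design: StudyDesign, couplings: list[CouplingSpec]
) -> None:
    for c in couplings:
        for roi in c.roi_pair:
            if roi not in design.rois:
                raise UnknownROIError(f"coupling references unknown ROI {roi!r}")
        lo, hi = design.epoch_window
        if not (lo <= c.coupling_window[0] and c.coupling_window[1] <= hi):
            raise WindowError(
                f"coupling_window {c.coupling_window} outside epoch {design.epoch_window}"
            )


def generate_subject(
    design: StudyDesign,
    couplings: list[CouplingSpec] | None = None,
    subject_kappa: float = 1.0,
    seed: int | None = None,
    evoked_amplitude: float = 0.0,
    with_aux: bool = False,
) -> EpochArray:
    """Generate one subject's epochs with the requested coupling structure.

    Deterministic given ``seed``.  ``evoked_amplitude`` scales a
    phase-locked evoked component added identically to every trial and
    ROI; set > 0 to build evoked-only null fixtures.
    """
    couplings = list(couplings or [])
    _validate_couplings(design, couplings)
    rng = np.random.default_rng(design.seed if seed is None else seed)

    n_trials = design.n_trials
    n_rois = len(design.rois)
    n_samples = design.n_samples
    times = design.epoch_window[0] + np.arange(n_samples) * 1000.0 / design.sampling_rate

    data = one_over_f_noise(rng, (n_trials, n_rois, n_samples), design.sampling_rate)

    if evoked_amplitude != 0.0:
        data += evoked_amplitude * _evoked_component(times)[None, None, :]

    trial_table = design.trial_table()
    t_sec = times / 1000.0
    for c in couplings:
        amp = c.coupling_strength * subject_kappa
        if amp == 0.0:
            continue
        tmask = np.ones(n_trials, dtype=bool)
        if c.conditions is not None:
            tmask &= trial_table["condition"].isin(c.conditions).to_numpy()
        if c.stimulus_types is not None:
            tmask &= trial_table["stimulus"].isin(c.stimulus_types).to_numpy()
        ia = design.rois.index(c.roi_pair[0])
        ib = design.rois.index(c.roi_pair[1])
        gate_a = _gate(times, c.coupling_window)
        delay_ms = c.delay_ms
        gate_b = _gate(times - delay_ms, c.coupling_window)
        # draw a phase for every trial so the stream is cell-independent
        phases = rng.uniform(0, 2 * np.pi, size=n_trials)
        # source carrier; B receives the same carrier evaluated delay earlier
        carrier_a = np.cos(2 * np.pi * c.center_frequency * t_sec[None, :] + phases[:, None])
        t_b = t_sec - delay_ms / 1000.0
        carrier_b = np.cos(2 * np.pi * c.center_frequency * t_b[None, :] + phases[:, None])
        sel = tmask[:, None]
        data[:, ia, :] += amp * gate_a[None, :] * carrier_a * sel
        data[:, ib, :] += amp * gate_b[None, :] * carrier_b * sel

    aux = rng.standard_normal((n_trials, n_samples)) if with_aux else None
    return EpochArray(
        data=data,
        sfreq=design.sampling_rate,
        tmin=design.epoch_window[0],
        rois=list(design.rois),
        trials=design.trial_table(),
        aux=aux,
    )


def generate_cohort(
    design: StudyDesign,
    couplings: list[CouplingSpec] | None = None,
    behavioral: BehavioralSpec | None = None,
    seed: int | None = None,
    kappa_sigma: float = 0.5,
    **subject_kwargs,
) -> list[tuple[EpochArray, float]]:
    """Generate ``design.n_subjects`` subjects with paired accuracies.

    Per-subject coupling gains ``kappa_s`` are log-normal(mu=0,
    sigma=``kappa_sigma``); accuracy is ``base + slope * kappa_s`` plus
    Gaussian noise, clipped to [0, 1].  Returns a list of
    ``(EpochArray, accuracy)`` pairs.
    """
    if design.n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    behavioral = behavioral or BehavioralSpec()
    if kappa_sigma == 0.0 and behavioral.accuracy_slope != 0.0:
        warnings.warn(
            "degenerate kappa distribution with non-zero slope: "
            "synchrony-accuracy correlation is unidentifiable",
            stacklevel=2,
        )
    rng = np.random.default_rng(design.seed if seed is None else seed)
    kappas = np.exp(rng.normal(0.0, kappa_sigma, size=design.n_subjects))
    subject_seeds = rng.integers(0, 2**31 - 1, size=design.n_subjects)

    out = []
    for kappa, sseed in zip(kappas, subject_seeds):
        epochs = generate_subject(
            design, couplings, subject_kappa=float(kappa), seed=int(sseed), **subject_kwargs
        )
        acc = (
            behavioral.base_accuracy
            + behavioral.accuracy_slope * kappa
            + rng.normal(0.0, behavioral.noise_sd)
        )
        out.append((epochs, float(np.clip(acc, 0.0, 1.0))))
    return out
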