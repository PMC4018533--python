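import numpy as np
import pytest

from phasesync import CouplingSpec, EpochArray, FrequencyGrid, StudyDesign


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    """3 left-hemisphere ROIs, 10 trials per cell, full default timing."""
    return StudyDesign(
        n_subjects=4,
        trials_per_cell=10,
        tokens=["tok"],
        rois=["AC-lh", "TPJ-lh", "vPMC-lh"],
        seed=99,
    )


@pytest.fixture
def strong_coupling():
    """20 Hz quarter-cycle-lag coupling in the 50-200 ms window."""
    return CouplingSpec(
        roi_pair=("AC-lh", "vPMC-lh"),
        center_frequency=20.0,
        phase_lag=np.pi / 2,
        coupling_window=(50.0, 200.0),
        coupling_strength=5.0,
    )


@pytest.fixture
def single_freq_grid():
    return FrequencyGrid(20.0, 20.0, 3.0)


def make_epochs(data, sfreq=1000.0, tmin=-200.0, rois=None, aux=None):
    data = np.asarray(data, dtype=float)
    if rois is None:
        rois = [f"roi{i}" for i in range(data.shape[1])]
    return EpochArray(data=data, sfreq=sfreq, tmin=tmin, rois=rois, aux=aux)


def sinusoid_pair_epochs(
    n_trials,
    freq=20.0,
    delay_s=0.0125,
    sfreq=1000.0,
    n_samples=700,
    tmin=-200.0,
    phases=None,
    rng=None,
):
    """Two-ROI epochs: B is A delayed by ``delay_s`` with shared per-trial phase."""
    if phases is None:
        phases = (rng or np.random.default_rng(0)).uniform(0, 2 * np.pi, n_trials)
    t = np.arange(n_samples) / sfreq
    a = np.cos(2 * np.pi * freq * t[None, :] + phases[:, None])
    b = np.cos(2 * np.pi * freq * (t[None, :] - delay_s) + phases[:, None])
    return make_epochs(np.stack([a, b], axis=1), sfreq=sfreq, tmin=tmin, rois=["A", "B"])
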