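"""Group-level inference: repeated-measures contrasts, Spearman, FDR, d-prime.

All repeated-measures effects here have a single degree of freedom, so
each is computed as a within-subject contrast d_s followed by a one-
sample t-test on d; F = t**2 with df = (1, n - 1).  This is numerically
identical to the textbook sums-of-squares RM-ANOVA for 2-level factors
(asserted against an independent oracle in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EffectResult",
    "rm_anova_2x2",
    "rm_anova_oneway",
    "posthoc_paired_t",
    "spearman_correlation",
    "fdr_correct",
    "dprime",
    "build_group_table",
]


@dataclass
class EffectResult:
    effect: str  # condition_main | stimulus_main | interaction | oneway_stimulus
    F: float
    df: tuple[int, int]
    p_raw: float
    p_fdr: float | None = None
    location: dict | None = None


def _contrast_f(d: np.ndarray, effect: str, location: dict | None) -> EffectResult:
    """One-sample t on a within-subject contrast, reported as F = t^2."""
    n = len(d)
    mean = d.mean()
    se = d.std(ddof=1) / np.sqrt(n)
    if se == 0:
        f = 0.0 if mean == 0 else np.inf
    else:
        f = (mean / se) ** 2
    p = float(stats.f.sf(f, 1, n - 1)) if np.isfinite(f) else 0.0
    return EffectResult(effect=effect, F=float(f), df=(1, n - 1), p_raw=p, location=location)


def rm_anova_2x2(
    cells: np.ndarray, location: dict | None = None
) -> tuple[EffectResult, EffectResult, EffectResult]:
    """Two-way repeated-measures ANOVA on a (n_subjects, 2, 2) cell array.

    Axis 1 is condition (e.g. passive/active), axis 2 stimulus type
    (e.g. intact/noisy).  Returns (condition_main, stimulus_main,
    interaction), each with df = (1, n - 1).
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 3 or cells.shape[1:] != (2, 2):
        raise ValueError("cells must be (n_subjects, 2, 2)")
    if np.isnan(cells).any():
        raise ValueError("missing cell: all 4 cells required per subject")
    cond = cells.mean(axis=2)  # (n, 2) averaged over stimulus
    stim = cells.mean(axis=1)  # (n, 2) averaged over condition
    d_cond = cond[:, 1] - cond[:, 0]
    d_stim = stim[:, 1] - stim[:, 0]
    d_inter = (cells[:, 1, 1] - cells[:, 1, 0]) - (cells[:, 0, 1] - cells[:, 0, 0])
    return (
        _contrast_f(d_cond, "condition_main", location),
        _contrast_f(d_stim, "stimulus_main", location),
        _contrast_f(d_inter, "interaction", location),
    )


def rm_anova_oneway(values: np.ndarray, location: dict | None = None) -> EffectResult:
    """One-way (2-level) repeated-measures ANOVA on (n_subjects, 2) values."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 2:
        raise ValueError("values must be (n_subjects, 2)")
    if np.isnan(values).any():
        raise ValueError("missing cell")
    return _contrast_f(values[:, 1] - values[:, 0], "oneway_stimulus", location)


def posthoc_paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Paired t-test: t and two-sided p for mean(x - y) != 0."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    se = d.std(ddof=1) / np.sqrt(n)
    if se == 0:
        return 0.0, 1.0
    t = d.mean() / se
    p = 2 * float(stats.t.sf(abs(t), n - 1))
    return float(t), p


def spearman_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    p-value uses the t-approximation (suitable for n around 20).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def fdr_correct(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one analysis family)."""
    p = np.asarray(p_values, dtype=float)
    flat = p.ravel()
    if np.any((flat <= 0) | (flat > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    adjusted = multipletests(flat, method="fdr_bh")[1]
    return adjusted.reshape(p.shape)


def dprime(
    hits: float,
    false_alarms: float,
    n_signal: int | None = None,
    n_noise: int | None = None,
) -> float:
    """Signal-detection d' = z(hit rate) - z(false-alarm rate).

    Rates of exactly 0 or 1 are corrected log-linearly — the count is
    replaced by (count + 0.5) / (N + 1) — which requires the per-class
    trial counts.
    """
    if not (0 <= hits <= 1 and 0 <= false_alarms <= 1):
        raise ValueError("rates must lie in [0, 1]")

    def _fix(rate: float, n: int | None) -> float:
        if rate in (0.0, 1.0):
            if n is None:
                raise ValueError(
                    "a rate of exactly 0 or 1 needs a trial count for correction"
                )
            return (rate * n + 0.5) / (n + 1)
        return rate

    h = _fix(hits, n_signal)
    fa = _fix(false_alarms, n_noise)
    return float(stats.norm.ppf(h) - stats.norm.ppf(fa))


def build_group_table(
    syncmaps: list,
    accuracies: list[float] | None = None,
    dprimes: list[float] | None = None,
) -> pd.DataFrame:
    """Long-format group table from per-subject/cell SyncMaps.

    Each SyncMap's ``meta`` must identify at least ``subject``; condition
    and stimulus labels are carried through when present.  Behavioral
    scores are joined by subject order.
    """
    frames = [sm.to_dataframe() for sm in syncmaps]
    table = pd.concat(frames, ignore_index=True)
    if accuracies is not None:
        acc = pd.DataFrame(
            {"subject": sorted(table["subject"].unique()), "accuracy": accuracies}
        )
        table = table.merge(acc, on="subject", how="left")
    if dprimes is not None:
        dp = pd.DataFrame(
            {"subject": sorted(table["subject"].unique()), "dprime": dprimes}
        )
        table = table.merge(dp, on="subject", how="left")
    return table
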