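"""End-to-end orchestration: synth -> preprocess -> spectral -> connectivity
-> surrogate -> group statistics -> SEM, with artifacts written per stage.

Every stage output is a pure function of (inputs, config, seed); the
report carries the config hash and all seeds for provenance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .config import PipelineConfig
from .connectivity import compute_syncmap
from .groupstats import fdr_correct
from .preprocess import baseline_correct, equalize_trial_counts, reject_trials
from .sem import (
    compare_models,
    enumerate_loop_models,
    extract_band_signal,
    fit_loop_model,
    fit_pairwise,
)
from .spectral import FrequencyGrid, morlet_transform
from .surrogate import surrogate_test, wpli_statistic
from .synth import generate_cohort

logger = logging.getLogger("phasesync")

__all__ = ["run_pipeline"]


def _cells(config: PipelineConfig):
    for ci, cond in enumerate(config.design.conditions):
        for si, stim in enumerate(config.design.stimulus_types):
            yield ci, cond, si, stim


def _vector_f(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """F = t^2 over subject axis 0, df (1, n-1), vectorized over the rest."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(sd > 0, (mean / (sd / np.sqrt(n))) ** 2, 0.0)
    p = sps.f.sf(f, 1, n - 1)
    return f, p


def _vector_spearman(w: np.ndarray, acc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman r and t-approximation p over subject axis 0, vectorized."""
    n = w.shape[0]
    rw = sps.rankdata(w, axis=0)
    ra = sps.rankdata(acc)
    rw = rw - rw.mean(axis=0)
    ra = ra - ra.mean()
    num = np.tensordot(ra, rw, axes=(0, 0))
    den = np.sqrt((ra**2).sum() * (rw**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
    p = 2 * sps.t.sf(np.abs(t), n - 2)
    return r, p


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full analysis on synthetic data; returns the report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design
    grid: FrequencyGrid = config.frequency_grid
    logger.info("simulate: %d subjects, %d trials each", design.n_subjects, design.n_trials)

    cohort = generate_cohort(
        design, config.couplings, config.behavioral, seed=config.seeds["simulate"]
    )
    accuracies = np.array([acc for _, acc in cohort])

    pairs = config.pairs
    if pairs is None:
        from itertools import combinations

        pairs = list(combinations(design.rois, 2))

    n_subj = design.n_subjects
    freqs = grid.frequencies
    n_windows = int(round((config.analysis_window[1] - config.analysis_window[0]) / config.window_width))
    W = np.full(
        (n_subj, len(design.conditions), len(design.stimulus_types), len(pairs), len(freqs), n_windows),
        np.nan,
    )

    sync_rows = []
    cell_epochs_store: list[dict[tuple[int, int], object]] = []
    for s in range(n_subj):
        epochs, _acc = cohort[s]
        cohort[s] = None  # free the uncut epochs once cells are extracted
        epochs = baseline_correct(epochs, config.rejection.baseline_window)
        epochs, _log = reject_trials(epochs, config.rejection)
        groups, keys = [], []
        for ci, cond, si, stim in _cells(config):
            mask = (epochs.trials["condition"] == cond) & (epochs.trials["stimulus"] == stim)
            groups.append(epochs.select_trials(np.where(mask.to_numpy())[0]))
            keys.append((ci, si))
        groups = equalize_trial_counts(groups, seed=config.seeds["equalize"] + s)
        store: dict[tuple[int, int], object] = {}
        for (ci, si), cell in zip(keys, groups):
            store[(ci, si)] = cell
            tf = morlet_transform(cell, grid)
            sm = compute_syncmap(
                tf,
                pairs=pairs,
                time_range=config.analysis_window,
                width=config.window_width,
                meta={
                    "subject": s,
                    "condition": design.conditions[ci],
                    "stimulus": design.stimulus_types[si],
                },
            )
            W[s, ci, si] = sm.wpli
            sync_rows.append(sm.to_dataframe())
        cell_epochs_store.append(store)
        logger.info("subject %d: syncmaps done", s)

    sync_table = pd.concat(sync_rows, ignore_index=True)
    sync_table.to_csv(out / "syncmap.csv", index=False)

    # ---------------- group statistics ----------------
    report_effects = []
    if len(design.conditions) == 2 and len(design.stimulus_types) == 2:
        d_cond = W.mean(axis=2)[:, 1] - W.mean(axis=2)[:, 0]
        d_stim = W.mean(axis=1)[:, 1] - W.mean(axis=1)[:, 0]
        d_int = (W[:, 1, 1] - W[:, 1, 0]) - (W[:, 0, 1] - W[:, 0, 0])
        effect_arrays = {
            "condition_main": d_cond,
            "stimulus_main": d_stim,
            "interaction": d_int,
            "oneway_stimulus": W[:, 0, 1] - W[:, 0, 0],
        }
        for name, d in effect_arrays.items():
            f, p = _vector_f(d)
            p_fdr = fdr_correct(np.clip(p, 1e-300, 1.0))
            for idx in np.argwhere(np.isfinite(f)):
                pi, fi, wi = idx
                report_effects.append(
                    {
                        "effect": name,
                        "pair": f"{pairs[pi][0]}--{pairs[pi][1]}",
                        "frequency": float(freqs[fi]),
                        "window_start": float(config.analysis_window[0] + wi * config.window_width),
                        "statistic": float(f[pi, fi, wi]),
                        "p_raw": float(p[pi, fi, wi]),
                        "p_fdr": float(p_fdr[pi, fi, wi]),
                    }
                )

    # correlation with behavior: active x noisy cell by default
    ci_corr = design.conditions.index("active") if "active" in design.conditions else -1
    si_corr = design.stimulus_types.index("noisy") if "noisy" in design.stimulus_types else -1
    r, p = _vector_spearman(W[:, ci_corr, si_corr], accuracies)
    p_fdr = fdr_correct(np.clip(np.where(np.isfinite(p), p, 1.0), 1e-300, 1.0))
    for idx in np.argwhere(np.isfinite(r)):
        pi, fi, wi = idx
        report_effects.append(
            {
                "effect": "spearman_accuracy",
                "pair": f"{pairs[pi][0]}--{pairs[pi][1]}",
                "frequency": float(freqs[fi]),
                "window_start": float(config.analysis_window[0] + wi * config.window_width),
                "statistic": float(r[pi, fi, wi]),
                "p_raw": float(p[pi, fi, wi]),
                "p_fdr": float(p_fdr[pi, fi, wi]),
            }
        )

    effects = pd.DataFrame(report_effects)
    effects.to_csv(out / "effects.csv", index=False)
    significant = effects[effects["p_fdr"] < config.alpha].copy()

    # ---------------- surrogate control ----------------
    surrogate_rows = []
    top = significant.sort_values("p_fdr").drop_duplicates("pair").head(config.max_surrogate_tests)
    for _, row in top.iterrows():
        pair = tuple(row["pair"].split("--"))
        fi = int(np.argmin(np.abs(freqs - row["frequency"])))
        sub_grid = FrequencyGrid(freqs[fi], freqs[fi], 1.0, grid.cycles_divisor)
        ps = []
        for s in range(n_subj):
            cell = cell_epochs_store[s][(ci_corr, si_corr)]
            tf = morlet_transform(cell, sub_grid)
            w0 = row["window_start"]
            smask = (tf.times >= w0 - 1e-9) & (tf.times < w0 + config.window_width - 1e-9)
            res = surrogate_test(
                tf,
                wpli_statistic(pair, 0, np.where(smask)[0]),
                n_shuffles=config.n_shuffles,
                seed=config.seeds["surrogate"] + s,
            )
            ps.append(res.p_value)
        surrogate_rows.append(
            {
                "effect": row["effect"],
                "pair": row["pair"],
                "frequency": row["frequency"],
                "window_start": row["window_start"],
                "median_p": float(np.median(ps)),
                "n_significant_subjects": int(np.sum(np.array(ps) < config.alpha)),
            }
        )
    surrogates = pd.DataFrame(surrogate_rows)
    surrogates.to_csv(out / "surrogate.csv", index=False)

    # ---------------- SEM directionality + loop comparison ----------------
    sem_report: dict = {}
    corr_effects = effects[effects["effect"] == "spearman_accuracy"]
    target = None
    sig_corr = corr_effects[corr_effects["p_fdr"] < config.alpha]
    pool = sig_corr if len(sig_corr) else corr_effects
    if len(pool):
        target = pool.iloc[np.argmax(np.abs(pool["statistic"].to_numpy()))]
    if target is not None:
        pair = tuple(target["pair"].split("--"))
        f0 = float(target["frequency"])
        lag = max(1, int(round(design.sampling_rate / (4 * f0))))
        sub_grid = FrequencyGrid(f0, f0, 1.0, grid.cycles_divisor)
        sig_a, sig_b = [], []
        loop_signals = []
        sem_ok = all(n in design.rois for n in config.sem_nodes)
        for s in range(n_subj):
            cell = cell_epochs_store[s][(ci_corr, si_corr)]
            tf = morlet_transform(cell, sub_grid)
            band = extract_band_signal(tf, (f0, f0), config.analysis_window, rois=list(pair))
            sig_a.append(band[:, 0])
            sig_b.append(band[:, 1])
            if sem_ok:
                loop_signals.append(
                    extract_band_signal(tf, (f0, f0), config.analysis_window, rois=list(config.sem_nodes))
                )
        direction = fit_pairwise(
            np.array(sig_a),
            np.array(sig_b),
            lag=lag,
            n_boot=config.n_boot,
            n_perm=config.n_perm,
            seed=config.seeds["sem"],
        )
        sem_report["pairwise"] = {
            "pair": target["pair"],
            "frequency": f0,
            "lag_samples": lag,
            "mean_beta_ab": float(direction.beta_ab.mean()),
            "mean_beta_ba": float(direction.beta_ba.mean()),
            "t": direction.t,
            "p": direction.p_value,
            "direction": (
                f"{pair[0]}->{pair[1]}"
                if direction.beta_ab.mean() > direction.beta_ba.mean()
                else f"{pair[1]}->{pair[0]}"
            )
            if direction.p_value < config.alpha
            else "undirected",
        }
        if sem_ok:
            models = enumerate_loop_models(tuple(config.sem_nodes), lag_ms=lag * 1000.0 / design.sampling_rate)
            fits_per_model = []
            for m in models:
                fits_per_model.append(
                    [fit_loop_model(m, loop_signals[s], lag=lag, seed=config.seeds["sem"]) for s in range(n_subj)]
                )
            ranking = compare_models(fits_per_model)
            ranking.to_csv(out / "model_ranking.csv", index=False)
            sem_report["loop_ranking"] = ranking.to_dict(orient="records")

    report = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seeds": config.seeds,
        "n_subjects": n_subj,
        "n_effects_tested": int(len(effects)),
        "n_significant": int(len(significant)),
        "significant_effects": significant.sort_values("p_fdr").head(50).to_dict(orient="records"),
        "surrogate": surrogate_rows,
        "sem": sem_report,
    }
    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=2, default=str)
    logger.info("pipeline done: %d significant effects", len(significant))
    return report
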