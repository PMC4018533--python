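"""Effective connectivity: lagged path models, directionality, loop comparison.

A reciprocal zero-lag path model between two observed variables is not
identified, so every model here is *lagged*: each node at time t is
regressed on its parent(s) at time t - tau, where tau defaults to a
quarter cycle of the effect's center frequency.  For the three-node loop
models the observed vector is (A_t, B_t, C_t, A_{t-tau}, B_{t-tau},
C_{t-tau}); free parameters are the 3 directed lagged paths, 3
endogenous residual variances, and the 6 exogenous (co)variances — 12 in
all — leaving df = 21 - 12 = 9 for every direction assignment, so model
comparison never crosses df.

chi^2 = (n_effective - 1) * F_ML with n_effective the number of trials,
not samples: within-trial samples are autocorrelated and would otherwise
inflate the statistic.  RMSEA = sqrt(max(chi^2 - df, 0) /
(df * (n_effective - 1))).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import (
    ConvergenceError,
    InsufficientTrialsError,
    ModelSpecError,
    PhaseSyncError,
    WindowError,
)
from .spectral import TFCube

__all__ = [
    "ModelSpec",
    "SemFit",
    "PairDirectionality",
    "extract_band_signal",
    "fit_pairwise",
    "enumerate_loop_models",
    "fit_loop_model",
    "fit_loop_model_cov",
    "compare_models",
    "simulate_loop_data",
    "rmsea_from_chi2",
]


def rmsea_from_chi2(chi_square: float, df: int, n_effective: int) -> float:
    """RMSEA = sqrt(max(chi^2 - df, 0) / (df * (n_effective - 1)))."""
    return float(np.sqrt(max(chi_square - df, 0.0) / (df * (n_effective - 1))))


@dataclass(frozen=True)
class ModelSpec:
    """A directed lagged path model over named nodes."""

    nodes: tuple[str, ...]
    directed_edges: tuple[tuple[str, str], ...]
    lag_ms: float = 12.5

    def __post_init__(self) -> None:
        for src, dst in self.directed_edges:
            if src not in self.nodes or dst not in self.nodes:
                raise ModelSpecError(f"edge ({src}, {dst}) references unknown node")
            if src == dst:
                raise ModelSpecError("self-loops are not allowed")

    def label(self) -> str:
        return ", ".join(f"{s}->{d}" for s, d in self.directed_edges)


@dataclass
class SemFit:
    model: ModelSpec
    beta: dict[tuple[str, str], float]
    chi_square: float
    df: int
    rmsea: float
    n_effective: int
    f_ml: float = np.nan
    psi: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "edges": [list(e) for e in self.model.directed_edges],
                "beta": {f"{s}->{d}": b for (s, d), b in self.beta.items()},
                "chi_square": self.chi_square,
                "df": self.df,
                "rmsea": self.rmsea,
                "n_effective": self.n_effective,
            }
        )


@dataclass
class PairDirectionality:
    beta_ab: np.ndarray  # per subject
    beta_ba: np.ndarray
    ci_ab: np.ndarray  # (n_subjects, 2) bootstrap percentile CI
    ci_ba: np.ndarray
    t: float
    p_value: float
    n_permutations: int


# ----------------------------------------------------------------------
def extract_band_signal(
    tf: TFCube,
    frequency_range: tuple[float, float],
    time_range: tuple[float, float],
    rois: list[str] | None = None,
) -> np.ndarray:
    """Band-limited real signal for SEM: trials x nodes x samples.

    Real part of the wavelet coefficients, averaged over the frequency
    bins inside ``frequency_range`` (inclusive), restricted to
    ``time_range`` ([t0, t1) ms), standardized per trial x node.
    """
    f0, f1 = frequency_range
    fmask = (tf.freqs >= f0 - 1e-9) & (tf.freqs <= f1 + 1e-9)
    if not fmask.any():
        raise WindowError(f"no grid frequencies inside [{f0}, {f1}] Hz")
    t0, t1 = time_range
    tmask = (tf.times >= t0 - 1e-9) & (tf.times < t1 - 1e-9)
    if not tmask.any():
        raise WindowError(f"no samples inside [{t0}, {t1}) ms")
    idx = [tf.roi_index(r) for r in rois] if rois is not None else range(len(tf.rois))
    coeffs = tf.coefficients[:, list(idx)][:, :, fmask][:, :, :, tmask]
    sig = np.real(coeffs).mean(axis=2)  # trials x nodes x samples
    mean = sig.mean(axis=2, keepdims=True)
    sd = sig.std(axis=2, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (sig - mean) / sd


# ----------------------------------------------------------------------
def _pooled_beta(x: np.ndarray, y: np.ndarray, lag: int) -> float:
    """OLS slope of y_t on x_{t-lag}, samples pooled over trials."""
    xs = x[:, : x.shape[1] - lag].ravel()
    ys = y[:, lag:].ravel()
    sxx = xs @ xs
    if sxx == 0:
        raise PhaseSyncError("zero-variance regressor in pairwise fit")
    return float((xs @ ys) / sxx)


def _trial_products(x: np.ndarray, y: np.ndarray, lag: int) -> tuple[np.ndarray, np.ndarray]:
    xs = x[:, : x.shape[1] - lag]
    ys = y[:, lag:]
    return np.einsum("ij,ij->i", xs, ys), np.einsum("ij,ij->i", xs, xs)


def fit_pairwise(
    signals_a: np.ndarray,
    signals_b: np.ndarray,
    lag: int,
    n_boot: int = 1000,
    n_perm: int = 10000,
    seed: int = 0,
) -> PairDirectionality:
    """Reciprocal lagged path coefficients with bootstrap and permutation test.

    ``signals_a`` and ``signals_b`` are (n_subjects, n_trials, n_samples).
    Per subject, beta_A->B regresses B(t) on A(t - lag) pooled over
    trials (and symmetrically).  Bootstrap resamples trials, not samples.
    The group test is a paired sign-flip permutation t-test on
    beta_A->B - beta_B->A across subjects.
    """
    a = np.asarray(signals_a, dtype=float)
    b = np.asarray(signals_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("signals must both be (n_subjects, n_trials, n_samples)")
    n_subjects, n_trials, n_samples = a.shape
    if n_trials < 2:
        raise InsufficientTrialsError("pairwise fit requires >= 2 trials")
    if lag >= n_samples:
        raise WindowError("lag must be shorter than the window")
    rng = np.random.default_rng(seed)

    beta_ab = np.empty(n_subjects)
    beta_ba = np.empty(n_subjects)
    ci_ab = np.empty((n_subjects, 2))
    ci_ba = np.empty((n_subjects, 2))
    for s in range(n_subjects):
        beta_ab[s] = _pooled_beta(a[s], b[s], lag)
        beta_ba[s] = _pooled_beta(b[s], a[s], lag)
        sxy_ab, sxx_ab = _trial_products(a[s], b[s], lag)
        sxy_ba, sxx_ba = _trial_products(b[s], a[s], lag)
        draws = rng.integers(0, n_trials, size=(n_boot, n_trials))
        boot_ab = sxy_ab[draws].sum(axis=1) / sxx_ab[draws].sum(axis=1)
        boot_ba = sxy_ba[draws].sum(axis=1) / sxx_ba[draws].sum(axis=1)
        ci_ab[s] = np.percentile(boot_ab, [2.5, 97.5])
        ci_ba[s] = np.percentile(boot_ba, [2.5, 97.5])

    d = beta_ab - beta_ba
    se = d.std(ddof=1) / np.sqrt(n_subjects)
    t_obs = 0.0 if se == 0 else d.mean() / se
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subjects))
    flipped = signs * d[None, :]
    null_se = flipped.std(axis=1, ddof=1) / np.sqrt(n_subjects)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_null = np.where(null_se > 0, flipped.mean(axis=1) / null_se, 0.0)
    p = (1 + np.sum(np.abs(t_null) >= abs(t_obs))) / (1 + n_perm)
    return PairDirectionality(
        beta_ab=beta_ab,
        beta_ba=beta_ba,
        ci_ab=ci_ab,
        ci_ba=ci_ba,
        t=float(t_obs),
        p_value=float(p),
        n_permutations=n_perm,
    )


# ----------------------------------------------------------------------
def enumerate_loop_models(
    nodes: tuple[str, ...] = ("AC", "TPJ", "vPMC"), lag_ms: float = 12.5
) -> list[ModelSpec]:
    """All unidirectional direction assignments of the complete edge set.

    For 3 nodes the triangle has 3 edges and 2**3 = 8 models, including
    both cyclic orderings.
    """
    nodes = tuple(nodes)
    undirected = list(combinations(nodes, 2))
    models = []
    for mask in range(2 ** len(undirected)):
        edges = []
        for i, (u, v) in enumerate(undirected):
            edges.append((u, v) if not (mask >> i) & 1 else (v, u))
        models.append(ModelSpec(nodes=nodes, directed_edges=tuple(edges), lag_ms=lag_ms))
    return models


def _implied_sigma(
    beta: np.ndarray,
    log_psi: np.ndarray,
    chol_flat: np.ndarray,
    parents: list[list[tuple[int, int]]],
    p: int,
) -> np.ndarray:
    """Model-implied covariance of (y_1..y_p, x_1..x_p)."""
    L = np.zeros((p, p))
    tril = np.tril_indices(p)
    L[tril] = chol_flat
    diag = np.arange(p)
    L[diag, diag] = np.exp(L[diag, diag])
    phi = L @ L.T
    B = np.zeros((p, p))
    for child, plist in enumerate(parents):
        for parent, ei in plist:
            B[child, parent] = beta[ei]
    psi = np.diag(np.exp(log_psi))
    syy = B @ phi @ B.T + psi
    syx = B @ phi
    top = np.hstack([syy, syx])
    bottom = np.hstack([syx.T, phi])
    return np.vstack([top, bottom])


def _f_ml(sigma: np.ndarray, S: np.ndarray, logdet_S: float) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    try:
        inv = np.linalg.solve(sigma, S)
    except np.linalg.LinAlgError:
        return np.inf
    return logdet + np.trace(inv) - logdet_S - S.shape[0]


def fit_loop_model(
    model: ModelSpec,
    signals: np.ndarray,
    lag: int,
    n_effective: int | None = None,
    tol: float = 1e-8,
    max_restarts: int = 3,
    seed: int = 0,
) -> SemFit:
    """ML fit of a directed lagged path model to trials x nodes x samples data.

    The sample covariance S pools (x_{t-lag}, y_t) sample pairs over all
    trials.  F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - 2p is minimized
    with a quasi-Newton method on an unconstrained parameterization
    (paths free, log residual variances, Cholesky factor of the
    exogenous covariance).
    """
    signals = np.asarray(signals, dtype=float)
    n_trials, p, n_samples = signals.shape
    if p != len(model.nodes):
        raise ModelSpecError("signal node axis does not match model nodes")
    if lag < 1 or lag >= n_samples:
        raise WindowError("lag must be in [1, n_samples)")
    n_effective = n_trials if n_effective is None else n_effective

    y = signals[:, :, lag:].transpose(0, 2, 1).reshape(-1, p)
    x = signals[:, :, :-lag].transpose(0, 2, 1).reshape(-1, p)
    data = np.hstack([y, x])
    S = np.cov(data, rowvar=False, ddof=1)
    return fit_loop_model_cov(
        model, S, n_effective, tol=tol, max_restarts=max_restarts, seed=seed
    )


def fit_loop_model_cov(
    model: ModelSpec,
    S: np.ndarray,
    n_effective: int,
    tol: float = 1e-8,
    max_restarts: int = 3,
    seed: int = 0,
) -> SemFit:
    """ML fit of a lagged path model directly to a (2p x 2p) covariance.

    Variable order is (y_1..y_p, x_1..x_p) with y the nodes at t and x
    the nodes at t - lag.  Used by :func:`fit_loop_model` and by oracle
    tests that construct the implied covariance analytically.
    """
    p = len(model.nodes)
    S = np.asarray(S, dtype=float)
    if S.shape != (2 * p, 2 * p):
        raise ModelSpecError(f"covariance must be {2 * p} x {2 * p}")
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise PhaseSyncError("sample covariance is singular")

    node_index = {n: i for i, n in enumerate(model.nodes)}
    n_edges = len(model.directed_edges)
    parents: list[list[tuple[int, int]]] = [[] for _ in range(p)]
    for ei, (src, dst) in enumerate(model.directed_edges):
        parents[node_index[dst]].append((node_index[src], ei))

    n_moments = (2 * p) * (2 * p + 1) // 2
    n_params = n_edges + p + p * (p + 1) // 2
    df = n_moments - n_params
    if df <= 0:
        raise ModelSpecError(f"model is not over-identified (df = {df})")

    # warm start: per-equation OLS for paths, S_xx Cholesky for Phi
    S_xx = S[p:, p:]
    beta0 = np.zeros(n_edges)
    psi0 = np.zeros(p)
    for child in range(p):
        plist = parents[child]
        if plist:
            cols = [pa for pa, _ in plist]
            A = S_xx[np.ix_(cols, cols)]
            bvec = S[p + np.array(cols), child]
            coef = np.linalg.solve(A, bvec)
            for (pa, ei), c in zip(plist, coef):
                beta0[ei] = c
            resid_var = S[child, child] - coef @ bvec
        else:
            resid_var = S[child, child]
        psi0[child] = np.log(max(resid_var, 1e-6))
    L0 = np.linalg.cholesky(S_xx)
    chol0 = L0.copy()
    dix = np.arange(p)
    chol0[dix, dix] = np.log(chol0[dix, dix])
    theta0 = np.concatenate([beta0, psi0, chol0[np.tril_indices(p)]])

    def objective(theta: np.ndarray) -> float:
        beta = theta[:n_edges]
        log_psi = theta[n_edges : n_edges + p]
        chol_flat = theta[n_edges + p :]
        return _f_ml(_implied_sigma(beta, log_psi, chol_flat, parents, p), S, logdet_S)

    rng = np.random.default_rng(seed)
    best = None
    start = theta0
    for attempt in range(1 + max_restarts):
        res = optimize.minimize(objective, start, method="L-BFGS-B", tol=tol)
        if res.success and np.isfinite(res.fun):
            best = res
            break
        if best is None or (np.isfinite(res.fun) and res.fun < best.fun):
            best = res
        start = theta0 + rng.normal(0, 0.1, size=theta0.shape)
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(
            "loop model fit failed to converge",
            diagnostics={"model": model.label(), "message": getattr(best, "message", "")},
        )

    f_ml = max(float(best.fun), 0.0)
    chi2 = (n_effective - 1) * f_ml
    rmsea = rmsea_from_chi2(chi2, df, n_effective)
    beta_hat = best.x[:n_edges]
    psi_hat = np.exp(best.x[n_edges : n_edges + p])
    return SemFit(
        model=model,
        beta={edge: float(beta_hat[ei]) for ei, edge in enumerate(model.directed_edges)},
        chi_square=float(chi2),
        df=int(df),
        rmsea=rmsea,
        n_effective=int(n_effective),
        f_ml=f_ml,
        psi={n: float(psi_hat[i]) for i, n in enumerate(model.nodes)},
    )


def compare_models(
    fits: list[SemFit] | list[list[SemFit]], cutoff: float = 0.07
) -> pd.DataFrame:
    """Rank models by mean RMSEA across subjects.

    ``fits`` is either one SemFit per model, or a list per model holding
    one SemFit per subject.  Returns a DataFrame sorted by mean RMSEA
    with a good-fit flag at ``cutoff``.
    """
    if not fits:
        raise ValueError("no fits to compare")
    rows = []
    for entry in fits:
        group = entry if isinstance(entry, (list, tuple)) else [entry]
        rmseas = np.array([f.rmsea for f in group])
        rows.append(
            {
                "model": group[0].model.label(),
                "mean_rmsea": float(rmseas.mean()),
                "sd_rmsea": float(rmseas.std(ddof=1)) if len(rmseas) > 1 else 0.0,
                "n_subjects": len(rmseas),
                "good_fit": bool(rmseas.mean() < cutoff),
            }
        )
    out = pd.DataFrame(rows).sort_values("mean_rmsea", kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def simulate_loop_data(
    model: ModelSpec,
    beta: float | dict[tuple[str, str], float] = 0.5,
    n_trials: int = 500,
    n_samples: int = 100,
    lag: int = 5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate trials x nodes x samples data exactly under a lagged model.

    Each node at time t equals the sum of beta * parent(t - lag) over its
    incoming edges plus white Gaussian noise; a burn-in of 10 * lag
    samples is discarded so the pooled lagged covariance is stationary.
    """
    p = len(model.nodes)
    node_index = {n: i for i, n in enumerate(model.nodes)}
    M = np.zeros((p, p))
    for src, dst in model.directed_edges:
        b = beta if np.isscalar(beta) else beta[(src, dst)]
        M[node_index[dst], node_index[src]] = b
    if np.max(np.abs(np.linalg.eigvals(M))) >= 1:
        raise ValueError("path matrix is unstable (spectral radius >= 1)")
    rng = np.random.default_rng(seed)
    burn = 10 * lag
    total = n_samples + burn
    out = np.empty((n_trials, p, total))
    noise = rng.normal(0, noise_sd, size=(n_trials, p, total))
    out[:, :, :lag] = noise[:, :, :lag]
    for t in range(lag, total):
        out[:, :, t] = out[:, :, t - lag] @ M.T + noise[:, :, t]
    return out[:, :, burn:]
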