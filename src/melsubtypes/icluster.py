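"""Joint latent-variable clustering of multiple omic matrices.

The model is the Gaussian latent-factor formulation: each standardized data
type X_t (features x samples) satisfies X_t = W_t Z + eps_t with a shared
latent representation Z ~ N(0, I_K), diagonal noise Psi_t, and
lasso-penalized loadings W_t. EM alternates the exact E-step E[Z|X] with an
M-step that solves the penalized loading problem by coordinate descent
(soft-thresholding) and updates Psi from residual moments, so the penalized
observed log-likelihood is non-decreasing. Cluster labels (K+1 clusters)
come from k-means on the per-sample latent expectations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .containers import OmicsMatrix

log = logging.getLogger(__name__)

_PSI_FLOOR = 1e-8


def standardize_features(df: pd.DataFrame) -> pd.DataFrame:
    """Per-feature zero-mean unit-variance scaling; drops constant features."""
    vals = df.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    out = (vals[keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(out, index=df.index[keep], columns=df.columns)


@dataclass
class IClusterModel:
    K: int
    W: pd.DataFrame            # stacked loadings, feature x K
    psi: pd.Series             # diagonal noise variances
    EZ: pd.DataFrame           # K x samples latent expectations
    lambdas: list              # lasso penalty per data type
    datatype_of: pd.Series     # feature -> data type index
    loglik_trace: np.ndarray   # penalized log-likelihood per EM iteration
    labels: pd.Series
    restart_index: int
    converged: bool
    flags: list = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _as_frames(datasets) -> list[pd.DataFrame]:
    frames = []
    for d in datasets:
        df = d.values if isinstance(d, OmicsMatrix) else d
        if not isinstance(df, pd.DataFrame):
            df = pd.DataFrame(np.asarray(d, dtype=float))
        frames.append(df)
    cols = frames[0].columns
    for f in frames[1:]:
        if len(f.columns) != len(cols) or not set(f.columns) == set(cols):
            raise ValueError("datasets must share an identical sample axis")
    frames = [f.loc[:, cols] for f in frames]
    for f in frames:
        if not np.isfinite(f.to_numpy(dtype=float)).all():
            raise ValueError("datasets must be finite (impute first)")
    return frames


def _penalized_loglik(X, W, psi, lam_vec):
    p, n = X.shape
    K = W.shape[1]
    Xw = X / psi[:, None]
    A = np.eye(K) + W.T @ (W / psi[:, None])
    B = W.T @ Xw                      # K x n
    sign, logdetA = np.linalg.slogdet(A)
    Ainv = np.linalg.inv(A)
    quad = float((X * Xw).sum() - np.einsum("kn,kl,ln->", B, Ainv, B))
    logdet = float(np.log(psi).sum() + logdetA)
    ll = -0.5 * (n * p * np.log(2 * np.pi) + n * logdet + quad)
    return ll - float(lam_vec @ np.abs(W).sum(axis=1)), Ainv, B


def _em_single(X, lam_vec, K, rng, tol, max_iter, cd_sweeps=6):
    p, n = X.shape
    W = rng.normal(0.0, 0.1, (p, K))
    psi = np.ones(p)
    trace = []
    converged = False
    for _it in range(max_iter):
        pll, Ainv, B = _penalized_loglik(X, W, psi, lam_vec)
        trace.append(pll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol * max(abs(trace[-2]), 1.0):
            converged = trace[-1] - trace[-2] > -1e-6 * max(abs(trace[-2]), 1.0)
            break
        EZ = Ainv @ B                                  # K x n
        M = n * Ainv + EZ @ EZ.T                       # sum E[zz']
        C = X @ EZ.T                                   # p x K
        thresh = lam_vec * psi                         # per-feature threshold
        for _ in range(cd_sweeps):
            for k in range(K):
                resid = C[:, k] - W @ M[:, k] + W[:, k] * M[k, k]
                W[:, k] = np.sign(resid) * np.maximum(np.abs(resid) - thresh, 0.0) \
                    / M[k, k]
        xx = (X * X).sum(axis=1)
        psi = (xx - 2 * (W * C).sum(axis=1)
               + np.einsum("pk,kl,pl->p", W, M, W)) / n
        psi = np.maximum(psi, _PSI_FLOOR)
    _, Ainv, B = _penalized_loglik(X, W, psi, lam_vec)
    EZ = Ainv @ B
    return W, psi, EZ, np.asarray(trace), converged


def icluster_fit(
    datasets,
    K: int,
    lam=0.05,
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    kmeans_init: int = 10,
) -> IClusterModel:
    """Fit the joint latent model and assign K+1 clusters.

    ``lam`` is the lasso penalty (scalar, or one value per data type) applied
    to the standardized-feature loadings. The best of ``n_restarts`` random
    EM starts by final penalized log-likelihood is kept.
    """
    frames = _as_frames(datasets)
    samples = frames[0].columns
    n = len(samples)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K + 1 > n:
        raise ValueError("K+1 clusters exceed the number of samples")
    lams = list(np.broadcast_to(np.asarray(lam, dtype=float), (len(frames),)))
    if any(l < 0 for l in lams):
        raise ValueError("lambda must be >= 0")
    X = np.vstack([f.to_numpy(dtype=float) for f in frames])
    feat_index = pd.Index(
        [f"{t}:{feat}" for t, f in enumerate(frames) for feat in f.index])
    dtype_of = pd.Series(
        np.concatenate([[t] * len(f.index) for t, f in enumerate(frames)]),
        index=feat_index)
    lam_vec = np.concatenate(
        [np.full(len(f.index), lams[t]) for t, f in enumerate(frames)])

    ss = np.random.SeedSequence(seed)
    best = None
    for r, sub in enumerate(ss.spawn(n_restarts)):
        rng = np.random.default_rng(sub)
        W, psi, EZ, trace, conv = _em_single(X, lam_vec, K, rng, tol, max_iter)
        if best is None or trace[-1] > best[3][-1]:
            best = (W, psi, EZ, trace, conv, r)
    W, psi, EZ, trace, conv, r_best = best

    flags = []
    if np.abs(W).max() == 0:
        flags.append("all_loadings_zero")
        log.warning("icluster_fit: lambda shrank every loading to zero")
    km = KMeans(n_clusters=K + 1, n_init=kmeans_init,
                random_state=int(ss.generate_state(1)[0] % (2**31)))
    raw = km.fit_predict(EZ.T)
    labels = pd.Series([f"iC{l + 1}" for l in raw], index=samples,
                       name="icluster_subtype")
    return IClusterModel(
        K=K,
        W=pd.DataFrame(W, index=feat_index, columns=[f"z{k+1}" for k in range(K)]),
        psi=pd.Series(psi, index=feat_index, name="psi"),
        EZ=pd.DataFrame(EZ, index=[f"z{k+1}" for k in range(K)], columns=samples),
        lambdas=lams,
        datatype_of=dtype_of,
        loglik_trace=trace,
        labels=labels,
        restart_index=r_best,
        converged=conv,
        flags=flags,
    )


def _restart_labels(datasets, K, lam, n_restarts, seed, tol, max_iter):
    frames = _as_frames(datasets)
    samples = frames[0].columns
    X = np.vstack([f.to_numpy(dtype=float) for f in frames])
    lams = list(np.broadcast_to(np.asarray(lam, dtype=float), (len(frames),)))
    lam_vec = np.concatenate(
        [np.full(len(f.index), lams[t]) for t, f in enumerate(frames)])
    ss = np.random.SeedSequence(seed)
    out = []
    for sub in ss.spawn(n_restarts):
        rng = np.random.default_rng(sub)
        _, _, EZ, trace, _ = _em_single(X, lam_vec, K, rng, tol, max_iter)
        km = KMeans(n_clusters=K + 1, n_init=5,
                    random_state=int(rng.integers(2**31)))
        out.append((km.fit_predict(EZ.T), trace[-1]))
    return out, samples


def choose_K(
    datasets,
    K_candidates=(2, 3),
    lam=0.05,
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[int, pd.DataFrame]:
    """Pick the latent dimension by restart stability.

    For each candidate K, stability is the mean pairwise adjusted Rand index
    between the cluster labelings of the random restarts; the most stable K
    wins. Candidates tied exactly (the saturated regime where every restart
    reproduces the same partition at several K) resolve to the larger K: a
    perfectly reproducible finer partition is substructure the smaller K
    merges. Emits a warning when every candidate is unstable (< 0.8, the
    regime structureless data occupies)."""
    rows = []
    ss = np.random.SeedSequence(seed)
    for K, sub in zip(K_candidates, ss.spawn(len(K_candidates))):
        labelings, _ = _restart_labels(
            datasets, K, lam, n_restarts, int(sub.generate_state(1)[0] % (2**31)),
            tol, max_iter)
        aris = [adjusted_rand_score(a[0], b[0])
                for a, b in combinations(labelings, 2)]
        rows.append((K, float(np.mean(aris))))
    diag = pd.DataFrame(rows, columns=["K", "stability"])
    best = diag["stability"].max()
    if best < 0.8:
        log.warning("choose_K: all candidate K unstable (max stability %.2f)", best)
        diag.attrs["low_stability"] = True
    cand = diag[np.isclose(diag["stability"], best, atol=1e-9)]
    k_star = int(cand["K"].max())
    return k_star, diag


def tune_lambda(
    datasets,
    K: int,
    grid=(0.01, 0.05, 0.15),
    n_restarts: int = 8,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 100,
) -> tuple[float, pd.DataFrame]:
    """Small stability grid for the lasso penalty (shared across data types)."""
    rows = []
    ss = np.random.SeedSequence(seed)
    for lam, sub in zip(grid, ss.spawn(len(grid))):
        labelings, _ = _restart_labels(
            datasets, K, lam, n_restarts, int(sub.generate_state(1)[0] % (2**31)),
            tol, max_iter)
        aris = [adjusted_rand_score(a[0], b[0])
                for a, b in combinations(labelings, 2)]
        rows.append((lam, float(np.mean(aris))))
    diag = pd.DataFrame(rows, columns=["lambda", "stability"])
    best = diag.sort_values(["stability", "lambda"], ascending=[False, True],
                            kind="stable").iloc[0]["lambda"]
    return float(best), diag
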