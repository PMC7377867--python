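"""Brunet-style NMF with consensus clustering and rank diagnostics.

The factorization minimizes the generalized Kullback-Leibler divergence
D(V || WH) with the classic multiplicative updates; consensus clustering
runs many randomly initialized factorizations, hard-assigns each sample to
its dominant metagene, and records how often sample pairs co-cluster. Rank
selection follows the cophenetic-correlation criterion with mean silhouette
width (both computed on the consensus matrix) as tie-breaker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .containers import OmicsMatrix

log = logging.getLogger(__name__)

_EPS = np.finfo(float).tiny


@dataclass
class NMFFactorization:
    W: np.ndarray
    H: np.ndarray
    objective: float
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    seed: int


@dataclass
class ConsensusResult:
    k: int
    consensus: pd.DataFrame
    cophenetic: float
    silhouette: float
    labels: pd.Series
    n_runs: int
    degenerate_runs: int = 0
    flags: list = field(default_factory=list)


def kl_divergence(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH); zero entries of V contribute WH."""
    WH = W @ H
    mask = V > 0
    term = np.where(mask, V * np.log(np.where(mask, V, 1.0) / (WH + _EPS)) - V, 0.0)
    return float((term + WH).sum())


def nonnegative_transform(m: OmicsMatrix | pd.DataFrame) -> pd.DataFrame:
    """Split each signed row into a positive-part and a negative-part row.

    Doubles the feature count and is losslessly invertible
    (``pos - neg = input``); required before NMF on fold-change matrices.
    """
    df = m.values if isinstance(m, OmicsMatrix) else m
    vals = df.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("nonnegative_transform requires finite values")
    pos = np.clip(vals, 0, None)
    neg = np.clip(-vals, 0, None)
    idx = pd.Index([f"{f}__pos" for f in df.index] + [f"{f}__neg" for f in df.index])
    return pd.DataFrame(np.vstack([pos, neg]), index=idx, columns=df.columns)


def nmf_brunet(
    V: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> NMFFactorization:
    """KL-divergence NMF by multiplicative updates.

    Initialization is uniform random scaled to the mean of V; iteration stops
    when the relative change of the objective (checked every 10 updates)
    drops below ``tol``. The KL objective is non-increasing per update.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("V must be non-negative")
    if np.any(V.sum(axis=1) == 0):
        raise ValueError("V must have no all-zero rows")
    p, n = V.shape
    if not 1 <= k < min(p, n):
        raise ValueError(f"k={k} out of range for shape {V.shape}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(_EPS, 1.0, (p, k)) * scale
    H = rng.uniform(_EPS, 1.0, (k, n)) * scale

    trace = [kl_divergence(V, W, H)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        if it % 10 == 0 or it == max_iter:
            obj = kl_divergence(V, W, H)
            trace.append(obj)
            prev = trace[-2]
            if prev - obj < tol * max(abs(prev), 1.0):
                converged = True
                break
    return NMFFactorization(W=W, H=H, objective=trace[-1],
                            objective_trace=np.asarray(trace), n_iter=it,
                            converged=converged, seed=seed)


def _hard_labels(H: np.ndarray) -> np.ndarray:
    return H.argmax(axis=0)


def consensus_cluster(
    V,
    k: int,
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    sample_ids=None,
) -> ConsensusResult:
    """Consensus clustering over randomly restarted NMF runs.

    consensus[i, j] is the fraction of restarts in which samples i and j
    share a dominant metagene. Final labels come from average-linkage
    hierarchical clustering of 1 - consensus cut at k; the cophenetic
    correlation compares that dendrogram with 1 - consensus, and the
    silhouette is computed on 1 - consensus with the final labels. Restarts
    that leave a cluster empty are retried on a fresh substream (up to 5
    times) before being accepted with a flag.
    """
    if isinstance(V, pd.DataFrame):
        sample_ids = V.columns if sample_ids is None else sample_ids
        V = V.to_numpy(dtype=float)
    V = np.asarray(V, dtype=float)
    n = V.shape[1]
    if sample_ids is None:
        sample_ids = pd.RangeIndex(n)
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_runs * 6)]
    co = np.zeros((n, n))
    degenerate = 0
    si = 0
    for _run in range(n_runs):
        labels = None
        for _try in range(6):
            fit = nmf_brunet(V, k, seed=seeds[si], max_iter=max_iter, tol=tol)
            si += 1
            cand = _hard_labels(fit.H)
            if len(np.unique(cand)) == k:
                labels = cand
                break
        if labels is None:
            degenerate += 1
            labels = cand
        co += labels[:, None] == labels[None, :]
    consensus = co / n_runs
    np.fill_diagonal(consensus, 1.0)

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.average(condensed)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    flags = []
    if len(np.unique(labels)) < k:
        flags.append("fewer_than_k_clusters")
    if np.std(condensed) == 0:
        coph = 1.0 if np.allclose(condensed, 0) else np.nan
    else:
        coph = float(np.corrcoef(hierarchy.cophenet(Z), condensed)[0, 1])
        if np.isnan(coph):
            coph = 1.0
    if len(np.unique(labels)) > 1:
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
    else:
        sil = float("nan")
        flags.append("silhouette_undefined")
    return ConsensusResult(
        k=k,
        consensus=pd.DataFrame(consensus, index=sample_ids, columns=sample_ids),
        cophenetic=coph,
        silhouette=sil,
        labels=pd.Series([f"N{l}" for l in labels], index=sample_ids,
                         name="nmf_subtype"),
        n_runs=n_runs,
        degenerate_runs=degenerate,
        flags=flags,
    )


def select_rank(
    V,
    k_min: int = 2,
    k_max: int = 10,
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    stability_floor: float = 0.9,
) -> tuple[int, pd.DataFrame, dict]:
    """Consensus diagnostics for each k in [k_min, k_max]; the selected rank
    maximizes the cophenetic correlation, with ties broken by the larger
    silhouette; among candidates still exactly tied (which happens only when
    the consensus saturates at perfect stability) the largest k wins, since a
    perfectly reproducible finer split is real substructure that the smaller
    rank merges. Returns (k_star, diagnostics table, results by k); a warning
    flag is set when even the best cophenetic is below ``stability_floor``."""
    if isinstance(V, pd.DataFrame):
        dims = V.shape
    else:
        dims = np.asarray(V).shape
    if not 2 <= k_min <= k_max < min(dims):
        raise ValueError("need 2 <= k_min <= k_max < min(V dims)")
    ss = np.random.SeedSequence(seed)
    results = {}
    rows = []
    for k, sub in zip(range(k_min, k_max + 1), ss.spawn(k_max - k_min + 1)):
        res = consensus_cluster(V, k, n_runs=n_runs,
                                seed=int(sub.generate_state(1)[0] % (2**31)),
                                max_iter=max_iter, tol=tol)
        results[k] = res
        rows.append((k, res.cophenetic, res.silhouette, res.degenerate_runs))
    diag = pd.DataFrame(rows, columns=["k", "cophenetic", "silhouette",
                                       "degenerate_runs"])
    best = diag["cophenetic"].max()
    cand = diag[np.isclose(diag["cophenetic"], best, atol=1e-9)]
    best_sil = cand["silhouette"].max()
    cand = cand[np.isclose(cand["silhouette"], best_sil, atol=1e-9)]
    k_star = int(cand["k"].max())
    if best < stability_floor:
        log.warning("select_rank: max cophenetic %.3f < %.2f; data may lack "
                    "cluster structure", best, stability_floor)
        diag.attrs["low_stability"] = True
    return k_star, diag, results
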