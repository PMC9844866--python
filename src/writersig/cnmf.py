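"""Consensus non-negative matrix factorization (CNMF) subtype discovery.

Repeated randomly initialized NMF runs are aggregated into a sample-by-
sample co-clustering (consensus) matrix; samples are then partitioned by
average-linkage hierarchical clustering of 1 - consensus, and cluster
consistency is summarized by the average silhouette width (ASW) and the
cophenetic correlation.

The factorization minimizes the squared Frobenius error with the classic
multiplicative update rule, whose objective is non-increasing at every
iteration.  Log-scale (possibly negative) input is shifted by its global
minimum before factorization, which preserves all between-sample
contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .errors import ConfigurationError, InputError, ClusteringError

__all__ = [
    "NMFResult",
    "ConsensusResult",
    "nmf",
    "consensus_matrix",
    "cluster_from_consensus",
    "asw",
    "cophenetic_correlation",
    "consensus_cluster",
]

_EPS = 1e-12


@dataclass
class NMFResult:
    W: np.ndarray
    H: np.ndarray
    reconstruction_error: float
    n_iter: int
    converged: bool
    error_history: list[float] = field(default_factory=list)


@dataclass
class ConsensusResult:
    consensus: np.ndarray
    labels: np.ndarray
    asw: float
    cophenetic: float
    n_runs: int
    k: int
    degenerate: bool = False


def nmf(X: np.ndarray, k: int, seed: int = 0, max_iter: int = 500,
        tol: float = 1e-6) -> NMFResult:
    """Rank-k NMF by multiplicative updates on the squared Frobenius loss.

    Stops when the relative error improvement drops below ``tol`` or at
    ``max_iter``.  Initialization is uniform nonnegative from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InputError("X must be a 2-d matrix")
    if np.any(X < 0):
        raise InputError("NMF input must be nonnegative")
    if not 1 <= k < min(X.shape):
        raise ConfigurationError(
            f"k={k} out of range for a {X.shape[0]}x{X.shape[1]} matrix")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / k) if X.mean() > 0 else 1.0
    W = rng.uniform(0, 1, size=(X.shape[0], k)) * scale
    H = rng.uniform(0, 1, size=(k, X.shape[1])) * scale

    def frob2(W, H):
        return float(np.linalg.norm(X - W @ H) ** 2)

    errors = [frob2(W, H)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ H @ H.T + _EPS)
        err = frob2(W, H)
        errors.append(err)
        prev = errors[-2]
        if prev > 0 and (prev - err) / prev < tol:
            converged = True
            break
    return NMFResult(W, H, errors[-1], it, converged, errors)


def _shift_nonnegative(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    lo = X.min()
    return X - lo if lo < 0 else X


def consensus_matrix(X: np.ndarray, k: int, n_runs: int = 30, seed: int = 0,
                     max_iter: int = 500, tol: float = 1e-6) -> np.ndarray:
    """Co-clustering frequency over ``n_runs`` re-initialized NMF runs.

    Each run r uses seed ``seed + r``; a sample is assigned to the row of H
    with maximal value (ties toward the lower factor index).  Negative
    input is shifted by its global minimum first.
    """
    if n_runs < 2:
        raise ConfigurationError("n_runs must be >= 2")
    if k < 2:
        raise ConfigurationError("consensus clustering requires k >= 2")
    X = _shift_nonnegative(X)
    n = X.shape[1]
    counts = np.zeros((n, n))
    for r in range(n_runs):
        res = nmf(X, k, seed=seed + r, max_iter=max_iter, tol=tol)
        assign = np.argmax(res.H, axis=0)
        counts += assign[:, None] == assign[None, :]
    consensus = counts / n_runs
    consensus = (consensus + consensus.T) / 2
    np.fill_diagonal(consensus, 1.0)
    return consensus


def _check_consensus(consensus: np.ndarray) -> np.ndarray:
    consensus = np.asarray(consensus, dtype=float)
    if consensus.ndim != 2 or consensus.shape[0] != consensus.shape[1]:
        raise InputError("consensus must be square")
    if not np.allclose(consensus, consensus.T, atol=1e-12):
        raise InputError("consensus must be symmetric")
    if consensus.min() < -1e-12 or consensus.max() > 1 + 1e-12:
        raise InputError("consensus entries must lie in [0, 1]")
    return consensus


def _average_linkage(consensus: np.ndarray):
    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    return average(squareform(D, checks=False)), D


def cluster_from_consensus(consensus: np.ndarray, k: int) -> np.ndarray:
    """Cut the average-linkage dendrogram of 1 - consensus at k clusters.

    Labels are relabeled deterministically: cluster 1 is the one containing
    the lowest-index sample, cluster 2 the next first-occurring, and so on.
    """
    consensus = _check_consensus(consensus)
    if k < 2 or k > consensus.shape[0]:
        raise ConfigurationError(f"k={k} invalid for {consensus.shape[0]} samples")
    Z, _ = _average_linkage(consensus)
    raw = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(raw)) < k:
        raise ClusteringError(
            f"consensus matrix supports only {len(np.unique(raw))} distinct "
            f"clusters, {k} requested")
    # first-occurrence relabeling
    mapping: dict[int, int] = {}
    for lab in raw:
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
    return np.array([mapping[lab] for lab in raw], dtype=int)


def asw(consensus: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width on the dissimilarity 1 - consensus."""
    consensus = _check_consensus(consensus)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InputError("ASW requires at least two non-empty clusters")
    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    return float(silhouette_score(D, labels, metric="precomputed"))


def cophenetic_correlation(consensus: np.ndarray) -> float:
    """Pearson correlation of 1 - consensus with its cophenetic distances."""
    consensus = _check_consensus(consensus)
    Z, D = _average_linkage(consensus)
    d = squareform(D, checks=False)
    if np.allclose(d, d[0]):
        raise InputError("cophenetic correlation undefined for a constant matrix")
    corr, _ = cophenet(Z, d)
    return float(corr)


def consensus_cluster(X: np.ndarray, k: int = 2, n_runs: int = 30,
                      seed: int = 0, max_iter: int = 500,
                      tol: float = 1e-6) -> ConsensusResult:
    """Full CNMF subtyping: consensus matrix, labels, ASW, cophenetic."""
    consensus = consensus_matrix(X, k, n_runs=n_runs, seed=seed,
                                 max_iter=max_iter, tol=tol)
    degenerate = False
    try:
        labels = cluster_from_consensus(consensus, k)
    except ClusteringError:
        # all samples co-cluster in every run; arbitrary split, flagged
        labels = np.ones(consensus.shape[0], dtype=int)
        labels[consensus.shape[0] // 2:] = 2
        degenerate = True
    try:
        width = asw(consensus, labels)
    except InputError:
        width = float("nan")
    try:
        coph = cophenetic_correlation(consensus)
    except InputError:
        coph = float("nan")
    return ConsensusResult(consensus, labels, width, coph, n_runs, k, degenerate)
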