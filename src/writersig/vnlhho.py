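"""Variable-neighborhood-learning Harris Hawks optimizer (VNLHHO) for
wrapper gene selection.

Candidate gene subsets are encoded as continuous hawk positions in
[0, 1]^G and binarized through a sigmoid transfer function.  Each
iteration applies the canonical Harris Hawks phases — exploration while
the escaping energy |E| = |2*E0*(1 - t/T)| >= 1, soft/hard besiege of the
best solution (the rabbit) otherwise, with Levy-flight progressive rapid
dives accepted only on improvement — followed by a variable-neighborhood
learning step in which every hawk moves part of its coordinates toward the
best hawk within +-k ring positions; k widens under stagnation and resets
on improvement.

Fitness is alpha * cv_error + (1 - alpha) * subset_fraction, with the
cross-validated error of a k-nearest-neighbor classifier on standardized
features.  Fold assignment is drawn once per run so fitness is a
deterministic function of the mask, which makes the best-so-far trajectory
provably non-increasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import ExpressionMatrix
from .errors import ConfigurationError, InputError

__all__ = [
    "VNLHHOConfig",
    "SelectionResult",
    "FitnessEvaluator",
    "evaluate_fitness",
    "binarize",
    "select_features",
]


@dataclass(frozen=True)
class VNLHHOConfig:
    pop_size: int = 30
    max_iter: int = 100
    fitness_alpha: float = 0.99
    cv_folds: int = 5
    knn_k: int = 5
    transfer_slope: float = 10.0
    levy_beta: float = 1.5
    vnl_k_max: int = 3
    stagnation_limit: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.pop_size >= 4, "pop_size must be >= 4"),
            (self.max_iter >= 1, "max_iter must be >= 1"),
            (0 < self.fitness_alpha <= 1, "fitness_alpha must lie in (0, 1]"),
            (self.cv_folds >= 2, "cv_folds must be >= 2"),
            (self.knn_k >= 1, "knn_k must be >= 1"),
            (self.transfer_slope > 0, "transfer_slope must be positive"),
            (1 < self.levy_beta <= 2, "levy_beta must lie in (1, 2]"),
            (self.vnl_k_max >= 1, "vnl_k_max must be >= 1"),
            (self.stagnation_limit >= 1, "stagnation_limit must be >= 1"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigurationError(message)


@dataclass
class SelectionResult:
    selected_genes: list[str]
    selected_mask: np.ndarray
    best_fitness: float
    fitness_history: list[float]
    config_echo: VNLHHOConfig
    n_evaluations: int


class FitnessEvaluator:
    """Wrapper fitness: KNN cross-validated error plus a sparsity penalty.

    Features are z-scored across samples once; stratified fold membership
    is drawn from ``rng`` at construction and reused for every mask.
    Evaluations are memoized by mask.
    """

    def __init__(self, X: np.ndarray, labels: np.ndarray,
                 config: VNLHHOConfig, rng: np.random.Generator):
        X = np.asarray(X, dtype=float)          # samples x genes
        labels = np.asarray(labels)
        levels = np.unique(labels)
        if len(levels) != 2:
            raise InputError(f"two groups required, got {len(levels)}")
        y = (labels == levels[1]).astype(int)
        if min(np.bincount(y)) < config.cv_folds:
            raise InputError("each group needs at least cv_folds samples")
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.X = (X - X.mean(axis=0)) / sd
        self.y = y
        self.config = config
        self.n_genes = X.shape[1]
        self.folds = self._stratified_folds(rng)
        self.n_evaluations = 0
        self._cache: dict[bytes, float] = {}

    def _stratified_folds(self, rng) -> list[np.ndarray]:
        folds: list[list[int]] = [[] for _ in range(self.config.cv_folds)]
        for cls in (0, 1):
            idx = np.flatnonzero(self.y == cls)
            idx = idx[rng.permutation(idx.size)]
            for pos, i in enumerate(idx):
                folds[pos % self.config.cv_folds].append(int(i))
        return [np.array(sorted(f), dtype=int) for f in folds]

    def cv_error(self, mask: np.ndarray) -> float:
        Xm = self.X[:, mask]
        k = self.config.knn_k
        wrong = 0
        n = self.X.shape[0]
        all_idx = np.arange(n)
        for test in self.folds:
            train = np.setdiff1d(all_idx, test, assume_unique=True)
            D = cdist(Xm[test], Xm[train], metric="sqeuclidean")
            kk = min(k, train.size)
            nn = np.argpartition(D, kk - 1, axis=1)[:, :kk]
            votes = self.y[train][nn].mean(axis=1)
            pred = (votes > 0.5).astype(int)  # vote ties predict class 0
            wrong += int((pred != self.y[test]).sum())
        return wrong / n

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self.n_genes:
            raise InputError("mask length must equal number of genes")
        if not mask.any():
            return math.inf
        key = mask.tobytes()
        if key in self._cache:
            return self._cache[key]
        cfg = self.config
        fit = (cfg.fitness_alpha * self.cv_error(mask)
               + (1 - cfg.fitness_alpha) * mask.sum() / self.n_genes)
        self._cache[key] = fit
        self.n_evaluations += 1
        return fit


def evaluate_fitness(mask, X, labels, config: VNLHHOConfig) -> float:
    """One-off fitness evaluation with folds drawn from ``config.seed``."""
    X = _to_sample_matrix(X)
    ev = FitnessEvaluator(X, labels, config, np.random.default_rng(config.seed))
    return ev(np.asarray(mask, dtype=bool))


def binarize(position: np.ndarray, rng: np.random.Generator,
             slope: float = 10.0) -> np.ndarray:
    """Stochastic sigmoid binarization: select gene g iff u_g < S(pos_g)."""
    position = np.asarray(position, dtype=float)
    prob = 1.0 / (1.0 + np.exp(-slope * (position - 0.5)))
    return rng.random(position.size) < prob


def _levy(size: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Levy-flight step by the Mantegna algorithm."""
    sigma = (math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
             / (math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
             ) ** (1 / beta)
    u = rng.normal(0, sigma, size)
    v = rng.normal(0, 1, size)
    return 0.01 * u / np.abs(v) ** (1 / beta)


class _Swarm:
    """Mutable optimizer state: positions, masks, fitness, rabbit."""

    def __init__(self, positions, masks, fits):
        self.positions = positions
        self.masks = masks
        self.fits = fits
        best = int(np.argmin(fits))
        self.rabbit_pos = positions[best].copy()
        self.rabbit_mask = masks[best].copy()
        self.rabbit_fit = float(fits[best])

    def refresh(self, i, pos, rng, evaluator, slope, mask=None, fit=None):
        pos = np.clip(pos, 0.0, 1.0)
        if mask is None:
            mask = binarize(pos, rng, slope)
            fit = evaluator(mask)
        self.positions[i] = pos
        self.masks[i] = mask
        self.fits[i] = fit
        if fit < self.rabbit_fit:
            self.rabbit_pos = pos.copy()
            self.rabbit_mask = mask.copy()
            self.rabbit_fit = float(fit)


def hho_iteration(swarm: _Swarm, t: int, config: VNLHHOConfig,
                  rng: np.random.Generator, evaluator: FitnessEvaluator) -> None:
    """One Harris Hawks update of every hawk (exploration or besiege)."""
    N, G = swarm.positions.shape
    T = config.max_iter
    slope = config.transfer_slope
    for i in range(N):
        x = swarm.positions[i]
        e0 = rng.uniform(-1, 1)
        E = 2.0 * e0 * (1.0 - t / T)
        if abs(E) >= 1:  # exploration
            q = rng.random()
            if q >= 0.5:
                other = swarm.positions[rng.integers(N)]
                r1, r2 = rng.random(2)
                new = other - r1 * np.abs(other - 2 * r2 * x)
            else:
                mean_pos = swarm.positions.mean(axis=0)
                r3, r4 = rng.random(2)
                new = (swarm.rabbit_pos - mean_pos) - r3 * (r4 * 1.0)
            swarm.refresh(i, new, rng, evaluator, slope)
            continue
        r = rng.random()
        J = 2.0 * (1.0 - rng.random())
        if r >= 0.5 and abs(E) >= 0.5:      # soft besiege
            delta = swarm.rabbit_pos - x
            new = delta - E * np.abs(J * swarm.rabbit_pos - x)
            swarm.refresh(i, new, rng, evaluator, slope)
        elif r >= 0.5:                      # hard besiege
            new = swarm.rabbit_pos - E * np.abs(swarm.rabbit_pos - x)
            swarm.refresh(i, new, rng, evaluator, slope)
        else:                               # progressive rapid dives
            if abs(E) >= 0.5:
                y = swarm.rabbit_pos - E * np.abs(J * swarm.rabbit_pos - x)
            else:
                mean_pos = swarm.positions.mean(axis=0)
                y = swarm.rabbit_pos - E * np.abs(J * swarm.rabbit_pos - mean_pos)
            y = np.clip(y, 0.0, 1.0)
            y_mask = binarize(y, rng, slope)
            y_fit = evaluator(y_mask)
            if y_fit < swarm.fits[i]:
                swarm.refresh(i, y, rng, evaluator, slope, y_mask, y_fit)
                continue
            z = np.clip(y + rng.random(G) * _levy(G, config.levy_beta, rng),
                        0.0, 1.0)
            z_mask = binarize(z, rng, slope)
            z_fit = evaluator(z_mask)
            if z_fit < swarm.fits[i]:
                swarm.refresh(i, z, rng, evaluator, slope, z_mask, z_fit)
            # neither dive improved: hawk keeps its position


def vnl_step(swarm: _Swarm, k: int, config: VNLHHOConfig,
             rng: np.random.Generator, evaluator: FitnessEvaluator) -> None:
    """Variable-neighborhood learning on a ring of hawks.

    Each hawk finds the best-fitness hawk within +-k ring positions
    (itself included) and moves a random half of its coordinates toward
    it.
    """
    N, G = swarm.positions.shape
    slope = config.transfer_slope
    snapshot = swarm.positions.copy()
    snapshot_fits = swarm.fits.copy()
    for i in range(N):
        ring = [(i + o) % N for o in range(-k, k + 1)]
        nb = ring[int(np.argmin(snapshot_fits[ring]))]
        if nb == i:
            continue
        u = rng.random()
        coords = rng.choice(G, size=max(G // 2, 1), replace=False)
        new = swarm.positions[i].copy()
        new[coords] += u * (snapshot[nb][coords] - new[coords])
        if np.array_equal(new, swarm.positions[i]):
            continue
        swarm.refresh(i, new, rng, evaluator, slope)


def _to_sample_matrix(X) -> np.ndarray:
    """Accept genes-x-samples containers; return samples x genes array."""
    if isinstance(X, ExpressionMatrix):
        return X.values.T
    return np.asarray(X, dtype=float).T


def select_features(X, labels, config: VNLHHOConfig | None = None,
                    gene_ids: list[str] | None = None,
                    use_vnl: bool = True) -> SelectionResult:
    """Run VNLHHO feature selection and return the best-ever gene subset.

    ``X`` is genes x samples (an ExpressionMatrix carries its own gene
    ids).  Fully reproducible from ``config.seed``; the recorded
    fitness_history is non-increasing.
    """
    if config is None:
        config = VNLHHOConfig()
    if isinstance(X, ExpressionMatrix) and gene_ids is None:
        gene_ids = list(X.gene_ids)
    Xs = _to_sample_matrix(X)
    n, G = Xs.shape
    if G < 2:
        raise InputError("need at least 2 genes to select from")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(G)]

    rng = np.random.default_rng(config.seed)
    evaluator = FitnessEvaluator(Xs, labels, config, rng)

    N = config.pop_size
    positions = rng.uniform(0, 1, size=(N, G))
    masks = np.zeros((N, G), dtype=bool)
    fits = np.empty(N)
    for i in range(N):
        masks[i] = binarize(positions[i], rng, config.transfer_slope)
        fits[i] = evaluator(masks[i])
    if not np.isfinite(fits).any():
        # pathological: all-empty initialization; seed one gene
        masks[0, 0] = True
        fits[0] = evaluator(masks[0])
        positions[0, 0] = 1.0
    swarm = _Swarm(positions, masks, fits)

    history = [swarm.rabbit_fit]
    k = 1
    stagnation = 0
    for t in range(config.max_iter):
        before = swarm.rabbit_fit
        hho_iteration(swarm, t, config, rng, evaluator)
        if use_vnl:
            vnl_step(swarm, k, config, rng, evaluator)
        if swarm.rabbit_fit < before:
            k = 1
            stagnation = 0
        else:
            stagnation += 1
            if stagnation >= config.stagnation_limit:
                k = min(k + 1, config.vnl_k_max)
                stagnation = 0
        history.append(swarm.rabbit_fit)

    selected = [gene_ids[j] for j in np.flatnonzero(swarm.rabbit_mask)]
    return SelectionResult(selected, swarm.rabbit_mask.copy(),
                           swarm.rabbit_fit, history, config,
                           evaluator.n_evaluations)
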