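"""Ordination of root systems: non-metric MDS on bottleneck-distance
matrices and correlation-matrix PCA on trait tables.

NMDS minimises Kruskal stress-1 over rank-preserving (monotone)
embeddings via SMACOF with isotonic regression; one classical-scaling
(Torgerson) initialisation plus seeded random restarts guard against
local minima, and the best-stress solution is kept.  PCA standardises
variables first (correlation-matrix PCA); constant columns are dropped
with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import smacof

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    ids: list[str]
    coordinates: np.ndarray          # n x k scores
    method: str                      # "nmds" or "pca"
    stress: float | None = None      # Kruskal stress-1 (NMDS)
    explained_variance: np.ndarray | None = None  # variance fractions (PCA)
    loadings: np.ndarray | None = None            # PCA components (k x p)
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson scaling: eigen-embedding of the double-centred squared
    distance matrix (used as a warm start for SMACOF)."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    w = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w)


def ordinate_nmds(matrix: pd.DataFrame | np.ndarray, k: int = 2,
                  seed: int = 0, n_restarts: int = 20,
                  max_iter: int = 500) -> OrdinationResult:
    """Non-metric multidimensional scaling of a symmetric dissimilarity
    matrix into ``k`` dimensions (Kruskal stress-1, seeded restarts)."""
    if isinstance(matrix, pd.DataFrame):
        ids = [str(i) for i in matrix.index]
        d = matrix.to_numpy(dtype=float)
    else:
        d = np.asarray(matrix, dtype=float)
        ids = [str(i) for i in range(d.shape[0])]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if np.allclose(d, 0.0):
        return OrdinationResult(ids=ids, coordinates=np.zeros((n, k)),
                                method="nmds", stress=0.0, seed=seed)

    rng = np.random.default_rng(seed)
    best_coords, best_stress = None, np.inf
    inits = [_classical_mds(d, k)]
    inits += [rng.normal(size=(n, k)) * d.max()
              for _ in range(max(0, n_restarts - 1))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for init in inits:
            coords, stress = smacof(
                d, metric=False, n_components=k, init=init, n_init=1,
                max_iter=max_iter, eps=1e-9, normalized_stress=True,
                random_state=np.random.RandomState(seed))
            if stress < best_stress:
                best_coords, best_stress = coords, stress
    logger.info("NMDS: %d points, k=%d, stress-1=%.6g", n, k, best_stress)
    return OrdinationResult(ids=ids, coordinates=best_coords, method="nmds",
                            stress=float(best_stress), seed=seed)


def ordinate_pca(traits: pd.DataFrame, k: int | None = None) -> OrdinationResult:
    """PCA on the correlation matrix of a trait table (variables are
    standardised to unit variance before the decomposition)."""
    x = traits.to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 plants and 2 traits")
    if np.isnan(x).any():
        raise ValueError("trait matrix contains missing values")
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all trait columns are constant")
    if not keep.all():
        dropped = list(traits.columns[~keep])
        warnings.warn(f"dropping constant trait column(s): {dropped}")
    xs = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    k = min(k or 2, xs.shape[1], xs.shape[0])
    pca = PCA(n_components=min(xs.shape), svd_solver="full")
    scores = pca.fit_transform(xs)
    return OrdinationResult(
        ids=[str(i) for i in traits.index],
        coordinates=scores[:, :k],
        method="pca",
        explained_variance=pca.explained_variance_ratio_,
        loadings=pca.components_,
        extras={"columns": list(traits.columns[keep])},
    )


def kmedoids_labels(d: np.ndarray, k: int = 2, seed: int = 0,
                    max_iter: int = 50) -> np.ndarray:
    """Partitioning-around-medoids on a precomputed distance matrix.

    k = 2 is solved exactly by exhaustive search over medoid pairs;
    larger k uses seeded alternating refinement.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if k == 2:
        best, best_cost = None, np.inf
        for i in range(n):
            for j in range(i + 1, n):
                cost = np.minimum(d[i], d[j]).sum()
                if cost < best_cost:
                    best, best_cost = (i, j), cost
        return np.argmin(d[list(best)], axis=0)
    rng = np.random.default_rng(seed)
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        labels = np.argmin(d[medoids], axis=0)
        new = np.array([
            np.flatnonzero(labels == c)[np.argmin(
                d[np.ix_(labels == c, labels == c)].sum(axis=1))]
            if (labels == c).any() else medoids[c]
            for c in range(k)])
        if np.array_equal(np.sort(new), np.sort(medoids)):
            break
        medoids = new
    return np.argmin(d[medoids], axis=0)


def class_recovery(labels: np.ndarray, truth: np.ndarray) -> float:
    """Best-permutation agreement (fraction) between a 2-class
    clustering and the generating categories."""
    labels = np.asarray(labels)
    _, truth_codes = np.unique(np.asarray(truth), return_inverse=True)
    acc = np.mean(labels == truth_codes)
    return float(max(acc, 1.0 - acc))
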