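"""scikit-learn-compatible transformers over collections of root systems.

These wrap the collection-level analysis steps so they compose with
sklearn pipelines and model selection:

* :class:`TraitExtractor` — list of trees -> plants x traits DataFrame
* :class:`PersistenceTransformer` — list of trees -> list of barcodes
* :class:`BottleneckMatrixTransformer` — barcodes -> pairwise distance matrix
* :class:`NMDS` — precomputed dissimilarity matrix -> k-D embedding
* :class:`CorrelationPCA` — trait table -> standardized-variable PCA scores

All are stateless transforms except the two ordinations, which expose
fitted attributes (``embedding_``, ``stress_``, ``components_``, ...).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import ordination, persistence, segments, traits
from .fitter import tree_fitter_indices
from .tree import RootSystemTree


class TraitExtractor(TransformerMixin, BaseEstimator):
    """Compute the aggregated whole-plant trait matrix from root system trees.

    Parameters
    ----------
    with_fitter : bool, default True
        Also compute the Fitter topological indices per plant.
    """

    def __init__(self, with_fitter: bool = True):
        self.with_fitter = with_fitter

    def fit(self, X: list[RootSystemTree], y=None):
        self.n_features_in_ = len(traits.TRAIT_COLUMNS)
        return self

    def transform(self, X: list[RootSystemTree]) -> pd.DataFrame:
        table = segments.build_segment_table(list(X))
        idx = {t.plant_id: tree_fitter_indices(t) for t in X} \
            if self.with_fitter else None
        return traits.trait_matrix(table, indices=idx)


class PersistenceTransformer(TransformerMixin, BaseEstimator):
    """Geodesic H0 persistence barcodes, one per root system."""

    def fit(self, X, y=None):
        return self

    def transform(self, X: list[RootSystemTree]) -> list[persistence.Barcode]:
        table = segments.build_segment_table(list(X))
        return persistence.compute_barcodes(table)


class BottleneckMatrixTransformer(TransformerMixin, BaseEstimator):
    """Pairwise bottleneck-distance matrix over a list of barcodes."""

    def fit(self, X, y=None):
        return self

    def transform(self, X: list[persistence.Barcode]) -> pd.DataFrame:
        return persistence.pairwise_bottleneck(list(X))


class NMDS(TransformerMixin, BaseEstimator):
    """Non-metric MDS of a precomputed dissimilarity matrix.

    Fitted attributes: ``embedding_`` (n x k), ``stress_`` (Kruskal
    stress-1), ``ids_``.
    """

    def __init__(self, n_components: int = 2, n_restarts: int = 20,
                 random_state: int = 0):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        res = ordination.ordinate_nmds(
            X, k=self.n_components, seed=self.random_state,
            n_restarts=self.n_restarts)
        self.embedding_ = res.coordinates
        self.stress_ = res.stress
        self.ids_ = res.ids
        return self

    def transform(self, X):
        return self.fit(X).embedding_

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


class CorrelationPCA(TransformerMixin, BaseEstimator):
    """PCA on the correlation matrix of a trait table.

    Fitted attributes: ``components_``, ``explained_variance_ratio_``,
    ``columns_`` (the non-constant variables used).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        self._result = ordination.ordinate_pca(X, k=self.n_components)
        self.components_ = self._result.loadings
        self.explained_variance_ratio_ = self._result.explained_variance
        self.columns_ = self._result.extras["columns"]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.fit(X)._result.coordinates

    def fit_transform(self, X, y=None):
        return self.fit(X)._result.coordinates
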