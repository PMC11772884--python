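"""Recurrent cellular neighborhood (RCN) discovery.

Every annotated cell is queried for the cell-type composition of its
neighborhood within a fixed radius (50 um by default, within its own
sample only).  The resulting cells x types count matrix is treated as a
corpus (documents = cells, words = neighbor types) and decomposed by
latent Dirichlet allocation; K-means over the per-cell topic loadings,
pooled across samples, yields RCN labels whose per-RCN type composition
and per-patient occurrence frequencies summarize recurring local motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.decomposition import LatentDirichletAllocation

from .io_core import ValidationError

__all__ = [
    "NeighborhoodMatrix",
    "RCNModel",
    "neighborhood_matrix",
    "fit_topics",
    "cluster_rcn",
    "rcn_composition",
]


@dataclass
class NeighborhoodMatrix:
    """Cells x cell-type neighbor counts within a radius."""

    X: np.ndarray  # (n_cells, n_types) counts
    types: list[str]
    cell_index: pd.Index
    radius_um: float
    include_self: bool

    def frequencies(self) -> np.ndarray:
        """Row-normalized neighbor proportions (all-zero rows stay zero)."""
        tot = self.X.sum(axis=1, keepdims=True).astype(float)
        return np.divide(self.X, tot, out=np.zeros(self.X.shape, float), where=tot > 0)


@dataclass
class RCNModel:
    """LDA topics over neighborhood composition, plus K-means RCNs."""

    topic_type: np.ndarray  # (n_topics, n_types), rows sum to 1
    loadings: np.ndarray  # (n_cells, n_topics), rows sum to 1
    types: list[str]
    cell_index: pd.Index
    seed: int
    kmeans_centers: np.ndarray | None = None
    labels: np.ndarray | None = None  # 1..k


def neighborhood_matrix(
    cells: pd.DataFrame,
    radius_um: float = 50.0,
    include_self: bool = False,
    type_col: str = "cell_type",
    sample_col: str = "sample_id",
    vocabulary: list[str] | None = None,
) -> NeighborhoodMatrix:
    """Count, per cell, its neighbors of each type within ``radius_um``.

    Neighborhoods are computed within each sample only; the index cell is
    excluded from its own neighborhood unless ``include_self``.
    """
    types = sorted(vocabulary) if vocabulary is not None else sorted(cells[type_col].unique())
    t_index = {t: j for j, t in enumerate(types)}
    unknown = set(cells[type_col].unique()) - set(types)
    if unknown:
        raise ValidationError(f"cell types outside vocabulary: {sorted(unknown)}")
    X = np.zeros((len(cells), len(types)), dtype=np.int64)
    pos = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    t_codes = cells[type_col].map(t_index).to_numpy()
    for _, idx in cells.groupby(sample_col).indices.items():
        tree = cKDTree(pos[idx])
        pairs = tree.query_pairs(r=radius_um, output_type="ndarray")
        for a, b in pairs:
            X[idx[a], t_codes[idx[b]]] += 1
            X[idx[b], t_codes[idx[a]]] += 1
    if include_self:
        X[np.arange(len(cells)), t_codes] += 1
    return NeighborhoodMatrix(
        X=X, types=types, cell_index=cells.index, radius_um=radius_um,
        include_self=include_self,
    )


def fit_topics(matrix: NeighborhoodMatrix, n_topics: int, seed: int = 0,
               max_iter: int = 30) -> RCNModel:
    """Latent Dirichlet allocation over neighborhood counts.

    Documents are cells, words are neighbor cell types.  Deterministic
    given the seed (batch variational inference).
    """
    if n_topics < 1:
        raise ValidationError("n_topics must be >= 1")
    if n_topics > len(matrix.types):
        warnings.warn(
            f"n_topics={n_topics} exceeds the {len(matrix.types)}-type vocabulary; "
            "the model is degenerate but allowed"
        )
    lda = LatentDirichletAllocation(
        n_components=n_topics, random_state=seed, learning_method="batch",
        max_iter=max_iter,
    )
    loadings = lda.fit_transform(matrix.X)
    loadings = loadings / loadings.sum(axis=1, keepdims=True)
    topic_type = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return RCNModel(
        topic_type=topic_type, loadings=loadings, types=matrix.types,
        cell_index=matrix.cell_index, seed=seed,
    )


def cluster_rcn(model: RCNModel, k: int, seed: int = 0, n_init: int = 10) -> RCNModel:
    """K-means over topic loadings pooled across samples; labels 1..k."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > model.loadings.shape[0]:
        raise ValidationError(f"k={k} exceeds the {model.loadings.shape[0]} fitted cells")
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    labels = km.fit_predict(model.loadings) + 1
    model.kmeans_centers = km.cluster_centers_
    model.labels = labels
    return model


def rcn_composition(
    labels: np.ndarray,
    cells: pd.DataFrame,
    type_col: str = "cell_type",
    sample_col: str = "sample_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-RCN cell-type abundance and per-patient occurrence frequencies.

    Returns ``(composition, patient_freq)``: composition rows (one per
    RCN) sum to 1 over types; patient_freq rows (one per sample) sum to
    1 over RCNs — the fraction of that patient's cells in each RCN.
    """
    if len(labels) != len(cells):
        raise ValidationError("labels and cells must align")
    df = cells[[type_col, sample_col]].copy()
    df["rcn"] = np.asarray(labels)
    comp = df.groupby(["rcn", type_col]).size().unstack(fill_value=0)
    comp = comp.div(comp.sum(axis=1), axis=0)
    pat = df.groupby([sample_col, "rcn"]).size().unstack(fill_value=0)
    pat = pat.div(pat.sum(axis=1), axis=0)
    return comp, pat
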