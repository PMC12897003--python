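"""Normalization, variable-gene selection, PCA, graph clustering, UMAP.

The stage is a pure function of (matrix, config, seed): normalization is
log1p counts-per-10k, highly variable genes are ranked by standardized
dispersion within mean-expression bins, PCA signs follow a fixed
convention, community detection runs on a shared-nearest-neighbor graph
with a seeded modularity optimizer, and the 2-D embedding is seeded
UMAP (visualization and subtype partitioning only).

When more than one batch is declared, scaled expression is centered per
batch — a deliberately simple surrogate for anchor-based integration,
adequate for the small multiplicative batch effects the synthetic
cohorts can carry.
"""

from __future__ import annotations

import warnings

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix

__all__ = [
    "normalize_log1p_cp10k",
    "select_hvgs",
    "scale_matrix",
    "pca_embed",
    "cluster_cells",
    "umap2d",
]


def normalize_log1p_cp10k(cm: CountMatrix) -> pd.DataFrame:
    """log(1 + 1e4 * count / cell_total), genes x cells DataFrame."""
    totals = np.asarray(cm.counts.sum(axis=0)).ravel().astype(float)
    if np.any(totals == 0):
        bad = [cm.cells[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(f"cells with zero total counts: {bad}")
    dense = cm.to_dense().astype(float)
    norm = np.log1p(1e4 * dense / totals[None, :])
    return pd.DataFrame(norm, index=list(cm.genes), columns=list(cm.cells))


def select_hvgs(norm: pd.DataFrame, n: int = 2000, n_mean_bins: int = 20) -> list[str]:
    """Top-``n`` genes by standardized dispersion.

    Dispersion (variance/mean of normalized expression) is z-scored
    within equal-frequency bins of mean expression, so highly expressed
    genes do not dominate the ranking.  Deterministic given the input;
    never selects a constant-expression gene while varying genes remain.
    """
    if n > norm.shape[0]:
        raise ValueError(f"n={n} exceeds gene count {norm.shape[0]}")
    X = norm.to_numpy()
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1) if X.shape[1] > 1 else np.zeros(len(mean))
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    varying = var > 0
    if n >= norm.shape[0]:
        return list(norm.index)

    # Equal-frequency mean bins over varying genes; z-score dispersion per bin.
    z = np.full(len(mean), -np.inf)
    idx = np.flatnonzero(varying)
    if idx.size:
        order = np.argsort(mean[idx], kind="stable")
        n_bins = min(n_mean_bins, idx.size)
        bins = np.array_split(idx[order], n_bins)
        for members in bins:
            d = disp[members]
            sd = d.std(ddof=0)
            z[members] = (d - d.mean()) / sd if sd > 0 else 0.0
    # Rank: standardized dispersion desc, stable tie-break by gene order.
    ranked = np.argsort(-z, kind="stable")
    chosen = [i for i in ranked if varying[i]][:n]
    if len(chosen) < n:  # pad with constant genes only if unavoidable
        rest = [i for i in ranked if not varying[i]]
        chosen += rest[: n - len(chosen)]
    chosen_set = set(chosen)
    return [g for i, g in enumerate(norm.index) if i in chosen_set]


def scale_matrix(
    norm: pd.DataFrame,
    genes: list[str] | None = None,
    clip_value: float = 10.0,
    batches: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene zero mean, unit variance, clipped at +/-clip_value.

    With more than one declared batch, expression is centered within
    each batch before global scaling (integration surrogate).
    """
    sub = norm.loc[genes] if genes is not None else norm
    X = sub.to_numpy().astype(float).copy()
    if batches is not None:
        labels = np.asarray(batches)
        uniq = np.unique(labels)
        if len(uniq) > 1:
            for b in uniq:
                cols = labels == b
                X[:, cols] -= X[:, cols].mean(axis=1, keepdims=True)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -clip_value, clip_value)
    return pd.DataFrame(Z, index=sub.index, columns=sub.columns)


def pca_embed(scaled: pd.DataFrame, n_pcs: int = 30) -> np.ndarray:
    """Cells x n_pcs principal-component scores.

    Sign convention: each component is flipped so its largest-magnitude
    gene loading is positive, making scores reproducible across runs.
    """
    X = scaled.to_numpy().T  # cells x genes
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 cells")
    k = min(n_pcs, min(X.shape))
    pca = PCA(n_components=k, svd_solver="full" if min(X.shape) < 500 else "auto",
              random_state=0)
    scores = pca.fit_transform(X)
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def _snn_graph(pcs: np.ndarray, k_neighbors: int, prune: float = 1.0 / 15.0) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = pcs.shape[0]
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    neigh = [set(row) | {i} for i, row in enumerate(idx)]
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = inter / union
            if w >= prune:
                edges.append((i, j))
                weights.append(w)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_cells(
    pcs: np.ndarray,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Modularity community labels on the SNN graph, deterministic given seed."""
    if k_neighbors >= pcs.shape[0]:
        raise ValueError("k_neighbors must be < number of cells")
    g = _snn_graph(pcs, k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if g.ecount() else None,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    return np.asarray(part.membership)


def umap2d(
    pcs: np.ndarray,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.3,
) -> np.ndarray:
    """Seeded 2-D UMAP of the PC scores (visualization/partitioning only)."""
    import umap  # deferred: numba compilation is slow at import/first call

    n = pcs.shape[0]
    if n < 10:
        raise ValueError("UMAP embedding needs at least 10 cells")
    nn = min(n_neighbors, n - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            coords = umap.UMAP(
                n_components=2,
                n_neighbors=nn,
                min_dist=min_dist,
                random_state=int(seed),
                init="spectral",
            ).fit_transform(pcs)
        except Exception:
            coords = None
    if coords is None or not np.all(np.isfinite(coords)):
        # Degenerate geometry (e.g. identical cells): deterministic fallback.
        rng = np.random.default_rng(seed)
        coords = rng.normal(scale=1e-3, size=(n, 2))
    return np.asarray(coords, dtype=float)
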