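"""Marker-guided cluster annotation and serotonergic subtyping.

Clusters are scored against the canonical EC marker panel (CHGA, CHGB,
SCGN, NEUROD1, SLC18A1, ADGRG4); high-scoring clusters become EC when
their cells come from normal mucosa and SI-NET when they come from
tumor tissue.  EC cells are then partitioned into serotonergic and
non-serotonergic subtypes by a one-dimensional two-means cut on the
2-D embedding axis with the stronger separation, with the side showing
higher serotonin-pathway marker expression (TPH1 + SLC18A1) labeled
serotonergic.  The cut position and per-side marker means are emitted
for audit, since the original partition thresholds are not recoverable
from published text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .synthetic import EC_PANEL

__all__ = [
    "MarkerPanel",
    "score_clusters",
    "assign_classes",
    "split_serotonergic",
    "SplitAudit",
]


@dataclass
class MarkerPanel:
    """Named marker gene list; genes matched case-insensitively."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("marker panel must be non-empty")
        self.genes = tuple(g.upper() for g in self.genes)


EC_MARKER_PANEL = MarkerPanel("EC_canonical", EC_PANEL)


def score_clusters(
    norm: pd.DataFrame,
    cluster_labels: np.ndarray,
    panel: MarkerPanel,
) -> pd.Series:
    """Per-cluster mean of per-gene mean normalized panel expression.

    Panel genes absent from the matrix contribute 0 with a warning.
    """
    present = [g for g in panel.genes if g in norm.index]
    missing = [g for g in panel.genes if g not in norm.index]
    if missing:
        warnings.warn(f"panel {panel.name}: genes absent from matrix: {missing}", stacklevel=2)
    if not present:
        raise ValueError(f"no gene of panel {panel.name} present in matrix")
    labels = np.asarray(cluster_labels)
    scores = {}
    for cl in np.unique(labels):
        cols = labels == cl
        per_gene = norm.loc[present].to_numpy()[:, cols].mean(axis=1)
        # missing genes count as zeros in the panel mean
        scores[cl] = per_gene.sum() / len(panel.genes)
    return pd.Series(scores).sort_index()


def assign_classes(
    cluster_scores: pd.Series,
    cluster_labels: np.ndarray,
    origins: np.ndarray,
    score_factor: float = 1.7,
    min_cluster_size: int = 5,
) -> pd.DataFrame:
    """Class labels (EC / SI-NET / other) from cluster panel scores.

    Clusters scoring above ``score_factor`` times the median cluster
    score are neuroendocrine; their cells are labeled EC when the cell
    originates from normal tissue and SI-NET when from tumor tissue.
    Tumor-origin cells can therefore never be labeled EC.  Clusters
    smaller than ``min_cluster_size`` are never called neuroendocrine
    (stray single-cell "clusters" carry no panel evidence).  If no
    cluster passes, all cells are "other" (warned, not fatal).
    """
    labels = np.asarray(cluster_labels)
    origins = np.asarray(origins)
    if labels.shape != origins.shape:
        raise ValueError("cluster labels and origins must align per cell")
    threshold = score_factor * float(cluster_scores.median())
    sizes = pd.Series(labels).value_counts()
    ne_clusters = {
        cl for cl in cluster_scores.index[cluster_scores > threshold]
        if sizes.get(cl, 0) >= min_cluster_size
    }
    if not ne_clusters:
        warnings.warn("no cluster exceeds the EC panel score threshold; zero EC cells",
                      stacklevel=2)
    cls = np.full(labels.shape, "other", dtype=object)
    in_ne = np.isin(labels, list(ne_clusters)) if ne_clusters else np.zeros(labels.shape, bool)
    cls[in_ne & (origins == "normal")] = "EC"
    cls[in_ne & (origins == "tumor")] = "SI-NET"
    return pd.DataFrame({"cluster": labels, "origin": origins, "class_label": cls})


@dataclass
class SplitAudit:
    """Audit record for the serotonergic/non-serotonergic cut."""

    axis: str                      # which embedding axis was cut
    cutoff: float                  # midpoint between the two 1-D means
    separation: float              # between-group / total variance on that axis
    bimodal: bool                  # separation exceeded the threshold
    marker_mean_serotonergic: float
    marker_mean_other: float


def split_serotonergic(
    coords: np.ndarray,
    norm_ec: pd.DataFrame,
    marker_genes: tuple[str, ...] = ("TPH1", "SLC18A1"),
    bimodality_threshold: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, SplitAudit]:
    """Two-group cut of EC cells on the 2-D embedding.

    Runs a 1-D two-means split on each candidate embedding axis — the
    two raw layout axes plus the layout's own principal axes, which
    capture diagonally placed clusters — and keeps the direction with
    the larger between-group variance fraction.  If that fraction stays
    below ``bimodality_threshold`` the population is flagged unimodal
    and a single group ("serotonergic" for all) is returned with a
    warning.  Otherwise the side with the higher mean TPH1 + SLC18A1
    expression is labeled serotonergic.

    Returns (labels, audit) where labels are "serotonergic" /
    "non-serotonergic" per EC cell.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be n_cells x 2")
    n = coords.shape[0]
    if n < 4:
        raise ValueError("need at least 4 EC cells to split")
    if norm_ec.shape[1] != n:
        raise ValueError("normalized matrix and coordinates must cover the same cells")
    if np.allclose(coords, coords[0]):
        raise ValueError("degenerate embedding: all coordinates identical")

    centered = coords - coords.mean(axis=0)
    eigvecs = np.linalg.eigh(np.cov(centered.T))[1]
    candidates = {
        "umap1": coords[:, 0],
        "umap2": coords[:, 1],
        "layout_pc1": centered @ eigvecs[:, 1],  # eigh: largest eigenvalue last
        "layout_pc2": centered @ eigvecs[:, 0],
    }
    best = None
    for axis, x in candidates.items():
        if np.allclose(x, x[0]):
            continue
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(x[:, None])
        assign = km.labels_
        centers = km.cluster_centers_.ravel()
        total = x.var()
        between = sum(
            (assign == c).mean() * (x[assign == c].mean() - x.mean()) ** 2 for c in (0, 1)
        )
        sep = between / total if total > 0 else 0.0
        if best is None or sep > best[0]:
            best = (sep, axis, assign, centers)
    sep, axis, assign, centers = best

    marker_present = [g for g in marker_genes if g.upper() in norm_ec.index]
    if not marker_present:
        raise ValueError(f"none of the side-labeling markers {marker_genes} present")
    marker_expr = norm_ec.loc[[g.upper() for g in marker_present]].to_numpy().mean(axis=0)

    if sep < bimodality_threshold:
        warnings.warn(
            f"EC embedding looks unimodal (separation {sep:.3f} < "
            f"{bimodality_threshold}); returning a single serotonergic group",
            stacklevel=2,
        )
        labels = np.full(n, "serotonergic", dtype=object)
        return labels, SplitAudit(
            axis=axis, cutoff=float(np.mean(centers)), separation=float(sep),
            bimodal=False,
            marker_mean_serotonergic=float(marker_expr.mean()),
            marker_mean_other=float("nan"),
        )

    side_means = [marker_expr[assign == c].mean() for c in (0, 1)]
    sero_side = int(np.argmax(side_means))
    labels = np.where(assign == sero_side, "serotonergic", "non-serotonergic").astype(object)
    return labels, SplitAudit(
        axis=axis,
        cutoff=float(np.mean(centers)),
        separation=float(sep),
        bimodal=True,
        marker_mean_serotonergic=float(side_means[sero_side]),
        marker_mean_other=float(side_means[1 - sero_side]),
    )
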