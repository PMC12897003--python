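"""Per-cell QC metrics and the three filtering rules.

Cells are removed when they have fewer than ``min_features`` or more
than ``max_features`` detected genes, when their mitochondrial count
fraction exceeds ``max_mito_fraction``, or when their stress score
(mean log-normalized expression of the five canonical stress-response
genes) lies strictly above a high percentile of the post-QC score
distribution.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import CountMatrix, RunConfig
from .synthetic import STRESS_GENES

__all__ = ["compute_cell_qc", "filter_cells", "stress_filter", "DEFAULT_MITO_PREFIX"]

DEFAULT_MITO_PREFIX = "MT-"


def _mito_mask(cm: CountMatrix, mito_genes: list[str] | None) -> np.ndarray:
    if mito_genes is None:
        return np.array([g.startswith(DEFAULT_MITO_PREFIX) for g in cm.genes])
    wanted = {g.upper() for g in mito_genes}
    return np.array([g in wanted for g in cm.genes])


def _stress_scores(cm: CountMatrix, stress_genes: tuple[str, ...]) -> np.ndarray:
    """Mean log1p counts-per-10k over the stress genes (depth-independent)."""
    present = [g for g in stress_genes if g.upper() in set(cm.genes)]
    missing = set(g.upper() for g in stress_genes) - set(cm.genes)
    if missing:
        warnings.warn(f"stress genes absent from matrix: {sorted(missing)}", stacklevel=3)
    if not present:
        return np.zeros(cm.n_cells)
    totals = np.asarray(cm.counts.sum(axis=0)).ravel().astype(float)
    totals[totals == 0] = 1.0  # zero-total cells score 0 and fail QC anyway
    idx = [cm.gene_index(g) for g in present]
    sub = np.asarray(cm.counts[idx, :].todense()).astype(float)
    return np.log1p(1e4 * sub / totals[None, :]).mean(axis=0)


def compute_cell_qc(
    cm: CountMatrix,
    mito_genes: list[str] | None = None,
    stress_genes: tuple[str, ...] = STRESS_GENES,
) -> pd.DataFrame:
    """One row per cell: n_features, total_counts, mito_fraction, stress_score.

    Mitochondrial genes default to the ``MT-`` symbol prefix; an explicit
    list overrides the prefix rule.
    """
    if cm.n_cells == 0 or cm.n_genes == 0:
        raise ValueError("empty count matrix")
    counts = cm.counts
    n_features = np.asarray((counts > 0).sum(axis=0)).ravel()
    totals = np.asarray(counts.sum(axis=0)).ravel()
    mito = _mito_mask(cm, mito_genes)
    mito_counts = np.asarray(counts[mito, :].sum(axis=0)).ravel() if mito.any() else np.zeros(cm.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    return pd.DataFrame(
        {
            "barcode": cm.cells,
            "n_features": n_features.astype(int),
            "total_counts": totals.astype(int),
            "mito_fraction": mito_fraction,
            "stress_score": _stress_scores(cm, stress_genes),
        }
    )


def filter_cells(qc: pd.DataFrame, config: RunConfig) -> np.ndarray:
    """Feature-count and mitochondrial filters.

    Keep iff min_features <= n_features <= max_features (inclusive
    bounds: "fewer than"/"more than" are removed) and
    mito_fraction <= max_mito_fraction (strictly "more than" removed).
    """
    config.validate()
    n = qc["n_features"].to_numpy()
    mito = qc["mito_fraction"].to_numpy()
    return (
        (n >= config.min_features)
        & (n <= config.max_features)
        & (mito <= config.max_mito_fraction)
    )


def stress_filter(
    data: pd.DataFrame | CountMatrix,
    percentile: float = 98.0,
    base_mask: np.ndarray | None = None,
    stress_genes: tuple[str, ...] = STRESS_GENES,
) -> np.ndarray:
    """Remove cells whose stress score strictly exceeds the given
    percentile of the stress-score distribution.

    ``data`` is either a QC table from :func:`compute_cell_qc` or a raw
    CountMatrix (scores computed on the fly).  The percentile (linear
    interpolation between order statistics) is computed over cells
    passing ``base_mask`` (the basic QC mask), so junk cells do not
    distort the cutoff.  Returns a keep-mask over all cells; cells
    outside ``base_mask`` are marked removed.
    """
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    if isinstance(data, CountMatrix):
        scores = _stress_scores(data, stress_genes)
    else:
        scores = data["stress_score"].to_numpy()
    if base_mask is None:
        base_mask = np.ones(len(scores), dtype=bool)
    base_mask = np.asarray(base_mask, dtype=bool)
    if base_mask.sum() < 2:
        raise ValueError("stress filter needs at least 2 cells")
    cutoff = np.percentile(scores[base_mask], percentile)
    return base_mask & (scores <= cutoff)
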