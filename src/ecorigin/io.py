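"""Readers and writers for the formats the pipeline touches.

Count matrices travel as MatrixMarket coordinate triplets with
``genes.tsv``/``barcodes.tsv`` sidecars (the 10x triplet dialect) or as
dense TSV with genes as rows.  Gene symbols are uppercased on ingest and
matched case-insensitively throughout the package, because marker panels
are given as HGNC symbols while public matrices vary in case.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

__all__ = [
    "CountMatrix",
    "ReferenceTable",
    "RunConfig",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_dense_tsv",
    "write_dense_tsv",
    "read_reference_table",
    "load_config",
    "write_run_log",
]


@dataclass
class CountMatrix:
    """Sparse gene-by-cell raw count matrix with identifiers.

    Invariants enforced on construction: gene symbols unique after
    uppercasing, barcodes unique, counts finite non-negative integers.
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.genes = [str(g).upper() for g in self.genes]
        self.cells = [str(c) for c in self.cells]
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols not unique after uppercasing")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell barcodes")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        data = self.counts.data
        if data.size:
            if not np.all(np.isfinite(data)):
                raise ValueError("counts contain non-finite entries")
            if np.any(data < 0):
                raise ValueError("counts contain negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts contain non-integer entries")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self, symbol: str) -> int:
        """Case-insensitive gene lookup; raises KeyError if absent."""
        try:
            return self.genes.index(symbol.upper())
        except ValueError:
            raise KeyError(f"gene {symbol!r} not in matrix") from None

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            genes=list(self.genes),
            cells=[self.cells[i] for i in idx],
            counts=self.counts[:, idx],
        )


class ReferenceTable:
    """Gene symbol -> enteroendocrine-expressed flag (true/false/unknown).

    Emulates a local cross-reference of tissue-level enteroendocrine
    expression (Human Protein Atlas style).  Lookup of a gene absent from
    the table returns ``None`` ("unknown").
    """

    def __init__(self, flags: dict[str, bool]):
        upper = {}
        for gene, flag in flags.items():
            g = str(gene).upper()
            if g in upper:
                raise ValueError(f"duplicate gene row in reference table: {g}")
            upper[g] = bool(flag)
        self._flags = upper

    def lookup(self, gene: str) -> bool | None:
        return self._flags.get(str(gene).upper())

    def __len__(self) -> int:
        return len(self._flags)

    def __contains__(self, gene: str) -> bool:
        return str(gene).upper() in self._flags

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self._flags),
                "enteroendocrine": ["yes" if v else "no" for v in self._flags.values()],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


_TRUE = {"yes", "1", "true"}
_FALSE = {"no", "0", "false"}


def read_reference_table(path: str | Path) -> ReferenceTable:
    """Read a TSV with header columns ``gene`` and ``enteroendocrine``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "enteroendocrine"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"reference table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    flags: dict[str, bool] = {}
    for gene, raw in zip(df["gene"], df["enteroendocrine"]):
        g = str(gene).upper()
        if g in flags:
            raise ValueError(f"duplicate gene row in reference table: {g}")
        val = str(raw).strip().lower()
        if val in _TRUE:
            flags[g] = True
        elif val in _FALSE:
            flags[g] = False
        else:
            raise ValueError(f"unrecognized enteroendocrine flag {raw!r} for gene {g}")
    return ReferenceTable(flags)


def _read_single_column(path: str | Path, take_last_field: bool = False) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            out.append(fields[-1] if take_last_field else fields[0])
    return out


def read_mtx_triplet(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> CountMatrix:
    """Read a 10x-style MTX triplet into gene-major orientation.

    Orientation is inferred by matching the MatrixMarket dimensions
    against the lengths of the gene and barcode files; an ambiguous
    square case (equal gene and barcode counts) is an error.
    """
    mat = sp.coo_matrix(scipy.io.mmread(str(matrix_path)))
    # 10x genes.tsv may carry (gene_id, symbol); take the last field.
    genes = _read_single_column(genes_path, take_last_field=True)
    cells = _read_single_column(barcodes_path)
    n_genes, n_cells = len(genes), len(cells)
    r, c = mat.shape
    gene_major = (r == n_genes and c == n_cells)
    cell_major = (r == n_cells and c == n_genes)
    if gene_major and cell_major:
        raise ValueError(
            "orientation ambiguous: equal gene and barcode counts with a square matrix"
        )
    if gene_major:
        counts = mat
    elif cell_major:
        counts = mat.T
    else:
        raise ValueError(
            f"dimension mismatch: matrix is {r}x{c} but found "
            f"{n_genes} genes and {n_cells} barcodes"
        )
    return CountMatrix(genes=genes, cells=cells, counts=sp.csr_matrix(counts))


def write_mtx_triplet(
    cm: CountMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write gene-major MatrixMarket coordinate integer triplet."""
    scipy.io.mmwrite(str(matrix_path), cm.counts.tocoo(), field="integer")
    with open(genes_path, "w") as fh:
        for g in cm.genes:
            fh.write(f"{g}\n")
    with open(barcodes_path, "w") as fh:
        for c in cm.cells:
            fh.write(f"{c}\n")


def read_dense_tsv(path: str | Path) -> CountMatrix:
    """Dense TSV count matrix, genes as rows, barcodes as header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(
        genes=list(df.index.astype(str)),
        cells=list(df.columns.astype(str)),
        counts=sp.csr_matrix(df.to_numpy()),
    )


def write_dense_tsv(cm: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(cm.to_dense(), index=cm.genes, columns=cm.cells).to_csv(path, sep="\t")


@dataclass
class RunConfig:
    """Resolved pipeline configuration.

    Defaults follow the study conventions: feature-count window
    [200, 7000], mitochondrial fraction cutoff 0.40, stress filter at the
    98th percentile, 2000 highly variable genes, 1000 bootstrap
    iterations.
    """

    # QC
    min_features: int = 200
    max_features: int = 7000
    max_mito_fraction: float = 0.40
    stress_percentile: float = 98.0
    # reduction / clustering
    n_hvgs: int = 2000
    n_pcs: int = 30
    k_neighbors: int = 15
    resolution: float = 1.0
    clip_value: float = 10.0
    # annotation
    ec_score_factor: float = 1.7
    min_ne_cluster_size: int = 5
    bimodality_threshold: float = 0.8
    # identity axis
    n_bootstrap: int = 1000
    n_bins: int = 24
    n_ctrl: int = 100
    equal_group_size: int = 0  # 0 -> resample every group to the smallest group's size
    # differential expression / reciprocal calls
    alpha: float = 0.05
    min_cells: int = 3
    detect_min_fraction: float = 0.10
    absent_max_fraction: float = 0.0
    # randomness
    seed: int = 0
    # optional file paths
    input_matrix: str = ""
    input_genes: str = ""
    input_barcodes: str = ""
    reference_table: str = ""

    def validate(self) -> "RunConfig":
        if not 0 < self.stress_percentile < 100:
            raise ValueError(f"stress_percentile must be in (0, 100), got {self.stress_percentile}")
        for name in ("max_mito_fraction", "detect_min_fraction", "absent_max_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_features < 0 or self.max_features < self.min_features:
            raise ValueError("require 0 <= min_features <= max_features")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        for name in ("n_hvgs", "n_pcs", "k_neighbors", "n_bootstrap", "n_bins", "n_ctrl", "min_cells", "min_ne_cluster_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.resolution < 0:
            raise ValueError("resolution must be >= 0")
        if self.equal_group_size < 0:
            raise ValueError("equal_group_size must be >= 0")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        return self

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs).validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a flat key-value (YAML mapping) config file.

    Unspecified fields fall back to the defaults above; unknown keys are
    rejected loudly.  An empty file yields the full default config.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key: value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw).validate()


def write_run_log(path: str | Path, config: RunConfig, **extra) -> None:
    """Log the fully resolved configuration plus run metadata as JSON."""
    from . import __version__

    payload = {"package_version": __version__, "config": config.to_dict()}
    payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
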