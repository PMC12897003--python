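"""Synthetic single-cell cohorts with ground-truth labels.

The generator emulates the population structure the downstream analysis
assumes: serotonergic and non-serotonergic enterochromaffin (EC) cells
from normal ileal mucosa, SI-NET tumor cells, background epithelial and
immune populations, and a spiked subpopulation of stressed cells.
Counts are negative-binomial with log-normal cell library sizes;
mitochondrial pseudo-genes receive a configurable fraction of each
cell's library in expectation, and stressed cells get an additive
log2 mean shift on the five canonical stress-response genes.

Every generated cell carries a truth record (population, stressed flag,
batch, sample origin), so filters, annotation, and signature recovery
can be scored against known labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, ReferenceTable

__all__ = [
    "STRESS_GENES",
    "EC_PANEL",
    "SUBTYPE_PANEL",
    "LOE_GENES",
    "GOE_GENES",
    "SERO_SIGNATURE_GENES",
    "NONSERO_SIGNATURE_GENES",
    "PopulationSpec",
    "generate_cohort",
    "default_study_cohort",
    "mixture_cohort",
    "default_reference_table",
]

# Canonical stress-response genes; present in every generated gene universe.
STRESS_GENES = ("HSPA1A", "HSPA1B", "HSP90AA1", "HSPB1", "DNAJB1")

# Canonical EC identification panel.
EC_PANEL = ("CHGA", "CHGB", "SCGN", "NEUROD1", "SLC18A1", "ADGRG4")

# 14-gene serotonergic/non-serotonergic subtyping panel.
SUBTYPE_PANEL = (
    "TPH1", "DDC", "SLC18A1", "CHGA", "CHGB", "LMX1A", "FEV",
    "SCN3A", "TRPM3", "SCG2", "NTS", "PYY", "CCK", "ADGRG4",
)

# Reciprocal-expression fixture genes: lost vs gained in SI-NET relative
# to serotonergic EC cells.
LOE_GENES = ("BRINP3", "CEACAM20", "DLL1", "EVPL", "FABP5", "NPNT", "PKHD1L1", "PPP1R1C")
GOE_GENES = ("CNTNAP5", "CTNNA2", "DACH2", "GLRA3", "GRIA2", "MYT1L", "SYT14", "TRPS1")

# Planted subtype expression programs (filler symbols, not real genes).
SERO_SIGNATURE_GENES = tuple(f"SEROSIG{i:02d}" for i in range(1, 21))
NONSERO_SIGNATURE_GENES = tuple(f"NONSEROSIG{i:02d}" for i in range(1, 21))


@dataclass
class PopulationSpec:
    """One simulated cell population.

    ``markers`` maps gene symbol to log2 fold-change over the shared
    baseline; ``silenced`` genes have their mean forced to exactly zero
    (used to plant absolute loss/gain-of-expression events).
    """

    name: str
    n_cells: int
    markers: dict[str, float] = field(default_factory=dict)
    silenced: tuple[str, ...] = ()
    mito_fraction: float = 0.05
    stressed_fraction: float = 0.0
    origin: str = "normal"  # sample origin: "normal" mucosa or "tumor"
    batch: str = "batch0"

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for g, fc in self.markers.items():
            if not np.isfinite(fc):
                raise ValueError(f"non-finite fold-change for {g}")
        if not 0 <= self.mito_fraction < 1:
            raise ValueError("mito_fraction must be in [0, 1)")
        if not 0 <= self.stressed_fraction <= 1:
            raise ValueError("stressed_fraction must be in [0, 1]")
        if self.origin not in ("normal", "tumor"):
            raise ValueError("origin must be 'normal' or 'tumor'")
        self.markers = {str(g).upper(): float(fc) for g, fc in self.markers.items()}
        self.silenced = tuple(str(g).upper() for g in self.silenced)


def _build_gene_universe(specs: list[PopulationSpec], n_genes: int, n_mito: int) -> list[str]:
    named: list[str] = []
    seen: set[str] = set()

    def add(g: str) -> None:
        if g not in seen:
            named.append(g)
            seen.add(g)

    for g in STRESS_GENES:
        add(g)
    for spec in specs:
        for g in spec.markers:
            add(g)
        for g in spec.silenced:
            add(g)
    mito = [f"MT-{i}" for i in range(1, n_mito + 1)]
    n_filler = n_genes - len(named) - len(mito)
    if n_filler < 0:
        raise ValueError(
            f"n_genes={n_genes} too small for {len(named)} named + {len(mito)} mito genes"
        )
    filler = [f"GENE{i:04d}" for i in range(1, n_filler + 1)]
    return named + filler + mito


def generate_cohort(
    specs: list[PopulationSpec],
    n_genes: int = 1500,
    seed: int = 0,
    *,
    n_mito: int = 10,
    dispersion: float = 0.5,
    mean_library_size: float = 5000.0,
    libsize_sigma: float = 0.35,
    stress_shift: float = 6.0,
    batch_effect_sd: float = 0.0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a cohort from population specs.

    Parameters
    ----------
    specs
        Population definitions; marker genes must fit in the gene universe.
    n_genes
        Total gene universe size, including mitochondrial pseudo-genes.
    dispersion
        Negative-binomial size parameter theta (var = mu + mu^2/theta).
    mean_library_size
        Expected counts per cell before the log-normal library factor.
    libsize_sigma
        Sigma of the log-normal per-cell library-size factor.
    stress_shift
        Additive log2 mean shift on the stress genes for stressed cells.
    batch_effect_sd
        Sd of per-batch multiplicative log2 gene effects (0 = no effect).

    Returns
    -------
    (CountMatrix, truth table) with identical cell ordering.  The truth
    table has columns barcode, population, stressed, batch, origin.
    """
    if not specs:
        raise ValueError("empty population spec list")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    genes = _build_gene_universe(specs, n_genes, n_mito)
    gene_idx = {g: i for i, g in enumerate(genes)}
    for spec in specs:
        for g in spec.markers:
            if g not in gene_idx:  # pragma: no cover - universe includes markers
                raise ValueError(f"marker gene {g} absent from universe")

    is_mito = np.array([g.startswith("MT-") for g in genes])
    stress_idx = np.array([gene_idx[g] for g in STRESS_GENES])

    # Shared baseline relative expression (log-normal across genes).
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    base[is_mito] = 1.0  # mito weights set per population below

    batches = sorted({s.batch for s in specs})
    batch_fx = {
        b: (np.exp2(rng.normal(0.0, batch_effect_sd, size=len(genes))) if batch_effect_sd > 0
            else np.ones(len(genes)))
        for b in batches
    }

    blocks: list[np.ndarray] = []
    records: list[dict] = []
    cell_counter = 0
    for spec in specs:
        if spec.n_cells == 0:
            continue
        w = base.copy()
        for g, fc in spec.markers.items():
            w[gene_idx[g]] *= 2.0 ** fc
        for g in spec.silenced:
            w[gene_idx[g]] = 0.0
        w *= batch_fx[spec.batch]
        # Mitochondrial pseudo-genes take mito_fraction of the library in
        # expectation: weight them at f/(1-f) of the non-mito total.
        w[is_mito] = 0.0
        nonmito_total = w.sum()
        f = spec.mito_fraction
        if f > 0:
            w[is_mito] = (f / (1.0 - f)) * nonmito_total / is_mito.sum()

        # Exact seeded stressed-cell count, so planted fractions are
        # recovered by percentile filters without binomial wobble.
        n_stressed = int(round(spec.stressed_fraction * spec.n_cells))
        stressed = np.zeros(spec.n_cells, dtype=bool)
        if n_stressed:
            stressed[rng.choice(spec.n_cells, size=n_stressed, replace=False)] = True

        lib = mean_library_size * rng.lognormal(0.0, libsize_sigma, size=spec.n_cells)
        w_plain = w / w.sum()
        w_stress = w.copy()
        w_stress[stress_idx] *= 2.0 ** stress_shift
        w_stress /= w_stress.sum()
        mu = np.where(stressed[None, :], w_stress[:, None], w_plain[:, None]) * lib[None, :]

        # NB via gamma-Poisson mixture.
        lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
        counts = rng.poisson(lam)
        blocks.append(counts)
        for i in range(spec.n_cells):
            records.append(
                {
                    "barcode": f"CELL{cell_counter:05d}",
                    "population": spec.name,
                    "stressed": bool(stressed[i]),
                    "batch": spec.batch,
                    "origin": spec.origin,
                }
            )
            cell_counter += 1

    counts = np.concatenate(blocks, axis=1)
    truth = pd.DataFrame.from_records(records)
    cm = CountMatrix(genes=genes, cells=list(truth["barcode"]), counts=sp.csr_matrix(counts))
    return cm, truth


def _ec_background_specs(stressed_fraction: float = 0.02) -> list[PopulationSpec]:
    """Background epithelial/immune populations for both sample origins."""
    return [
        PopulationSpec(
            "enterocyte", 250,
            markers={"APOA4": 4, "FABP2": 4, "ALPI": 3},
            stressed_fraction=stressed_fraction,
        ),
        PopulationSpec(
            "crypt_enterocyte", 150,
            markers={"LGR5": 4, "OLFM4": 4, "MKI67": 3},
            stressed_fraction=stressed_fraction,
        ),
        PopulationSpec(
            "goblet", 150,
            markers={"MUC2": 5, "TFF3": 4, "SPINK4": 3},
            stressed_fraction=stressed_fraction,
        ),
        PopulationSpec(
            "t_cell", 200,
            markers={"CD3D": 4, "CD3E": 4, "TRAC": 3, "PTPRC": 3},
            stressed_fraction=stressed_fraction,
        ),
        PopulationSpec(
            "monocyte", 150,
            markers={"CD14": 4, "LYZ": 5, "FCN1": 3},
            stressed_fraction=stressed_fraction,
        ),
        PopulationSpec(
            "t_cell_tumor", 150,
            markers={"CD3D": 4, "CD3E": 4, "TRAC": 3, "PTPRC": 3},
            stressed_fraction=stressed_fraction,
            origin="tumor",
        ),
    ]


def _sero_ec_spec(n_cells: int = 40) -> PopulationSpec:
    markers = {
        "TPH1": 5, "DDC": 4, "SLC18A1": 4, "ADGRG4": 5,
        "CHGA": 4, "CHGB": 4, "SCGN": 3, "NEUROD1": 3,
        "FEV": 3, "LMX1A": 3, "SCN3A": 2, "TRPM3": 2, "SCG2": 3,
    }
    markers.update({g: 4.0 for g in SERO_SIGNATURE_GENES})
    markers.update({g: 2.0 for g in LOE_GENES})  # expressed in normal EC
    return PopulationSpec(
        "serotonergic_EC", n_cells, markers=markers, silenced=GOE_GENES, origin="normal",
    )


def _nonsero_ec_spec(n_cells: int = 36) -> PopulationSpec:
    markers = {
        "CHGA": 4, "CHGB": 4, "SCGN": 3, "NEUROD1": 3,
        "NTS": 4, "PYY": 4, "CCK": 4, "TRPM3": 2, "SCG2": 2,
    }
    markers.update({g: 4.0 for g in NONSERO_SIGNATURE_GENES})
    markers.update({g: 2.0 for g in LOE_GENES})
    return PopulationSpec(
        "nonserotonergic_EC", n_cells, markers=markers, silenced=GOE_GENES, origin="normal",
    )


def _sinet_spec(n_cells: int = 30, lam: float = 0.75) -> PopulationSpec:
    """SI-NET population: serotonergic neuroendocrine program plus a
    distinct tumor program; its subtype-signature expression mixes the
    two EC programs at coefficient ``lam`` (1 = fully serotonergic)."""
    markers = {
        "TPH1": 5, "DDC": 4, "SLC18A1": 4, "ADGRG4": 2,
        "CHGA": 5, "CHGB": 5, "SCGN": 3, "NEUROD1": 3, "FEV": 3, "SCG2": 3,
    }
    markers.update({g: 4.0 * lam for g in SERO_SIGNATURE_GENES})
    markers.update({g: 4.0 * (1.0 - lam) for g in NONSERO_SIGNATURE_GENES})
    markers.update({g: 5.0 for g in GOE_GENES})
    markers.update({f"TUMORPROG{i:02d}": 4.0 for i in range(1, 11)})
    return PopulationSpec(
        "SI-NET", n_cells, markers=markers, silenced=LOE_GENES, origin="tumor",
    )


def default_study_cohort(
    seed: int = 0,
    *,
    n_sero: int = 40,
    n_nonsero: int = 36,
    n_sinet: int = 30,
    lam: float = 0.75,
    n_genes: int = 1500,
    stressed_fraction: float = 0.02,
    **kwargs,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Default study-sized fixture: 76 EC cells (40 serotonergic + 36
    non-serotonergic), 30 SI-NET cells, and background populations from
    both sample origins with a 2% stressed subpopulation.

    LoE fixture genes are silenced (exactly zero) in SI-NET cells; GoE
    fixture genes are silenced in both EC subtypes.
    """
    specs = [
        _sero_ec_spec(n_sero),
        _nonsero_ec_spec(n_nonsero),
        _sinet_spec(n_sinet, lam=lam),
        *_ec_background_specs(stressed_fraction),
    ]
    return generate_cohort(specs, n_genes=n_genes, seed=seed, **kwargs)


def mixture_cohort(
    lam: float,
    seed: int = 0,
    *,
    n_per_side: int = 50,
    n_sinet: int = 30,
    n_genes: int = 1000,
    **kwargs,
) -> tuple[CountMatrix, pd.DataFrame]:
    """EC-plus-tumor cohort for parameter recovery: the SI-NET subtype
    program is a ``lam``-weighted mixture of the serotonergic and
    non-serotonergic EC programs (no background populations)."""
    if not 0 <= lam <= 1:
        raise ValueError("lam must be in [0, 1]")
    specs = [
        _sero_ec_spec(n_per_side),
        _nonsero_ec_spec(n_per_side),
        _sinet_spec(n_sinet, lam=lam),
    ]
    return generate_cohort(specs, n_genes=n_genes, seed=seed, **kwargs)


def default_reference_table(n_decoys: int = 20) -> ReferenceTable:
    """Enteroendocrine-specificity reference matching the default cohort:
    all planted LoE and GoE genes flagged enteroendocrine-expressed, plus
    decoy genes flagged not-expressed.  Genes absent from the table look
    up as unknown."""
    flags = {g: True for g in LOE_GENES + GOE_GENES}
    flags.update({f"GENE{i:04d}": False for i in range(1, n_decoys + 1)})
    return ReferenceTable(flags)
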