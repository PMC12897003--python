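"""End-to-end orchestration: simulate -> qc -> embed -> annotate -> axis
-> deg -> reciprocal.

Stages communicate through files (TSV/MTX) under a run directory so
each stage is independently runnable and resumable, and a run manifest
records the resolved config, per-stage output hashes, seeds, timings
and warnings.  Identical config + seed reproduce byte-identical stage
tables.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, axis as axis_mod, qc as qc_mod, reciprocal as rec_mod, reduce as red_mod
from .differential import run_deg
from .io import CountMatrix, RunConfig, read_mtx_triplet, read_reference_table, write_mtx_triplet, write_run_log
from .synthetic import default_study_cohort, default_reference_table

__all__ = [
    "run_pipeline",
    "stage_simulate",
    "stage_qc",
    "stage_embed",
    "stage_annotate",
    "stage_axis",
    "stage_deg",
    "stage_reciprocal",
    "PipelineError",
]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.data: dict = {"config": config.to_dict(), "stages": {}, "warnings": []}

    def record(self, stage: str, outputs: list[Path], t0: float) -> None:
        self.data["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
            "seconds": round(time.perf_counter() - t0, 3),
        }

    def warn(self, stage: str, message: str) -> None:
        self.data["warnings"].append({"stage": stage, "message": message})

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def _matrix_paths(outdir: Path, stem: str) -> tuple[Path, Path, Path]:
    return outdir / f"{stem}.mtx", outdir / f"{stem}.genes.tsv", outdir / f"{stem}.barcodes.tsv"


def stage_simulate(config: RunConfig, outdir: Path) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate the default study-sized cohort and write MTX + truth TSV."""
    outdir.mkdir(parents=True, exist_ok=True)
    cm, truth = default_study_cohort(seed=config.seed)
    write_mtx_triplet(cm, *_matrix_paths(outdir, "counts"))
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    default_reference_table().write(outdir / "reference.tsv")
    return cm, truth


def stage_qc(
    cm: CountMatrix, config: RunConfig, outdir: Path
) -> tuple[CountMatrix, pd.DataFrame, np.ndarray]:
    """QC metrics, feature/mito filters, then the stress-percentile filter."""
    qc = qc_mod.compute_cell_qc(cm)
    base = qc_mod.filter_cells(qc, config)
    keep = qc_mod.stress_filter(qc, config.stress_percentile, base_mask=base)
    qc.assign(pass_basic_qc=base, keep=keep).to_csv(outdir / "cell_qc.tsv", sep="\t", index=False)
    filtered = cm.subset_cells(keep)
    write_mtx_triplet(filtered, *_matrix_paths(outdir, "counts_filtered"))
    return filtered, qc, keep


def stage_embed(
    cm: CountMatrix, config: RunConfig, outdir: Path, batches: pd.Series | None = None
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Normalize, select HVGs, scale, PCA, cluster, 2-D embed."""
    norm = red_mod.normalize_log1p_cp10k(cm)
    hvgs = red_mod.select_hvgs(norm, min(config.n_hvgs, norm.shape[0]))
    scaled = red_mod.scale_matrix(norm, hvgs, config.clip_value, batches)
    pcs = red_mod.pca_embed(scaled, config.n_pcs)
    labels = red_mod.cluster_cells(pcs, config.k_neighbors, config.resolution, config.seed)
    coords = red_mod.umap2d(pcs, config.seed)
    pd.DataFrame({"barcode": cm.cells, "cluster": labels,
                  "umap1": coords[:, 0], "umap2": coords[:, 1]}).to_csv(
        outdir / "embedding.tsv", sep="\t", index=False)
    with open(outdir / "hvgs.txt", "w") as fh:
        fh.write("\n".join(hvgs) + "\n")
    return norm, pcs, labels, coords


def stage_annotate(
    norm: pd.DataFrame,
    cluster_labels: np.ndarray,
    coords: np.ndarray,
    origins: np.ndarray,
    config: RunConfig,
    outdir: Path,
) -> pd.DataFrame:
    """EC/SI-NET class assignment and serotonergic subtype split."""
    scores = annotate.score_clusters(norm, cluster_labels, annotate.EC_MARKER_PANEL)
    ann = annotate.assign_classes(scores, cluster_labels, origins,
                                  config.ec_score_factor, config.min_ne_cluster_size)
    ann.insert(0, "barcode", list(norm.columns))
    ann["subtype"] = "not-applicable"
    ec_mask = (ann["class_label"] == "EC").to_numpy()
    if ec_mask.sum() >= 4:
        sub_labels, audit = annotate.split_serotonergic(
            coords[ec_mask],
            norm.loc[:, ec_mask],
            bimodality_threshold=config.bimodality_threshold,
            seed=config.seed,
        )
        ann.loc[ec_mask, "subtype"] = sub_labels
        with open(outdir / "subtype_audit.json", "w") as fh:
            json.dump(audit.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
    scores.rename("ec_panel_score").to_csv(outdir / "cluster_scores.tsv", sep="\t")
    ann.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    return ann


def stage_axis(
    norm: pd.DataFrame, ann: pd.DataFrame, config: RunConfig, outdir: Path
) -> axis_mod.AxisSummary:
    """Signatures, module scores, identity axis, bootstrap summary."""
    is_ec = (ann["class_label"] == "EC").to_numpy()
    subtype = ann["subtype"].to_numpy()
    norm_ec = norm.loc[:, is_ec]
    sig = axis_mod.derive_signatures(norm_ec, subtype[is_ec], alpha=config.alpha,
                                     min_cells=config.min_cells)
    keep = is_ec | (ann["class_label"] == "SI-NET").to_numpy()
    norm_ne = norm.loc[:, keep]
    s_sero = axis_mod.module_score(norm_ne, sig.serotonergic, config.n_bins,
                                   config.n_ctrl, seed=config.seed)
    s_non = axis_mod.module_score(norm_ne, sig.non_serotonergic, config.n_bins,
                                  config.n_ctrl, seed=config.seed + 1)
    ax = axis_mod.axis_values(s_sero, s_non)
    groups = np.where(is_ec[keep], subtype[keep], "SI-NET")
    summary = axis_mod.bootstrap_axis(ax, groups, n_iter=config.n_bootstrap,
                                      seed=config.seed,
                                      equal_group_size=config.equal_group_size)
    pd.DataFrame({
        "barcode": list(norm_ne.columns), "group": groups,
        "score_serotonergic": s_sero, "score_nonserotonergic": s_non, "axis": ax,
    }).to_csv(outdir / "axis_scores.tsv", sep="\t", index=False)
    summary.group_stats.to_csv(outdir / "axis_summary.tsv", sep="\t", index=False)
    with open(outdir / "axis_summary.json", "w") as fh:
        json.dump(summary.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "signatures.json", "w") as fh:
        json.dump({"serotonergic": list(sig.serotonergic),
                   "non_serotonergic": list(sig.non_serotonergic)}, fh, indent=2)
        fh.write("\n")
    return summary


def stage_deg(
    norm: pd.DataFrame, ann: pd.DataFrame, config: RunConfig, outdir: Path
) -> pd.DataFrame:
    """SI-NET vs serotonergic-EC differential expression table."""
    sinet = (ann["class_label"] == "SI-NET").to_numpy()
    sero = ((ann["class_label"] == "EC") & (ann["subtype"] == "serotonergic")).to_numpy()
    deg = run_deg(norm, sinet, sero, alpha=config.alpha, min_cells=config.min_cells)
    deg.to_csv(outdir / "deg_sinet_vs_sero.tsv", sep="\t", index=False)
    return deg


def stage_reciprocal(
    norm: pd.DataFrame,
    ann: pd.DataFrame,
    deg: pd.DataFrame,
    config: RunConfig,
    outdir: Path,
    reference_path: Path | None = None,
) -> pd.DataFrame:
    """LoE/GoE calls with enteroendocrine reference verification."""
    sinet = (ann["class_label"] == "SI-NET").to_numpy()
    sero = ((ann["class_label"] == "EC") & (ann["subtype"] == "serotonergic")).to_numpy()
    significant = list(deg.loc[deg["significant"], "gene"])
    calls = rec_mod.call_reciprocal(
        norm, significant, sinet, sero,
        detect_min_fraction=config.detect_min_fraction,
        absent_max_fraction=config.absent_max_fraction,
    )
    reference = (read_reference_table(reference_path) if reference_path is not None
                 else default_reference_table())
    verified = rec_mod.verify_against_reference(calls, reference)
    verified.to_csv(outdir / "reciprocal_calls.tsv", sep="\t", index=False)
    return verified


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run all stages; returns the manifest dict.

    Input comes either from ``config.input_matrix``/``input_genes``/
    ``input_barcodes`` (with a truth/annotation origin column expected
    in a sidecar) or, when unset, from the built-in simulator.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)

    def run_stage(name, fn, *args, outputs=(), **kwargs):
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                result = fn(*args, **kwargs)
            for w in caught:
                manifest.warn(name, str(w.message))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        manifest.record(name, [outdir / o for o in outputs if (outdir / o).exists()], t0)
        return result

    if config.input_matrix:
        cm = run_stage(
            "load", read_mtx_triplet, config.input_matrix, config.input_genes,
            config.input_barcodes,
        )
        truth = pd.DataFrame({"barcode": cm.cells, "origin": "normal",
                              "batch": "batch0"})
    else:
        cm, truth = run_stage(
            "simulate", stage_simulate, config, outdir,
            outputs=["counts.mtx", "counts.genes.tsv", "counts.barcodes.tsv",
                     "truth.tsv", "reference.tsv"],
        )

    cm_f, qc, keep = run_stage(
        "qc", stage_qc, cm, config, outdir,
        outputs=["cell_qc.tsv", "counts_filtered.mtx"],
    )
    truth_f = truth.loc[np.asarray(keep)].reset_index(drop=True)

    batches = truth_f["batch"] if truth_f["batch"].nunique() > 1 else None
    norm, pcs, labels, coords = run_stage(
        "embed", stage_embed, cm_f, config, outdir, batches,
        outputs=["embedding.tsv", "hvgs.txt"],
    )

    ann = run_stage(
        "annotate", stage_annotate, norm, labels, coords,
        truth_f["origin"].to_numpy(), config, outdir,
        outputs=["annotation.tsv", "cluster_scores.tsv", "subtype_audit.json"],
    )
    n_ec = int((ann["class_label"] == "EC").sum())
    n_sinet = int((ann["class_label"] == "SI-NET").sum())
    if n_ec == 0 or n_sinet == 0:
        manifest.write()
        raise PipelineError(
            "annotate",
            f"cannot continue: {n_ec} EC and {n_sinet} SI-NET cells annotated",
        )

    run_stage("axis", stage_axis, norm, ann, config, outdir,
              outputs=["axis_scores.tsv", "axis_summary.tsv", "axis_summary.json",
                       "signatures.json"])
    deg = run_stage("deg", stage_deg, norm, ann, config, outdir,
                    outputs=["deg_sinet_vs_sero.tsv"])
    ref_path = Path(config.reference_table) if config.reference_table else (
        outdir / "reference.tsv" if (outdir / "reference.tsv").exists() else None
    )
    run_stage("reciprocal", stage_reciprocal, norm, ann, deg, config, outdir,
              reference_path=ref_path, outputs=["reciprocal_calls.tsv"])

    write_run_log(outdir / "run_log.json", config, seed=config.seed)
    manifest.write()
    return manifest.data
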