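"""Shared fixtures: synthetic cohorts and their processed stages.

Session-scoped where the computation is heavy (UMAP, clustering) so the
chain simulate -> qc -> embed -> annotate is built once and reused.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ecorigin as eo
from ecorigin.reduce import scale_matrix
from ecorigin.synthetic import PopulationSpec, generate_cohort

SEED = 11


@pytest.fixture(scope="session")
def study_cohort():
    """Default study-sized cohort: 76 EC + 30 SI-NET + background."""
    return eo.default_study_cohort(seed=SEED)


@pytest.fixture(scope="session")
def two_pop_cohort():
    """Two well-separated populations with 20-gene expression programs."""
    prog_a = {f"PROGA{i:02d}": 4.0 for i in range(1, 21)}
    prog_b = {f"PROGB{i:02d}": 4.0 for i in range(1, 21)}
    return generate_cohort(
        [PopulationSpec("a", 100, markers=prog_a),
         PopulationSpec("b", 100, markers=prog_b)],
        n_genes=500,
        seed=3,
    )


@pytest.fixture(scope="session")
def two_pop_pcs(two_pop_cohort):
    cm, truth = two_pop_cohort
    norm = eo.normalize_log1p_cp10k(cm)
    pcs = eo.pca_embed(scale_matrix(norm, eo.select_hvgs(norm, 200)), 20)
    return pcs, truth


@pytest.fixture(scope="session")
def processed(study_cohort):
    """QC-filtered, normalized, clustered, embedded, annotated cohort."""
    cm, truth = study_cohort
    cfg = eo.RunConfig(seed=SEED)
    qc = eo.compute_cell_qc(cm)
    keep = eo.stress_filter(qc, cfg.stress_percentile,
                            base_mask=eo.filter_cells(qc, cfg))
    cmf = cm.subset_cells(keep)
    truth_f = truth.loc[np.asarray(keep)].reset_index(drop=True)
    norm = eo.normalize_log1p_cp10k(cmf)
    hvgs = eo.select_hvgs(norm, min(cfg.n_hvgs, norm.shape[0]))
    pcs = eo.pca_embed(scale_matrix(norm, hvgs, cfg.clip_value), cfg.n_pcs)
    clusters = eo.cluster_cells(pcs, cfg.k_neighbors, cfg.resolution, cfg.seed)
    coords = eo.umap2d(pcs, cfg.seed)
    from ecorigin.annotate import EC_MARKER_PANEL

    scores = eo.score_clusters(norm, clusters, EC_MARKER_PANEL)
    ann = eo.assign_classes(scores, clusters, truth_f["origin"].to_numpy(),
                            cfg.ec_score_factor)
    ann.insert(0, "barcode", list(norm.columns))
    ann["subtype"] = "not-applicable"
    ec_mask = (ann["class_label"] == "EC").to_numpy()
    sub_labels, audit = eo.split_serotonergic(
        coords[ec_mask], norm.loc[:, ec_mask],
        bimodality_threshold=cfg.bimodality_threshold, seed=cfg.seed,
    )
    ann.loc[ec_mask, "subtype"] = sub_labels
    return {
        "config": cfg,
        "counts": cmf,
        "truth": truth_f,
        "norm": norm,
        "hvgs": hvgs,
        "pcs": pcs,
        "clusters": clusters,
        "coords": coords,
        "cluster_scores": scores,
        "annotation": ann,
        "split_audit": audit,
    }


@pytest.fixture(scope="session")
def ec_subtypes(processed):
    """EC cells with truth and inferred subtype labels, plus signatures."""
    ann = processed["annotation"]
    truth = processed["truth"]
    norm = processed["norm"]
    ec = (ann["class_label"] == "EC").to_numpy()
    sig = eo.derive_signatures(norm.loc[:, ec], ann["subtype"].to_numpy()[ec])
    return {"ec_mask": ec, "signatures": sig, "ann": ann, "truth": truth, "norm": norm}
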