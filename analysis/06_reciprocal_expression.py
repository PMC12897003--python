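#!/usr/bin/env python
"""Reciprocal gain/loss-of-expression classification.

Among the genes significant in the SI-NET vs serotonergic-EC
comparison, classifies each as loss-of-expression (undetected in SI-NET
but expressed in serotonergic ECs) or gain-of-expression (the reverse),
then cross-references the calls against the local enteroendocrine-
specificity table and reports the verified candidates.
"""

import argparse
from pathlib import Path

import pandas as pd

from ecorigin.io import RunConfig, read_mtx_triplet
from ecorigin.pipeline import stage_reciprocal
from ecorigin.reduce import normalize_log1p_cp10k

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

cfg = RunConfig(seed=args.seed)
cm = read_mtx_triplet(args.outdir / "counts_filtered.mtx",
                      args.outdir / "counts_filtered.genes.tsv",
                      args.outdir / "counts_filtered.barcodes.tsv")
norm = normalize_log1p_cp10k(cm)
ann = pd.read_csv(args.outdir / "annotation.tsv", sep="\t")
deg = pd.read_csv(args.outdir / "deg_sinet_vs_sero.tsv", sep="\t")

calls = stage_reciprocal(norm, ann, deg, cfg, args.outdir,
                         reference_path=args.outdir / "reference.tsv")
print(calls.to_string(index=False))
n_loe = int((calls["call"] == "LoE").sum())
n_goe = int((calls["call"] == "GoE").sum())
print(f"\n{n_loe} LoE + {n_goe} GoE calls; "
      f"{int(calls['verified'].sum())} verified against the enteroendocrine "
      f"reference -> {args.outdir}/reciprocal_calls.tsv")
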