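# Methods

`ecorigin` re-implements, as a tested pipeline, a single-cell analysis
that asks whether small-intestinal neuroendocrine tumor (SI-NET) cells
transcriptionally resemble their candidate cell of origin — the
serotonergic enterochromaffin (EC) cell — more than the non-serotonergic
EC subtype. The patient data behind the original analysis is
controlled-access, so the package ships a synthetic-cohort generator
with ground-truth labels; every claim the test suite makes is a claim
about method behavior under that generative model, not about patient
biology.

## The synthetic cohort

Counts for gene *g* in cell *c* of population *p* are negative-binomial,

    x_gc ~ NB(mu_gc, theta),    mu_gc = L_c * w_pg / sum_g w_pg,

with a log-normal library size `L_c = L0 * exp(sigma * Z)` (defaults
`L0 = 5000`, `sigma = 0.35`) and dispersion `theta = 0.5`
(`var = mu + mu^2 / theta`), a deliberately noisy regime typical of
shallow droplet data. Relative weights `w_pg` are a shared log-normal
baseline multiplied by `2^FC` for each population's marker genes, so a
marker's planted log2 fold-change is recovered (to within composition
effects) by the empirical log-ratio of population means. Genes in a
population's `silenced` list have their mean forced to exactly zero —
this is how absolute loss/gain-of-expression events are planted
(a finite fold-change can never produce structural zeros).

Mitochondrial pseudo-genes `MT-1 … MT-10` receive, in expectation, a
configurable fraction (default 5%) of each cell's library. Stressed
cells receive a +6 log2 mean shift on the five canonical
stress-response genes (HSPA1A, HSPA1B, HSP90AA1, HSPB1, DNAJB1), which
are present in every generated universe. The stressed subset is an
exact seeded count, `round(fraction * n_cells)` per population, rather
than per-cell Bernoulli draws: a percentile-based filter contract
("2% planted, 98th-percentile cutoff") is only well-posed when the
planted fraction does not wobble binomially around the cutoff mass.

The default study-sized cohort has 76 EC cells (40 serotonergic, 36
non-serotonergic), 30 SI-NET cells, and six background populations
(enterocytes, crypt enterocytes, goblet cells, monocytes, T cells, and
tumor-infiltrating T cells; ~950 cells, 2% stressed) over 1500 genes.
The EC/SI-NET counts are the study's; background sizes are free
parameters chosen for desk-scale runtime (the full pipeline runs in
about 20 s). Subtype identity is carried by two disjoint 20-gene
programs (`SEROSIG*`, `NONSEROSIG*`, FC = 4) plus the canonical marker
panel; the SI-NET program mixes the two EC programs at coefficient
λ (default 0.75, i.e. closer to serotonergic) and adds a 10-gene tumor
program, the eight gain-of-expression (GoE) genes (silenced in both EC
subtypes), and silences the eight loss-of-expression (LoE) genes.
`mixture_cohort(lam)` exposes λ for parameter-recovery sweeps: the
recovered similarity should increase monotonically in λ, and does.

What the generator does **not** emulate: doublets, ambient RNA, UMI
saturation, cell-cycle structure, realistic gene–gene correlation
beyond the planted programs, and marker-gene specificity (every gene
keeps a shared baseline in every population, so "off" genes are dim,
not absent). Passing tests therefore demonstrate correct algorithmic
behavior and statistical calibration, not robustness to those
artifacts.

## QC and stress filtering

Per cell: detected-feature count, total counts, mitochondrial fraction
(genes with the `MT-` prefix by default, overridable), and a stress
score — the mean log1p counts-per-10k of the five stress genes (a mean
of depth-normalized values, so deep cells are not penalized). Cells are
kept when `200 <= n_features <= 7000` (bounds inclusive; "fewer
than"/"more than" are removed) and `mito_fraction <= 0.40` (strictly
"more than 40%" removed). The stress filter then removes cells whose
score lies strictly above the 98th percentile (linear interpolation
between order statistics) of the distribution computed over cells that
passed the basic filters — computing the cutoff after feature/mito
filtering keeps junk cells from distorting it. Re-applying the filter
against the same base distribution is a no-op; recomputing the
percentile on an already-filtered set would always remove more cells,
which is why the cutoff is defined on the post-basic-QC distribution
rather than iteratively.

## Reduction and clustering

Normalization is `log(1 + 1e4 * count / cell_total)`. Highly variable
genes (default 2000) are ranked by dispersion (variance/mean of
normalized expression) z-scored within 20 equal-frequency bins of mean
expression. Scaling is per-gene z-scoring clipped at ±10; with more
than one declared batch, expression is centered per batch first — a
deliberately simple stand-in for anchor-based integration, adequate for
the small multiplicative batch effects the generator can produce, and
documented as such. PCA (default 30 components) fixes each component's
sign so its largest-magnitude loading is positive. Clustering runs
seeded modularity optimization (Leiden, RB-configuration quality;
resolution 1.0) on a shared-nearest-neighbor graph (k = 15, Jaccard
edge weights, pruned below 1/15). UMAP (seeded) is used only for
visualization and subtype partitioning; degenerate geometries fall back
to a deterministic jitter layout so downstream code always receives
finite coordinates.

## Annotation and subtyping

Clusters are scored by the mean normalized expression of the canonical
EC panel (CHGA, CHGB, SCGN, NEUROD1, SLC18A1, ADGRG4; absent genes
count as zero). Clusters scoring above `1.7 x median cluster score`
and containing at least 5 cells are neuroendocrine; their cells become
EC when drawn from normal mucosa and SI-NET when drawn from tumor
tissue (tumor-origin cells can never be labeled EC). Both thresholds
are calibrations of unstated parameters: under the generator's shared
baseline, background clusters score ~1.2 while the weakest true
neuroendocrine cluster (non-serotonergic EC, which lacks TPH1, SLC18A1
and ADGRG4) scores ~2.2, so a 2x-median cut would lose it while
1.7x separates the two regimes with margin on both sides; the
minimum-size rule exists because graph clustering occasionally emits
single-cell clusters whose panel score is noise, and one stray cell
mislabeled SI-NET breaks every strict-zero detection rule downstream.

The serotonergic/non-serotonergic split is a one-dimensional two-means
cut of the EC cells' embedding coordinates. Candidate directions are
the two raw layout axes plus the layout's own principal axes (clusters
placed diagonally separate on neither raw axis); the direction with the
largest between-group variance fraction wins. If that fraction stays
below 0.8 the population is declared unimodal and left unsplit with a
warning — 0.8 sits above the ratio a two-means cut extracts from
unimodal references (2/π ≈ 0.64 for a Gaussian, 0.75 for a uniform)
and below what separated clusters produce (≥ 0.84 observed). The side
with higher mean TPH1 + SLC18A1 expression is labeled serotonergic;
cut position, separation and per-side marker means are written to an
audit file because the original partition thresholds are not
recoverable from published text.

## The identity axis

Subtype signatures are the genes significantly higher in one EC subtype
(Mann–Whitney, Bonferroni-adjusted p ≤ 0.05, direction by mean
difference), disjoint by construction. Each signature is quantified per
cell as a control-bin module score: genes are placed in 24
equal-frequency bins of genome-wide mean expression, each signature
gene draws up to 100 control genes from its bin (seeded, without
replacement, signature genes excluded from the pool), and the score is
the mean expression of the signature minus the mean of the pooled
controls. The identity-axis value is the serotonergic minus the
non-serotonergic score; positive values mean serotonergic alignment.

Groups (serotonergic EC, non-serotonergic EC, SI-NET) are summarized by
mean/median/sd and pairwise Cohen's d (pooled sd, df-weighted). The
bootstrap (default 1000 iterations) resamples every group with
replacement to the smallest group's size ("equal group sizes"; a fixed
common size is config-selectable) and records group means; confidence
intervals are 2.5/97.5 percentiles. Similarity of the tumor group to
the two EC subtypes is the complementary-distance normalization

    sim_to_sero = d_nonsero / (d_sero + d_nonsero),

which sums to 1 with its counterpart by construction and reproduces the
published pair (0.67/0.33) exactly from the published distances
(0.87/1.75). It is computed per bootstrap iteration and summarized
(primary), and also once on the bootstrap-mean triple (reported
alongside); the two agree to ~0.001 in practice.

## Differential expression and reciprocal calls

`mw_test` uses the exact null distribution of the rank-sum U statistic
(dynamic program, cached per sample-size pair; two-sided p is the
symmetric tail probability, capped at 1) when the combined sample is
≤ 16 with no ties, and the normal approximation with tie and continuity
corrections otherwise; the two modes differ by < 0.011 at n = 8 per
side. `run_deg` skips genes with zero expression in both groups and
excludes them from the Bonferroni denominator; direction and the
reported log fold-change are differences of group mean log-normalized
expression. Cross-dataset overlap keeps genes significant in both
tables with consistent direction.

A significant gene is called LoE when undetected in SI-NET cells
(detection fraction ≤ 0, strict zero by default, tolerance
configurable) and expressed in serotonergic ECs (detection ≥ 10%, a
floor against single-cell dropout), GoE in the reverse case; genes in
neither regime are dropped but remain auditable in the DE table. Calls
are verified against a local gene → enteroendocrine-expressed table
(true/false/unknown); unknown genes are kept with `verified = false`
and reason "missing reference".

## Numerical and reproducibility choices

Every randomized operation takes an explicit seed; the pipeline is a
pure function of (matrix, config, seed) and reruns are byte-identical
at the TSV level. Stages communicate through files under a run
directory and a manifest records the resolved config, per-stage output
hashes, timings and warnings. Percentiles use linear interpolation;
HVG ties break by gene order; PCA signs follow the largest-loading
convention; zero-total cells are a hard error at normalization.

Problem sizes used by the test and acceptance runs — ~1000–2000 cells,
500–2000 genes, 100 null replicates, 1000 bootstrap iterations — are
the package's defaults for a laptop-scale study of this design.

## Known limitations

Anchor-based integration is not implemented (per-batch centering is a
documented simplification); copy-number inference, network/enrichment
analysis, and live reference-database queries are out of scope. The
published gene counts (767/1921/370-gene overlaps and related tallies)
derive from controlled-access cohorts and are not reproducible here;
what the package reproduces is the arithmetic of the published group
summaries and the behavior of each method on cohorts with known truth.
The subtype cut assumes at most two EC subtypes and a roughly linear
separation in the embedding; more complex EC heterogeneity would
require a different partitioning rule.
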