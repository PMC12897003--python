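"""The transcriptional identity axis and its statistics.

Serotonergic and non-serotonergic signatures are derived from the EC
subtypes by rank-based differential expression; each signature is
quantified per cell as a control-bin module score (mean expression of
the set minus mean expression of expression-matched control genes), and
the per-cell difference of the two scores is the identity-axis value: a
continuum from non-serotonergic to serotonergic transcriptional
identity.  Group summaries come with Cohen's d effect sizes and a
bootstrap (equal group sizes, resampling with replacement) that yields
percentile confidence intervals for group means and for the
complementary-distance similarity of the tumor group to each EC
subtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import run_deg

__all__ = [
    "SignaturePair",
    "AxisSummary",
    "derive_signatures",
    "module_score",
    "axis_values",
    "cohens_d",
    "similarity",
    "bootstrap_axis",
]


@dataclass
class SignaturePair:
    """Two disjoint gene sets driving the identity axis."""

    serotonergic: tuple[str, ...]
    non_serotonergic: tuple[str, ...]

    def __post_init__(self) -> None:
        self.serotonergic = tuple(g.upper() for g in self.serotonergic)
        self.non_serotonergic = tuple(g.upper() for g in self.non_serotonergic)
        if not self.serotonergic or not self.non_serotonergic:
            raise ValueError("both signatures must be non-empty")
        overlap = set(self.serotonergic) & set(self.non_serotonergic)
        if overlap:
            raise ValueError(f"signatures must be disjoint; overlap: {sorted(overlap)}")


def derive_signatures(
    norm: pd.DataFrame,
    subtype_labels: np.ndarray,
    alpha: float = 0.05,
    min_cells: int = 3,
) -> SignaturePair:
    """Signature genes per EC subtype by Mann-Whitney + Bonferroni.

    A gene joins a subtype's signature when its Bonferroni-adjusted
    two-sided p is <= alpha and its mean normalized expression is higher
    in that subtype; a gene can therefore appear on at most one side.
    """
    labels = np.asarray(subtype_labels)
    sero = labels == "serotonergic"
    nonsero = labels == "non-serotonergic"
    if sero.sum() < min_cells or nonsero.sum() < min_cells:
        raise ValueError("each subtype needs at least "
                         f"{min_cells} cells (got {sero.sum()} / {nonsero.sum()})")
    deg = run_deg(norm, sero, nonsero, alpha=alpha, min_cells=min_cells)
    sig = deg[deg["significant"]]
    up_sero = tuple(sig.loc[sig["direction"] == "up", "gene"])
    up_nonsero = tuple(sig.loc[sig["direction"] == "down", "gene"])
    if not up_sero or not up_nonsero:
        raise ValueError(
            "empty signature: no significantly upregulated genes for "
            f"{'serotonergic' if not up_sero else 'non-serotonergic'} subtype"
        )
    return SignaturePair(serotonergic=up_sero, non_serotonergic=up_nonsero)


def module_score(
    norm: pd.DataFrame,
    gene_set: tuple[str, ...],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Control-bin module score per cell.

    Genes are binned into ``n_bins`` equal-frequency bins of genome-wide
    average expression; every set gene contributes up to ``n_ctrl``
    control genes drawn (seeded, without replacement, set genes
    excluded) from its own bin.  The score is the mean expression of the
    set minus the mean expression of the pooled control genes, so a set
    indistinguishable from its bin-mates scores ~0.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    wanted = [g.upper() for g in gene_set]
    present = [g for g in wanted if g in norm.index]
    if not present:
        raise ValueError("no gene of the set present in the matrix")
    rng = np.random.default_rng(seed)
    X = norm.to_numpy()
    genes = list(norm.index)
    avg = X.mean(axis=1)

    # Equal-frequency bins by rank of average expression.
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(genes), dtype=int)
    for b, members in enumerate(np.array_split(order, n_bins)):
        bin_of[members] = b

    gene_pos = {g: i for i, g in enumerate(genes)}
    set_idx = [gene_pos[g] for g in present]
    set_pos = set(set_idx)
    ctrl: set[int] = set()
    for gi in set_idx:
        mates = np.flatnonzero(bin_of == bin_of[gi])
        pool = np.array([m for m in mates if m not in set_pos])
        if pool.size == 0:
            continue
        take = min(n_ctrl, pool.size)
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    set_mean = X[set_idx, :].mean(axis=0)
    if ctrl:
        ctrl_mean = X[sorted(ctrl), :].mean(axis=0)
    else:  # pathological: the set fills its bins entirely
        ctrl_mean = np.zeros(X.shape[1])
    return set_mean - ctrl_mean


def axis_values(score_sero: np.ndarray, score_nonsero: np.ndarray) -> np.ndarray:
    """Identity-axis value per cell: serotonergic minus non-serotonergic score."""
    score_sero = np.asarray(score_sero, dtype=float)
    score_nonsero = np.asarray(score_nonsero, dtype=float)
    if score_sero.shape != score_nonsero.shape:
        raise ValueError("score vectors must cover the same cells")
    return score_sero - score_nonsero


def cohens_d(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """(mean_a - mean_b) / pooled sd, variances weighted by df."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def similarity(
    mean_sero: float, mean_nonsero: float, mean_tumor: float
) -> tuple[float, float]:
    """Complementary-distance similarity of the tumor group mean to the
    two EC subtype means; the pair sums to 1 exactly.

    sim_to_sero = d_nonsero / (d_sero + d_nonsero) and vice versa, where
    d_* are absolute distances between group means on the identity axis.
    """
    d_s = abs(mean_tumor - mean_sero)
    d_n = abs(mean_tumor - mean_nonsero)
    if d_s + d_n == 0:
        raise ValueError("tumor mean coincides with both reference means")
    sim_s = d_n / (d_s + d_n)
    return sim_s, 1.0 - sim_s


def _percentile_ci(samples: np.ndarray, level: float = 95.0) -> tuple[float, float]:
    lo, hi = np.percentile(samples, [(100 - level) / 2, 100 - (100 - level) / 2])
    return float(lo), float(hi)


@dataclass
class AxisSummary:
    """Identity-axis group summaries with bootstrap uncertainty."""

    group_stats: pd.DataFrame          # group, n, mean, median, sd, boot CI
    cohens_d: dict[tuple[str, str], float]
    distances: dict[tuple[str, str], float]
    similarity_observed: tuple[float, float] | None
    similarity_mean: float | None      # iteration-wise mean (primary)
    similarity_sd: float | None
    similarity_ci: tuple[float, float] | None
    similarity_of_boot_means: float | None  # computed once on bootstrapped means
    n_iter: int = 0
    m_resample: int = 0
    boot_means: dict[str, np.ndarray] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out = {
            "n_iter": self.n_iter,
            "m_resample": self.m_resample,
            "group_stats": self.group_stats.to_dict(orient="records"),
            "cohens_d": {f"{a} vs {b}": v for (a, b), v in self.cohens_d.items()},
            "distances": {f"{a} vs {b}": v for (a, b), v in self.distances.items()},
        }
        if self.similarity_observed is not None:
            out["similarity"] = {
                "observed_to_serotonergic": self.similarity_observed[0],
                "observed_to_nonserotonergic": self.similarity_observed[1],
                "mean_to_serotonergic": self.similarity_mean,
                "sd": self.similarity_sd,
                "ci95": list(self.similarity_ci),
                "of_bootstrap_means": self.similarity_of_boot_means,
            }
        return out


def bootstrap_axis(
    axis: np.ndarray,
    group_labels: np.ndarray,
    n_iter: int = 1000,
    seed: int = 0,
    equal_group_size: int = 0,
    ref_groups: tuple[str, str] = ("serotonergic", "non-serotonergic"),
    target_group: str = "SI-NET",
) -> AxisSummary:
    """Bootstrap of identity-axis group means with equal group sizes.

    Every iteration resamples ``m`` cells with replacement from each
    group, where ``m`` is the smallest group's size (or
    ``equal_group_size`` when positive), and records the group means.
    Confidence intervals are 2.5/97.5 percentiles of the bootstrapped
    means.  When both reference groups and the target group are present,
    the complementary-distance similarity is computed per iteration and
    summarized by mean, sd and percentile CI (primary), alongside the
    similarity of the bootstrap-mean triple.
    """
    axis = np.asarray(axis, dtype=float)
    labels = np.asarray(group_labels)
    groups = [g for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    values = {g: axis[labels == g] for g in groups}
    for g, v in values.items():
        if v.size == 0:
            raise ValueError(f"empty group {g!r}")
    m = equal_group_size if equal_group_size > 0 else min(v.size for v in values.values())

    rng = np.random.default_rng(seed)
    boot = {g: np.empty(n_iter) for g in groups}
    for it in range(n_iter):
        for g in groups:
            v = values[g]
            boot[g][it] = v[rng.integers(0, v.size, size=m)].mean()

    rows = []
    for g in groups:
        v = values[g]
        lo, hi = _percentile_ci(boot[g])
        rows.append(
            {
                "group": g,
                "n": int(v.size),
                "mean": float(v.mean()),
                "median": float(np.median(v)),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "boot_mean": float(boot[g].mean()),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    stats = pd.DataFrame(rows)

    d_eff, dist = {}, {}
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            if values[a].size > 1 and values[b].size > 1:
                try:
                    d_eff[(a, b)] = cohens_d(values[a], values[b])
                except ValueError:
                    d_eff[(a, b)] = float("nan")
            dist[(a, b)] = float(abs(values[a].mean() - values[b].mean()))

    sim_obs = sim_mean = sim_sd = sim_ci = sim_of_means = None
    sero, nonsero = ref_groups
    if {sero, nonsero, target_group}.issubset(groups):
        sim_obs = similarity(values[sero].mean(), values[nonsero].mean(),
                             values[target_group].mean())
        per_iter = np.array([
            similarity(boot[sero][i], boot[nonsero][i], boot[target_group][i])[0]
            for i in range(n_iter)
        ])
        sim_mean = float(per_iter.mean())
        sim_sd = float(per_iter.std(ddof=1))
        sim_ci = _percentile_ci(per_iter)
        sim_of_means = similarity(
            boot[sero].mean(), boot[nonsero].mean(), boot[target_group].mean()
        )[0]

    return AxisSummary(
        group_stats=stats,
        cohens_d=d_eff,
        distances=dist,
        similarity_observed=sim_obs,
        similarity_mean=sim_mean,
        similarity_sd=sim_sd,
        similarity_ci=sim_ci,
        similarity_of_boot_means=sim_of_means,
        n_iter=n_iter,
        m_resample=int(m),
        boot_means=boot,
    )
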