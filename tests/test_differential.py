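"""Mann-Whitney testing, Bonferroni control, cross-dataset overlap."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecorigin as eo
from ecorigin.differential import run_deg
from ecorigin.synthetic import PopulationSpec, generate_cohort


def enumeration_p(values_a, values_b):
    """Brute-force two-sided p: enumerate every assignment of the pooled
    ranks to group A and count arrangements at least as extreme in
    |U - nm/2|.  Independent of the implementation's DP."""
    a, b = list(values_a), list(values_b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n, m = len(a), len(b)
    u_obs = sum(rank[v] for v in a) - n * (n + 1) / 2
    center = n * m / 2
    extreme = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        u = sum(combo) - n * (n + 1) / 2
        if abs(u - center) >= abs(u_obs - center) - 1e-9:
            extreme += 1
    return extreme / comb(n + m, n)


class TestMwTest:
    def test_separated_groups_exact_example(self):
        u, p = eo.mw_test([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        _, p = eo.mw_test([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert p == 1.0

    def test_all_values_identical_convention(self):
        u, p = eo.mw_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0 and u == 3.0

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            eo.mw_test([], [1.0])

    @pytest.mark.parametrize("n_a,n_b", [(2, 3), (4, 4), (3, 5)])
    def test_exact_mode_matches_enumeration(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(20):
            a = rng.normal(size=n_a)
            b = rng.normal(size=n_b)
            _, p = eo.mw_test(a, b)
            assert p == pytest.approx(enumeration_p(a, b), abs=1e-12)

    def test_exact_and_asymptotic_agree_at_n8(self):
        """|p_exact - p_asymptotic| < 0.02 over every achievable U at
        n_a = n_b = 8 (tie-free p depends on U only)."""
        from scipy.stats import mannwhitneyu

        from ecorigin.differential import _exact_p

        n = 8
        reps = {}
        for combo in itertools.combinations(range(1, 2 * n + 1), n):
            u = sum(combo) - n * (n + 1) // 2
            reps.setdefault(u, combo)
        assert len(reps) == n * n + 1
        for u, combo in reps.items():
            a = [float(r) for r in combo]
            b = [float(r) for r in range(1, 2 * n + 1) if r not in combo]
            p_asym = mannwhitneyu(a, b, method="asymptotic",
                                  use_continuity=True).pvalue
            assert abs(_exact_p(u, n, n) - p_asym) < 0.02

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_group_swap_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 12, 2)
        a, b = rng.normal(size=n_a), rng.normal(size=n_b)
        u_ab, p_ab = eo.mw_test(a, b)
        u_ba, p_ba = eo.mw_test(b, a)
        assert u_ba == pytest.approx(n_a * n_b - u_ab)
        assert p_ba == pytest.approx(p_ab)


def _norm_frame(X):
    return pd.DataFrame(X, index=[f"G{i}" for i in range(X.shape[0])],
                        columns=[f"C{j}" for j in range(X.shape[1])])


class TestRunDeg:
    @pytest.fixture(scope="class")
    def planted(self):
        prog = {f"DE{i:02d}": 4.0 for i in range(20)}
        cm, truth = generate_cohort(
            [PopulationSpec("hi", 50, markers=prog), PopulationSpec("lo", 50)],
            n_genes=500, seed=21,
        )
        norm = eo.normalize_log1p_cp10k(cm)
        mask = (truth["population"] == "hi").to_numpy()
        return norm, mask, list(prog)

    def test_planted_genes_flagged(self, planted):
        """FC=4 planted genes recovered at the power the cohort's
        negative-binomial noise supports (>=90% of 20 genes)."""
        norm, mask, genes = planted
        deg = run_deg(norm, mask, ~mask)
        flagged = set(deg.loc[deg["significant"], "gene"])
        assert sum(g in flagged for g in genes) >= 0.9 * len(genes)

    def test_false_positive_rate_among_nulls(self, planted):
        norm, mask, genes = planted
        deg = run_deg(norm, mask, ~mask)
        nulls = deg[~deg["gene"].isin(genes)]
        assert (nulls["significant"].mean()) <= 0.05

    def test_direction_follows_mean_difference(self, planted):
        norm, mask, genes = planted
        deg = run_deg(norm, mask, ~mask).set_index("gene")
        assert (deg.loc[genes, "direction"] == "up").all()
        up = deg["direction"] == "up"
        assert (deg.loc[up, "lfc"] >= 0).all()
        assert (deg.loc[~up, "lfc"] < 0).all()

    def test_bonferroni_arithmetic(self, planted):
        norm, mask, _ = planted
        deg = run_deg(norm, mask, ~mask)
        n_tested = len(deg)
        assert np.allclose(deg["p_adj"], np.minimum(1.0, deg["p"] * n_tested))
        # raw p of 1e-4 under 1000 tests would not survive: p_adj = 0.1
        assert min(1.0, 1e-4 * 1000) == pytest.approx(0.1)

    def test_all_zero_genes_excluded_from_table_and_denominator(self):
        X = np.zeros((4, 10))
        X[0] = np.concatenate([np.ones(5) * 3, np.zeros(5)])
        X[1] = 1.0
        norm = _norm_frame(X)
        mask = np.array([True] * 5 + [False] * 5)
        deg = run_deg(norm, mask, ~mask)
        assert set(deg["gene"]) == {"G0", "G1"}

    def test_too_small_group_is_error(self):
        norm = _norm_frame(np.ones((3, 6)))
        mask = np.array([True, True, False, False, False, False])
        with pytest.raises(ValueError, match="too small"):
            run_deg(norm, mask, ~mask)

    def test_small_sample_path_agrees_with_scalar_mw(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(2.0, size=(10, 10)).astype(float)
        norm = _norm_frame(X)
        mask = np.array([True] * 5 + [False] * 5)
        deg = run_deg(norm, mask, ~mask).set_index("gene")
        for g in deg.index:
            u, p = eo.mw_test(X[int(g[1:]), :5], X[int(g[1:]), 5:])
            assert deg.loc[g, "U"] == pytest.approx(u)
            assert deg.loc[g, "p"] == pytest.approx(p)


class TestOverlapDeg:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "p_adj", "direction", "significant"])

    def test_disjoint_significant_sets_empty_overlap(self):
        d = self._table([("A", 0.01, "up", True), ("B", 0.5, "up", False)])
        v = self._table([("B", 0.01, "up", True), ("A", 0.9, "up", False)])
        assert len(eo.overlap_deg(d, v)) == 0

    def test_direction_mismatch_excluded(self):
        d = self._table([("A", 0.01, "up", True)])
        v = self._table([("A", 0.01, "down", True)])
        assert len(eo.overlap_deg(d, v, require_direction=True)) == 0
        relaxed = eo.overlap_deg(d, v, require_direction=False)
        assert len(relaxed) == 1 and not relaxed["direction_consistent"].iloc[0]

    def test_symmetric_as_gene_sets(self):
        d = self._table([("A", 0.01, "up", True), ("B", 0.02, "down", True)])
        v = self._table([("B", 0.03, "down", True), ("C", 0.01, "up", True)])
        ab = set(eo.overlap_deg(d, v)["gene"])
        ba = set(eo.overlap_deg(v, d)["gene"])
        assert ab == ba == {"B"}

    def test_two_cohorts_from_same_spec_overlap_recovers_planted(self):
        prog = {f"DE{i:02d}": 4.0 for i in range(20)}
        specs = [PopulationSpec("hi", 50, markers=prog), PopulationSpec("lo", 50)]
        tables = []
        for seed in (31, 32):
            cm, truth = generate_cohort(specs, n_genes=500, seed=seed)
            norm = eo.normalize_log1p_cp10k(cm)
            mask = (truth["population"] == "hi").to_numpy()
            tables.append(run_deg(norm, mask, ~mask))
        overlap = eo.overlap_deg(*tables)
        recovered = sum(g in set(overlap["gene"]) for g in prog)
        assert recovered >= 0.8 * len(prog)
        assert overlap.attrs["n_up"] + overlap.attrs["n_down"] == len(overlap)


def test_familywise_error_controlled_under_null():
    """No planted effects: Bonferroni keeps the familywise error at or
    below alpha (small replicate count here; the full-scale null study
    lives in the acceptance suite)."""
    hits = 0
    reps = 20
    for r in range(reps):
        cm, _ = generate_cohort([PopulationSpec("x", 60)], n_genes=800, seed=300 + r)
        norm = eo.normalize_log1p_cp10k(cm)
        mask = np.zeros(60, dtype=bool)
        mask[:30] = True
        deg = run_deg(norm, mask, ~mask)
        hits += int(deg["significant"].any())
    assert hits / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)
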