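"""Identity-axis statistics: signatures, module scores, effect sizes,
similarity, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecorigin as eo
from ecorigin.axis import SignaturePair, module_score
from ecorigin.synthetic import NONSERO_SIGNATURE_GENES, SERO_SIGNATURE_GENES


class TestCohensD:
    def test_hand_computed_example(self):
        # pooled sd = sqrt(2) -> d = -1/sqrt(2)
        assert eo.cohens_d([0, 2], [1, 3]) == pytest.approx(-1 / np.sqrt(2))

    def test_identical_distributions_give_zero(self):
        assert eo.cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(0.0)

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=30), rng.normal(1, 1, size=25)
        assert eo.cohens_d(a + 7, b + 7) == pytest.approx(eo.cohens_d(a, b))

    def test_zero_pooled_sd_is_error(self):
        with pytest.raises(ValueError, match="pooled"):
            eo.cohens_d([1.0, 1.0], [2.0, 2.0])

    def test_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=40), rng.normal(0.8, 1.3, size=35)
        assert eo.cohens_d(a, b) == pytest.approx(
            pingouin.compute_effsize(a, b, eftype="cohen"))


class TestSimilarity:
    def test_tumor_at_serotonergic_mean(self):
        assert eo.similarity(2.0, -1.0, 2.0) == (1.0, 0.0)

    def test_tumor_midway(self):
        assert eo.similarity(2.0, 0.0, 1.0) == (0.5, 0.5)

    def test_printed_group_means_reproduce_printed_similarity(self):
        """Group means 1.98 / -0.64 / 1.11 give distances 0.87 and 1.75,
        hence similarity 0.67 / 0.33."""
        sim_s, sim_n = eo.similarity(1.98, -0.64, 1.11)
        assert abs(1.11 - 1.98) == pytest.approx(0.87)
        assert abs(1.11 - (-0.64)) == pytest.approx(1.75)
        assert round(sim_s, 2) == 0.67
        assert round(sim_n, 2) == 0.33

    def test_coincident_reference_means_error(self):
        with pytest.raises(ValueError):
            eo.similarity(1.0, 1.0, 1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50)))
    def test_pair_sums_to_one(self, means):
        ms, mn, mt = means
        if abs(mt - ms) + abs(mt - mn) == 0:
            return
        s, n = eo.similarity(ms, mn, mt)
        assert s + n == 1.0
        assert 0 <= s <= 1


class TestAxisValues:
    def test_arithmetic(self):
        assert eo.axis_values([2.5], [0.5])[0] == pytest.approx(2.0)
        assert eo.axis_values([1.0], [1.0])[0] == 0.0

    def test_antisymmetric_under_signature_swap(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert np.allclose(eo.axis_values(a, b), -eo.axis_values(b, a))

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="same cells"):
            eo.axis_values([1.0, 2.0], [1.0])


class TestModuleScore:
    def _iid_matrix(self, n_genes=300, n_cells=40, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(1.0, 0.2, size=(n_genes, n_cells)).clip(0)
        return pd.DataFrame(X, index=[f"G{i}" for i in range(n_genes)],
                            columns=[f"C{j}" for j in range(n_cells)])

    def test_self_cancellation(self):
        """A set indistinguishable from its bin-mates scores ~0."""
        norm = self._iid_matrix()
        s = module_score(norm, tuple(f"G{i}" for i in range(30)), seed=1)
        assert np.abs(s).max() < 0.2

    def test_additivity(self):
        """Adding c to the set genes in one cell raises its score by ~c."""
        norm = self._iid_matrix()
        gene_set = tuple(f"G{i}" for i in range(30))
        base = module_score(norm, gene_set, seed=1)
        shifted = norm.copy()
        shifted.loc[list(gene_set), "C5"] += 2.0
        bumped = module_score(shifted, gene_set, seed=1)
        assert bumped[5] - base[5] == pytest.approx(2.0, abs=0.15)

    def test_empty_set_after_matching_is_error(self):
        with pytest.raises(ValueError, match="no gene"):
            module_score(self._iid_matrix(), ("NOPE",), seed=0)

    def test_seeded_and_pure(self):
        norm = self._iid_matrix()
        gene_set = tuple(f"G{i}" for i in range(10))
        assert np.array_equal(module_score(norm, gene_set, seed=3),
                              module_score(norm, gene_set, seed=3))

    def test_seed_perturbation_below_signal(self, ec_subtypes):
        """Control resampling noise stays below the signature signal."""
        norm = ec_subtypes["norm"]
        sig = ec_subtypes["signatures"].serotonergic
        ann = ec_subtypes["ann"]
        s1 = module_score(norm, sig, n_ctrl=25, seed=1)
        s2 = module_score(norm, sig, n_ctrl=25, seed=99)
        sero = ((ann["class_label"] == "EC") & (ann["subtype"] == "serotonergic")).to_numpy()
        nonsero = ((ann["class_label"] == "EC") & (ann["subtype"] == "non-serotonergic")).to_numpy()
        signal = s1[sero].mean() - s1[nonsero].mean()
        assert np.abs(s1 - s2).max() < signal

    def test_signature_score_separates_subtypes(self, ec_subtypes):
        from sklearn.metrics import roc_auc_score

        norm = ec_subtypes["norm"]
        ann = ec_subtypes["ann"]
        ec = ec_subtypes["ec_mask"]
        s = module_score(norm, ec_subtypes["signatures"].serotonergic, seed=1)
        y = ann.loc[ec, "subtype"].to_numpy() == "serotonergic"
        assert roc_auc_score(y, s[ec]) > 0.95

    def test_tracks_standard_control_bin_scoring(self, ec_subtypes):
        """Independent implementation of expression-bin control scoring
        (scanpy) agrees up to control-sampling noise."""
        sc = pytest.importorskip("scanpy")
        import anndata as ad

        norm = ec_subtypes["norm"]
        sig = list(ec_subtypes["signatures"].serotonergic)
        ours = module_score(norm, tuple(sig), seed=1)
        A = ad.AnnData(norm.to_numpy().T.copy())
        A.var_names = list(norm.index)
        sc.tl.score_genes(A, sig, ctrl_size=100, n_bins=24, score_name="ref",
                          random_state=0)
        assert np.corrcoef(ours, A.obs["ref"].to_numpy())[0, 1] > 0.95


class TestDeriveSignatures:
    def test_recovers_planted_program_genes(self, ec_subtypes):
        sig = ec_subtypes["signatures"]
        rec_sero = sum(g in sig.serotonergic for g in SERO_SIGNATURE_GENES)
        rec_non = sum(g in sig.non_serotonergic for g in NONSERO_SIGNATURE_GENES)
        assert rec_sero >= 0.8 * len(SERO_SIGNATURE_GENES)
        assert rec_non >= 0.8 * len(NONSERO_SIGNATURE_GENES)

    def test_direction_rule_keeps_sides_disjoint(self, ec_subtypes):
        sig = ec_subtypes["signatures"]
        assert not set(sig.serotonergic) & set(sig.non_serotonergic)
        for g in SERO_SIGNATURE_GENES:
            assert g not in sig.non_serotonergic

    def test_identical_expression_yields_error(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(2.0, size=(50, 30)).astype(float)
        norm = pd.DataFrame(X, index=[f"G{i}" for i in range(50)],
                            columns=[f"C{j}" for j in range(30)])
        labels = np.array(["serotonergic"] * 15 + ["non-serotonergic"] * 15)
        with pytest.raises(ValueError, match="empty signature"):
            eo.derive_signatures(norm, labels)

    def test_too_few_cells_is_error(self):
        norm = pd.DataFrame(np.ones((5, 4)), index=[f"G{i}" for i in range(5)],
                            columns=list("abcd"))
        labels = np.array(["serotonergic"] * 2 + ["non-serotonergic"] * 2)
        with pytest.raises(ValueError, match="at least"):
            eo.derive_signatures(norm, labels)

    def test_signature_pair_rejects_overlap(self):
        with pytest.raises(ValueError, match="disjoint"):
            SignaturePair(("A", "B"), ("B", "C"))


class TestBootstrapAxis:
    def _grouped_axis(self, seed=0):
        """Axis values drawn at the published group summaries."""
        rng = np.random.default_rng(seed)
        vals = np.concatenate([
            rng.normal(1.98, 0.19, 40),
            rng.normal(-0.64, 0.55, 36),
            rng.normal(1.11, 0.35, 30),
        ])
        labels = np.array(["serotonergic"] * 40 + ["non-serotonergic"] * 36
                          + ["SI-NET"] * 30)
        return vals, labels

    def test_bootstrap_mean_consistent_with_observed(self):
        vals, labels = self._grouped_axis()
        out = eo.bootstrap_axis(vals, labels, n_iter=500, seed=1)
        for _, row in out.group_stats.iterrows():
            # MC error of the bootstrap mean ~ sd / sqrt(m * n_iter)
            tol = 4 * row["sd"] / np.sqrt(out.m_resample * 500)
            assert abs(row["boot_mean"] - row["mean"]) < tol
            assert row["ci_low"] <= row["mean"] <= row["ci_high"]

    def test_same_seed_identical_summary(self):
        vals, labels = self._grouped_axis()
        a = eo.bootstrap_axis(vals, labels, n_iter=200, seed=4)
        b = eo.bootstrap_axis(vals, labels, n_iter=200, seed=4)
        assert a.group_stats.equals(b.group_stats)
        assert a.similarity_mean == b.similarity_mean

    def test_ci_width_shrinks_with_resample_size(self):
        """CI widths at m=300 are narrower than at m=30 for groups drawn
        at the published serotonergic / non-serotonergic summaries."""
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(1.98, 0.19, 400),
                               rng.normal(-0.64, 0.55, 400)])
        labels = np.array(["serotonergic"] * 400 + ["non-serotonergic"] * 400)
        w30 = eo.bootstrap_axis(vals, labels, n_iter=400, seed=6,
                                equal_group_size=30)
        w300 = eo.bootstrap_axis(vals, labels, n_iter=400, seed=6,
                                 equal_group_size=300)
        for g in ("serotonergic", "non-serotonergic"):
            r30 = w30.group_stats.set_index("group").loc[g]
            r300 = w300.group_stats.set_index("group").loc[g]
            assert (r300["ci_high"] - r300["ci_low"]) < (r30["ci_high"] - r30["ci_low"])

    def test_equal_group_sizes_default_to_smallest(self):
        vals, labels = self._grouped_axis()
        out = eo.bootstrap_axis(vals, labels, n_iter=50, seed=0)
        assert out.m_resample == 30

    def test_similarity_pair_sums_to_one_every_iteration(self):
        vals, labels = self._grouped_axis()
        out = eo.bootstrap_axis(vals, labels, n_iter=100, seed=2)
        assert out.similarity_mean is not None
        assert 0 <= out.similarity_mean <= 1
        lo, hi = out.similarity_ci
        assert lo <= out.similarity_mean <= hi

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="2 groups"):
            eo.bootstrap_axis(np.ones(5), np.array(["a"] * 5), n_iter=10, seed=0)


def test_fixture_axis_group_ordering(ec_subtypes):
    """Serotonergic > SI-NET > non-serotonergic group means, mirroring
    the published ordering of the identity axis."""
    norm = ec_subtypes["norm"]
    ann = ec_subtypes["ann"]
    sig = ec_subtypes["signatures"]
    keep = ann["class_label"].isin(["EC", "SI-NET"]).to_numpy()
    sub = norm.loc[:, keep]
    ax = eo.axis_values(eo.module_score(sub, sig.serotonergic, seed=1),
                        eo.module_score(sub, sig.non_serotonergic, seed=2))
    groups = np.where((ann["class_label"] == "EC").to_numpy()[keep],
                      ann["subtype"].to_numpy()[keep], "SI-NET")
    m = {g: ax[groups == g].mean() for g in np.unique(groups)}
    assert m["serotonergic"] > m["SI-NET"] > m["non-serotonergic"]
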