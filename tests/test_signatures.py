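import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panomix.preprocess import concatenate_blocks
from panomix.signatures import (GeneScoreTable, anova_by_cluster,
                                define_signatures, dunn_test, gene_scores,
                                logrank_by_cluster, overrepresentation_test,
                                phenotype_association, signature_funnel,
                                tukey_pairwise)
from panomix.ssvd import SSVDResult

from conftest import make_block


def extended(rng, n=10, p=4, gene_ids=None):
    return concatenate_blocks([make_block(rng.standard_normal((n, p)),
                                          gene_ids=gene_ids)])


class TestGeneScores:
    def test_single_feature_unit_loading_is_column(self, rng):
        X = extended(rng)
        W = np.zeros((1, 4)); W[0, 2] = 1.0
        res = SSVDResult(np.ones((10, 1)) / np.sqrt(10), W, np.array([1.0]),
                         np.zeros(1), 0.5)
        table = gene_scores(X, res)
        np.testing.assert_allclose(table.scores["g00002"], X.values[:, 2])

    def test_two_features_match_matrix_product(self, rng):
        X = extended(rng, gene_ids=["gA", "gA", "gB", "gB"])
        W = np.array([[0.6, -0.8, 0.0, 0.0]])
        res = SSVDResult(np.ones((10, 1)) / np.sqrt(10), W, np.array([2.0]),
                         np.zeros(1), 0.5)
        table = gene_scores(X, res)
        expected = X.values[:, :2] @ (2.0 * W[0, :2])
        np.testing.assert_allclose(table.scores["gA"], expected, atol=1e-12)
        assert "gB" not in table.scores.columns      # all loadings zero

    def test_unweighted_route(self, rng):
        X = extended(rng)
        W = np.zeros((1, 4)); W[0, 1] = 0.5
        res = SSVDResult(np.ones((10, 1)), W, np.array([3.0]), np.zeros(1), 0.5)
        t = gene_scores(X, res, weighted=False)
        np.testing.assert_allclose(t.scores["g00001"], 0.5 * X.values[:, 1])

    def test_two_route_consistency_on_exact_factorization(self, rng):
        """X built exactly as Z diag(d) W: summing d_k Z[:,k] W[k, F_g]
        reproduces the column-combination score to numerical precision."""
        n, p, K = 15, 8, 2
        Z = np.linalg.qr(rng.standard_normal((n, K)))[0]
        W = np.zeros((K, p))
        W[0, [0, 1, 4]] = [0.7, -0.2, 0.5]
        W[1, [1, 6]] = [0.9, 0.3]
        d = np.array([4.0, 2.0])
        gene_ids = ["gA", "gA", "gB", "gB", "gA", "gC", "gC", "gC"]
        block = make_block(Z @ np.diag(d) @ W, gene_ids=gene_ids)
        X = concatenate_blocks([block])
        res = SSVDResult(Z, W, d, np.zeros(K), 0.5)
        table = gene_scores(X, res)
        genes = np.asarray(gene_ids)
        combo = (d[:, None] * W).sum(axis=0)
        for g in table.scores.columns:
            Fg = np.flatnonzero((genes == g) & res.feature_support)
            route_b = sum(d[k] * Z[:, k] * (W[k, Fg] @ combo[Fg])
                          for k in range(K))
            np.testing.assert_allclose(table.scores[g], route_b, atol=1e-10)

    def test_class_scores_over_gene_sets(self, rng):
        X = extended(rng, gene_ids=["gA", "gA", "gB", "gC"])
        W = np.array([[1.0, 0.5, -0.5, 0.0]])
        res = SSVDResult(np.ones((10, 1)), W, np.array([1.0]), np.zeros(1), 0.5)
        t = gene_scores(X, res, gene_sets={"setAB": ["gA", "gB"]})
        expected = X.values[:, :3] @ W[0, :3]
        np.testing.assert_allclose(t.class_scores["setAB"], expected)


def planted_table(rng, n_per=40, k=3, n_genes=20, shift=1.5, planted=None):
    """Score table with optional (gene index -> cluster) mean shifts."""
    n = n_per * k
    labels = np.repeat(np.arange(k), n_per)
    scores = rng.standard_normal((n, n_genes))
    for g, c in (planted or {}).items():
        scores[labels == c, g] += shift
    cols = [f"g{j:03d}" for j in range(n_genes)]
    return GeneScoreTable(pd.DataFrame(scores, columns=cols)), labels, cols


class TestAnova:
    def test_single_gene_threshold_is_alpha(self, rng):
        table, labels, _ = planted_table(rng, n_genes=1)
        out = anova_by_cluster(table, labels)
        assert out.attrs["threshold"] == pytest.approx(0.05)

    def test_planted_shift_detected(self, rng):
        table, labels, cols = planted_table(rng, planted={0: 1})
        out = anova_by_cluster(table, labels)
        assert out.set_index("gene").loc[cols[0], "significant"]

    def test_null_familywise_control(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(200):
            table, labels, _ = planted_table(rng, n_per=15, n_genes=20)
            out = anova_by_cluster(table, labels)
            hits += out["significant"].any()
        assert hits / 200 <= 0.05 + 0.03

    def test_noise_samples_excluded(self, rng):
        table, labels, _ = planted_table(rng, planted={0: 1})
        labels = labels.copy(); labels[:5] = -1
        out = anova_by_cluster(table, labels)
        assert len(out) == 20


class TestTukey:
    def test_two_groups_reduce_to_t_test(self, rng):
        table, labels, cols = planted_table(rng, k=2, n_genes=1,
                                            planted={0: 0})
        pairs = tukey_pairwise(table, labels, [cols[0]])
        x = table.scores[cols[0]].to_numpy()
        _, p_t = stats.ttest_ind(x[labels == 0], x[labels == 1])
        assert pairs["p_adj"].iloc[0] == pytest.approx(p_t, abs=2e-3)

    def test_planted_exclusive_gene_direction(self, rng):
        table, labels, cols = planted_table(rng, planted={2: 1})
        pairs = tukey_pairwise(table, labels, [cols[2]])
        inv = pairs[(pairs.cluster_a == 1) | (pairs.cluster_b == 1)]
        other = pairs[(pairs.cluster_a != 1) & (pairs.cluster_b != 1)]
        assert inv["reject"].all() and not other["reject"].any()
        signs = np.where(inv["cluster_b"] == 1, 1, -1) * np.sign(inv["diff"])
        assert (signs > 0).all()


def pairwise_row(gene, a, b, diff, reject):
    return dict(gene=gene, cluster_a=a, cluster_b=b, diff=diff,
                p_adj=0.001 if reject else 0.5, reject=reject)


class TestDefineSignatures:
    def test_exclusive_up_gene(self):
        pairs = pd.DataFrame([
            pairwise_row("g1", 0, 1, -1.0, True),   # 1 - 0 ... g1 high in 0
            pairwise_row("g1", 0, 2, -1.2, True),
            pairwise_row("g1", 1, 2, -0.1, False),
        ])
        sigs = define_signatures(pairs)
        assert sigs.signatures == {0: [("g1", "up")]}

    def test_partial_separation_excluded(self):
        pairs = pd.DataFrame([
            pairwise_row("g1", 0, 1, -1.0, True),
            pairwise_row("g1", 0, 2, -1.0, False),   # only 1 of 2 pairs
            pairwise_row("g1", 1, 2, 0.1, False),
        ])
        assert define_signatures(pairs).signatures == {}

    def test_double_qualification_excluded(self):
        # monotone gene: low in 0, high in 2 -> qualifies for both, dropped
        pairs = pd.DataFrame([
            pairwise_row("g1", 0, 1, 1.0, True),
            pairwise_row("g1", 0, 2, 2.0, True),
            pairwise_row("g1", 1, 2, 1.0, True),
        ])
        assert define_signatures(pairs).signatures == {}

    def test_signatures_always_disjoint(self, rng):
        rows = []
        for g in range(30):
            for a, b in [(0, 1), (0, 2), (1, 2)]:
                rows.append(pairwise_row(f"g{g}", a, b,
                                         float(rng.standard_normal()),
                                         bool(rng.random() < 0.6)))
        sigs = define_signatures(pd.DataFrame(rows))
        seen = set()
        for genes in sigs.signatures.values():
            ids = {g for g, _ in genes}
            assert not ids & seen
            seen |= ids


class TestFunnel:
    def test_planted_recovery_with_clean_null_genes(self, rng):
        table, labels, cols = planted_table(rng, planted={0: 0, 1: 1, 2: 2})
        anova, pairs, sigs = signature_funnel(table, labels)
        called = {(c, g) for c, gl in sigs.signatures.items() for g, _ in gl}
        assert called == {(0, cols[0]), (1, cols[1]), (2, cols[2])}

    def test_empty_when_no_gene_significant(self, rng):
        table, labels, _ = planted_table(rng, n_per=10, n_genes=5)
        anova, pairs, sigs = signature_funnel(table, labels)
        assert sigs.all_genes() == set() or len(sigs.all_genes()) == 0


class TestPhenotypes:
    def test_planted_covariate_flagged_and_dunn_separates(self, rng):
        labels = np.repeat([0, 1, 2], 40)
        cov = pd.DataFrame({"x": rng.standard_normal(120) + 2.0 * (labels == 2)})
        res = phenotype_association(cov, labels)
        assert res.omnibus.loc[0, "significant"]
        dunn = res.pairwise["x"]
        inv = dunn[(dunn.group_a == 2) | (dunn.group_b == 2)]
        assert (inv["p_adj"] < 0.05).all()

    def test_null_covariate_rarely_significant(self):
        rng = np.random.default_rng(13)
        labels = np.repeat([0, 1, 2], 30)
        hits = sum(
            phenotype_association(
                pd.DataFrame({"x": rng.standard_normal(90)}), labels
            ).omnibus.loc[0, "significant"]
            for _ in range(100))
        assert hits <= 6            # >= 94% non-significant at 0.05

    def test_constant_covariate_skipped_with_warning(self, rng):
        labels = np.repeat([0, 1], 20)
        cov = pd.DataFrame({"c": np.ones(40), "x": rng.standard_normal(40)})
        with pytest.warns(UserWarning, match="constant"):
            res = phenotype_association(cov, labels)
        assert list(res.omnibus["covariate"]) == ["x"]

    def test_categorical_uses_chi_square(self, rng):
        labels = np.repeat([0, 1], 30)
        cov = pd.DataFrame({"cat": rng.choice(list("xy"), 60)})
        res = phenotype_association(cov, labels)
        assert res.omnibus.loc[0, "test"] == "chi2"

    def test_dunn_tie_corrected_z_finite(self, rng):
        v = np.round(rng.standard_normal(60), 1)     # many ties
        labels = np.repeat([0, 1, 2], 20)
        out = dunn_test(v, labels)
        assert np.isfinite(out["z"]).all() and len(out) == 3


class TestLogrank:
    def test_single_cluster_rejected(self, rng):
        t = rng.exponential(5, 20)
        with pytest.raises(ValueError, match="two clusters"):
            logrank_by_cluster(t, np.ones(20, int), np.zeros(20, int))

    def test_zero_event_cluster_median_not_reached(self, rng):
        t = rng.exponential(5, 40) + 0.01
        status = np.concatenate([np.ones(20, int), np.zeros(20, int)])
        labels = np.repeat([0, 1], 20)
        out = logrank_by_cluster(t, status, labels)
        assert np.isnan(out.set_index("cluster").loc[1, "median_survival"])
        assert 0 <= out.attrs["p"] <= 1

    def test_power_under_strong_hazard_ratio(self):
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(25):
            labels = np.repeat([0, 1, 2], 50)
            scale = np.where(labels == 0, 5.0 / 3, 5.0)
            t = rng.exponential(scale)
            c = rng.exponential(10.0, 150)
            out = logrank_by_cluster(np.minimum(t, c) + 1e-9,
                                     (t <= c).astype(int), labels)
            hits += out.attrs["p"] < 0.05
        assert hits / 25 >= 0.8


class TestOverrepresentation:
    def test_fully_hit_set_has_minimal_p(self):
        universe = [f"g{i}" for i in range(40)]
        sets = {"A": universe[:10], "B": universe[10:20]}
        out = overrepresentation_test(universe[:10], universe, sets)
        out = out.set_index("set")
        assert out.loc["A", "p"] < out.loc["B", "p"]
        assert out.loc["A", "p"] < 1e-6

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(20)]
        out = overrepresentation_test(universe[:5], universe,
                                      {"B": universe[10:15]})
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation_test(["g1"], [], {"A": ["g1"]})

    def test_list_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation_test(["zz"], ["g1"], {"A": ["g1"]})
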