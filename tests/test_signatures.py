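import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crcith.io import ExpressionMatrix, GeneSet
from crcith.signatures import (
    EnrichmentResult,
    _cosine_distance,
    _ranksum_z,
    call_heterogeneity,
    classify_ntp,
    derive_templates,
    geneset_comparison,
    marker_score,
    moderated_ttest,
    permutation_pvalue,
    rank_score,
)


def random_expr(rng, n_genes, n_samples, loc=5.0):
    vals = rng.normal(loc, 1.0, size=(n_genes, n_samples))
    return ExpressionMatrix(
        tuple(f"g{i}" for i in range(n_genes)),
        tuple(f"s{j}" for j in range(n_samples)),
        vals,
    )


class TestModeratedTtest:
    def test_equal_means_give_zero_lfc_large_p(self):
        rng = np.random.default_rng(0)
        vals = np.tile(rng.normal(5, 1, size=(50, 1)), (1, 8)) + rng.normal(
            0, 0.3, size=(50, 8)
        )
        expr = ExpressionMatrix(
            tuple(f"g{i}" for i in range(50)), tuple(f"s{j}" for j in range(8)), vals
        )
        de = moderated_ttest(expr, ["s0", "s1", "s2", "s3"], ["s4", "s5", "s6", "s7"])
        assert abs(de["log2fc"]).mean() < 0.5
        assert de["p"].median() > 0.2

    def test_zero_prior_df_equals_ordinary_t(self):
        rng = np.random.default_rng(1)
        expr = random_expr(rng, 30, 10)
        a, b = list(expr.sample_ids[:5]), list(expr.sample_ids[5:])
        de = moderated_ttest(expr, a, b, prior_df=0)
        t_ref, p_ref = stats.ttest_ind(expr.values[:, :5], expr.values[:, 5:], axis=1)
        np.testing.assert_allclose(de["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(de["p"], p_ref, atol=1e-10)

    def test_bh_adjustment_matches_step_up_brute_force(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.03, 0.04])
        adj = multipletests(p, method="fdr_bh")[1]
        # brute-force step-up: min over j >= i of m * p_(j) / j
        m = len(p)
        expected = [min(m * p[j] / (j + 1) for j in range(i, m)) for i in range(m)]
        np.testing.assert_allclose(adj, expected)
        np.testing.assert_allclose(adj, [0.04] * 4)

    def test_overlapping_groups_rejected(self):
        rng = np.random.default_rng(2)
        expr = random_expr(rng, 5, 6)
        with pytest.raises(ValueError, match="overlap"):
            moderated_ttest(expr, ["s0", "s1"], ["s1", "s2"])


class TestDeriveTemplates:
    def test_selected_genes_satisfy_thresholds(self, training_cohort, templates):
        expr, sheet, _ = training_cohort
        for c in templates.classes:
            st_ = templates.stats[c]
            for gs, sign in ((templates.up[c], 1), (templates.down[c], -1)):
                if gs is None:
                    continue
                sel = st_.loc[sorted(gs.genes)]
                assert (sel["adj_p"] < 0.001).all()
                assert (sign * sel["log2fc"] > 1.0).all()

    def test_lfc_boundary_inclusion_and_exclusion(self):
        # near-noiseless genes with group-mean differences 1.2 (in) and 0.9 (out)
        rng = np.random.default_rng(3)
        n = 40
        base = rng.normal(5, 0.001, size=(60, 2 * n))
        base[0, :n] += 1.2
        base[1, :n] += 0.9
        labels = pd.Series(
            ["A"] * n + ["B"] * n, index=[f"s{j}" for j in range(2 * n)]
        )
        expr = ExpressionMatrix(
            tuple(f"g{i}" for i in range(60)), tuple(labels.index), base
        )
        tpl = derive_templates(expr, labels, prior_df=0)
        assert "g0" in tpl.up["A"].genes
        assert "g1" not in tpl.up["A"].genes

    def test_planted_template_recovery_precision(self, training_cohort, templates):
        _, _, truth = training_cohort
        tg = truth.genes.set_index("gene_id")
        n_true = n_got = 0
        for c in templates.classes:
            for direction, gs in (("up", templates.up[c]), ("down", templates.down[c])):
                got = set(gs.genes) if gs else set()
                planted = set(
                    tg[(tg["template_class"] == c) & (tg["template_direction"] == direction)].index
                )
                n_got += len(got)
                n_true += len(got & planted)
        assert n_true / n_got >= 0.9

    def test_planted_templates_rank_top_by_significance(self, training_cohort, templates):
        _, _, truth = training_cohort
        tg = truth.genes.set_index("gene_id")
        for c in templates.classes:
            planted = set(tg[tg["template_class"] == c].index)
            st_ = templates.stats[c].sort_values("p")
            top = set(st_.index[: len(planted)])
            assert len(top & planted) / len(planted) >= 0.95

    def test_small_class_rejected(self):
        rng = np.random.default_rng(4)
        expr = random_expr(rng, 10, 6)
        labels = pd.Series(
            ["A", "A", "B", "B", "B", "B"], index=list(expr.sample_ids)
        )
        with pytest.raises(ValueError, match="A"):
            derive_templates(expr, labels)


class TestRankScore:
    def test_single_top_gene_scores_one(self):
        s = pd.Series(np.arange(10, dtype=float), index=[f"g{i}" for i in range(10)])
        assert rank_score(s, GeneSet("u", frozenset({"g9"}), "up")) == 1.0

    def test_single_bottom_gene_scores_zero(self):
        s = pd.Series(np.arange(10, dtype=float), index=[f"g{i}" for i in range(10)])
        assert rank_score(s, GeneSet("u", frozenset({"g0"}), "up")) == 0.0

    def test_matches_hand_coded_mean_rank_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            vals = rng.normal(size=20)
            genes = [f"g{i}" for i in range(20)]
            s = pd.Series(vals, index=genes)
            up = set(rng.choice(genes, size=4, replace=False))
            dn = set(rng.choice([g for g in genes if g not in up], size=3, replace=False))
            got = rank_score(
                s, GeneSet("u", frozenset(up), "up"), GeneSet("d", frozenset(dn), "down")
            )
            # oracle: explicit rank arithmetic
            order = {g: r for g, r in zip(s.sort_values().index, range(1, 21))}
            mean_up = np.mean([order[g] for g in up])
            mean_dn = np.mean([21 - order[g] for g in dn])
            exp_up = (mean_up - 2.5) / 16.0
            exp_dn = (mean_dn - 2.0) / 17.0
            assert got == pytest.approx(0.5 * (exp_up + exp_dn), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            vals = rng.normal(size=30)
            genes = [f"g{i}" for i in range(30)]
            up = GeneSet("u", frozenset(rng.choice(genes, 5, replace=False)), "up")
            dn = GeneSet("d", frozenset(rng.choice(genes, 5, replace=False)), "down")
            s = pd.Series(vals, index=genes)
            base = rank_score(s, up, dn)
            for f in (np.exp, lambda x: x**3, lambda x: 10 * x - 2):
                assert rank_score(pd.Series(f(vals), index=genes), up, dn) == pytest.approx(
                    base, abs=1e-12
                )

    def test_template_covering_universe_rejected(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            rank_score(s, GeneSet("u", frozenset({"a", "b"}), "up"))


class TestPermutationPvalue:
    def test_extreme_score_gives_min_pvalue(self):
        # up genes pinned at the very top: no random set can beat them
        vals = np.concatenate([np.arange(50.0), [1e6, 1e6 + 1, 1e6 + 2]])
        genes = [f"g{i}" for i in range(53)]
        s = pd.Series(vals, index=genes)
        up = GeneSet("u", frozenset(genes[-3:]), "up")
        res = permutation_pvalue(s, up, B=200, seed=1)
        assert res.pvalue == pytest.approx(1.0 / 201.0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(7)
        s = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        up = GeneSet("u", frozenset([f"g{i}" for i in range(10)]), "up")
        p1 = permutation_pvalue(s, up, B=300, seed=9).pvalue
        p2 = permutation_pvalue(s, up, B=300, seed=9).pvalue
        assert p1 == p2

    def test_pvalue_floor_invariant(self):
        rng = np.random.default_rng(8)
        s = pd.Series(rng.normal(size=60), index=[f"g{i}" for i in range(60)])
        up = GeneSet("u", frozenset([f"g{i}" for i in range(5)]), "up")
        res = permutation_pvalue(s, up, B=150, seed=2)
        assert res.pvalue >= 1.0 / (res.n_null + 1)

    def test_small_b_rejected(self):
        s = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            permutation_pvalue(s, GeneSet("u", frozenset({"a"}), "up"), B=10)


class TestCallHeterogeneity:
    @staticmethod
    def make(ps, scores):
        return [
            EnrichmentResult(f"s", c, sc, p, 500)
            for c, p, sc in zip(["CMS1", "CMS2", "CMS3", "CMS4"], ps, scores)
        ]

    def test_two_significant_is_heterogeneous_with_top_scoring_major(self):
        call = call_heterogeneity(self.make([0.01, 0.03, 0.4, 0.6], [0.6, 0.8, 0.5, 0.5]))
        assert call.status == "heterogeneous"
        assert call.major_class == "CMS2"
        assert call.significant_classes == frozenset({"CMS1", "CMS2"})

    def test_none_significant_is_unclassified(self):
        call = call_heterogeneity(self.make([0.2, 0.3, 0.4, 0.6], [0.5] * 4))
        assert call.status == "unclassified"
        assert call.major_class is None

    def test_exactly_one_significant_is_homogeneous(self):
        call = call_heterogeneity(self.make([0.01, 0.3, 0.4, 0.6], [0.9, 0.5, 0.5, 0.5]))
        assert call.status == "homogeneous"
        assert call.major_class == "CMS1"

    def test_alpha_is_strict(self):
        call = call_heterogeneity(self.make([0.05, 0.04, 0.5, 0.5], [0.6, 0.7, 0.5, 0.5]))
        assert call.status == "homogeneous"  # 0.05 is not < 0.05

    def test_duplicate_class_rejected(self):
        results = self.make([0.01, 0.03, 0.4, 0.6], [0.5] * 4)
        results[1] = EnrichmentResult("s", "CMS1", 0.5, 0.03, 500)
        with pytest.raises(ValueError):
            call_heterogeneity(results)


class TestClassifyNtp:
    def test_cosine_distance_hand_oracle(self):
        a = np.array([1.0, 2.0, 0.0, -1.0, 3.0])
        b = np.array([1.0, 1.0, -1.0, -1.0, 1.0])
        expected = 1.0 - np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert _cosine_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_template_like_sample_assigned_at_zero_distance(self):
        rng = np.random.default_rng(11)
        genes = tuple(f"g{i}" for i in range(40))
        up = frozenset(genes[:5])
        dn = frozenset(genes[5:10])
        from crcith.signatures import TemplateCollection

        tpl = TemplateCollection(
            classes=["A", "B"],
            up={"A": GeneSet("A_UP", up, "up"), "B": GeneSet("B_UP", frozenset(genes[10:15]), "up")},
            down={"A": GeneSet("A_DN", dn, "down"), "B": GeneSet("B_DN", frozenset(genes[15:20]), "down")},
        )
        # construct samples whose z-scores at template genes equal the signed pattern
        vals = rng.normal(0, 0.2, size=(40, 12))
        for j in range(6):  # first half: class A pattern
            vals[:5, j] += 3.0
            vals[5:10, j] -= 3.0
        for j in range(6, 12):
            vals[10:15, j] += 3.0
            vals[15:20, j] -= 3.0
        expr = ExpressionMatrix(genes, tuple(f"s{j}" for j in range(12)), vals)
        res = classify_ntp(expr, tpl, B=200, seed=1)
        assert (res["cls"][:6] == "A").all()
        assert (res["cls"][6:] == "B").all()
        assert res["classified"].all()

    def test_synthetic_subtype_accuracy(self, default_cohort, templates):
        expr, sheet, _ = default_cohort
        res = classify_ntp(expr, templates, B=200, seed=5)
        truth = sheet.set_index("sample_id")["subtype"]
        acc = (res["cls"] == truth.loc[res.index]).mean()
        assert acc >= 0.95


class TestMarkerScore:
    def test_constant_markers(self):
        expr = ExpressionMatrix(("m1", "m2"), ("s1", "s2"), np.full((2, 2), 4.2))
        out = marker_score(expr, GeneSet("caf", frozenset({"m1", "m2"})))
        assert np.allclose(out, 4.2)

    def test_single_marker_equals_gene_row(self, tiny_expr):
        out = marker_score(tiny_expr, GeneSet("m", frozenset({"g1"})))
        np.testing.assert_allclose(out, tiny_expr.values[0])

    def test_mean_oracle(self, tiny_expr):
        out = marker_score(tiny_expr, GeneSet("m", frozenset({"g1", "g3"})))
        np.testing.assert_allclose(out, tiny_expr.values[[0, 2]].mean(axis=0))

    def test_no_marker_measured(self, tiny_expr):
        with pytest.raises(ValueError):
            marker_score(tiny_expr, GeneSet("m", frozenset({"zz"})))


class TestGenesetComparison:
    def test_strong_set_is_significant_with_direction(self):
        rng = np.random.default_rng(12)
        expr = random_expr(rng, 200, 12)
        vals = expr.values.copy()
        vals[:10, :6] += 3.0  # first 10 genes up in group A
        expr = ExpressionMatrix(expr.gene_ids, expr.sample_ids, vals)
        a, b = list(expr.sample_ids[:6]), list(expr.sample_ids[6:])
        sets = [
            GeneSet("hit", frozenset(expr.gene_ids[:10])),
            GeneSet("null", frozenset(expr.gene_ids[100:120])),
        ]
        out = geneset_comparison(expr, a, b, sets)
        assert out.loc["hit", "p"] < 0.01
        assert out.loc["hit", "direction"] == "up in A"
        assert out.loc["null", "p"] > 0.01

    def test_vif_relationship_holds(self):
        rng = np.random.default_rng(13)
        expr = random_expr(rng, 100, 10)
        a, b = list(expr.sample_ids[:5]), list(expr.sample_ids[5:])
        gs = GeneSet("s", frozenset(expr.gene_ids[:15]))
        out = geneset_comparison(expr, a, b, [gs])
        de = moderated_ttest(expr, a, b)
        in_mask = np.isin(np.array(expr.gene_ids), list(gs.genes))
        z0 = _ranksum_z(de["t"].to_numpy()[in_mask], de["t"].to_numpy()[~in_mask])
        vif = 1.0 + 14 * out.loc["s", "rho_bar"]
        assert out.loc["s", "z"] == pytest.approx(z0 / np.sqrt(vif), abs=1e-10)

    def test_null_sets_roughly_calibrated(self):
        rng = np.random.default_rng(14)
        ps = []
        for i in range(100):
            expr = random_expr(np.random.default_rng(100 + i), 80, 10)
            a, b = list(expr.sample_ids[:5]), list(expr.sample_ids[5:])
            gs = GeneSet("s", frozenset(expr.gene_ids[:10]))
            ps.append(geneset_comparison(expr, a, b, [gs]).loc["s", "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
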