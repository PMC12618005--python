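"""Expression-response computations: BH, classification, ranking, GSEA, ΔΔCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavesleep.expression import (
    GeneSet,
    bh_adjust,
    classify_population_response,
    count_degs,
    delta_delta_ct,
    enrichment_score,
    preranked_gsea,
    rank_genes,
    read_gmt,
)
from oracle_utils import bh_stepup, gsea_es


def de_table(genes, lfc, p, padj=None):
    df = pd.DataFrame({"gene": genes, "log2fc": lfc, "pvalue": p})
    df["padj"] = bh_adjust(p) if padj is None else padj
    return df


class TestBH:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_applied_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_equals_stepup_oracle_and_dominates_raw(self, p):
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, bh_stepup(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-12).all()

    def test_monotone_after_sorting(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_nan_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])


class TestClassification:
    def test_rule_application(self):
        s = de_table(["a", "b", "c", "d"], [1, 1, -1, 1], [0.001] * 4,
                     padj=[0.01, 0.01, 0.20, 0.20])
        c = de_table(["a", "b", "c", "d"], [1, -1, -1, 1], [0.001] * 4,
                     padj=[0.01, 0.20, 0.01, 0.20])
        out = classify_population_response(s, c).set_index("gene")
        assert out.loc["a", "category"] == "shared"
        assert out.loc["b", "category"] == "surface_specific"
        assert out.loc["c", "category"] == "cave_specific"
        assert out.loc["d", "category"] == "nonresponsive"
        assert out.loc["b", "cave_direction"] == "down"

    def test_outer_gene_universe(self):
        s = de_table(["a", "b"], [1, 1], [0.001, 0.5], padj=[0.01, 0.9])
        c = de_table(["a", "z"], [1, -2], [0.001, 0.001], padj=[0.01, 0.01])
        out = classify_population_response(s, c).set_index("gene")
        assert set(out.index) == {"a", "b", "z"}
        assert out.loc["z", "category"] == "cave_specific"
        assert out.loc["z", "surface_direction"] is None

    def test_duplicate_gene_ids_raise(self):
        s = de_table(["a", "a"], [1, 1], [0.1, 0.1])
        with pytest.raises(ValueError):
            classify_population_response(s, s)

    def test_categories_partition_union(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(100)]
        s = de_table(genes, rng.normal(size=100), rng.random(100))
        c = de_table(genes, rng.normal(size=100), rng.random(100))
        out = classify_population_response(s, c)
        assert len(out) == 100
        assert set(out["category"]) <= {"shared", "surface_specific", "cave_specific",
                                        "nonresponsive"}


class TestCountDegs:
    def test_zero_and_planted_counts(self):
        none = de_table(["a", "b"], [1, 1], [0.9, 0.8], padj=[0.9, 0.9])
        planted = de_table(["a", "b", "c"], [1, 1, 1], [1e-9, 1e-9, 0.9],
                           padj=[1e-8, 1e-8, 0.9])
        counts = count_degs({"none": none, "planted": planted})
        assert counts["none"] == 0 and counts["planted"] == 2

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        t = de_table([f"g{i}" for i in range(200)], rng.normal(size=200), rng.random(200))
        n = [count_degs({"t": t}, alpha=a)["t"] for a in (0.01, 0.05, 0.2)]
        assert n == sorted(n)


class TestRankGenes:
    def test_signed_score_arithmetic(self):
        t = de_table(["up", "dn", "flat"], [2.0, -2.0, 0.0], [0.01, 0.01, 0.01])
        r = rank_genes(t)
        assert r["up"] == pytest.approx(2.0)
        assert r["dn"] == pytest.approx(-2.0)
        assert r["flat"] == 0.0

    def test_p_equal_one_scores_zero(self):
        r = rank_genes(de_table(["a"], [3.0], [1.0]))
        assert r["a"] == 0.0

    def test_p_zero_clamped_to_smallest_positive(self):
        t = de_table(["a", "b"], [1.0, 1.0], [0.0, 1e-20])
        r = rank_genes(t)
        assert np.isfinite(r["a"]) and r["a"] == pytest.approx(20.0)

    def test_descending_with_lexicographic_ties(self):
        t = de_table(["zz", "aa", "mm"], [1.0, 1.0, -1.0], [0.1, 0.1, 0.001])
        assert rank_genes(t).index.tolist() == ["aa", "zz", "mm"]

    def test_missing_log2fc_raises(self):
        t = pd.DataFrame({"gene": ["a"], "log2fc": [np.nan], "pvalue": [0.1]})
        with pytest.raises(ValueError):
            rank_genes(t)


class TestEnrichmentScore:
    def test_four_gene_worked_example(self):
        scores = np.array([3.0, 2.0, 1.0, 0.5])
        hits = np.array([True, False, False, False])
        assert enrichment_score(scores, hits) == pytest.approx(1.0)

    def test_entire_universe_convention(self):
        assert enrichment_score(np.array([3.0, 1.0]), np.array([True, True])) == 1.0

    def test_bottom_heavy_set_is_negative(self):
        scores = np.linspace(3, -3, 20)
        hits = np.zeros(20, bool)
        hits[-4:] = True
        assert enrichment_score(scores, hits) < 0

    @settings(derandomize=True, max_examples=200)
    @given(seed=st.integers(0, 10_000), weight=st.sampled_from([0.0, 1.0, 2.0]))
    def test_equals_running_sum_oracle_and_bounded(self, seed, weight):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=50))[::-1]
        hits = rng.random(50) < 0.2
        if hits.sum() == 0:
            hits[rng.integers(50)] = True
        es = enrichment_score(scores, hits, weight)
        assert es == pytest.approx(gsea_es(scores, hits, weight), abs=1e-12)
        assert -1.0 <= es <= 1.0

    def test_all_zero_hit_scores_error(self):
        scores = np.array([1.0, 0.0, 0.0])
        hits = np.array([False, True, True])
        with pytest.raises(ValueError):
            enrichment_score(scores, hits, weight=1.0)


class TestPrerankedGsea:
    @pytest.fixture()
    def ranked(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i:03d}" for i in range(200)]
        t = de_table(genes, rng.normal(size=200), rng.random(200))
        return rank_genes(t)

    def test_top_loaded_set_enriched(self, ranked):
        top = GeneSet("top", frozenset(ranked.index[:15]))
        rnd = GeneSet("rnd", frozenset(np.random.default_rng(1).choice(ranked.index, 15,
                                                                       replace=False)))
        res = preranked_gsea(ranked, [top, rnd], n_perm=500, seed=3, min_size=10)
        res = res.set_index("set")
        assert res.loc["top", "ES"] > 0.8
        assert res.loc["top", "pval"] < 0.05
        assert res.loc["top", "pval"] <= res.loc["top", "padj"] <= 1.0

    def test_size_filter_and_disjoint_warning(self, ranked):
        small = GeneSet("small", frozenset(ranked.index[:3]))
        foreign = GeneSet("foreign", frozenset({"not_a_gene"}))
        with pytest.warns(UserWarning, match="foreign"):
            res = preranked_gsea(ranked, [small, foreign], n_perm=100, seed=0)
        assert res.empty

    def test_determinism(self, ranked):
        gs = [GeneSet("s", frozenset(ranked.index[5:25]))]
        a = preranked_gsea(ranked, gs, n_perm=200, seed=9)
        b = preranked_gsea(ranked, gs, n_perm=200, seed=9)
        assert a.equals(b)

    def test_too_few_permutations_raise(self, ranked):
        with pytest.raises(ValueError):
            preranked_gsea(ranked, [GeneSet("s", frozenset(ranked.index[:15]))], n_perm=10)

    def test_all_zero_scores_raise(self):
        ranked = pd.Series(np.zeros(20), index=[f"g{i}" for i in range(20)])
        with pytest.raises(ValueError):
            preranked_gsea(ranked, [GeneSet("s", frozenset(ranked.index[:12]))])

    def test_gmt_roundtrip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg9\n")
        sets = read_gmt(p)
        assert sets[0].name == "setA" and sets[0].genes == {"g1", "g2", "g3"}
        assert sets[1].genes == {"g9"}


class TestDeltaDeltaCt:
    def qpcr(self, rows):
        return pd.DataFrame(rows, columns=["sample", "condition", "gene", "ct"])

    def test_identical_cts_fold_one(self):
        rows = [(s, c, g, 20.0) for s in ("s1", "s2") for c in [("control" if s == "s1"
                else "treated")] for g in ("rpl13a", "per1")]
        res = delta_delta_ct(self.qpcr(rows))
        assert np.allclose(res.summary["fold_change"], 1.0)

    def test_worked_example_fold_four(self):
        rows = [
            ("u1", "control", "rpl13a", 15.0), ("u1", "control", "per1", 22.0),
            ("t1", "treated", "rpl13a", 15.0), ("t1", "treated", "per1", 20.0),
        ]
        res = delta_delta_ct(self.qpcr(rows)).summary.set_index(["condition", "gene"])
        assert res.loc[("treated", "per1"), "delta_delta_ct"] == pytest.approx(-2.0)
        assert res.loc[("treated", "per1"), "fold_change"] == pytest.approx(4.0)
        assert res.loc[("control", "per1"), "fold_change"] == pytest.approx(1.0)

    def test_swapping_conditions_inverts_fold(self):
        rows = [
            ("u1", "control", "rpl13a", 15.0), ("u1", "control", "per1", 22.0),
            ("t1", "treated", "rpl13a", 15.0), ("t1", "treated", "per1", 20.0),
        ]
        res = delta_delta_ct(self.qpcr(rows), reference_condition="treated")
        fold = res.summary.set_index(["condition", "gene"]).loc[("control", "per1"),
                                                                "fold_change"]
        assert fold == pytest.approx(0.25)

    def test_replicates_averaged_on_ct_scale(self):
        rows = [
            ("u1", "control", "rpl13a", 15.0),
            ("u1", "control", "per1", 21.0), ("u1", "control", "per1", 23.0),
            ("t1", "treated", "rpl13a", 15.0), ("t1", "treated", "per1", 20.0),
        ]
        res = delta_delta_ct(self.qpcr(rows)).summary.set_index(["condition", "gene"])
        assert res.loc[("treated", "per1"), "fold_change"] == pytest.approx(4.0)

    def test_missing_housekeeping_names_sample(self):
        rows = [("u1", "control", "per1", 22.0)]
        with pytest.raises(ValueError, match="u1"):
            delta_delta_ct(self.qpcr(rows))
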