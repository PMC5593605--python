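"""Coding-noncoding network: gene filtering, correlation p-values, edges,
topology, and gene-set enrichment."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

import pedmeth as pm
from pedmeth import evaluate
from pedmeth.errors import ConfigError, DataError
from pedmeth.expression import ExpressionMatrix


def _em(df):
    return ExpressionMatrix(df=df, sample_to_stage={c: "s" for c in df.columns})


class TestFilterGenes:
    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(30)
        df = pd.DataFrame(
            rng.gamma(2, 5, (100, 12)),
            index=[f"g{i}" for i in range(100)],
            columns=[f"c{i}" for i in range(12)],
        )
        kept = pm.filter_genes(_em(df), min_max_expr=5, var_keep_fraction=0.75)
        logd = np.log2(df + 1)
        variances = logd.var(axis=1, ddof=1)
        cut = variances.quantile(0.25)
        expected = set(df.index[(df.max(axis=1) > 5) & (variances >= cut)])
        assert set(kept.index) == expected

    def test_low_max_expression_dropped(self):
        df = pd.DataFrame(
            {"c1": [4.9, 50.0], "c2": [4.9, 60.0], "c3": [1.0, 70.0], "c4": [2.0, 10.0]},
            index=["low", "high"],
        )
        kept = pm.filter_genes(_em(df), var_keep_fraction=1.0)
        assert list(kept.index) == ["high"]

    def test_nothing_surviving_raises(self):
        df = pd.DataFrame({"c1": [0.1], "c2": [0.1]}, index=["g"])
        with pytest.raises(DataError):
            pm.filter_genes(_em(df))


class TestFisherPvalue:
    def test_worked_example_r08_n10(self):
        t = 0.8 * math.sqrt(8) / math.sqrt(1 - 0.64)
        assert t == pytest.approx(3.7712, abs=1e-4)
        p = pm.fisher_pvalue(np.array([0.8]), 10)[0]
        # independent route: regularized incomplete beta for the t tail
        oracle = special.betainc(4.0, 0.5, 8.0 / (8.0 + t * t))
        assert p == pytest.approx(oracle, rel=1e-12)
        assert p == pytest.approx(5.4e-3, rel=0.05)

    def test_perfect_correlation_maps_to_zero_without_blowup(self):
        p = pm.fisher_pvalue(np.array([1.0, -1.0]), 20)
        assert (p == 0).all()

    def test_monotone_decreasing_in_abs_r(self):
        r = np.linspace(0, 0.999, 50)
        p = pm.fisher_pvalue(r, 30)
        assert (np.diff(p) < 0).all()

    def test_matches_permutation_null_at_n50(self):
        rng = np.random.default_rng(31)
        n, B = 50, 10_000
        x = rng.normal(size=n)
        y = 0.25 * x + rng.normal(size=n)
        r_obs = np.corrcoef(x, y)[0, 1]
        p_analytic = pm.fisher_pvalue(np.array([r_obs]), n)[0]
        perm_r = np.empty(B)
        for b in range(B):
            perm_r[b] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_perm = np.mean(np.abs(perm_r) >= abs(r_obs))
        mc_sd = math.sqrt(max(p_perm * (1 - p_perm), 1e-6) / B)
        assert abs(p_analytic - p_perm) < 4 * mc_sd + 0.01


class TestPccAndFisher:
    def test_pairs_cover_upper_triangle_with_ordered_names(self):
        rng = np.random.default_rng(32)
        df = pd.DataFrame(
            rng.random((6, 10)), index=[f"g{i}" for i in range(6)]
        )
        pairs = pm.pcc_and_fisher(df)
        assert len(pairs) == 15
        assert (pairs.gene_a < pairs.gene_b).all()

    def test_constant_gene_pairs_reported_missing(self):
        df = pd.DataFrame(
            {"c1": [1.0, 2.0], "c2": [1.0, 3.0], "c3": [1.0, 4.0], "c4": [1.0, 5.0]},
            index=["const", "varies"],
        ).astype(float)
        pairs = pm.pcc_and_fisher(df)
        assert pairs.r.isna().all()

    def test_network_invariant_under_gene_permutation(self):
        rng = np.random.default_rng(33)
        df = pd.DataFrame(
            rng.random((8, 20)), index=[f"g{i}" for i in range(8)]
        )
        a = pm.pcc_and_fisher(df)
        b = pm.pcc_and_fisher(df.sample(frac=1, random_state=7))
        key = ["gene_a", "gene_b"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True),
        )


class TestBuildNetwork:
    def _pairs(self):
        return pd.DataFrame(
            {
                "gene_a": ["a", "a", "b"],
                "gene_b": ["b", "c", "c"],
                "r": [0.85, 0.79, -0.9],
                "p": [0.001, 0.001, 0.001],
                "n": 50,
            }
        )

    def test_seed_and_correlation_gates(self):
        edges, nodes = pm.build_network(self._pairs(), seed_genes=["b"])
        # a-b kept (seeded, |r|>0.8); a-c fails |r|; b-c kept (negative r counts)
        assert set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy())) == {("a", "b"), ("b", "c")}
        edges2, _ = pm.build_network(self._pairs(), seed_genes=["z"])
        assert edges2.empty  # no seeded endpoint anywhere

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ConfigError):
            pm.build_network(self._pairs(), seed_genes=[])

    def test_planted_modules_dominate_fixture_network(self, dataset, analysis):
        rec = evaluate.module_edge_precision(analysis["edges"], dataset.truth.modules)
        assert rec["n_edges"] > 0
        assert rec["precision"] >= 0.9
        # every retained edge satisfies both gates and touches a seed gene
        e = analysis["edges"]
        assert (e.r.abs() > 0.8).all() and (e.p < 0.05).all()
        seeds = set(analysis["seed_genes"])
        assert (e.gene_a.isin(seeds) | e.gene_b.isin(seeds)).all()


class TestTopology:
    def test_star_and_components_and_handshake(self):
        edges = pd.DataFrame(
            {"gene_a": ["h", "h", "h", "h", "h"], "gene_b": list("abcde"),
             "r": 0.9, "p": 0.001}
        )
        g = pm.to_graph(edges)
        topo = pm.topology(g)
        assert topo["degrees"]["h"] == 5
        assert topo["hubs"][0] == "h"
        assert topo["degrees"].sum() == 2 * topo["n_edges"]
        tri = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")])
        assert pm.topology(tri)["component_sizes"] == [3, 3]

    def test_empty_network(self):
        topo = pm.topology(nx.Graph())
        assert topo["n_nodes"] == 0 and topo["hubs"] == []


class TestGenesetEnrichment:
    def test_exact_query_gives_fold_n_over_k(self):
        universe = [f"g{i}" for i in range(40)]
        terms = pd.DataFrame(
            {"term": ["t1"] * 5 + ["t2"] * 5,
             "gene": universe[:5] + universe[10:15]}
        )
        res = pm.geneset_enrichment(universe[:5], terms, universe).set_index("term")
        assert res.loc["t1", "fold_enrichment"] == pytest.approx(40 / 5)
        assert res.loc["t1", "p"] < res.loc["t2", "p"]
        assert res.loc["t2", "overlap"] == 0

    def test_p_matches_enumeration_for_small_universes(self):
        rng = np.random.default_rng(34)
        for _ in range(20):
            N = int(rng.integers(6, 26))
            universe = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            term_genes = list(rng.choice(universe, K, replace=False))
            query = list(rng.choice(universe, n, replace=False))
            terms = pd.DataFrame({"term": "t", "gene": term_genes})
            res = pm.geneset_enrichment(query, terms, universe)
            k = len(set(term_genes) & set(query))
            enum_p = sum(
                math.comb(K, i) * math.comb(N - K, n - i)
                for i in range(k, min(K, n) + 1)
            ) / math.comb(N, n)
            assert res.iloc[0].p == pytest.approx(enum_p, abs=1e-12)

    def test_query_outside_universe_rejected(self):
        terms = pd.DataFrame({"term": ["t"], "gene": ["g1"]})
        with pytest.raises(DataError):
            pm.geneset_enrichment(["zz"], terms, ["g1", "g2"])

    def test_q_monotone_and_at_least_p(self):
        rng = np.random.default_rng(35)
        universe = [f"g{i}" for i in range(60)]
        rows = []
        for t in range(12):
            for g in rng.choice(universe, 8, replace=False):
                rows.append({"term": f"t{t}", "gene": g})
        res = pm.geneset_enrichment(
            list(rng.choice(universe, 15, replace=False)), pd.DataFrame(rows), universe
        ).sort_values("p")
        assert (res.q.to_numpy() >= res.p.to_numpy() - 1e-15).all()
        assert (np.diff(res.q.to_numpy()) >= -1e-15).all()
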