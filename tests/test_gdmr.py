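"""Gamete-specific DMR calling, clustering, enrichment, parental bias."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pedmeth as pm
from pedmeth import evaluate
from pedmeth import gdmr as gdmr_mod
from pedmeth.errors import ConfigError, DataError


def _tm(levels, sid, chrom="c"):
    """One TileMethylome with tiles [k*100,(k+1)*100) at the given levels."""
    n = len(levels)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * 100,
            "end": np.arange(1, n + 1) * 100,
            "level": levels,
            "pooled_meth": 0,
            "pooled_total": 50,
            "cpg_density": 1.0,
            "n_cpgs_used": 5,
        }
    )
    return pm.TileMethylome(sample_id=sid, df=df)


def _cpg_frames(tile_levels, n_cpg=5, jitter=0.02, seed=0):
    """Per-CpG level frames consistent with the replicate tile levels."""
    rng = np.random.default_rng(seed)
    frames = []
    for rep, levels in enumerate(tile_levels):
        recs = []
        for k, lv in enumerate(levels):
            for j in range(n_cpg):
                recs.append(
                    ("c", k * 100 + 10 * j,
                     float(np.clip(lv + rng.normal(0, jitter), 0, 1)))
                )
        frames.append(pd.DataFrame(recs, columns=["chrom", "pos", "level"]))
    return frames


class TestThresholdRule:
    def test_clear_sperm_specific_tile_called(self):
        sperm = [[0.88], [0.92]]
        oocyte = [[0.08], [0.12]]
        for method, kw in (
            ("replicates", {}),
            ("cpg", {"sperm_cpg": _cpg_frames(sperm), "oocyte_cpg": _cpg_frames(oocyte, seed=1)}),
        ):
            out = pm.call_gdmrs(
                [_tm(lv, f"s{i}") for i, lv in enumerate(sperm)],
                [_tm(lv, f"o{i}") for i, lv in enumerate(oocyte)],
                method=method,
                **kw,
            )
            assert len(out) == 1 and out.iloc[0].gamete == "sperm"
            assert out.iloc[0].mean_sperm == pytest.approx(0.9)

    def test_intermediate_difference_not_called(self):
        out = pm.call_gdmrs(
            [_tm([0.61], "s1"), _tm([0.59], "s2")],
            [_tm([0.11], "o1"), _tm([0.09], "o2")],
            method="replicates",
        )
        assert out.empty  # 0.60 does not exceed 0.75

    def test_direction_consistent_with_thresholds(self, analysis):
        g = analysis["gdmrs"]
        sperm = g[g.gamete == "sperm"]
        oocyte = g[g.gamete == "oocyte"]
        assert ((sperm.mean_sperm > 0.75) & (sperm.mean_oocyte < 0.25)).all()
        assert ((oocyte.mean_oocyte > 0.75) & (oocyte.mean_sperm < 0.25)).all()
        assert (g.q < 0.05).all()

    def test_config_errors(self):
        reps = [_tm([0.5], "a"), _tm([0.5], "b")]
        with pytest.raises(ConfigError):
            pm.call_gdmrs(reps, reps, hi=0.2, lo=0.3)
        with pytest.raises(ConfigError):
            pm.call_gdmrs(reps[:1], reps)


def test_bh_qvalues_monotone_in_p():
    rng = np.random.default_rng(8)
    sperm = rng.uniform(0.76, 0.99, (2, 300))
    oocyte = rng.uniform(0.01, 0.24, (2, 300))
    out = pm.call_gdmrs(
        [_tm(sperm[i], f"s{i}") for i in range(2)],
        [_tm(oocyte[i], f"o{i}") for i in range(2)],
        method="replicates",
        fdr=0.9,
    )
    s = out.sort_values("p")
    assert (np.diff(s.q.to_numpy()) >= -1e-15).all()
    assert (s.q >= s.p - 1e-15).all()


def test_planted_gdmr_recovery_meets_margins(dataset, analysis):
    rec = evaluate.gdmr_recovery(analysis["gdmrs"], dataset.truth.gdmrs)
    assert rec["sensitivity"] >= 0.95
    assert rec["precision"] >= 0.95


class TestClusterDynamics:
    def _matrix(self):
        rng = np.random.default_rng(1)
        protos = rng.random((6, 9))
        rows = np.repeat(protos, 10, axis=0) + rng.normal(0, 0.01, (60, 9))
        return pd.DataFrame(rows, columns=[f"st{i}" for i in range(9)])

    def test_separable_groups_form_pure_clusters(self):
        m = self._matrix()
        labels, centroids = pm.cluster_dynamics(m, k=6, seed=0)
        for i in range(6):
            block = labels[i * 10 : (i + 1) * 10]
            assert len(set(block)) == 1
        assert centroids.shape == (6, 9)

    def test_deterministic_for_seed(self):
        m = self._matrix()
        a, _ = pm.cluster_dynamics(m, k=6, seed=5)
        b, _ = pm.cluster_dynamics(m, k=6, seed=5)
        assert np.array_equal(a, b)

    def test_sse_beats_random_assignments(self):
        m = self._matrix()
        X = m.to_numpy()
        labels, _ = pm.cluster_dynamics(m, k=6, seed=0)

        def sse(lab):
            total = 0.0
            for c in np.unique(lab):
                grp = X[lab == c]
                total += ((grp - grp.mean(axis=0)) ** 2).sum()
            return total

        ours = sse(labels)
        rng = np.random.default_rng(2)
        for _ in range(100):
            assert ours <= sse(rng.integers(1, 7, len(X)))

    def test_fewer_dmrs_than_k_rejected(self):
        m = self._matrix().head(3)
        with pytest.raises(DataError):
            pm.cluster_dynamics(m, k=6, seed=0)


class TestAnnotationEnrichment:
    def test_worked_tail_example_verified_by_enumeration(self):
        # universe 20 tiles, 5 labeled, 10 DMRs, 4 labeled among them
        N, K, n, k = 20, 5, 10, 4
        enum_p = sum(
            math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1)
        ) / math.comb(N, n)
        assert enum_p == pytest.approx(28028 / 184756)
        universe = pd.DataFrame({"lab": [True] * K + [False] * (N - K)})
        mask = np.zeros(N, bool)
        mask[:4] = True  # 4 labeled
        mask[10:16] = True  # 6 unlabeled
        res = pm.annotation_enrichment(universe, mask, ["lab"])
        assert res.iloc[0].p == pytest.approx(enum_p, abs=1e-12)
        assert res.iloc[0].overlap == 4

    def test_saturated_and_empty_overlap_give_p_one(self):
        universe = pd.DataFrame({"all": [True] * 12, "none_hit": [True] * 4 + [False] * 8})
        mask = np.zeros(12, bool)
        mask[5:9] = True  # DMRs entirely in the unlabeled part of none_hit
        res = pm.annotation_enrichment(universe, mask, ["all", "none_hit"]).set_index("label")
        assert res.loc["all"].p == pytest.approx(1.0)
        assert res.loc["none_hit", "overlap"] == 0
        assert res.loc["none_hit"].p == pytest.approx(1.0)

    def test_enumeration_oracle_on_random_small_universes(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            N = int(rng.integers(5, 26))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            lab = np.zeros(N, bool)
            lab[rng.choice(N, K, replace=False)] = True
            mask = np.zeros(N, bool)
            mask[rng.choice(N, n, replace=False)] = True
            k = int((lab & mask).sum())
            res = pm.annotation_enrichment(pd.DataFrame({"x": lab}), mask, ["x"])
            enum_p = sum(
                math.comb(K, i) * math.comb(N - K, n - i)
                for i in range(k, min(K, n) + 1)
            ) / math.comb(N, n)
            assert res.iloc[0].p == pytest.approx(enum_p, abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(DataError):
            pm.annotation_enrichment(pd.DataFrame(), np.array([]), ["x"])


class TestParentalBias:
    def _assigned(self, counts):
        rows = []
        i = 0
        for cls, gamete, n in counts:
            for _ in range(n):
                rows.append(("c", i * 100, i * 100 + 100, gamete, f"g{i}", cls, False))
                i += 1
        return pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "gamete", "gene_id", "gene_class", "ambiguous"],
        )

    def test_chi_square_matches_direct_formula(self):
        a = self._assigned(
            [("lncRNA", "sperm", 67), ("lncRNA", "oocyte", 33),
             ("coding", "sperm", 51), ("coding", "oocyte", 49)]
        )
        res = pm.parental_bias(a)
        obs = np.array([[67, 33], [51, 49]], float)
        row, col = obs.sum(1, keepdims=True), obs.sum(0, keepdims=True)
        exp = row @ col / obs.sum()
        chi2_oracle = ((obs - exp) ** 2 / exp).sum()
        assert res["chi2"] == pytest.approx(chi2_oracle, abs=1e-12)
        assert res["p"] == pytest.approx(stats.chi2.sf(chi2_oracle, 1), abs=1e-12)
        assert res["sperm_fraction"]["lncRNA"] == pytest.approx(0.67)

    def test_identical_distributions_give_null_chi_square(self):
        a = self._assigned(
            [("lncRNA", "sperm", 30), ("lncRNA", "oocyte", 30),
             ("coding", "sperm", 30), ("coding", "oocyte", 30)]
        )
        res = pm.parental_bias(a)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_dmr_spanning_both_classes_counted_in_each(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["l", "p"],
                "gene_class": ["lncRNA", "coding"],
                "chrom": ["c", "c"],
                "strand": ["+", "+"],
                "start": [0, 150],
                "end": [200, 400],
                "tss": [0, 150],
                "promoter_start": [-1000, -850],
                "promoter_end": [1000, 1150],
                "exon_starts": ["0", "150"],
                "exon_ends": ["200", "400"],
            }
        )
        dmr = pd.DataFrame(
            {"chrom": ["c"], "start": [100], "end": [200], "gamete": ["sperm"]}
        )
        assigned = pm.assign_dmrs_to_genes(dmr, genes, region="body")
        assert sorted(assigned.gene_class) == ["coding", "lncRNA"]
        assert assigned.ambiguous.all()
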