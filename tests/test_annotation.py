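"""Gene models, tile-feature assignment, TSS profiles, K-S comparison."""

import numpy as np
import pandas as pd
import pytest

import pedmeth as pm
from pedmeth import annotation as ann_mod
from pedmeth.errors import DataError

from conftest import region_overlap_oracle


def _write_gtf(path, rows):
    with open(path, "w") as fh:
        for gid, chrom, strand, start, end in rows:
            attrs = f'gene_id "{gid}"; transcript_id "{gid}.1"; gene_biotype "coding";'
            for feat in ("gene", "transcript", "exon"):
                fh.write(f"{chrom}\tt\t{feat}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n")


class TestLoadGenes:
    def test_strand_rule_for_tss_and_promoter(self, tmp_path):
        p = tmp_path / "g.gtf"
        _write_gtf(p, [("minus", "chr1", "-", 1000, 3000), ("plus", "chr1", "+", 1000, 3000)])
        g = pm.load_genes(p).set_index("gene_id")
        assert g.loc["minus", "tss"] == 3000
        assert (g.loc["minus", "promoter_start"], g.loc["minus", "promoter_end"]) == (2000, 4000)
        assert g.loc["plus", "tss"] == 1000
        assert (g.loc["plus", "promoter_start"], g.loc["plus", "promoter_end"]) == (0, 2000)

    def test_gtf_and_bed12_readers_agree(self, small_dataset, tmp_path):
        pm.write_fixture(small_dataset, tmp_path)
        from_gtf = pm.load_genes(tmp_path / "annotation" / "genes.gtf")
        from_bed = pm.load_genes(tmp_path / "annotation" / "genes.bed", class_label=None)
        cols = ["gene_id", "chrom", "strand", "start", "end", "tss",
                "promoter_start", "promoter_end", "exon_starts", "exon_ends"]
        pd.testing.assert_frame_equal(from_gtf[cols], from_bed[cols])

    def test_unknown_strand_rejected_listing_gene(self, tmp_path):
        p = tmp_path / "g.gtf"
        _write_gtf(p, [("odd", "chr1", ".", 100, 400)])
        with pytest.raises(DataError, match="odd"):
            pm.load_genes(p)

    def test_promoter_width_is_2kb_for_every_gene(self, dataset):
        g = dataset.annotation.genes
        assert ((g.promoter_end - g.promoter_start) == 2000).all()


class TestDistalLncRNAFilter:
    def _genes(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "gene_class", "chrom", "start", "end"]
        )

    def test_near_and_far_examples(self):
        lnc = self._genes([("l1", "lncRNA", "c1", 2000, 3000), ("l2", "lncRNA", "c2", 0, 500)])
        cod = self._genes([("p1", "coding", "c1", 3500, 5000)])
        kept = pm.filter_distal_lncrna(lnc, cod, min_dist=1000)
        # l1 is 500 bp away -> dropped; l2 has no coding gene on its chromosome
        assert kept.gene_id.tolist() == ["l2"]

    def test_matches_all_pairs_brute_force(self, dataset):
        g = dataset.annotation.genes
        lnc = g[g.gene_class == "lncRNA"].reset_index(drop=True)
        cod = g[g.gene_class == "coding"].reset_index(drop=True)
        kept = set(pm.filter_distal_lncrna(lnc, cod, min_dist=1000).gene_id)
        expected = set()
        for r in lnc.itertuples():
            ok = True
            for c in cod.itertuples():
                if c.chrom != r.chrom:
                    continue
                dist = max(c.start - r.end, r.start - c.end)
                if dist < 1000:
                    ok = False
            if ok:
                expected.add(r.gene_id)
        assert kept == expected


class TestAssignTiles:
    def test_half_open_overlap_rule(self):
        tiles = pd.DataFrame({"chrom": ["c"] * 2, "start": [100, 100], "end": [200, 200]})
        feats = {
            "promoter": pd.DataFrame({"chrom": ["c"], "start": [150], "end": [400]}),
            "exon": pd.DataFrame({"chrom": ["c"], "start": [200], "end": [300]}),
        }
        out = pm.assign_tiles(tiles, feats)
        assert out.promoter.all()
        assert not out.exon.any()  # [100,200) does not touch [200,300)

    def test_matches_brute_force_overlap_scan(self, dataset, tile_methylomes):
        tiles = next(iter(tile_methylomes.values())).df.head(5000)
        feats = {k: v for k, v in dataset.annotation.features.items()}
        out = pm.assign_tiles(tiles, feats)
        rng = np.random.default_rng(0)
        idx = rng.choice(len(out), size=300, replace=False)
        for name, fdf in feats.items():
            ivs = list(zip(fdf.chrom, fdf.start, fdf.end))
            for i in idx:
                row = out.iloc[i]
                assert row[name] == region_overlap_oracle(
                    (row.chrom, row.start, row.end), ivs
                )

    def test_labels_stable_under_tile_permutation(self, dataset, tile_methylomes):
        tiles = next(iter(tile_methylomes.values())).df.head(500)
        feats = dataset.annotation.features
        a = pm.assign_tiles(tiles, feats)
        b = pm.assign_tiles(tiles.sample(frac=1, random_state=1), feats)
        merged = a.merge(b, on=["chrom", "start", "end"], suffixes=("_a", "_b"))
        for name in feats:
            assert (merged[f"{name}_a"] == merged[f"{name}_b"]).all()


class TestRegionMethylation:
    def _methylome(self, rows):
        return pm.StageMethylome(
            stage="s",
            df=pd.DataFrame(rows, columns=["chrom", "start", "end", "level"]),
            n_replicates=2,
        )

    def test_mean_of_overlapping_tiles_and_missingness(self):
        m = self._methylome([("c", 0, 100, 0.2), ("c", 100, 200, 0.6)])
        regions = pd.DataFrame(
            {"region_id": ["a", "b"], "chrom": ["c", "c"],
             "start": [50, 1000], "end": [150, 1100]}
        )
        lv = pm.region_methylation(m, regions)
        assert lv["a"] == pytest.approx(0.4)
        assert np.isnan(lv["b"])  # uncovered region is missing, not 0

    def test_lncrna_promoters_hotter_than_coding_on_fixture(self, dataset, stage_methylomes):
        genes = dataset.annotation.genes
        prom = genes[["gene_id", "chrom", "promoter_start", "promoter_end"]].rename(
            columns={"gene_id": "region_id", "promoter_start": "start", "promoter_end": "end"}
        )
        lv = pm.region_methylation(stage_methylomes["sperm"], prom)
        cls = genes.set_index("gene_id").gene_class
        assert lv[cls == "lncRNA"].mean() > lv[cls == "coding"].mean()


class TestTSSProfile:
    def _gene(self, gid, chrom, strand, start, end):
        tss = start if strand == "+" else end
        return {
            "gene_id": gid, "gene_class": "coding", "chrom": chrom, "strand": strand,
            "start": start, "end": end, "tss": tss,
            "promoter_start": tss - 1000, "promoter_end": tss + 1000,
            "exon_starts": str(start), "exon_ends": str(end),
        }

    def _uniform_tiles(self, level=0.5, n=400):
        return pd.DataFrame(
            {"chrom": "c", "start": np.arange(n) * 100,
             "end": np.arange(1, n + 1) * 100, "level": level}
        )

    def test_flat_methylome_gives_flat_profile(self):
        genes = pd.DataFrame([self._gene("g", "c", "+", 20_000, 25_000)])
        prof = pm.tss_profile(self._uniform_tiles(), genes)
        assert (prof["mean"] == 0.5).all()
        assert len(prof) == 100  # 10 kb of 100-bp bins

    def test_minus_strand_profile_mirrors_plus_recoding(self):
        rng = np.random.default_rng(4)
        tiles = self._uniform_tiles()
        tiles["level"] = rng.random(len(tiles))
        plus = pd.DataFrame([self._gene("g", "c", "+", 20_000, 25_000)])
        minus = pd.DataFrame([self._gene("g", "c", "-", 15_000, 20_000)])
        # same TSS position (20,000), opposite orientation
        p = pm.tss_profile(tiles, plus).set_index("offset_bp")["mean"]
        m = pm.tss_profile(tiles, minus).set_index("offset_bp")["mean"]
        for off in p.index:
            mirrored = -off - 100  # bin [off, off+100) maps to [-off-100, -off)
            assert m[mirrored] == pytest.approx(p[off])


class TestKSCompare:
    def test_identical_and_disjoint_samples(self):
        a = np.linspace(0, 1, 50)
        d, p = pm.ks_compare(a, a)
        assert d == 0
        d, _ = pm.ks_compare(a, a + 10)
        assert d == 1

    def test_statistic_matches_ecdf_gap_oracle(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 50), rng.normal(0.4, 1.3, 60)
        d, _ = pm.ks_compare(a, b)
        grid = np.concatenate([a, b])
        gaps = [abs((a <= x).mean() - (b <= x).mean()) for x in grid]
        assert d == pytest.approx(max(gaps), abs=1e-12)

    def test_tiny_samples_rejected(self):
        with pytest.raises(DataError):
            pm.ks_compare([1.0], [1.0, 2.0])
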