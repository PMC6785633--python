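"""Gene-LAD membership, strand-aware distances, variation, capture windows."""

import math

import numpy as np
import pytest

from conftest import brute_force_distances
from ladcycle import (
    GeneRecord,
    IntervalSet,
    assign_membership,
    distance_variation,
    gene_to_nearest_lad,
    genes_near_lads,
    read_genes_bed,
    write_genes_bed,
)


def lads(*pairs, chrom="c"):
    return IntervalSet.from_tuples([(chrom, s, e) for s, e in pairs]).normalize()


class TestMembership:
    def test_tss_respects_strand(self):
        ladset = lads((150, 250))
        plus = GeneRecord("g+", "c", 200, 300, "+")   # TSS 200, inside
        minus = GeneRecord("g-", "c", 200, 300, "-")  # TSS 299, outside
        got = assign_membership([plus, minus], ladset)
        assert got == {"g+": True, "g-": False}

    def test_matches_bp_oracle(self):
        rng = np.random.default_rng(30)
        ladset = lads(*[(int(s), int(s) + int(rng.integers(50, 200)))
                        for s in rng.choice(np.arange(0, 9000, 300), 10, replace=False)])
        genes = [
            GeneRecord(f"g{i}", "c", int(s), int(s) + 60, "+" if i % 2 else "-")
            for i, s in enumerate(rng.integers(0, 9900, 50))
        ]
        got = assign_membership(genes, ladset)
        covered = {p for iv in ladset for p in range(iv.start, iv.end)}
        for g in genes:
            assert got[g.gene_id] == (g.tss in covered)


class TestNearestDistance:
    def test_between_two_lads_plus_strand(self):
        rec = gene_to_nearest_lad(GeneRecord("g", "c", 200, 300, "+"), lads((0, 100), (500, 600)))
        assert (rec.d5, rec.d3, rec.nearest) == (100.0, 200.0, 100.0)
        assert not rec.in_lad

    def test_gene_inside_lad_uses_neighbors(self):
        rec = gene_to_nearest_lad(GeneRecord("g", "c", 520, 540, "+"), lads((0, 100), (500, 600)))
        assert rec.in_lad
        assert rec.d5 == 420.0
        assert math.isnan(rec.d3)
        assert rec.nearest == 420.0

    def test_minus_strand_mirrors(self):
        rec = gene_to_nearest_lad(GeneRecord("g", "c", 200, 300, "-"), lads((0, 100), (500, 600)))
        assert (rec.d5, rec.d3) == (200.0, 100.0)

    def test_partial_overlap_gives_zero(self):
        rec = gene_to_nearest_lad(GeneRecord("g", "c", 200, 300, "+"), lads((100, 250)))
        assert rec.d5 == 0.0

    def test_oracle_on_random_layouts(self):
        """Distances equal a brute-force border scan on random toy layouts."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            starts = np.sort(rng.choice(np.arange(0, 40_000, 500), 12, replace=False))
            ladset = lads(*[(int(s), int(s + rng.integers(100, 450))) for s in starts])
            for i in range(20):
                gs = int(rng.integers(0, 41_000))
                gene = GeneRecord(f"g{i}", "c", gs, gs + int(rng.integers(10, 400)),
                                  "+" if rng.random() < 0.5 else "-")
                rec = gene_to_nearest_lad(gene, ladset)
                exp5, exp3 = brute_force_distances(gene, ladset)
                for got, exp in ((rec.d5, exp5), (rec.d3, exp3)):
                    assert (math.isnan(got) and math.isnan(exp)) or got == exp

    def test_mirror_symmetry(self):
        """Reflecting coordinates and flipping strands swaps d5/d3."""
        size = 10_000
        ladset = lads((1_000, 2_000), (6_000, 7_000))
        mirrored = lads(*[(size - e, size - s) for s, e in ((1_000, 2_000), (6_000, 7_000))])
        rng = np.random.default_rng(32)
        for i in range(30):
            s = int(rng.integers(0, size - 300))
            e = s + int(rng.integers(10, 300))
            strand = "+" if rng.random() < 0.5 else "-"
            flip = "-" if strand == "+" else "+"
            a = gene_to_nearest_lad(GeneRecord("g", "c", s, e, strand), ladset)
            b = gene_to_nearest_lad(GeneRecord("g", "c", size - e, size - s, flip), mirrored)
            def eq(x, y):
                return (math.isnan(x) and math.isnan(y)) or x == y
            assert eq(a.d5, b.d5) and eq(a.d3, b.d3)
            assert eq(a.nearest, b.nearest)


class TestDistanceVariation:
    def test_quadrant_example(self):
        table = distance_variation({"g": 1000.0}, {"g": 400.0}, {"g": 900.0})
        row = table.iloc[0]
        assert (row["delta_a"], row["delta_b"]) == (-600.0, 500.0)
        assert row["quadrant"] == "decrease-then-increase"

    def test_origin_and_telescoping(self):
        table = distance_variation({"g": 5.0}, {"g": 5.0}, {"g": 5.0})
        assert table.iloc[0]["quadrant"] == "origin"
        rng = np.random.default_rng(33)
        d0, d1, d2 = ({"g": float(rng.integers(0, 100))} for _ in range(3))
        t = distance_variation(d0, d1, d2).iloc[0]
        assert t["delta_a"] + t["delta_b"] == d2["g"] - d0["g"]

    def test_missing_distance_excluded_with_reason(self):
        table = distance_variation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": math.nan}, {"a": 1.0, "b": 3.0})
        assert list(table["gene_id"]) == ["a"]
        assert table.attrs["excluded"][0][0] == "b"


class TestNearLads:
    def test_window_capture(self):
        ladset = lads((10_000_000, 12_000_000))
        inside_g = GeneRecord("in", "c", 10_500_000, 10_600_000, "+")
        near_g = GeneRecord("near", "c", 8_000_000, 8_100_000, "+")
        far_g = GeneRecord("far", "c", 14_600_000, 14_700_000, "+")
        near, inside = genes_near_lads([inside_g, near_g, far_g], ladset)
        assert [g.gene_id for g in near] == ["near"]
        assert [g.gene_id for g in inside] == ["in"]

    def test_matches_brute_force_window(self):
        rng = np.random.default_rng(34)
        ladset = lads((5_000, 9_000), (20_000, 21_000))
        window = 3_000
        genes = [GeneRecord(f"g{i}", "c", int(s), int(s) + 500, "+")
                 for i, s in enumerate(rng.integers(0, 30_000, 60))]
        near, inside = genes_near_lads(genes, ladset, window_bp=window)
        for g in genes:
            hit_in = any(g.start < iv.end and g.end > iv.start for iv in ladset)
            hit_near = any(g.start < iv.end + window and g.end > iv.start - window
                           for iv in ladset) and not hit_in
            assert (g in inside) == hit_in
            assert (g in near) == hit_near


class TestGeneBedIO:
    def test_roundtrip(self, tmp_path):
        genes = [GeneRecord("a", "chr1", 10, 50, "+"), GeneRecord("b", "chr2", 5, 9, "-")]
        p = tmp_path / "genes.bed"
        write_genes_bed(genes, p)
        assert read_genes_bed(p) == genes

    def test_bed3_rejected(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t0\t10\n")
        with pytest.raises(ValueError, match="BED6"):
            read_genes_bed(p)
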