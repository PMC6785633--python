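"""Synthetic-data generator: determinism, constructions, inverse consistency."""

import math

import numpy as np
import pandas as pd
import pytest

from ladcycle import TimeGrid, gene_to_nearest_lad
from ladcycle.dynamics import border_values
from ladcycle.simulate import (
    ExpressionSpec,
    GateSpec,
    LadDynamicsSpec,
    SideSpec,
    generate_expression_timecourse,
    generate_genome,
    generate_lad_timecourse,
    round_half_up,
)


class TestGenome:
    def test_deterministic_under_seed(self):
        a = generate_genome(seed=9)
        b = generate_genome(seed=9)
        assert a.base_lads == b.base_lads
        assert a.genes == b.genes
        assert a.gene_truth.equals(b.gene_truth)

    def test_no_lads_means_all_far(self):
        g = generate_genome(n_lads=0, n_genes=9, seed=0)
        assert g.base_lads == []
        assert set(g.gene_truth["placement"]) == {"far"}

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="pack"):
            generate_genome(n_chroms=1, chrom_length=2_000_000, n_lads=50, seed=0)

    def test_placement_ground_truth_holds(self):
        from ladcycle.intervals import IntervalSet

        g = generate_genome(seed=3)
        ladset = IntervalSet(tuple(r.region for r in g.base_lads), normalized=True)
        truth = g.gene_truth.set_index("gene_id")["placement"]
        covered = {(iv.chrom, p) for iv in ladset for p in range(iv.start, iv.end, 1000)}
        for gene in g.genes:
            rec = gene_to_nearest_lad(gene, ladset)
            placement = truth[gene.gene_id]
            if placement == "inside":
                assert rec.in_lad
            elif placement == "near":
                assert not rec.in_lad
                assert rec.nearest <= 2_500_000
            else:
                assert not rec.in_lad
                assert math.isnan(rec.nearest) or rec.nearest >= 5_000_000


class TestLadTimecourse:
    def setup_method(self):
        self.grid = TimeGrid.default(n_replicates=2)
        self.base = generate_genome(n_lads=6, n_genes=3, seed=1).base_lads

    def test_static_spec_reproduces_base_lads(self):
        specs = {r.lad_id: LadDynamicsSpec(r.lad_id, SideSpec("constant", 1.0),
                                           SideSpec("constant", 1.0)) for r in self.base}
        course = generate_lad_timecourse(self.base, specs, self.grid, seed=0)
        expected = tuple(sorted(r.region for r in self.base))
        for iset in course.samples.values():
            assert iset.intervals == expected
        assert course.n_clamped == 0

    def test_gated_lad_absent_in_trough(self):
        lad = self.base[0]
        specs = {r.lad_id: LadDynamicsSpec(r.lad_id, SideSpec("constant", 1.0),
                                           SideSpec("constant", 1.0)) for r in self.base}
        specs[lad.lad_id] = LadDynamicsSpec(
            lad.lad_id, SideSpec("constant", 1.0), SideSpec("constant", 1.0),
            gate=GateSpec(period_h=24.0, phase_h=0.0, threshold=0.0),
        )
        course = generate_lad_timecourse(self.base, specs, self.grid, seed=0)
        # gate cosine at CT12 is -1 < 0: the LAD must be absent there
        for rep in self.grid.replicates:
            present = {iv for iv in course.samples[("CT12", rep)]}
            assert lad.region not in present
            assert lad.region in set(course.samples[("CT0", rep)])
        truth = course.truth
        gone = truth[(truth["lad_id"] == lad.lad_id) & (truth["ct"] == "CT12")]
        assert (gone["rel"] == 0.0).all()

    def test_inverse_consistency_with_border_series(self):
        """Recovered rel values match injected ones to bp quantization."""
        rng = np.random.default_rng(14)
        specs = {}
        for i, r in enumerate(self.base):
            period = [12.0, 18.0, 24.0, 30.0][i % 4]
            moving = SideSpec("cosine", baseline=0.6, amplitude=0.4, period_h=period,
                              phase_h=6.0 * float(rng.integers(0, 5)), noise_sd=0.0)
            still = SideSpec("constant", baseline=1.0)
            specs[r.lad_id] = LadDynamicsSpec(r.lad_id, moving if i % 2 else still,
                                              still if i % 2 else moving)
        course = generate_lad_timecourse(self.base, specs, self.grid, seed=2)
        truth = course.truth.set_index(["lad_id", "side", "ct", "replicate"])["rel"]
        for record in self.base:
            for (ct, rep), iset in course.samples.items():
                rel5, rel3 = border_values(record, iset)
                for side, got in (("5p", rel5), ("3p", rel3)):
                    injected = truth[(record.lad_id, side, ct, rep)]
                    assert got == pytest.approx(injected, abs=1.0 / record.length_bp)

    def test_truth_spec_table_covers_all_borders(self):
        specs = {r.lad_id: LadDynamicsSpec(r.lad_id) for r in self.base}
        course = generate_lad_timecourse(self.base, specs, self.grid, seed=0)
        assert len(course.spec_table) == 2 * len(self.base)
        assert len(course.truth) == 2 * len(self.base) * self.grid.n_ct * self.grid.n_replicates


class TestExpressionTimecourse:
    def setup_method(self):
        self.grid = TimeGrid.default(n_replicates=3)

    def test_constant_zero_noise_identical_columns(self):
        fpkm, truth, n_trunc = generate_expression_timecourse(
            [ExpressionSpec("g", "constant", base=7.0)], self.grid, seed=0
        )
        assert (fpkm.loc["g"] == 7.0).all()
        assert n_trunc == 0

    def test_cosine_arithmetic(self):
        fpkm, _, _ = generate_expression_timecourse(
            [ExpressionSpec("g", "periodic", base=5.0, amplitude=2.0, period_h=24.0,
                            phase_h=0.0)], self.grid, seed=0
        )
        assert fpkm.loc["g", "CT0_r1"] == pytest.approx(7.0)
        assert fpkm.loc["g", "CT6_r1"] == pytest.approx(5.0)
        assert fpkm.loc["g", "CT12_r1"] == pytest.approx(3.0)

    def test_seeded_reproducibility_byte_identical(self, tmp_path):
        spec = [ExpressionSpec("g", "noise", base=2.0, noise_sd=1.0)]
        paths = []
        for name in ("a.tsv", "b.tsv"):
            fpkm, _, _ = generate_expression_timecourse(spec, self.grid, seed=123)
            p = tmp_path / name
            fpkm.to_csv(p, sep="\t")
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_negative_draws_truncated(self):
        fpkm, _, n_trunc = generate_expression_timecourse(
            [ExpressionSpec("g", "noise", base=0.1, noise_sd=5.0)], self.grid, seed=1
        )
        assert n_trunc > 0
        assert (fpkm.loc["g"] >= 0).all()


def test_round_half_up():
    assert [round_half_up(x) for x in (0.4, 0.5, 1.5, 2.49)] == [0, 1, 2, 2]
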