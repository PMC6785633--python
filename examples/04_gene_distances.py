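"""Strand-aware gene-to-nearest-LAD distances and their circadian variation.

Distances run from the gene's 5'/3' ends to the nearest 3'/5' LAD border
(respecting strand); a gene inside a LAD is measured to its first neighbors.
Changes across CT0 -> CT12 -> CT24 are summarized as signed deltas and a
quadrant label (e.g. the LAD coverage peak at CT12 pulls genes closer, then
releases them).
"""

from ladcycle import GeneRecord, IntervalSet, distance_variation, gene_to_nearest_lad

lads_by_ct = {
    "CT0": IntervalSet.from_tuples([("chr1", 1_000_000, 2_000_000)]).normalize(),
    "CT12": IntervalSet.from_tuples([("chr1", 1_000_000, 2_600_000)]).normalize(),
    "CT24": IntervalSet.from_tuples([("chr1", 1_000_000, 2_200_000)]).normalize(),
}
genes = [
    GeneRecord("plusGene", "chr1", 3_000_000, 3_050_000, "+"),
    GeneRecord("minusGene", "chr1", 3_000_000, 3_050_000, "-"),
]

nearest = {}
for ct, ladset in lads_by_ct.items():
    nearest[ct] = {}
    for gene in genes:
        rec = gene_to_nearest_lad(gene, ladset)
        nearest[ct][gene.gene_id] = rec.nearest
        print(f"{ct:>5} {gene.gene_id:>9}: d5={rec.d5}, d3={rec.d3}, nearest={rec.nearest}")

table = distance_variation(nearest["CT0"], nearest["CT12"], nearest["CT24"])
print("\nvariation over CT0 -> CT12 -> CT24 (negative = moved closer):")
print(table.to_string(index=False))
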