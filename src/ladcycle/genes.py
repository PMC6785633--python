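"""Gene-LAD geometry: membership, strand-aware distances, capture windows.

A gene belongs to a LAD when its transcription start site (TSS) lies inside
the LAD. Gene-to-nearest-LAD distance is measured from the gene's 5' and 3'
ends to, respectively, the nearest 3' and 5' LAD border, respecting strand:
for a + gene the 5' end is the lower coordinate, for a - gene the higher.
A gene entirely inside a LAD gets distances to the first *neighboring* LAD
on each side (the containing LAD is excluded). A LAD overlapping but not
containing the gene yields distance 0 on that side. Missing values mean no
LAD exists on that side of the gene's chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import IntervalSet


@dataclass(frozen=True)
class GeneRecord:
    """A stranded gene with 0-based half-open body coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid gene body {self.gene_id}: {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        """Transcription start site: start for +, end-1 for - genes."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class DistanceRecord:
    gene_id: str
    in_lad: bool
    d5: float  # bp from the gene's 5' end to the nearest 3' LAD border; NaN if none
    d3: float  # bp from the gene's 3' end to the nearest 5' LAD border; NaN if none

    @property
    def nearest(self) -> float:
        present = [d for d in (self.d5, self.d3) if not math.isnan(d)]
        return min(present) if present else math.nan


def read_genes_bed(path: str | Path) -> list[GeneRecord]:
    """Read genes from BED6 (name = gene id, strand column required)."""
    path = Path(path)
    genes: list[GeneRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 with strand required for genes")
            try:
                genes.append(
                    GeneRecord(fields[3], fields[0], int(fields[1]), int(fields[2]), fields[5])
                )
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from err
    return genes


def write_genes_bed(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def assign_membership(genes: Iterable[GeneRecord], lads: IntervalSet) -> dict[str, bool]:
    """True per gene iff its single-bp TSS lies inside a LAD."""
    norm = lads.normalize()
    return {g.gene_id: norm.containing(g.chrom, g.tss) is not None for g in genes}


def gene_to_nearest_lad(gene: GeneRecord, lads: IntervalSet) -> DistanceRecord:
    """Strand-respecting distances from one gene to its nearest LAD borders."""
    norm = lads.normalize()
    containing = None
    for iv in norm.intervals:
        if iv.chrom == gene.chrom and iv.start <= gene.start and iv.end >= gene.end:
            containing = iv
            break
    in_lad = norm.containing(gene.chrom, gene.tss) is not None

    left_ends = [
        iv.end
        for iv in norm.intervals
        if iv.chrom == gene.chrom and iv != containing and iv.start < gene.start
    ]
    right_starts = [
        iv.start
        for iv in norm.intervals
        if iv.chrom == gene.chrom and iv != containing and iv.end > gene.end
    ]
    d_left = max(0, gene.start - max(left_ends)) if left_ends else math.nan
    d_right = max(0, min(right_starts) - gene.end) if right_starts else math.nan
    if gene.strand == "+":
        d5, d3 = d_left, d_right
    else:
        d5, d3 = d_right, d_left
    return DistanceRecord(gene.gene_id, in_lad, float(d5), float(d3))


def distance_table(
    genes: Sequence[GeneRecord], lads_by_ct: Mapping[str, IntervalSet]
) -> pd.DataFrame:
    """Per-(gene, CT) distance records as a long table."""
    rows = []
    for ct, lads in lads_by_ct.items():
        norm = lads.normalize()
        for gene in genes:
            rec = gene_to_nearest_lad(gene, norm)
            rows.append((gene.gene_id, ct, rec.in_lad, rec.d5, rec.d3, rec.nearest))
    return pd.DataFrame(rows, columns=["gene_id", "ct", "in_lad", "d5", "d3", "nearest"])


_QUADRANTS = {
    (1, 1): "increase-then-increase",
    (-1, 1): "decrease-then-increase",
    (-1, -1): "decrease-then-decrease",
    (1, -1): "increase-then-decrease",
}


def distance_variation(
    d_first: Mapping[str, float],
    d_mid: Mapping[str, float],
    d_last: Mapping[str, float],
) -> pd.DataFrame:
    """Signed changes in nearest-LAD distance over two equal time intervals.

    delta_a = nearest(mid) - nearest(first), delta_b = nearest(last) -
    nearest(mid) (negative = the gene moved closer to a LAD). The quadrant
    label combines the two signs; zero on either axis yields an on-axis
    category. Genes with a missing distance at any of the three CTs are
    excluded and reported with a reason.
    """
    rows = []
    excluded = []
    for gene_id in d_first:
        vals = (d_first.get(gene_id), d_mid.get(gene_id), d_last.get(gene_id))
        if any(v is None or math.isnan(v) for v in vals):
            excluded.append((gene_id, "missing nearest-LAD distance at one or more CTs"))
            continue
        da = vals[1] - vals[0]
        db = vals[2] - vals[1]
        sa, sb = int(math.copysign(1, da)) if da else 0, int(math.copysign(1, db)) if db else 0
        if sa == 0 and sb == 0:
            quadrant = "origin"
        elif sa == 0 or sb == 0:
            quadrant = "on-axis"
        else:
            quadrant = _QUADRANTS[(sa, sb)]
        rows.append((gene_id, da, db, quadrant))
    table = pd.DataFrame(rows, columns=["gene_id", "delta_a", "delta_b", "quadrant"])
    table.attrs["excluded"] = excluded
    return table


def genes_near_lads(
    genes: Sequence[GeneRecord],
    regions: IntervalSet,
    window_bp: int = 2_500_000,
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Genes whose body falls within ``window_bp`` of a region's 5'/3' end.

    Returns (near, inside): genes overlapping the widened window but not the
    region itself, and genes overlapping the region (reported separately).
    """
    if window_bp < 0:
        raise ValueError("window must be >= 0")
    norm = regions.normalize()
    near: list[GeneRecord] = []
    inside: list[GeneRecord] = []
    for gene in genes:
        hit_inside = False
        hit_near = False
        for iv in norm.intervals:
            if iv.chrom != gene.chrom:
                continue
            if gene.start < iv.end and gene.end > iv.start:
                hit_inside = True
                break
            if gene.start < iv.end + window_bp and gene.end > iv.start - window_bp:
                hit_near = True
        if hit_inside:
            inside.append(gene)
        elif hit_near:
            near.append(gene)
    return near, inside
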