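"""Per-LAD footprints and border time series across circadian time.

Each LAD's *maximal coverage* (cov_max) is the union of its coverage over
all circadian time points and replicates; it gets the reference value 1.
For every sample, the LAD's 5' and 3' extremities are standardized to a
relative length in [0, 1] against the cov_max limits: 1 means the border
reaches the cov_max limit on that side, 0 means the LAD is absent from the
sample. Internal configuration inside cov_max (splits, fusions) is ignored:
only the outermost extremities count. 5' is the lower genomic coordinate
(reference-strand convention); LADs are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, union_all

SIDE_5 = "5p"
SIDE_3 = "3p"


@dataclass(frozen=True)
class CovMaxRecord:
    """The maximal footprint of one LAD across all samples."""

    lad_id: str
    chrom: str
    start: int
    end: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def region(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def compute_covmax(lad_sets: Iterable[IntervalSet], id_prefix: str = "LAD") -> list[CovMaxRecord]:
    """Union of LAD coverage over all samples, one record per merged region.

    Records are disjoint, ordered by (chrom, start), with stable identifiers
    assigned in that order.
    """
    merged = union_all(lad_sets, label="cov_max")
    return [
        CovMaxRecord(f"{id_prefix}{i + 1:04d}", iv.chrom, iv.start, iv.end)
        for i, iv in enumerate(merged.intervals)
    ]


def covmax_frame(records: Iterable[CovMaxRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.lad_id, r.chrom, r.start, r.end, r.length_bp) for r in records],
        columns=["lad_id", "chrom", "start", "end", "length_bp"],
    )


def border_values(record: CovMaxRecord, sample: IntervalSet) -> tuple[float, float]:
    """Relative 5' and 3' lengths of one LAD in one sample.

    With cov_max [S, E) of length L and the sample's fragments inside it
    spanning [a, b): rel5 = 1 - (a - S)/L and rel3 = 1 - (E - b)/L. No
    fragment present gives (0, 0). A fragment straddling the cov_max limit
    indicates the cov_max was not built from this sample set and raises.
    """
    s, e = record.start, record.end
    length = record.length_bp
    frags = [
        iv
        for iv in sample.normalize().intervals
        if iv.chrom == record.chrom and iv.start < e and iv.end > s
    ]
    if not frags:
        return 0.0, 0.0
    for iv in frags:
        if iv.start < s or iv.end > e:
            raise ValueError(
                f"fragment {iv.chrom}:{iv.start}-{iv.end} extends outside cov_max "
                f"{record.lad_id} ({record.chrom}:{s}-{e})"
            )
    a = min(iv.start for iv in frags)
    b = max(iv.end for iv in frags)
    rel5 = 1.0 - (a - s) / length
    rel3 = 1.0 - (e - b) / length
    return rel5, rel3


def border_series_table(
    records: Iterable[CovMaxRecord],
    sample_sets: Mapping[tuple[str, str], IntervalSet],
) -> pd.DataFrame:
    """Long table of border values: lad_id, side, ct, replicate, value.

    ``sample_sets`` maps (ct_label, replicate_label) to that sample's LADs.
    """
    rows = []
    for record in records:
        for (ct, rep), iset in sample_sets.items():
            rel5, rel3 = border_values(record, iset)
            rows.append((record.lad_id, SIDE_5, ct, rep, rel5))
            rows.append((record.lad_id, SIDE_3, ct, rep, rel3))
    return pd.DataFrame(rows, columns=["lad_id", "side", "ct", "replicate", "value"])


# -- gain/loss decomposition ----------------------------------------------


def classify_gain_loss(reference: IntervalSet, comparison: IntervalSet) -> pd.DataFrame:
    """Decompose coverage differences into stand-alone vs extension changes.

    Gained regions (comparison minus reference) are "stand-alone" when the
    containing comparison LAD has zero overlap with the reference set, else
    "extension". Lost regions (reference minus comparison) are "stand-alone"
    when the containing reference LAD has no overlap with the comparison,
    else "shortening". A region book-ended to an existing LAD counts as an
    extension of it.
    """
    ref = reference.normalize()
    comp = comparison.normalize()
    rows = []
    for direction, regions, container_set, other_set, partial_mode in (
        ("gained", comp.subtract(ref), comp, ref, "extension"),
        ("lost", ref.subtract(comp), ref, comp, "shortening"),
    ):
        for iv in regions.intervals:
            parent = container_set.containing(iv.chrom, iv.start)
            assert parent is not None
            overlap = IntervalSet((parent,), normalized=True).intersect(other_set).coverage()
            mode = "stand-alone" if overlap == 0 else partial_mode
            rows.append((iv.chrom, iv.start, iv.end, direction, mode, iv.length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "mode", "bp"])


def gain_loss_totals(records: pd.DataFrame) -> pd.DataFrame:
    """Total bp per (direction, mode), including zero rows for all combos."""
    idx = pd.MultiIndex.from_tuples(
        [
            ("gained", "stand-alone"),
            ("gained", "extension"),
            ("lost", "stand-alone"),
            ("lost", "shortening"),
        ],
        names=["direction", "mode"],
    )
    if records.empty:
        totals = pd.Series(0, index=idx, name="bp")
    else:
        totals = records.groupby(["direction", "mode"])["bp"].sum().reindex(idx, fill_value=0)
        totals.name = "bp"
    return totals.reset_index()


def lad_stats(sets_by_ct: Mapping[str, IntervalSet]) -> pd.DataFrame:
    """Per-CT coverage (bp), LAD count and median LAD size."""
    rows = []
    for ct, iset in sets_by_ct.items():
        norm = iset.normalize()
        sizes = [iv.length for iv in norm.intervals]
        median = float(np.median(sizes)) if sizes else np.nan
        rows.append((ct, norm.coverage(), len(sizes), median))
    return pd.DataFrame(rows, columns=["ct", "coverage_bp", "n_lads", "median_size_bp"])
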