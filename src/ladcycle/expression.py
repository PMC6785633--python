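"""Periodicity classification of gene expression time courses.

FPKM series (genes x CT-by-replicate samples) are z-score normalized per
gene and replicate, fitted with the rhythm engine, and classified:
"periodic-<g>" when the combined p is below the stringent threshold and the
mean period falls in group g (12/18/24/30 h +- 3 h), "periodic-other" when
significant with a period outside all groups, "not-significant" otherwise.
A separate "non-periodic" reference set collects genes whose fit is
actively discordant with any cosine (1 > p > 0.9999).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .grid import TimeGrid
from .rhythm import meta_fit, zscore_normalize

STRONG_P = 0.005
RELAXED_P = 0.05
NONPERIODIC_LOWER = 0.9999


@dataclass(frozen=True)
class ExpressionMatrix:
    """FPKM values per gene over (CT, replicate) samples."""

    fpkm: pd.DataFrame  # index: gene_id; columns: "<CT>_<rep>"
    grid: TimeGrid

    def __post_init__(self) -> None:
        expected = [self.grid.sample_name(ct, rep) for ct, rep in self.grid.samples()]
        missing = [c for c in expected if c not in self.fpkm.columns]
        if missing:
            raise ValueError(f"FPKM matrix is missing sample columns: {missing}")
        if (self.fpkm[expected] < 0).any().any():
            raise ValueError("FPKM values must be non-negative")

    @classmethod
    def read_tsv(cls, path: str | Path, grid: TimeGrid) -> "ExpressionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame, grid)

    def expressed(self, threshold: float = 0.0) -> pd.Series:
        """A gene is expressed iff FPKM > threshold in at least one sample."""
        cols = [self.grid.sample_name(ct, rep) for ct, rep in self.grid.samples()]
        return (self.fpkm[cols] > threshold).any(axis=1)

    def series(self, gene_id: str) -> np.ndarray:
        """(n_replicates, n_ct) array of FPKM values for one gene."""
        out = np.empty((self.grid.n_replicates, self.grid.n_ct))
        for i, rep in enumerate(self.grid.replicates):
            for j, ct in enumerate(self.grid.ct_labels):
                out[i, j] = self.fpkm.at[gene_id, self.grid.sample_name(ct, rep)]
        return out


def classify_periodic(
    matrix: ExpressionMatrix,
    *,
    strong_p: float = STRONG_P,
    expressed_threshold: float = 0.0,
    **engine_kwargs,
) -> tuple[pd.DataFrame, list[str]]:
    """Fit every expressed gene and assign a periodicity class.

    Returns (results, excluded): a per-gene table of rhythm-fit fields plus
    ``cls``, and the gene ids excluded as unexpressed.
    """
    expressed = matrix.expressed(expressed_threshold)
    excluded = [g for g, keep in expressed.items() if not keep]
    rows = []
    times = np.asarray(matrix.grid.times_h)
    for gene_id in matrix.fpkm.index[expressed]:
        raw = matrix.series(gene_id)
        z = np.vstack([zscore_normalize(row) for row in raw])
        fit = meta_fit(z, times, series_id=gene_id, **engine_kwargs)
        if fit.p_combined < strong_p:
            cls = f"periodic-{fit.period_group}" if fit.period_group else "periodic-other"
        else:
            cls = "not-significant"
        rows.append(
            (
                gene_id,
                fit.p_jtk,
                fit.p_ls,
                fit.p_combined,
                fit.period_jtk,
                fit.period_ls,
                fit.period_mean,
                fit.phase_h,
                fit.amplitude,
                fit.base,
                fit.period_group,
                fit.phase_group,
                cls,
            )
        )
    results = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "p_jtk",
            "p_ls",
            "p_combined",
            "period_jtk",
            "period_ls",
            "period_mean",
            "phase_h",
            "amplitude",
            "base",
            "period_group",
            "phase_group",
            "cls",
        ],
    )
    return results, excluded


def classify_nonperiodic(results: pd.DataFrame, lower: float = NONPERIODIC_LOWER) -> pd.Index:
    """Genes actively discordant with any cosine fit: 1 > p_combined > lower.

    The bounds are strict on both sides: p = 1 (no information at all, e.g.
    a constant series) is excluded.
    """
    mask = (results["p_combined"] > lower) & (results["p_combined"] < 1.0)
    return pd.Index(results.loc[mask, "gene_id"])


def periodic_genes_in_lads(
    results: pd.DataFrame,
    membership_by_ct: Mapping[str, Mapping[str, bool]],
) -> pd.Series:
    """Per-CT fraction of significantly periodic genes whose TSS is in a LAD."""
    periodic = results.loc[results["cls"].str.startswith("periodic"), "gene_id"]
    out = {}
    for ct, membership in membership_by_ct.items():
        if len(periodic) == 0:
            out[ct] = np.nan
        else:
            out[ct] = float(np.mean([bool(membership[g]) for g in periodic]))
    return pd.Series(out, name="fraction_periodic_in_lads")
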