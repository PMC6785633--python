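"""Shared fixtures and brute-force oracles for the test suite.

The oracles here are deliberately naive (per-bp membership sets, full
permutation enumeration, closed-form formulas) and independent of the
implementation paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from ladcycle import GenomicInterval, IntervalSet, TimeGrid
from ladcycle.genes import GeneRecord
from ladcycle.rhythm import _kendall_s


@pytest.fixture
def grid6() -> TimeGrid:
    return TimeGrid.default(n_replicates=2)


@pytest.fixture
def times6() -> np.ndarray:
    return np.arange(0.0, 31.0, 6.0)


# -- per-bp interval oracle -------------------------------------------------


def bp_set(iset: IntervalSet) -> set[tuple[str, int]]:
    """Every covered (chrom, position) pair; exact but O(coverage)."""
    out: set[tuple[str, int]] = set()
    for iv in iset:
        for pos in range(iv.start, iv.end):
            out.add((iv.chrom, pos))
    return out


def random_interval_set(
    rng: np.random.Generator,
    chroms: tuple[str, ...] = ("chrA", "chrB"),
    genome_len: int = 2_000,
    n_intervals: int = 20,
    label: str = "",
) -> IntervalSet:
    ivs = []
    for _ in range(n_intervals):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, genome_len - 1))
        end = int(rng.integers(start + 1, min(genome_len, start + 200) + 1))
        ivs.append(GenomicInterval(chrom, start, end))
    return IntervalSet(tuple(ivs), label=label)


# -- JTK enumeration oracle -------------------------------------------------


def jtk_pattern_groups(ref: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Stable order and tie-group sizes of a reference pattern."""
    order = np.argsort(ref, kind="stable")
    ref_ord = ref[order]
    sizes = []
    run = 1
    for a, b in zip(ref_ord, ref_ord[1:]):
        if b == a:
            run += 1
        else:
            sizes.append(run)
            run = 1
    sizes.append(run)
    return order, sizes


def enumerated_pattern_p(y: np.ndarray, ref: np.ndarray) -> float:
    """P(|S| >= |S_obs|) over all n! permutations of the observed values."""
    order, sizes = jtk_pattern_groups(ref)
    s_obs = _kendall_s(y[order], sizes)
    hits = total = 0
    for perm in itertools.permutations(y):
        s = _kendall_s(np.asarray(perm)[order], sizes)
        hits += abs(s) >= abs(s_obs)
        total += 1
    return hits / total


# -- classical Lomb-Scargle reference --------------------------------------


def lomb_power_direct(y: np.ndarray, t: np.ndarray, freq: float) -> float:
    """Textbook Lomb periodogram at one ordinary frequency, mean-subtracted."""
    y = y - y.mean()
    w = 2.0 * np.pi * freq
    tau = np.arctan2(np.sum(np.sin(2 * w * t)), np.sum(np.cos(2 * w * t))) / (2 * w)
    c = np.cos(w * (t - tau))
    s = np.sin(w * (t - tau))
    return 0.5 * ((y @ c) ** 2 / (c @ c) + (y @ s) ** 2 / (s @ s))


# -- gene-distance brute-force oracle ---------------------------------------


def brute_force_distances(gene: GeneRecord, ladset: IntervalSet):
    """Naive scan over all LAD borders, excluding a gene-containing LAD."""
    containing = None
    for iv in ladset.normalize():
        if iv.chrom == gene.chrom and iv.start <= gene.start and iv.end >= gene.end:
            containing = iv
    left = [iv.end for iv in ladset if iv.chrom == gene.chrom and iv != containing
            and iv.start < gene.start]
    right = [iv.start for iv in ladset if iv.chrom == gene.chrom and iv != containing
             and iv.end > gene.end]
    d_left = max(0, gene.start - max(left)) if left else math.nan
    d_right = max(0, min(right) - gene.end) if right else math.nan
    return (d_left, d_right) if gene.strand == "+" else (d_right, d_left)
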