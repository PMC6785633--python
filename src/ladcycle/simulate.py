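"""Synthetic LAD time courses and expression matrices with known rhythms.

The generator emulates the measured quantities of a circadian LAD study on
a toy genome: per-(CT, replicate) LAD interval sets whose 5'/3' borders
oscillate as cosines of the relative length rel(t) = clamp(baseline +
amplitude*cos(2*pi*(t - phase)/period) + noise, 0, 1) inside a fixed base
(cov_max) region, including LADs that entirely appear and disappear through
a cosine gate; stranded genes placed inside, near, and far from LADs with
recorded ground truth; and FPKM series that are cosine-periodic, noisy and
aperiodic, or constant. Everything is deterministic under an explicit seed
and emitted in exactly the pipeline's input formats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import CovMaxRecord
from .genes import GeneRecord
from .grid import TimeGrid
from .intervals import GenomicInterval, IntervalSet


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-free: floor(x+0.5)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SideSpec:
    """Dynamics of one LAD border's relative length in [0, 1]."""

    mode: str = "constant"  # constant | noise | cosine
    baseline: float = 0.8
    amplitude: float = 0.0  # fraction of the cov_max length
    period_h: float = 24.0
    phase_h: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "noise", "cosine"):
            raise ValueError(f"unknown side mode {self.mode!r}")


@dataclass(frozen=True)
class GateSpec:
    """Whole-LAD appearance gate: present iff cos(2pi(t-phase)/period) >= threshold."""

    period_h: float = 24.0
    phase_h: float = 0.0
    threshold: float = 0.0


@dataclass(frozen=True)
class LadDynamicsSpec:
    lad_id: str
    side5: SideSpec = field(default_factory=SideSpec)
    side3: SideSpec = field(default_factory=SideSpec)
    gate: GateSpec | None = None


@dataclass(frozen=True)
class ExpressionSpec:
    """Ground-truth expression class of one gene."""

    gene_id: str
    label: str = "constant"  # periodic | noise | constant
    base: float = 10.0
    amplitude: float = 0.0
    period_h: float = 24.0
    phase_h: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in ("periodic", "noise", "constant"):
            raise ValueError(f"unknown expression label {self.label!r}")


@dataclass
class Genome:
    chrom_lengths: dict[str, int]
    base_lads: list[CovMaxRecord]
    genes: list[GeneRecord]
    gene_truth: pd.DataFrame  # gene_id, placement, anchor_lad


@dataclass
class LadTimecourse:
    samples: dict[tuple[str, str], IntervalSet]
    ns_samples: dict[str, IntervalSet]
    truth: pd.DataFrame  # lad_id, side, ct, replicate, rel
    spec_table: pd.DataFrame
    n_clamped: int


# -- genome layout ---------------------------------------------------------


def generate_genome(
    n_chroms: int = 2,
    chrom_length: int = 60_000_000,
    n_lads: int = 40,
    n_genes: int = 120,
    seed: int = 0,
    lad_size: tuple[int, int] = (300_000, 900_000),
    gene_size: tuple[int, int] = (5_000, 50_000),
    near_window_bp: int = 2_500_000,
    far_distance_bp: int = 5_000_000,
) -> Genome:
    """Toy genome with non-overlapping base LADs and placed, stranded genes.

    LADs occupy the first 60% of each chromosome in evenly spaced slots with
    random jitter; the tail of each chromosome stays LAD-free so that "far"
    genes can sit >= ``far_distance_bp`` from any LAD. Gene placements cycle
    inside -> near -> far and are recorded as ground truth.
    """
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    chrom_lengths = {c: int(chrom_length) for c in chroms}

    per_chrom = [n_lads // n_chroms + (1 if i < n_lads % n_chroms else 0) for i in range(n_chroms)]
    lad_region = int(0.6 * chrom_length)
    records: list[CovMaxRecord] = []
    idx = 0
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        slot = lad_region // k
        if slot < lad_size[1] + 40_000:
            raise ValueError("cannot pack the requested LADs: increase chrom_length or reduce n_lads")
        for j in range(k):
            size = int(rng.integers(lad_size[0], lad_size[1] + 1))
            room = slot - size - 20_000
            start = j * slot + 10_000 + int(rng.integers(0, room + 1))
            idx += 1
            records.append(CovMaxRecord(f"LAD{idx:04d}", chrom, start, start + size))
    records.sort(key=lambda r: (r.chrom, r.start))

    by_chrom: dict[str, list[CovMaxRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)

    genes: list[GeneRecord] = []
    truth_rows = []
    placements = ["inside", "near", "far"]
    for g in range(n_genes):
        placement = placements[g % 3] if records else "far"
        gene_id = f"gene{g + 1:04d}"
        length = int(rng.integers(gene_size[0], gene_size[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        if placement == "inside":
            lad = records[int(rng.integers(0, len(records)))]
            start = lad.start + int(rng.integers(0, max(1, lad.length_bp - length)))
            anchor = lad.lad_id
            chrom = lad.chrom
        elif placement == "near":
            lad = records[int(rng.integers(0, len(records)))]
            chrom = lad.chrom
            siblings = by_chrom[chrom]
            i = siblings.index(lad)
            limit_r = siblings[i + 1].start if i + 1 < len(siblings) else chrom_lengths[chrom]
            limit_l = siblings[i - 1].end if i > 0 else 0
            d_max_r = min(near_window_bp - length, limit_r - lad.end - length) - 10_000
            d_max_l = min(near_window_bp - length, lad.start - limit_l - length) - 10_000
            sides = [s for s, d_max in (("right", d_max_r), ("left", d_max_l)) if d_max > 10_000]
            if not sides:
                raise ValueError("no room next to LADs for near genes; widen LAD gaps")
            side = sides[int(rng.integers(0, len(sides)))]
            d_max = d_max_r if side == "right" else d_max_l
            d = int(rng.integers(10_000, d_max + 1))
            start = lad.end + d if side == "right" else lad.start - d - length
            anchor = lad.lad_id
        else:  # far
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            lo = lad_region + far_distance_bp
            hi = chrom_lengths[chrom] - length
            if hi <= lo:
                raise ValueError("no LAD-free room for far genes; increase chrom_length")
            start = int(rng.integers(lo, hi))
            anchor = ""
        genes.append(GeneRecord(gene_id, chrom, start, start + length, strand))
        truth_rows.append((gene_id, placement, anchor))

    gene_truth = pd.DataFrame(truth_rows, columns=["gene_id", "placement", "anchor_lad"])
    return Genome(chrom_lengths, records, genes, gene_truth)


# -- LAD time courses ------------------------------------------------------


def _realize_rel(spec: SideSpec, t: float, rng: np.random.Generator) -> tuple[float, bool]:
    """One draw of a border's relative length; returns (value, clamped)."""
    value = spec.baseline
    if spec.mode == "cosine":
        value += spec.amplitude * math.cos(2.0 * math.pi * (t - spec.phase_h) / spec.period_h)
    if spec.mode in ("noise", "cosine") and spec.noise_sd > 0:
        value += rng.normal(0.0, spec.noise_sd)
    clamped = value < 0.0 or value > 1.0
    return min(1.0, max(0.0, value)), clamped


def generate_lad_timecourse(
    base_lads: Sequence[CovMaxRecord],
    specs: Mapping[str, LadDynamicsSpec],
    grid: TimeGrid,
    seed: int = 0,
    emit_ns: bool = False,
) -> LadTimecourse:
    """Realize per-(CT, replicate) LAD sets from border dynamics specs.

    Borders are rounded to integer bp (half-up). A realization whose borders
    would cross, or that is shut by the gate, is emitted as an absent LAD
    (truth rel values 0 on both sides); crossings count as clamping events.
    """
    rng = np.random.default_rng(seed)
    samples: dict[tuple[str, str], IntervalSet] = {}
    truth_rows = []
    n_clamped = 0
    ordered = sorted(base_lads, key=lambda r: (r.chrom, r.start))

    for ct, t in zip(grid.ct_labels, grid.times_h):
        for rep in grid.replicates:
            intervals = []
            for lad in ordered:
                spec = specs[lad.lad_id]
                present = True
                if spec.gate is not None:
                    gate_val = math.cos(
                        2.0 * math.pi * (t - spec.gate.phase_h) / spec.gate.period_h
                    )
                    present = gate_val >= spec.gate.threshold
                rel5, c5 = _realize_rel(spec.side5, t, rng)
                rel3, c3 = _realize_rel(spec.side3, t, rng)
                n_clamped += int(c5) + int(c3)
                if not present or rel5 <= 0.0 or rel3 <= 0.0:
                    rel5 = rel3 = 0.0
                else:
                    length = lad.length_bp
                    start = lad.start + round_half_up((1.0 - rel5) * length)
                    end = lad.end - round_half_up((1.0 - rel3) * length)
                    if start >= end:
                        n_clamped += 1
                        rel5 = rel3 = 0.0
                    else:
                        intervals.append(GenomicInterval(lad.chrom, start, end))
                truth_rows.append((lad.lad_id, "5p", ct, rep, rel5))
                truth_rows.append((lad.lad_id, "3p", ct, rep, rel3))
            samples[(ct, rep)] = IntervalSet(
                tuple(sorted(intervals)), label=grid.sample_name(ct, rep), normalized=True
            )

    ns_samples: dict[str, IntervalSet] = {}
    if emit_ns:
        for rep in grid.replicates:
            intervals = []
            for lad in ordered:
                spec = specs[lad.lad_id]
                rel5, _ = _realize_rel(
                    SideSpec("noise", spec.side5.baseline, noise_sd=spec.side5.noise_sd), 0.0, rng
                )
                rel3, _ = _realize_rel(
                    SideSpec("noise", spec.side3.baseline, noise_sd=spec.side3.noise_sd), 0.0, rng
                )
                length = lad.length_bp
                start = lad.start + round_half_up((1.0 - rel5) * length)
                end = lad.end - round_half_up((1.0 - rel3) * length)
                if start < end:
                    intervals.append(GenomicInterval(lad.chrom, start, end))
            ns_samples[rep] = IntervalSet(
                tuple(sorted(intervals)), label=f"NS_{rep}", normalized=True
            )

    truth = pd.DataFrame(truth_rows, columns=["lad_id", "side", "ct", "replicate", "rel"])
    spec_rows = []
    for lad in ordered:
        spec = specs[lad.lad_id]
        for side_name, side in (("5p", spec.side5), ("3p", spec.side3)):
            spec_rows.append(
                (
                    lad.lad_id,
                    side_name,
                    side.mode,
                    side.baseline,
                    side.amplitude,
                    side.period_h,
                    side.phase_h,
                    side.noise_sd,
                    spec.gate is not None,
                    spec.gate.period_h if spec.gate else np.nan,
                )
            )
    spec_table = pd.DataFrame(
        spec_rows,
        columns=[
            "lad_id",
            "side",
            "mode",
            "baseline",
            "amplitude",
            "period_h",
            "phase_h",
            "noise_sd",
            "gated",
            "gate_period_h",
        ],
    )
    return LadTimecourse(samples, ns_samples, truth, spec_table, n_clamped)


def default_lad_specs(
    base_lads: Sequence[CovMaxRecord],
    seed: int = 0,
    periods: Sequence[float] = (12.0, 18.0, 24.0, 30.0),
    amplitude: float = 0.4,
    baseline: float = 0.6,
    noise_sd: float = 0.05,
    fraction_periodic: float = 0.5,
    fraction_noise: float = 0.25,
    fraction_gated: float = 0.1,
) -> dict[str, LadDynamicsSpec]:
    """A study-like mixture of border dynamics.

    Half the LADs carry a cosine border on one side (periods cycling through
    12/18/24/30 h, random phase on the grid), a quarter are noise-only, a
    tenth appear/disappear through a 24 h gate, and the rest are constant.
    Amplitude 0.4 and noise sd 0.05 mirror a clearly variable border against
    replicate-level measurement scatter.
    """
    rng = np.random.default_rng(seed)
    specs: dict[str, LadDynamicsSpec] = {}
    ordered = sorted(base_lads, key=lambda r: (r.chrom, r.start))
    n = len(ordered)
    n_periodic = int(round(fraction_periodic * n))
    n_noise = int(round(fraction_noise * n))
    n_gated = int(round(fraction_gated * n))
    for i, lad in enumerate(ordered):
        if i < n_periodic:
            period = periods[i % len(periods)]
            phase = float(rng.integers(0, 5)) * 6.0
            moving = SideSpec("cosine", baseline, amplitude, period, phase, noise_sd)
            still = SideSpec("noise", baseline + amplitude, noise_sd=noise_sd)
            side5, side3 = (moving, still) if i % 2 == 0 else (still, moving)
            specs[lad.lad_id] = LadDynamicsSpec(lad.lad_id, side5, side3)
        elif i < n_periodic + n_noise:
            specs[lad.lad_id] = LadDynamicsSpec(
                lad.lad_id,
                SideSpec("noise", baseline, noise_sd=noise_sd),
                SideSpec("noise", baseline, noise_sd=noise_sd),
            )
        elif i < n_periodic + n_noise + n_gated:
            specs[lad.lad_id] = LadDynamicsSpec(
                lad.lad_id,
                SideSpec("noise", 1.0, noise_sd=noise_sd),
                SideSpec("noise", 1.0, noise_sd=noise_sd),
                gate=GateSpec(24.0, float(rng.integers(0, 5)) * 6.0, 0.0),
            )
        else:
            specs[lad.lad_id] = LadDynamicsSpec(lad.lad_id)
    return specs


# -- expression time courses -----------------------------------------------


def generate_expression_timecourse(
    specs: Sequence[ExpressionSpec],
    grid: TimeGrid,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """FPKM matrix (genes x CT-by-replicate) from per-gene rhythm specs.

    FPKM(t) = max(0, base + amplitude*cos(2pi(t - phase)/period) + noise)
    for periodic genes; negative draws are truncated at 0 and counted.
    Returns (fpkm, truth, n_truncated).
    """
    rng = np.random.default_rng(seed)
    columns = [grid.sample_name(ct, rep) for ct, rep in grid.samples()]
    data = {}
    n_truncated = 0
    for spec in specs:
        row = []
        for ct, t in zip(grid.ct_labels, grid.times_h):
            for _rep in grid.replicates:
                value = spec.base
                if spec.label == "periodic":
                    value += spec.amplitude * math.cos(
                        2.0 * math.pi * (t - spec.phase_h) / spec.period_h
                    )
                if spec.label in ("periodic", "noise") and spec.noise_sd > 0:
                    value += rng.normal(0.0, spec.noise_sd)
                if value < 0:
                    n_truncated += 1
                    value = 0.0
                row.append(value)
        data[spec.gene_id] = row
    sample_order = [grid.sample_name(ct, rep) for ct in grid.ct_labels for rep in grid.replicates]
    fpkm = pd.DataFrame.from_dict(data, orient="index", columns=sample_order)
    fpkm = fpkm[columns]
    fpkm.index.name = "gene_id"
    truth = pd.DataFrame(
        [
            (s.gene_id, s.label, s.base, s.amplitude, s.period_h, s.phase_h, s.noise_sd)
            for s in specs
        ],
        columns=["gene_id", "label", "base", "amplitude", "period_h", "phase_h", "noise_sd"],
    )
    return fpkm, truth, n_truncated


def default_expression_specs(
    genes: Sequence[GeneRecord],
    seed: int = 0,
    periods: Sequence[float] = (12.0, 18.0, 24.0, 30.0),
    base: float = 10.0,
    amplitude: float = 4.0,
    noise_sd: float = 1.0,
    fraction_periodic: float = 0.4,
    fraction_noise: float = 0.3,
) -> list[ExpressionSpec]:
    """A study-like class mixture: periodic, noisy-aperiodic, constant genes.

    The default 4:1 amplitude-to-noise ratio corresponds to a clearly
    rhythmic transcript over biological replicate scatter.
    """
    rng = np.random.default_rng(seed)
    n = len(genes)
    n_periodic = int(round(fraction_periodic * n))
    n_noise = int(round(fraction_noise * n))
    specs = []
    for i, gene in enumerate(genes):
        if i < n_periodic:
            specs.append(
                ExpressionSpec(
                    gene.gene_id,
                    "periodic",
                    base=base,
                    amplitude=amplitude,
                    period_h=periods[i % len(periods)],
                    phase_h=float(rng.integers(0, 5)) * 6.0,
                    noise_sd=noise_sd,
                )
            )
        elif i < n_periodic + n_noise:
            specs.append(ExpressionSpec(gene.gene_id, "noise", base=base, noise_sd=noise_sd))
        else:
            specs.append(ExpressionSpec(gene.gene_id, "constant", base=base))
    return specs
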