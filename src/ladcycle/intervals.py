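"""Genomic interval sets with exact base-pair algebra and BED I/O.

Coordinates are 0-based, half-open (BED convention). An :class:`IntervalSet`
is the unit of all LAD computations: one sample (e.g. one circadian time
point x one replicate). Normalization sorts intervals by (chrom, start) and
fuses overlapping *and book-ended* intervals, since domain callers emit
contiguous domains and book-ended pieces are indistinguishable in coverage
terms. All set operations require normalized operands and are exact in bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple


class GenomicInterval(NamedTuple):
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _validated(chrom: str, start: int, end: int) -> GenomicInterval:
    start = int(start)
    end = int(end)
    if start < 0 or start >= end:
        raise ValueError(f"invalid interval {chrom}:{start}-{end} (need 0 <= start < end)")
    return GenomicInterval(str(chrom), start, end)


@dataclass(frozen=True)
class IntervalSet:
    """An immutable collection of genomic intervals with a sample label."""

    intervals: tuple[GenomicInterval, ...]
    label: str = ""
    normalized: bool = field(default=False, compare=False)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple], label: str = "") -> "IntervalSet":
        ivs = tuple(_validated(*t[:3]) for t in tuples)
        return cls(ivs, label=label)

    @classmethod
    def empty(cls, label: str = "") -> "IntervalSet":
        return cls((), label=label, normalized=True)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def by_chrom(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return out

    def coverage(self) -> int:
        """Total covered bp. Well defined (exact) for normalized sets."""
        return sum(iv.length for iv in self.normalize().intervals)

    def normalize(self) -> "IntervalSet":
        """Sort and merge overlapping or book-ended intervals. Idempotent."""
        if self.normalized:
            return self
        merged: list[GenomicInterval] = []
        for chrom in sorted(self.by_chrom()):
            pairs = sorted(self.by_chrom()[chrom])
            cur_s, cur_e = pairs[0]
            for s, e in pairs[1:]:
                if s <= cur_e:  # overlap or book-ended
                    cur_e = max(cur_e, e)
                else:
                    merged.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append(GenomicInterval(chrom, cur_s, cur_e))
        return IntervalSet(tuple(merged), label=self.label, normalized=True)

    # -- set algebra (operands are normalized internally) ------------------

    def union(self, other: "IntervalSet", label: str = "") -> "IntervalSet":
        return IntervalSet(
            self.intervals + other.intervals,
            label=label or self.label,
        ).normalize()

    def intersect(self, other: "IntervalSet", label: str = "") -> "IntervalSet":
        a, b = self.normalize(), other.normalize()
        bc = b.by_chrom()
        out: list[GenomicInterval] = []
        for chrom, pairs in a.by_chrom().items():
            other_pairs = bc.get(chrom, [])
            i = j = 0
            while i < len(pairs) and j < len(other_pairs):
                s1, e1 = pairs[i]
                s2, e2 = other_pairs[j]
                s, e = max(s1, s2), min(e1, e2)
                if s < e:
                    out.append(GenomicInterval(chrom, s, e))
                if e1 <= e2:
                    i += 1
                else:
                    j += 1
        out.sort()
        return IntervalSet(tuple(out), label=label or self.label, normalized=True)

    def subtract(self, other: "IntervalSet", label: str = "") -> "IntervalSet":
        a, b = self.normalize(), other.normalize()
        bc = b.by_chrom()
        out: list[GenomicInterval] = []
        for chrom, pairs in a.by_chrom().items():
            cuts = bc.get(chrom, [])
            for s, e in pairs:
                pos = s
                for cs, ce in cuts:
                    if ce <= pos:
                        continue
                    if cs >= e:
                        break
                    if cs > pos:
                        out.append(GenomicInterval(chrom, pos, cs))
                    pos = max(pos, ce)
                    if pos >= e:
                        break
                if pos < e:
                    out.append(GenomicInterval(chrom, pos, e))
        out.sort()
        return IntervalSet(tuple(out), label=label or self.label, normalized=True)

    def jaccard(self, other: "IntervalSet") -> float:
        """Bp-wise intersection over union; NaN when both sets are empty."""
        inter = self.intersect(other).coverage()
        uni = self.union(other).coverage()
        if uni == 0:
            return math.nan
        return inter / uni

    def containing(self, chrom: str, pos: int) -> GenomicInterval | None:
        """The (unique, post-normalization) interval containing a position."""
        for iv in self.normalize().intervals:
            if iv.chrom == chrom and iv.start <= pos < iv.end:
                return iv
        return None


def union_all(sets: Iterable[IntervalSet], label: str = "") -> IntervalSet:
    ivs: list[GenomicInterval] = []
    for s in sets:
        ivs.extend(s.intervals)
    return IntervalSet(tuple(ivs), label=label).normalize()


def intersect_all(sets: Iterable[IntervalSet], label: str = "") -> IntervalSet:
    sets = list(sets)
    if not sets:
        return IntervalSet.empty(label)
    acc = sets[0].normalize()
    for s in sets[1:]:
        acc = acc.intersect(s)
    return IntervalSet(acc.intervals, label=label, normalized=True)


# -- BED I/O ---------------------------------------------------------------


def read_bed(path: str | Path, label: str | None = None) -> IntervalSet:
    """Read a BED3+/BED6 file; track/browser/comment lines are skipped.

    Malformed lines (fewer than 3 fields, non-integer coordinates,
    start >= end) raise ``ValueError`` naming the line number.
    """
    path = Path(path)
    ivs: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields, got {len(fields)}")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates {s!r}/{e!r}") from err
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}")
            ivs.append(GenomicInterval(chrom, start, end))
    return IntervalSet(tuple(ivs), label=label if label is not None else path.stem)


def write_bed(iset: IntervalSet, path: str | Path, names: Iterable[str] | None = None) -> None:
    """Write a BED3 (or BED4 with ``names``) file sorted by (chrom, start)."""
    path = Path(path)
    ivs = sorted(iset.intervals)
    name_list = list(names) if names is not None else None
    if name_list is not None and len(name_list) != len(ivs):
        raise ValueError("names must match the number of intervals")
    with path.open("w") as fh:
        for i, iv in enumerate(ivs):
            if name_list is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name_list[i]}\n")
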