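"""Genomic-interval algebra for building and comparing enhancer sets.

Intervals follow the BED convention: 0-based, half-open ``[start, end)``.
SNP positions follow the VCF convention (1-based); the conversion between
the two is confined to :func:`snps_in_intervals`.

Strand is ignored throughout: enhancer activity, as represented here, is
strandless.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "OverlapMatrix",
    "merge_intervals",
    "cluster_merge",
    "intersect_sets",
    "subtract_sets",
    "overlap_percentage_matrix",
    "snps_in_intervals",
    "read_bed",
    "write_bed",
    "normalize_chrom",
]


def normalize_chrom(label: str, strip_chr: bool = True) -> str:
    """Normalise a chromosome label; optionally strip a leading ``chr``.

    Labels are otherwise compared as exact strings. Stripping is on by
    default because enhancer sets lifted over from different assemblies
    routinely disagree on the prefix.
    """
    label = str(label).strip()
    if strip_chr and label.lower().startswith("chr"):
        label = label[3:]
    return label


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    ``source`` is a free-text label of the originating set (e.g. the
    database or aligner the region came from); it does not take part in
    interval arithmetic.
    """

    chrom: str
    start: int
    end: int
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                f"(source={self.source!r}): require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of base pairs shared with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """A named set of sorted, non-overlapping genomic intervals.

    The invariants (sorted by ``(chrom, start)``; no two intervals on the
    same chromosome share a base pair) are enforced at construction; use
    :func:`merge_intervals` to build a set from arbitrary raw intervals.
    """

    __slots__ = ("name", "intervals")

    def __init__(self, name: str, intervals: Iterable[GenomicInterval], validate: bool = True):
        ivs = tuple(sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)))
        if validate:
            for a, b in itertools.pairwise(ivs):
                if a.chrom == b.chrom and b.start < a.end:
                    raise ValueError(
                        f"IntervalSet {name!r}: intervals {a.chrom}:{a.start}-{a.end} and "
                        f"{b.chrom}:{b.start}-{b.end} overlap; merge first"
                    )
        self.name = name
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.name == other.name and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet({self.name!r}, n={len(self)}, total_bp={self.total_bp})"

    @property
    def total_bp(self) -> int:
        return sum(iv.length for iv in self.intervals)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(iv.chrom for iv in self.intervals))

    def by_chrom(self, chrom: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.chrom == chrom]

    def rename(self, name: str) -> "IntervalSet":
        return IntervalSet(name, self.intervals)


def merge_intervals(
    intervals: Iterable[GenomicInterval],
    name: str = "merged",
    min_overlap: int = 0,
) -> IntervalSet:
    """Merge raw intervals into a sorted, non-overlapping :class:`IntervalSet`.

    Two intervals are joined when they share strictly more than
    ``min_overlap`` base pairs with the growing merged interval. The default
    ``min_overlap=0`` is standard BED-merge semantics: any positive overlap
    merges, book-ended intervals (0 bp shared) are kept apart.
    ``min_overlap=1`` gives the stricter "more than one bp" reading; note
    that under it the output may retain records sharing a single base pair,
    so the non-overlap invariant is only enforced for ``min_overlap=0``.
    """
    if min_overlap < 0:
        raise ValueError("min_overlap must be >= 0")
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom:
            shared = min(out[-1].end, iv.end) - iv.start
            if shared > min_overlap:
                prev = out.pop()
                iv = GenomicInterval(
                    iv.chrom, prev.start, max(prev.end, iv.end), prev.source
                )
        out.append(iv)
    return IntervalSet(name, out, validate=min_overlap == 0)


def cluster_merge(iset: IntervalSet, max_gap: int, name: str | None = None) -> IntervalSet:
    """Merge intervals separated by a gap strictly smaller than ``max_gap`` bp.

    Models the expansion of super-enhancer catalogues, where nearby
    enhancer sequences (e.g. within 30 kb) are collapsed into a single
    longer region. Merging proceeds left-to-right per chromosome and is
    transitive. ``max_gap=0`` degenerates to plain merging.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out: list[GenomicInterval] = []
    for iv in iset.intervals:
        if out and out[-1].chrom == iv.chrom and iv.start - out[-1].end < max_gap:
            prev = out.pop()
            iv = GenomicInterval(iv.chrom, prev.start, max(prev.end, iv.end), prev.source)
        out.append(iv)
    return IntervalSet(name if name is not None else iset.name, out)


def _per_chrom_pairs(
    a: IntervalSet, b: IntervalSet
) -> Iterator[tuple[str, list[GenomicInterval], list[GenomicInterval]]]:
    chroms = dict.fromkeys(list(a.chroms) + list(b.chroms))
    for chrom in chroms:
        yield chrom, a.by_chrom(chrom), b.by_chrom(chrom)


def intersect_sets(a: IntervalSet, b: IntervalSet, name: str | None = None) -> IntervalSet:
    """Base pairs covered by both ``a`` and ``b`` (e.g. regions carrying two
    histone marks at once)."""
    out: list[GenomicInterval] = []
    for chrom, avs, bvs in _per_chrom_pairs(a, b):
        i = j = 0
        while i < len(avs) and j < len(bvs):
            lo = max(avs[i].start, bvs[j].start)
            hi = min(avs[i].end, bvs[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi, f"{a.name}&{b.name}"))
            if avs[i].end <= bvs[j].end:
                i += 1
            else:
                j += 1
    return IntervalSet(name if name is not None else f"{a.name}&{b.name}", out)


def subtract_sets(a: IntervalSet, b: IntervalSet, name: str | None = None) -> IntervalSet:
    """Base pairs covered by ``a`` but not ``b`` (a mark-specific subset)."""
    out: list[GenomicInterval] = []
    for chrom, avs, bvs in _per_chrom_pairs(a, b):
        j = 0
        for iv in avs:
            cur = iv.start
            while j < len(bvs) and bvs[j].end <= iv.start:
                j += 1
            k = j
            while k < len(bvs) and bvs[k].start < iv.end:
                if bvs[k].start > cur:
                    out.append(GenomicInterval(chrom, cur, bvs[k].start, iv.source))
                cur = max(cur, bvs[k].end)
                k += 1
            if cur < iv.end:
                out.append(GenomicInterval(chrom, cur, iv.end, iv.source))
    return IntervalSet(name if name is not None else f"{a.name}-{b.name}", out)


@dataclass
class OverlapMatrix:
    """Row-relative pairwise overlap percentages between interval sets.

    ``values[r, c]`` is 100 x (bp shared by set r and set c) / (total bp of
    set r); the matrix is generally asymmetric and its diagonal is exactly
    100.
    """

    set_names: list[str]
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.set_names, columns=self.set_names)

    def __getitem__(self, key: tuple[str, str]) -> float:
        r, c = key
        return float(self.values[self.set_names.index(r), self.set_names.index(c)])


def overlap_percentage_matrix(sets: Sequence[IntervalSet]) -> OverlapMatrix:
    """Pairwise overlap of interval sets as row-relative percentages."""
    for s in sets:
        if s.total_bp == 0:
            raise ValueError(f"set {s.name!r} has total_bp = 0; ratio undefined")
    n = len(sets)
    values = np.full((n, n), 100.0)
    for r in range(n):
        for c in range(n):
            if r == c:
                continue
            shared = intersect_sets(sets[r], sets[c]).total_bp
            values[r, c] = 100.0 * shared / sets[r].total_bp
    return OverlapMatrix([s.name for s in sets], values)


def snps_in_intervals(
    chroms: Sequence[str] | np.ndarray,
    positions: Sequence[int] | np.ndarray,
    iset: IntervalSet,
    strip_chr: bool = True,
) -> np.ndarray:
    """Boolean membership of SNPs (1-based positions) in an interval set.

    A SNP at 1-based position ``p`` falls in ``[start, end)`` iff
    ``start < p <= end`` — i.e. its 0-based coordinate ``p-1`` is covered.
    Count members with ``.sum()`` (the "eSNP" count of a set).
    """
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size and positions.min() < 1:
        bad = int(positions.min())
        raise ValueError(f"SNP position {bad} < 1; positions are 1-based")
    chrom_arr = np.asarray([normalize_chrom(c, strip_chr) for c in chroms], dtype=object)
    member = np.zeros(positions.shape, dtype=bool)
    for chrom in iset.chroms:
        key = normalize_chrom(chrom, strip_chr)
        ivs = iset.by_chrom(chrom)
        starts = np.asarray([iv.start for iv in ivs], dtype=np.int64)
        ends = np.asarray([iv.end for iv in ivs], dtype=np.int64)
        sel = chrom_arr == key
        if not sel.any():
            continue
        p0 = positions[sel] - 1  # to 0-based
        idx = np.searchsorted(starts, p0, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(p0.shape, dtype=bool)
        hit[ok] = p0[ok] < ends[idx[ok]]
        member[sel] |= hit
    return member


# ---------------------------------------------------------------------------
# BED I/O (BED3+1: chrom, start, end, name)

def read_bed(path: str | Path, name: str | None = None, strip_chr: bool = True) -> IntervalSet:
    """Read a BED file into a merged :class:`IntervalSet`.

    Header-ish lines (``#``, ``track``, ``browser``) are skipped; column 4,
    when present, is kept as the interval source label.
    """
    path = Path(path)
    ivs: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            try:
                chrom = normalize_chrom(fields[0], strip_chr)
                start, end = int(fields[1]), int(fields[2])
                source = fields[3] if len(fields) > 3 else path.stem
                ivs.append(GenomicInterval(chrom, start, end, source))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return merge_intervals(ivs, name if name is not None else path.stem)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write an interval set as sorted, merged BED3+1 records."""
    with Path(path).open("w") as fh:
        for iv in iset.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iset.name}\n")
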