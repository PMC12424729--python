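"""Genomic intervals and interval arithmetic.

All coordinates in this package are 0-based half-open ``[start, end)``,
the BED convention.  :class:`GenomicInterval` is the universal coordinate
currency; :class:`PeakSet` is an ordered, name-unique collection of them.
Overlap primitives here are vectorised with numpy ``searchsorted`` over
per-chromosome sorted arrays, which keeps desk-scale sets (1e4-1e6
intervals) fast without heavyweight dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import DataError

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "merge_intervals",
    "overlaps_any",
    "count_overlapping",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name; must be non-empty.
    start, end : int
        0-based inclusive start and exclusive end, ``0 <= start < end``.
    name : str, optional
        Identifier (unique within a :class:`PeakSet`).
    score : float, optional
    strand : str, optional
        One of ``+``, ``-``, ``.``.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise DataError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise DataError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-", "."):
            raise DataError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """An ordered collection of :class:`GenomicInterval` with unique names.

    Intervals are sorted by ``(chrom, start, end)`` on construction; unnamed
    intervals are assigned ``peak_<i>`` names (i = position in sorted order)
    so every member can be referenced downstream.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = ""):
        ivs = sorted(intervals, key=GenomicInterval.sort_key)
        named: List[GenomicInterval] = []
        for i, iv in enumerate(ivs):
            if iv.name is None:
                iv = replace(iv, name=f"peak_{i}")
            named.append(iv)
        names = [iv.name for iv in named]
        if len(set(names)) != len(names):
            seen, dup = set(), None
            for n in names:
                if n in seen:
                    dup = n
                    break
                seen.add(n)
            raise DataError(f"duplicate interval name in peak set: {dup!r}")
        self.label = label
        self.intervals: List[GenomicInterval] = named
        self._index: Dict[str, GenomicInterval] = {iv.name: iv for iv in named}

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, name: str) -> GenomicInterval:
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @property
    def names(self) -> List[str]:
        return [iv.name for iv in self.intervals]

    def chromosomes(self) -> List[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def subset(self, names: Sequence[str], label: str = "") -> "PeakSet":
        return PeakSet([self._index[n] for n in names], label=label or self.label)

    def widths(self) -> np.ndarray:
        return np.array([iv.width for iv in self.intervals], dtype=int)

    def by_chrom(self) -> Dict[str, "_ChromArrays"]:
        """Per-chromosome sorted start/end arrays (cached)."""
        if not hasattr(self, "_by_chrom"):
            out: Dict[str, _ChromArrays] = {}
            for iv in self.intervals:
                out.setdefault(iv.chrom, _ChromBuilder()).add(iv)
            self._by_chrom = {c: b.build() for c, b in out.items()}
        return self._by_chrom


@dataclass
class _ChromArrays:
    starts: np.ndarray  # sorted by start
    ends: np.ndarray  # aligned with starts
    names: List[str]
    merged_starts: np.ndarray = field(default=None)  # internally merged, disjoint
    merged_ends: np.ndarray = field(default=None)
    ends_sorted: np.ndarray = field(default=None)


class _ChromBuilder:
    def __init__(self) -> None:
        self.items: List[GenomicInterval] = []

    def add(self, iv: GenomicInterval) -> None:
        self.items.append(iv)

    def build(self) -> _ChromArrays:
        starts = np.array([iv.start for iv in self.items], dtype=np.int64)
        ends = np.array([iv.end for iv in self.items], dtype=np.int64)
        names = [iv.name for iv in self.items]
        ms, me = _merge_arrays(starts, ends, gap=0)
        return _ChromArrays(
            starts=starts,
            ends=ends,
            names=names,
            merged_starts=ms,
            merged_ends=me,
            ends_sorted=np.sort(ends),
        )


def _merge_arrays(
    starts: np.ndarray, ends: np.ndarray, gap: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Merge sorted-by-start intervals; ``gap=0`` also merges book-ended ones."""
    if len(starts) == 0:
        return starts.copy(), ends.copy()
    out_s, out_e = [int(starts[0])], [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1] + gap:
            out_e[-1] = max(out_e[-1], int(e))
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> List[GenomicInterval]:
    """Merge overlapping (and, with ``gap=0``, book-ended) intervals.

    Returns sorted, disjoint intervals without names.
    """
    per_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        per_chrom.setdefault(iv.chrom, []).append(iv)
    out: List[GenomicInterval] = []
    for chrom in sorted(per_chrom):
        ivs = sorted(per_chrom[chrom], key=GenomicInterval.sort_key)
        s = np.array([iv.start for iv in ivs], dtype=np.int64)
        e = np.array([iv.end for iv in ivs], dtype=np.int64)
        ms, me = _merge_arrays(s, e, gap=gap)
        out.extend(GenomicInterval(chrom, int(a), int(b)) for a, b in zip(ms, me))
    return out


def _query_arrays(query: PeakSet) -> Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (row indices, starts, ends) for the query set."""
    out: Dict[str, List[List[int]]] = {}
    for i, iv in enumerate(query.intervals):
        out.setdefault(iv.chrom, []).append((i, iv.start, iv.end))
    return {
        c: tuple(np.array(col, dtype=np.int64) for col in zip(*rows))
        for c, rows in out.items()
    }


def overlaps_any(query: PeakSet, features: PeakSet) -> np.ndarray:
    """Boolean array (aligned with ``query.intervals``): overlaps >=1 feature by >=1 bp."""
    feat = features.by_chrom()
    flags = np.zeros(len(query), dtype=bool)
    for chrom, (idx, starts, ends) in _query_arrays(query).items():
        ca = feat.get(chrom)
        if ca is None or len(ca.merged_starts) == 0:
            continue
        # merged features are disjoint+sorted: the only candidate overlapping
        # [start, end) is the last one starting before `end`.
        j = np.searchsorted(ca.merged_starts, ends, side="left") - 1
        hit = (j >= 0) & (ca.merged_ends[np.maximum(j, 0)] > starts)
        flags[idx] = hit
    return flags


def count_overlapping(query: PeakSet, others: PeakSet) -> np.ndarray:
    """Per query interval: number of ``others`` intervals overlapping it by >=1 bp.

    ``others`` intervals are counted individually (no internal merging) — this
    is the fragment-counting primitive, where every fragment overlapping a
    peak contributes one count.
    """
    oth = others.by_chrom()
    counts = np.zeros(len(query), dtype=np.int64)
    for chrom, (idx, starts, ends) in _query_arrays(query).items():
        ca = oth.get(chrom)
        if ca is None:
            continue
        n = len(ca.starts)
        # overlap <=> other.start < end and other.end > start
        n_start_ge_end = n - np.searchsorted(ca.starts, ends, side="left")
        n_end_le_start = np.searchsorted(ca.ends_sorted, starts, side="right")
        counts[idx] = n - n_start_ge_end - n_end_le_start
    return counts
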