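"""Chromatin loops, contact matrices, APA and virtual-4C.

Loops come in as BEDPE anchor pairs; contact data as dense symmetric
per-chromosome matrices at a fixed bin resolution (10 kb by default, the
resolution at which the loops were called).  Anchor classification counts,
per loop, how many of its two anchors fall on nucleation sites; Aggregate
Peak Analysis (APA) averages the contact sub-matrix around each loop pixel
and scores the centre against the short-distance background corner.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import scipy.stats

from .exceptions import DataError
from .intervals import GenomicInterval, PeakSet, overlaps_any

__all__ = [
    "Loop",
    "ContactMatrix",
    "APAResult",
    "SpanStats",
    "classify_loop_anchors",
    "span_stats",
    "apa",
    "virtual_4c",
]


@dataclass(frozen=True)
class Loop:
    """A chromatin loop: two anchors in genomic order.

    ``span`` is the midpoint-to-midpoint distance in bp, defined only for
    intrachromosomal loops (``None`` otherwise, with ``interchromosomal``
    set).  ``n_nucleation_anchors`` is filled by
    :func:`classify_loop_anchors`.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    n_nucleation_anchors: Optional[int] = None

    def __post_init__(self) -> None:
        a, b = self.anchor1, self.anchor2
        if (a.chrom, a.start) > (b.chrom, b.start):
            raise DataError("loop anchors must be in (chrom, start) order")
        if self.n_nucleation_anchors not in (None, 0, 1, 2):
            raise DataError("n_nucleation_anchors must be 0, 1 or 2")

    @property
    def interchromosomal(self) -> bool:
        return self.anchor1.chrom != self.anchor2.chrom

    @property
    def span(self) -> Optional[int]:
        if self.interchromosomal:
            return None
        return abs(self.anchor2.midpoint - self.anchor1.midpoint)

    @staticmethod
    def from_anchors(a: GenomicInterval, b: GenomicInterval, **kw) -> "Loop":
        """Build a loop, normalizing anchor order by (chrom, start)."""
        if (a.chrom, a.start) > (b.chrom, b.start):
            a, b = b, a
        return Loop(a, b, **kw)


@dataclass
class ContactMatrix:
    """Dense symmetric contact matrix for one chromosome at fixed resolution."""

    chrom: str
    resolution: int
    bin_starts: np.ndarray  # ordered, uniform spacing == resolution
    values: np.ndarray  # square, symmetric, non-negative

    def __post_init__(self) -> None:
        self.bin_starts = np.asarray(self.bin_starts, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.bin_starts)
        if self.values.shape != (n, n):
            raise DataError(
                f"contact matrix shape {self.values.shape} does not match "
                f"{n} bins"
            )
        if n > 1 and not np.all(np.diff(self.bin_starts) == self.resolution):
            raise DataError("bins must be uniform and contiguous")
        if np.any(self.values < 0):
            raise DataError("contact values must be non-negative")
        if not np.allclose(self.values, self.values.T, rtol=1e-8, atol=1e-8):
            raise DataError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return len(self.bin_starts)

    def bin_index(self, pos: int) -> int:
        """Bin containing genomic position ``pos``; DataError if outside."""
        start0 = int(self.bin_starts[0])
        if pos < start0 or pos >= start0 + self.n_bins * self.resolution:
            raise DataError(
                f"position {self.chrom}:{pos} outside contact matrix span"
            )
        return (pos - start0) // self.resolution


@dataclass
class APAResult:
    """Aggregate Peak Analysis output.

    ``aggregate`` is the (2w+1) x (2w+1) mean sub-matrix over included loop
    pixels with anchor1 on rows; ``score`` is the centre pixel divided by the
    mean of the 3x3 lower-left corner (the shorter-genomic-distance
    background quadrant).
    """

    w: int
    aggregate: np.ndarray
    n_loops: int
    n_excluded: int
    score: float


def classify_loop_anchors(loops: Sequence[Loop], nucleation: PeakSet) -> List[Loop]:
    """Fill ``n_nucleation_anchors`` for every loop.

    An anchor counts as a nucleation anchor iff it overlaps >=1 nucleation
    interval by >=1 bp; each anchor contributes at most 1 regardless of how
    many nucleation peaks it touches.
    """
    loops = list(loops)
    if not loops:
        return []
    anchors = PeakSet(
        [replace(lp.anchor1, name=f"a1_{i}") for i, lp in enumerate(loops)]
        + [replace(lp.anchor2, name=f"a2_{i}") for i, lp in enumerate(loops)]
    )
    hit = dict(zip(anchors.names, overlaps_any(anchors, nucleation)))
    return [
        replace(lp, n_nucleation_anchors=int(hit[f"a1_{i}"]) + int(hit[f"a2_{i}"]))
        for i, lp in enumerate(loops)
    ]


@dataclass
class SpanStats:
    """Per-anchor-class loop span summary with one-way ANOVA."""

    groups: Dict[int, np.ndarray]  # n_nucleation_anchors -> spans (bp)
    group_n: Dict[int, int]
    group_mean: Dict[int, float]
    f_stat: float
    p_value: float


def span_stats(loops: Sequence[Loop]) -> SpanStats:
    """Group intrachromosomal loop spans by nucleation-anchor count; one-way ANOVA."""
    groups: Dict[int, List[int]] = {}
    for lp in loops:
        if lp.interchromosomal:
            continue
        if lp.n_nucleation_anchors is None:
            raise DataError("loops must be anchor-classified before span_stats")
        groups.setdefault(lp.n_nucleation_anchors, []).append(lp.span)
    arrays = {k: np.asarray(v, dtype=float) for k, v in sorted(groups.items())}
    nonempty = [a for a in arrays.values() if len(a) > 0]
    if len(nonempty) < 2:
        raise DataError("span_stats requires >= 2 non-empty anchor classes")
    if all(len(a) == 1 for a in nonempty):
        raise DataError("within-group variance undefined: all groups have n = 1")
    f, p = scipy.stats.f_oneway(*nonempty)
    return SpanStats(
        groups=arrays,
        group_n={k: int(len(a)) for k, a in arrays.items()},
        group_mean={k: float(np.mean(a)) for k, a in arrays.items()},
        f_stat=float(f),
        p_value=float(p),
    )


def apa(
    loops: Sequence[Loop],
    matrices: Dict[str, ContactMatrix],
    w: int = 5,
) -> APAResult:
    """Aggregate Peak Analysis over intrachromosomal loops.

    The loop pixel is (bin of anchor1 midpoint, bin of anchor2 midpoint).
    A loop is excluded (counted in ``n_excluded``) when its chromosome has
    no matrix, its (2w+1)^2 window leaves the matrix, or the pixel lies
    within 2w bins of the diagonal.  Raises when no loop survives.
    """
    resolutions = {m.resolution for m in matrices.values()}
    if len(resolutions) > 1:
        raise DataError("all contact matrices must share one resolution")
    size = 2 * w + 1
    acc = np.zeros((size, size), dtype=float)
    n_used = n_excluded = 0
    for lp in loops:
        m = matrices.get(lp.anchor1.chrom) if not lp.interchromosomal else None
        if m is None:
            n_excluded += 1
            continue
        try:
            b1 = m.bin_index(lp.anchor1.midpoint)
            b2 = m.bin_index(lp.anchor2.midpoint)
        except DataError:
            n_excluded += 1
            continue
        if b1 > b2:
            b1, b2 = b2, b1
        if b2 - b1 <= 2 * w:  # too near the diagonal
            n_excluded += 1
            continue
        if b1 - w < 0 or b2 + w >= m.n_bins:
            n_excluded += 1
            continue
        acc += m.values[b1 - w : b1 + w + 1, b2 - w : b2 + w + 1]
        n_used += 1
    if n_used == 0:
        raise DataError("APA: no loop produced a valid in-matrix window")
    aggregate = acc / n_used
    corner = aggregate[2 * w - 2 : 2 * w + 1, 0:3]
    corner_mean = float(np.mean(corner))
    if corner_mean <= 0:
        raise DataError("APA: background corner mean is zero")
    score = float(aggregate[w, w] / corner_mean)
    return APAResult(
        w=w, aggregate=aggregate, n_loops=n_used, n_excluded=n_excluded, score=score
    )


def virtual_4c(matrix: ContactMatrix, viewpoint: GenomicInterval) -> np.ndarray:
    """Contact profile anchored at ``viewpoint``.

    Returns the matrix row of the viewpoint's bin with the viewpoint bin
    itself masked to 0, normalized to sum to 1.
    """
    if viewpoint.chrom != matrix.chrom:
        raise DataError(
            f"viewpoint chromosome {viewpoint.chrom} != matrix {matrix.chrom}"
        )
    b = matrix.bin_index(viewpoint.midpoint)
    profile = matrix.values[b].astype(float).copy()
    profile[b] = 0.0
    total = profile.sum()
    if total <= 0:
        raise DataError("virtual 4C: no off-viewpoint signal in row")
    return profile / total
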