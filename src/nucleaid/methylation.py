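"""CpG-island methylation calls and GC content.

Rules (asymmetric boundaries on purpose, matching the stated analysis
conventions): a single CpG site is *methylated* iff its level is
strictly greater than 0.5; an island is *methylated* iff at least 20%
(inclusive) of its covered CpGs are methylated, *unmethylated* below
20%, and *no_data* when no CpG record overlaps it.  The methylated
fraction's denominator is the number of CpG records overlapping the
island, not the island's theoretical CpG count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .enrichment import ResamplingResult, resample_enrichment
from .exceptions import DataError
from .intervals import GenomicInterval, PeakSet

__all__ = [
    "CpGIslandCall",
    "SITE_METHYLATION_MIN",
    "ISLAND_METHYLATION_MIN",
    "call_site_methylation",
    "call_island_status",
    "island_calls_frame",
    "gc_content",
    "cgi_enrichment",
]

SITE_METHYLATION_MIN = 0.5  # strict: level > 0.5 is methylated
ISLAND_METHYLATION_MIN = 0.20  # inclusive: frac >= 0.20 is methylated


@dataclass(frozen=True)
class CpGIslandCall:
    island: GenomicInterval
    n_cpg: int
    n_meth: int
    status: str  # methylated | unmethylated | no_data

    def __post_init__(self) -> None:
        if not (0 <= self.n_meth <= self.n_cpg):
            raise DataError("0 <= n_meth <= n_cpg violated")
        if (self.status == "no_data") != (self.n_cpg == 0):
            raise DataError("status must be no_data iff the island has no CpGs")

    @property
    def frac_meth(self) -> float:
        return self.n_meth / self.n_cpg if self.n_cpg else float("nan")


def call_site_methylation(levels) -> np.ndarray:
    """Per-site boolean: methylated iff level > 0.5 (strict)."""
    arr = np.asarray(levels, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise DataError("methylation levels must lie in [0, 1]")
    return arr > SITE_METHYLATION_MIN


def call_island_status(islands: PeakSet, records: pd.DataFrame) -> List[CpGIslandCall]:
    """Call methylation status per island from a sorted per-CpG table.

    ``records`` needs columns chrom, pos, level (pos 0-based, sorted
    within chromosome).  Calls are a pure function of (island, records):
    record order never changes them.
    """
    by_chrom: Dict[str, tuple] = {}
    for chrom, grp in records.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        by_chrom[chrom] = (pos[order], grp["level"].to_numpy()[order])
    calls: List[CpGIslandCall] = []
    for iv in islands:
        tup = by_chrom.get(iv.chrom)
        if tup is None:
            calls.append(CpGIslandCall(iv, 0, 0, "no_data"))
            continue
        pos, level = tup
        lo = int(np.searchsorted(pos, iv.start, side="left"))
        hi = int(np.searchsorted(pos, iv.end, side="left"))
        n_cpg = hi - lo
        if n_cpg == 0:
            calls.append(CpGIslandCall(iv, 0, 0, "no_data"))
            continue
        n_meth = int(call_site_methylation(level[lo:hi]).sum())
        status = (
            "methylated"
            if n_meth / n_cpg >= ISLAND_METHYLATION_MIN
            else "unmethylated"
        )
        calls.append(CpGIslandCall(iv, n_cpg, n_meth, status))
    return calls


def island_calls_frame(calls: List[CpGIslandCall]) -> pd.DataFrame:
    """Tabular view of island calls (chrom, start, end, n_cpg, n_meth, frac, status)."""
    return pd.DataFrame(
        {
            "chrom": [c.island.chrom for c in calls],
            "start": [c.island.start for c in calls],
            "end": [c.island.end for c in calls],
            "name": [c.island.name for c in calls],
            "n_cpg": [c.n_cpg for c in calls],
            "n_meth": [c.n_meth for c in calls],
            "frac_meth": [c.frac_meth for c in calls],
            "status": [c.status for c in calls],
        }
    )


def gc_content(sequence: str) -> float:
    """(G + C) / (A + C + G + T), case-insensitive; N excluded; NaN if no ACGT."""
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGTN"}
    if sum(counts.values()) != len(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise DataError(f"sequence contains non-ACGTN characters: {bad}")
    denom = len(seq) - counts["N"]
    if denom == 0:
        return float("nan")
    return (counts["G"] + counts["C"]) / denom


def cgi_enrichment(
    nucleation: PeakSet,
    background: PeakSet,
    island_calls: List[CpGIslandCall],
    n_draws: int = 1000,
    seed: int = 0,
) -> Dict[str, ResamplingResult]:
    """Resampling O/E of methylated and unmethylated island overlap.

    Islands with no CpG data are excluded from both feature sets.  Returns
    one :class:`ResamplingResult` per status, keyed ``"methylated"`` /
    ``"unmethylated"``; draw streams for the two statuses are decoupled
    via deterministic sub-seeds of ``seed``.
    """
    out: Dict[str, ResamplingResult] = {}
    ss = np.random.SeedSequence(seed)
    subseeds = {
        status: int(child.generate_state(1)[0] % (2**31))
        for status, child in zip(("unmethylated", "methylated"), ss.spawn(2))
    }
    for status in ("unmethylated", "methylated"):
        islands = [c.island for c in island_calls if c.status == status]
        if not islands:
            raise DataError(f"no islands with status {status!r}")
        feature = PeakSet(
            [GenomicInterval(iv.chrom, iv.start, iv.end) for iv in islands],
            label=f"cgi_{status}",
        )
        out[status] = resample_enrichment(
            nucleation, background, feature, n_draws=n_draws, seed=subseeds[status]
        )
    return out
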