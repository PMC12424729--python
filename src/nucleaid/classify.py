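"""Nucleation-site classification from two binding contrasts.

The three-condition degron design (steady state -> auxin depletion ->
washout reintroduction) yields two contrasts over the union peaks:
contrast 1 compares auxin to steady state, contrast 2 reintroduction to
auxin.  A *nucleation* site is a steady-state peak whose signal drops
significantly under auxin and rebounds significantly after washout
(strictly beyond |log2FC| > 1.5 at adjusted p < 0.005 in both
contrasts).  Peaks first seen under auxin or reintroduction are
bookkept as *new* classes and excluded from the nucleation /
control-exclusive dichotomy; steady-state peaks still called under
auxin that are not nucleation are *persistent*; the remaining
steady-state peaks are *control-exclusive*.  Union peaks present in no
condition's calls are *excluded*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .diffbind import ContrastResult
from .exceptions import DataError
from .intervals import PeakSet, overlaps_any
from .io import GeneModel

__all__ = [
    "CONDITIONS",
    "CLASS_LABELS",
    "ClassifierThresholds",
    "PeakClassification",
    "flag_presence",
    "classify",
    "width_stats",
    "interpeak_distances",
    "annotate_genomic_context",
    "nearest_gene",
]

CONDITIONS = ("steady_state", "auxin", "reintroduction")
CLASS_LABELS = (
    "nucleation",
    "control_exclusive",
    "persistent",
    "new_in_auxin",
    "new_in_reintro",
    "excluded",
)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Strict significance cut-offs; boundary values are excluded."""

    lfc_min: float = 1.5
    padj_max: float = 0.005

    def __post_init__(self) -> None:
        if self.lfc_min <= 0:
            raise DataError("lfc_min must be positive")
        if not (0 < self.padj_max < 1):
            raise DataError("padj_max must lie in (0, 1)")


@dataclass
class PeakClassification:
    """Per-union-peak labels with the evidence that produced them.

    ``table`` is indexed by union peak name with columns: label,
    present_steady_state / present_auxin / present_reintroduction,
    lfc1, padj1, lfc2, padj2.
    """

    table: pd.DataFrame
    thresholds: ClassifierThresholds

    def names_for(self, label: str) -> List[str]:
        return list(self.table.index[self.table["label"] == label])

    def class_sizes(self) -> Dict[str, int]:
        vc = self.table["label"].value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in CLASS_LABELS}


def flag_presence(union: PeakSet, calls: Dict[str, PeakSet]) -> pd.DataFrame:
    """Presence flags: union peak present in condition C iff it overlaps a
    C-called peak by >= 1 bp.  ``calls`` must cover all three conditions."""
    missing = [c for c in CONDITIONS if c not in calls]
    if missing:
        raise DataError(f"missing peak calls for condition(s): {missing}")
    data = {
        f"present_{cond}": overlaps_any(union, calls[cond]) for cond in CONDITIONS
    }
    return pd.DataFrame(data, index=pd.Index(union.names, name="feature"))


def classify(
    presence: pd.DataFrame,
    contrast1: ContrastResult,
    contrast2: ContrastResult,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> PeakClassification:
    """Label every union peak (see module docstring for the decision rule).

    ``contrast1`` is auxin vs steady state, ``contrast2`` reintroduction
    vs auxin, both over exactly the union features.
    """
    features = presence.index
    for cr, which in ((contrast1, "contrast1"), (contrast2, "contrast2")):
        if not features.equals(cr.table.index):
            if set(features) != set(cr.table.index):
                raise DataError(f"{which} features differ from the union peak set")
            cr.table = cr.table.loc[features]
    in_ss = presence["present_steady_state"].to_numpy()
    in_aux = presence["present_auxin"].to_numpy()
    in_re = presence["present_reintroduction"].to_numpy()
    down1 = contrast1.significant(thresholds.lfc_min, thresholds.padj_max, sign=-1)
    up2 = contrast2.significant(thresholds.lfc_min, thresholds.padj_max, sign=+1)
    nucleation = in_ss & down1.to_numpy() & up2.to_numpy()

    labels = np.full(len(features), "excluded", dtype=object)
    new_aux = ~in_ss & in_aux
    new_re = ~in_ss & ~new_aux & in_re
    labels[new_aux] = "new_in_auxin"
    labels[new_re] = "new_in_reintro"
    labels[in_ss & nucleation] = "nucleation"
    labels[in_ss & ~nucleation & in_aux] = "persistent"
    labels[in_ss & ~nucleation & ~in_aux] = "control_exclusive"

    table = pd.DataFrame(
        {
            "label": labels,
            "present_steady_state": in_ss,
            "present_auxin": in_aux,
            "present_reintroduction": in_re,
            "lfc1": contrast1.table["log2FoldChange"].to_numpy(),
            "padj1": contrast1.table["padj"].to_numpy(),
            "lfc2": contrast2.table["log2FoldChange"].to_numpy(),
            "padj2": contrast2.table["padj"].to_numpy(),
        },
        index=features,
    )
    return PeakClassification(table=table, thresholds=thresholds)


def width_stats(classification: PeakClassification, union: PeakSet) -> pd.DataFrame:
    """Per-class width summary: n, median and quartiles of (end - start).

    Empty classes report n = 0 with missing quantiles.
    """
    widths = pd.Series(
        {iv.name: iv.width for iv in union}, name="width", dtype=float
    )
    rows = []
    for label in CLASS_LABELS:
        names = classification.names_for(label)
        w = widths.loc[names]
        if len(w):
            q25, med, q75 = np.percentile(w, [25, 50, 75])
        else:
            q25 = med = q75 = float("nan")
        rows.append(
            {"label": label, "n": len(w), "q25": q25, "median": med, "q75": q75}
        )
    return pd.DataFrame(rows).set_index("label")


def interpeak_distances(peaks: PeakSet) -> pd.Series:
    """Nearest-neighbour edge-to-edge gap per peak (bp).

    Overlapping neighbours give 0; a peak alone on its chromosome gets
    NaN (excluded from summaries).  Raises with fewer than two peaks.
    """
    if len(peaks) < 2:
        raise DataError("interpeak distances need >= 2 peaks")
    dist = pd.Series(np.nan, index=pd.Index(peaks.names, name="feature"))
    any_pair = False
    for chrom, ca in peaks.by_chrom().items():
        n = len(ca.starts)
        if n < 2:
            continue
        any_pair = True
        starts, ends, names = ca.starts, ca.ends, ca.names
        # distance to any earlier peak is minimized by the max end so far
        prefmax = np.maximum.accumulate(ends)
        left = np.full(n, np.inf)
        left[1:] = np.maximum(0, starts[1:] - prefmax[:-1])
        right = np.full(n, np.inf)
        right[:-1] = np.maximum(0, starts[1:] - ends[:-1])
        dist.loc[names] = np.minimum(left, right)
    if not any_pair:
        raise DataError("no chromosome carries two peaks; distances undefined")
    return dist


def annotate_genomic_context(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = 2000,
) -> pd.Series:
    """Per-peak genomic context from the peak midpoint.

    Priority: promoter (TSS +/- ``promoter_halfwidth``, inclusive) >
    exon > intron (inside a gene body) > intergenic.
    """
    genes = sorted(genes, key=lambda g: (g.chrom, g.body.start))
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rank = {"intergenic": 0, "intron": 1, "exon": 2, "promoter": 3}
    labels = []
    for iv in peaks:
        mid = iv.midpoint
        label = "intergenic"
        for g in by_chrom.get(iv.chrom, ()):
            if abs(mid - g.tss) <= promoter_halfwidth:
                label = "promoter"
                break  # top priority; no later gene can outrank it
            if g.body.start <= mid < g.body.end:
                hit = "exon" if any(a <= mid < b for a, b in g.exons) else "intron"
                if rank[hit] > rank[label]:
                    label = hit
        labels.append(label)
    return pd.Series(labels, index=pd.Index(peaks.names, name="feature"), name="context")


def nearest_gene(peaks: PeakSet, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Nearest gene by |peak midpoint - TSS| on the same chromosome.

    Ties break to the lexicographically smallest gene_id.  The reported
    distance is signed relative to the TSS respecting gene strand
    (positive = downstream of the TSS in the gene's direction).  Peaks on
    chromosomes without genes report a missing gene.
    """
    if not genes:
        raise DataError("nearest_gene requires at least one gene")
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    arrays = {}
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
        arrays[chrom] = (np.array([g.tss for g in gs], dtype=np.int64), gs)
    rows = []
    for iv in peaks:
        mid = iv.midpoint
        tup = arrays.get(iv.chrom)
        if tup is None:
            rows.append({"feature": iv.name, "gene_id": None, "distance": np.nan})
            continue
        tss, gs = tup
        j = int(np.searchsorted(tss, mid))
        cand_idx = [k for k in (j - 1, j) if 0 <= k < len(gs)]
        tie_dist = min(abs(mid - tss[k]) for k in cand_idx)
        # ties can only sit at TSS == mid +/- tie_dist; genes are sorted by
        # (tss, gene_id) so the first gene of each equal-TSS run wins
        ties = []
        for t in (mid - tie_dist, mid + tie_dist):
            k = int(np.searchsorted(tss, t, side="left"))
            if k < len(gs) and tss[k] == t:
                ties.append(gs[k])
        best = min(ties, key=lambda g: g.gene_id)
        signed = mid - best.tss if best.strand == "+" else best.tss - mid
        rows.append({"feature": iv.name, "gene_id": best.gene_id, "distance": signed})
    return pd.DataFrame(rows).set_index("feature")
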