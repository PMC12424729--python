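"""Differential-binding engine: union peaks, counting, normalization and
the negative-binomial Wald test.

The model: counts ``k_ij`` for peak *i* in sample *j* are treated as
negative binomial with mean ``s_j * q_ij`` and variance ``mu + alpha_i *
mu^2``, where ``s_j`` is a per-sample size factor (median-of-ratios
against a geometric-mean pseudo-reference) and ``alpha_i`` a per-peak
dispersion.  Dispersions are method-of-moments estimates on normalized
counts with condition means removed, floored at 1e-8 and shrunk halfway
toward their across-peak median.  A contrast B-over-A reports

    log2FC_i = log2((mu_B + c0) / (mu_A + c0)),          c0 = 0.5
    se_i^2   = (1/ln 2)^2 * sum_g (1/n_g) (1/(mu_g + c0) + alpha_i)

with a two-sided normal Wald p-value and Benjamini-Hochberg adjustment
across all union peaks (all-zero peaks included with p = 1, keeping the
multiple-testing family constant across contrasts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError
from .intervals import GenomicInterval, PeakSet, count_overlapping

__all__ = [
    "CountMatrix",
    "ContrastResult",
    "merge_union",
    "count_fragments",
    "estimate_size_factors",
    "estimate_dispersion",
    "wald_contrast",
    "bh_adjust",
    "ALPHA_MIN",
    "DISPERSION_SHRINKAGE",
    "PSEUDOCOUNT",
]

ALPHA_MIN = 1e-8
DISPERSION_SHRINKAGE = 0.5
PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Peak x sample integer counts with sample metadata.

    ``samples`` is indexed by sample id with at least a ``condition``
    column; ``size_factors`` is filled by :func:`estimate_size_factors`.
    """

    counts: pd.DataFrame  # features x samples, non-negative integers
    samples: pd.DataFrame  # indexed by sample id; columns condition, replicate
    size_factors: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise DataError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise DataError("feature ids must be unique")
        if list(self.counts.columns) != list(self.samples.index):
            raise DataError("count columns must match sample sheet order")
        if "condition" not in self.samples.columns:
            raise DataError("sample sheet must carry a 'condition' column")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise DataError("size factors must be positive")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise DataError("size factors not estimated yet")
        return self.counts / self.size_factors

    def condition_samples(self, condition: str) -> List[str]:
        hits = self.samples.index[self.samples["condition"] == condition]
        if len(hits) == 0:
            raise DataError(f"unknown condition {condition!r}")
        return list(hits)


@dataclass
class ContrastResult:
    """Per-feature statistics for one contrast (condition B over A).

    ``table`` columns: baseMean, log2FoldChange, lfcSE, dispersion,
    pvalue, padj — indexed by feature id.
    """

    condition_a: str
    condition_b: str
    table: pd.DataFrame

    def significant(self, lfc_min: float, padj_max: float, sign: int = 0) -> pd.Series:
        """Boolean mask of features passing strict |lfc| and padj thresholds.

        ``sign`` restricts direction: -1 down, +1 up, 0 either.
        """
        t = self.table
        if sign < 0:
            lfc_ok = t["log2FoldChange"] < -lfc_min
        elif sign > 0:
            lfc_ok = t["log2FoldChange"] > lfc_min
        else:
            lfc_ok = t["log2FoldChange"].abs() > lfc_min
        return lfc_ok & (t["padj"] < padj_max)


def merge_union(peaksets: Sequence[PeakSet]) -> PeakSet:
    """Merge per-condition peak calls into a non-redundant union set.

    Intervals overlapping by >= 1 bp or book-ended (end == start) merge
    across all inputs.  Union peaks are named ``union_<i>``; the names of
    every contributing source interval are preserved as a ``sources``
    attribute on the returned set (dict: union name -> sorted source names).
    """
    if not peaksets:
        raise DataError("merge_union requires at least one peak set")
    events = []  # (chrom, start, end, source name)
    for ps in peaksets:
        for iv in ps:
            events.append((iv.chrom, iv.start, iv.end, iv.name))
    events.sort(key=lambda t: (t[0], t[1], t[2]))
    merged: List[GenomicInterval] = []
    sources: Dict[str, List[str]] = {}
    cur = None  # [chrom, start, end, [names]]
    def flush():
        if cur is not None:
            name = f"union_{len(merged)}"
            merged.append(GenomicInterval(cur[0], cur[1], cur[2], name=name))
            sources[name] = sorted(set(cur[3]))
    for chrom, start, end, name in events:
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].append(name)
        else:
            flush()
            cur = [chrom, start, end, [name]]
    flush()
    union = PeakSet(merged, label="union")
    union.sources = sources
    return union


def count_fragments(union: PeakSet, fragments: Dict[str, PeakSet],
                    samples: Optional[pd.DataFrame] = None) -> CountMatrix:
    """Count per-sample fragments over union peaks.

    A fragment contributes +1 to every union peak it overlaps by >= 1 bp
    (a fragment spanning two peaks counts in both; within one peak it is
    never double-counted).
    """
    data = {
        sample: count_overlapping(union, frags) for sample, frags in fragments.items()
    }
    counts = pd.DataFrame(data, index=pd.Index(union.names, name="feature"))
    if samples is None:
        samples = pd.DataFrame(
            {"condition": ["unknown"] * len(fragments), "replicate": 1},
            index=pd.Index(list(fragments), name="sample"),
        )
    return CountMatrix(counts=counts, samples=samples.loc[counts.columns])


def estimate_size_factors(cm: CountMatrix) -> CountMatrix:
    """Median-of-ratios size factors (filled in place and returned).

    For each feature with all-positive counts, compute the ratio of each
    sample's count to the feature's geometric mean; ``s_j`` is the median
    ratio.  Factors are not renormalized further.
    """
    k = cm.counts.values.astype(float)
    all_pos = (k > 0).all(axis=1)
    if not all_pos.any():
        raise DataError(
            "no feature has positive counts in every sample; size factors "
            "undefined (pseudo-reference fallback is disabled)"
        )
    logk = np.log(k[all_pos])
    log_geomean = logk.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logk - log_geomean, axis=0))
    cm.size_factors = pd.Series(s, index=cm.counts.columns, name="size_factor")
    return cm


def estimate_dispersion(cm: CountMatrix, groups: Optional[pd.Series] = None) -> pd.Series:
    """Per-feature NB dispersion alpha_i (Var = mu + alpha mu^2).

    Method of moments on normalized counts with group (condition) means
    removed; raw estimates are floored at ``ALPHA_MIN`` and shrunk with
    weight ``DISPERSION_SHRINKAGE`` toward their median across features.
    """
    if cm.size_factors is None:
        raise DataError("estimate size factors before dispersion")
    if groups is None:
        groups = cm.samples["condition"]
    y = cm.normalized().values
    n = y.shape[1]
    labels = np.asarray(groups.loc[cm.counts.columns])
    uniq = np.unique(labels)
    resid = np.zeros_like(y)
    for g in uniq:
        cols = labels == g
        resid[:, cols] = y[:, cols] - y[:, cols].mean(axis=1, keepdims=True)
    dof = n - len(uniq)
    if dof <= 0:
        raise DataError("dispersion requires replicates (n_samples > n_groups)")
    var = (resid**2).sum(axis=1) / dof
    mean = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mean) / np.square(mean)
    raw = np.where(np.isfinite(raw), raw, ALPHA_MIN)
    raw = np.maximum(raw, ALPHA_MIN)
    alpha = (1 - DISPERSION_SHRINKAGE) * raw + DISPERSION_SHRINKAGE * np.median(raw)
    return pd.Series(alpha, index=cm.features, name="dispersion")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    return padj


def wald_contrast(
    cm: CountMatrix,
    condition_a: str,
    condition_b: str,
    dispersions: Optional[pd.Series] = None,
) -> ContrastResult:
    """NB Wald test of condition B over condition A.

    Group means are taken on normalized counts; see module docstring for
    the fold-change, standard-error and p-value definitions.  ``padj`` is
    BH-adjusted across all features in the matrix.
    """
    cols_a = cm.condition_samples(condition_a)
    cols_b = cm.condition_samples(condition_b)
    if dispersions is None:
        dispersions = estimate_dispersion(cm)
    alpha = dispersions.loc[cm.features].values
    y = cm.normalized()
    mu_a = y[cols_a].mean(axis=1).values
    mu_b = y[cols_b].mean(axis=1).values
    c0 = PSEUDOCOUNT
    log2fc = np.log2((mu_b + c0) / (mu_a + c0))
    inv_ln2_sq = 1.0 / np.log(2.0) ** 2
    se2 = inv_ln2_sq * (
        (1.0 / len(cols_a)) * (1.0 / (mu_a + c0) + alpha)
        + (1.0 / len(cols_b)) * (1.0 / (mu_b + c0) + alpha)
    )
    se = np.sqrt(se2)
    z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    all_zero = (cm.counts[cols_a + cols_b].values == 0).all(axis=1)
    p[all_zero] = 1.0
    table = pd.DataFrame(
        {
            "baseMean": y.mean(axis=1).values,
            "log2FoldChange": log2fc,
            "lfcSE": se,
            "dispersion": alpha,
            "pvalue": p,
            "padj": bh_adjust(p),
        },
        index=cm.features,
    )
    return ContrastResult(condition_a=condition_a, condition_b=condition_b, table=table)
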