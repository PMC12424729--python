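"""Synthetic fixture bundle with planted ground truth.

Emulates the statistical structure of a three-condition degron ChIP-seq
study (steady state -> auxin depletion -> washout reintroduction):

* peaks of six planted classes placed on a small multi-chromosome
  genome, with negative-binomial counts whose condition means follow
  each class's planted log2 fold changes (|log2FC| = 3 by default) and
  per-sample size factors;
* a genome sequence at background GC 0.42 with GC-rich CpG islands
  (GC >= 0.65, CpG dinucleotide density >= 0.06) preferentially planted
  unmethylated at nucleation peaks, plus a per-CpG methylation table;
* labeled feature interval sets (cofactor- and chromatin-state-like)
  with planted overlap rates at nucleation vs control-exclusive peaks;
* loops with 0/1/2 nucleation anchors and distance-decay contact
  matrices carrying focal enrichment at loop pixels.

Every generator is a pure function of (config, seed): identical
configurations yield byte-identical bundles.  The planted truth is
written alongside the outputs and is never read by analysis modules.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as nio
from .diffbind import CountMatrix
from .exceptions import ConfigError
from .intervals import GenomicInterval, PeakSet
from .io import GeneModel
from .loops import ContactMatrix, Loop

__all__ = [
    "SimConfig",
    "TruthTable",
    "generate_truth",
    "generate_counts",
    "generate_condition_calls",
    "generate_genome",
    "generate_methylation",
    "generate_genes",
    "generate_features",
    "generate_signal_track",
    "generate_loops_and_matrix",
    "write_bundle",
]

CLASS_ORDER = (
    "nucleation",
    "control_exclusive",
    "persistent",
    "new_in_auxin",
    "new_in_reintro",
    "background",
)

# planted (contrast1, contrast2) signs per class, in units of effect_size_lfc
_CLASS_LFC_SIGNS = {
    "nucleation": (-1, +1),
    "control_exclusive": (-1, 0),
    "persistent": (0, 0),
    "new_in_auxin": (+1, 0),
    "new_in_reintro": (0, +1),
    "background": (0, 0),
}

# planted per-condition peak-call presence per class
_CLASS_PRESENCE = {
    "nucleation": (True, False, True),
    "control_exclusive": (True, False, False),
    "persistent": (True, True, True),
    "new_in_auxin": (False, True, True),
    "new_in_reintro": (False, False, True),
    "background": (False, False, False),
}

CONDITIONS = ("steady_state", "auxin", "reintroduction")


@dataclass
class SimConfig:
    """Study-scale simulation parameters.

    Defaults mirror the study conditions at desk scale: ~1,100 nucleation
    peaks against ~4,700 other steady-state peaks, two replicates per
    condition, |log2FC| = 3 planted dynamics, log-normal peak widths with
    medians 1,342 bp (nucleation) and 714 bp (control-exclusive), 10 kb
    contact-matrix resolution, and loop anchor classes sized 500/260/102
    with mean spans 0.18/0.33/0.86 Mb.
    """

    seed: int
    # peak classes
    n_nucleation: int = 1100
    n_control_exclusive: int = 3800
    n_persistent: int = 900
    n_new_in_auxin: int = 370
    n_new_in_reintro: int = 450
    n_background: int = 180
    replicates: int = 2
    # genome
    n_chromosomes: int = 4
    chrom_length: int = 5_000_000
    min_peak_gap: int = 200
    # peak widths (log-normal, bp)
    nucleation_width_median: float = 1342.0
    control_width_median: float = 714.0
    other_width_median: float = 800.0
    width_sigma: float = 0.4
    # count model
    effect_size_lfc: float = 3.0
    baseline_mu_median: float = 500.0
    baseline_mu_sigma: float = 0.5
    low_mu_median: float = 25.0
    low_mu_sigma: float = 0.3
    dispersion_range: Tuple[float, float] = (0.01, 0.1)
    size_factor_range: Tuple[float, float] = (0.7, 1.4)
    # CpG islands and methylation
    background_gc: float = 0.42
    cgi_width: int = 1000
    cgi_cpg_token_rate: float = 0.12
    cgi_gc_min: float = 0.65
    cgi_cpg_density_min: float = 0.06
    p_cgi_at_nucleation: float = 0.8
    p_cgi_at_control: float = 0.3
    p_unmeth_cgi_nucleation: float = 0.9
    p_unmeth_cgi_control: float = 0.5
    n_cgi_random: int = 150
    p_unmeth_cgi_random: float = 0.5
    meth_rate_methylated_island: float = 0.6
    meth_rate_unmethylated_island: float = 0.05
    meth_rate_background_cpg: float = 0.8
    # labeled features: name -> (rate at nucleation, rate at control-exclusive)
    feature_rates: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "cofactor_primary": (0.95, 0.65),
            "cofactor_secondary": (0.80, 0.20),
            "state_bivalent": (0.93, 0.67),
            "state_repressed": (0.80, 0.08),
        }
    )
    feature_width: int = 600
    n_feature_noise: int = 500
    # genes
    p_gene_at_nucleation: float = 0.85
    p_gene_at_control: float = 0.35
    n_random_genes: int = 300
    gene_length_median: float = 20_000.0
    gene_length_sigma: float = 0.5
    # loops and contact matrices
    n_loops_zero: int = 500
    n_loops_one: int = 260
    n_loops_two: int = 102
    loop_span_mean_zero: float = 180_000.0
    loop_span_mean_one: float = 330_000.0
    loop_span_mean_two: float = 860_000.0
    loop_span_sigma: float = 0.5
    resolution: int = 10_000
    focal_factor: float = 5.0
    decay_scale: float = 100.0
    min_loop_span_bins: int = 3
    # background genomic bins (for genome-wide scaling factors)
    bin_background_mean: float = 50.0
    bin_dispersion: float = 0.02

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory for reproducibility")
        for name in (
            "n_nucleation",
            "n_control_exclusive",
            "n_persistent",
            "n_new_in_auxin",
            "n_new_in_reintro",
            "n_background",
            "n_loops_zero",
            "n_loops_one",
            "n_loops_two",
            "n_cgi_random",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.replicates < 1:
            raise ConfigError("need >= 1 replicate per condition")
        if self.dispersion_range[0] < 0 or self.dispersion_range[1] < self.dispersion_range[0]:
            raise ConfigError("invalid dispersion range")
        if self.chrom_length % self.resolution != 0:
            raise ConfigError("chrom_length must be a multiple of the resolution")

    def class_counts(self) -> Dict[str, int]:
        return {
            "nucleation": self.n_nucleation,
            "control_exclusive": self.n_control_exclusive,
            "persistent": self.n_persistent,
            "new_in_auxin": self.n_new_in_auxin,
            "new_in_reintro": self.n_new_in_reintro,
            "background": self.n_background,
        }

    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-scoped deterministic RNG derived from (seed, stage name)."""
        digest = int.from_bytes(stage.encode(), "big") % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, digest]))


@dataclass
class TruthTable:
    """Planted truth: per-peak table plus per-sample scale factors.

    ``peaks`` is indexed by peak name with columns chrom, start, end,
    label, mu (steady-state baseline mean), lfc1 (auxin vs steady state),
    lfc2 (reintroduction vs auxin), alpha (NB dispersion, Var = mu +
    alpha mu^2) and called_<condition> presence flags.
    """

    peaks: pd.DataFrame
    size_factors: pd.Series
    samples: pd.DataFrame

    def peak_set(self, label: Optional[str] = None) -> PeakSet:
        df = self.peaks if label is None else self.peaks[self.peaks["label"] == label]
        return PeakSet(
            [
                GenomicInterval(r.chrom, int(r.start), int(r.end), name=idx)
                for idx, r in df.iterrows()
            ],
            label=label or "all",
        )

    def condition_means(self) -> pd.DataFrame:
        """Expected (size-factor-free) mean per condition for every peak."""
        mu = self.peaks["mu"]
        return pd.DataFrame(
            {
                "steady_state": mu,
                "auxin": mu * 2.0 ** self.peaks["lfc1"],
                "reintroduction": mu * 2.0 ** (self.peaks["lfc1"] + self.peaks["lfc2"]),
            }
        )


def _place_peaks(
    rng: np.random.Generator, config: SimConfig, widths: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """Place peaks non-overlapping on the genome, classes interleaved."""
    n = len(widths)
    chrom_idx = rng.integers(0, config.n_chromosomes, size=n)
    rows = []
    for ci, chrom in enumerate(config.chrom_names()):
        mask = chrom_idx == ci
        w = widths[mask]
        lab = labels[mask]
        k = len(w)
        slack = config.chrom_length - int(w.sum()) - k * config.min_peak_gap
        if slack <= 0:
            raise ConfigError(
                f"{chrom}: genome shorter than total feature span "
                f"({w.sum()} bp of peaks on {config.chrom_length} bp)"
            )
        offsets = np.sort(rng.integers(0, slack, size=k))
        # order peaks randomly along the chromosome so classes interleave
        order = rng.permutation(k)
        w, lab = w[order], lab[order]
        starts = offsets + np.concatenate([[0], np.cumsum(w[:-1])]) + (
            np.arange(k) * config.min_peak_gap
        )
        for s, width, label in zip(starts, w, lab):
            rows.append((chrom, int(s), int(s + width), label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    df.index = pd.Index([f"peak_{i:05d}" for i in range(len(df))], name="feature")
    return df


def generate_truth(config: SimConfig) -> TruthTable:
    """Plant the per-peak truth table and per-sample size factors."""
    rng = config.rng("truth")
    widths_list, labels_list = [], []
    width_medians = {
        "nucleation": config.nucleation_width_median,
        "control_exclusive": config.control_width_median,
    }
    for label in CLASS_ORDER:
        k = config.class_counts()[label]
        med = width_medians.get(label, config.other_width_median)
        w = np.maximum(
            50, rng.lognormal(math.log(med), config.width_sigma, size=k)
        ).astype(int)
        widths_list.append(w)
        labels_list.append(np.full(k, label, dtype=object))
    widths = np.concatenate(widths_list)
    labels = np.concatenate(labels_list)
    peaks = _place_peaks(rng, config, widths, labels)

    high = ~peaks["label"].isin(["new_in_auxin", "new_in_reintro", "background"])
    mu = np.where(
        high,
        rng.lognormal(math.log(config.baseline_mu_median), config.baseline_mu_sigma, len(peaks)),
        rng.lognormal(math.log(config.low_mu_median), config.low_mu_sigma, len(peaks)),
    )
    signs = np.array([_CLASS_LFC_SIGNS[l] for l in peaks["label"]], dtype=float)
    peaks["mu"] = mu
    peaks["lfc1"] = signs[:, 0] * config.effect_size_lfc
    peaks["lfc2"] = signs[:, 1] * config.effect_size_lfc
    peaks["alpha"] = rng.uniform(*config.dispersion_range, size=len(peaks))
    presence = np.array([_CLASS_PRESENCE[l] for l in peaks["label"]], dtype=bool)
    for j, cond in enumerate(CONDITIONS):
        peaks[f"called_{cond}"] = presence[:, j]

    samples = pd.DataFrame(
        [
            (f"{cond}_rep{r + 1}", cond, r + 1)
            for cond in CONDITIONS
            for r in range(config.replicates)
        ],
        columns=["sample", "condition", "replicate"],
    ).set_index("sample")
    log_lo, log_hi = math.log(config.size_factor_range[0]), math.log(
        config.size_factor_range[1]
    )
    size_factors = pd.Series(
        np.exp(rng.uniform(log_lo, log_hi, size=len(samples))),
        index=samples.index,
        name="size_factor",
    )
    return TruthTable(peaks=peaks, size_factors=size_factors, samples=samples)


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """NB(mean, Var = mean + alpha mean^2) via gamma-Poisson mixing.

    Dispersions below 1e-8 fall back to the Poisson limit.
    """
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = alpha < 1e-8
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        a = alpha[~tiny]
        lam = rng.gamma(shape=1.0 / a, scale=mean[~tiny] * a)
        out[~tiny] = rng.poisson(lam)
    return out


def generate_counts(truth: TruthTable, config: SimConfig) -> CountMatrix:
    """Draw the peak x sample NB count matrix from the planted truth."""
    rng = config.rng("counts")
    cond_means = truth.condition_means()
    data = {}
    for sample, row in truth.samples.iterrows():
        m = cond_means[row["condition"]].values * truth.size_factors[sample]
        data[sample] = _nb_draw(rng, m, truth.peaks["alpha"].values)
    counts = pd.DataFrame(data, index=truth.peaks.index)
    return CountMatrix(counts=counts, samples=truth.samples.copy())


def generate_bin_counts(truth: TruthTable, config: SimConfig) -> CountMatrix:
    """Background read counts over uniform genomic bins.

    Emulates the genome-wide coverage summary used to derive per-sample
    scaling factors: bin means are condition-independent (background
    signal), so their between-sample ratios reflect only the planted
    size factors — unlike the peak matrix, whose composition shifts with
    the global binding loss.
    """
    rng = config.rng("bin_counts")
    n_bins = (config.chrom_length // config.resolution) * config.n_chromosomes
    names = pd.Index([f"bin_{i:05d}" for i in range(n_bins)], name="feature")
    data = {}
    for sample in truth.samples.index:
        m = np.full(n_bins, config.bin_background_mean * truth.size_factors[sample])
        data[sample] = _nb_draw(rng, m, np.full(n_bins, config.bin_dispersion))
    return CountMatrix(counts=pd.DataFrame(data, index=names), samples=truth.samples.copy())


def generate_condition_calls(truth: TruthTable, config: SimConfig) -> Dict[str, PeakSet]:
    """Per-condition peak calls derived from the planted presence flags."""
    calls = {}
    for cond in CONDITIONS:
        mask = truth.peaks[f"called_{cond}"]
        calls[cond] = PeakSet(
            [
                GenomicInterval(r.chrom, int(r.start), int(r.end), name=idx)
                for idx, r in truth.peaks[mask].iterrows()
            ],
            label=cond,
        )
    return calls


# ---------------------------------------------------------------------------
# Genome, CpG islands and methylation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _cgi_sequence(rng: np.random.Generator, width: int, config: SimConfig) -> str:
    """GC- and CpG-rich island sequence; retried until the contract holds."""
    gc_rich = np.array([0.165, 0.335, 0.335, 0.165])
    for _ in range(20):
        parts: List[str] = []
        length = 0
        is_cg = rng.random(width) < config.cgi_cpg_token_rate
        singles = rng.choice(4, size=width, p=gc_rich)
        for flag, s in zip(is_cg, singles):
            if flag:
                parts.append("CG")
                length += 2
            else:
                parts.append("ACGT"[s])
                length += 1
            if length >= width:
                break
        seq = "".join(parts)[:width]
        gc = (seq.count("G") + seq.count("C")) / width
        cpg = seq.count("CG") / width
        if gc >= config.cgi_gc_min and cpg >= config.cgi_cpg_density_min:
            return seq
    raise ConfigError("could not satisfy CGI composition contract; widen cgi_width")


def generate_genome(
    config: SimConfig, truth: Optional[TruthTable] = None
) -> Tuple[Dict[str, str], PeakSet, pd.DataFrame]:
    """Random genome with planted CpG islands.

    Returns (sequences, island PeakSet, island truth).  With ``truth``
    given, islands are planted at nucleation and control-exclusive peak
    midpoints with the configured probabilities (plus random islands);
    without it, only randomly-placed islands are generated.  The island
    truth frame records the planted methylation status and the class of
    the peak each island sits on (or "random").
    """
    rng = config.rng("genome")
    gc = config.background_gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences = {
        chrom: _BASES[rng.choice(4, size=config.chrom_length, p=p)].tobytes().decode()
        for chrom in config.chrom_names()
    }

    candidates: List[Tuple[str, int, str]] = []  # (chrom, center, origin class)
    if truth is not None:
        for label, prob in (
            ("nucleation", config.p_cgi_at_nucleation),
            ("control_exclusive", config.p_cgi_at_control),
        ):
            sub = truth.peaks[truth.peaks["label"] == label]
            keep = rng.random(len(sub)) < prob
            for (idx, r), k in zip(sub.iterrows(), keep):
                if k:
                    candidates.append((r.chrom, (int(r.start) + int(r.end)) // 2, label))
    for _ in range(config.n_cgi_random):
        chrom = config.chrom_names()[rng.integers(config.n_chromosomes)]
        center = int(
            rng.integers(config.cgi_width, config.chrom_length - config.cgi_width)
        )
        candidates.append((chrom, center, "random"))

    half = config.cgi_width // 2
    accepted: List[Tuple[str, int, int, str]] = []
    last_end: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, center, origin in candidates:
        start = max(0, center - half)
        end = min(config.chrom_length, start + config.cgi_width)
        if end - start < config.cgi_width:
            start = end - config.cgi_width
        if any(s < end and start < e for s, e in last_end.get(chrom, [])):
            continue  # overlapping a previously planted island: skip
        last_end.setdefault(chrom, []).append((start, end))
        accepted.append((chrom, start, end, origin))

    unmeth_prob = {
        "nucleation": config.p_unmeth_cgi_nucleation,
        "control_exclusive": config.p_unmeth_cgi_control,
        "random": config.p_unmeth_cgi_random,
    }
    islands, rows = [], []
    seq_arrays = {c: bytearray(s, "ascii") for c, s in sequences.items()}
    for i, (chrom, start, end, origin) in enumerate(
        sorted(accepted, key=lambda t: (t[0], t[1]))
    ):
        name = f"cgi_{i:04d}"
        seq_arrays[chrom][start:end] = _cgi_sequence(rng, end - start, config).encode()
        status = (
            "unmethylated" if rng.random() < unmeth_prob[origin] else "methylated"
        )
        islands.append(GenomicInterval(chrom, start, end, name=name))
        rows.append((name, chrom, start, end, origin, status))
    sequences = {c: bytes(a).decode() for c, a in seq_arrays.items()}
    cgi_truth = pd.DataFrame(
        rows, columns=["name", "chrom", "start", "end", "origin", "planted_status"]
    ).set_index("name")
    return sequences, PeakSet(islands, label="cgi"), cgi_truth


def _cpg_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


def generate_methylation(
    cgis: PeakSet,
    cgi_truth: pd.DataFrame,
    sequences: Dict[str, str],
    config: SimConfig,
) -> pd.DataFrame:
    """Per-CpG methylation table over the whole genome.

    Island CpGs follow the planted island status — methylated islands get
    >= 20% of their CpGs above level 0.5, unmethylated islands fewer —
    while background CpGs are mostly methylated, as in somatic genomes.
    Islands containing no CpG are skipped with a warning.
    """
    rng = config.rng("methylation")
    frames = []
    for chrom in sorted(sequences):
        pos = _cpg_positions(sequences[chrom])
        level = np.where(
            rng.random(len(pos)) < config.meth_rate_background_cpg,
            rng.uniform(0.7, 1.0, len(pos)),
            rng.uniform(0.0, 0.3, len(pos)),
        )
        for iv in cgis:
            if iv.chrom != chrom:
                continue
            lo = int(np.searchsorted(pos, iv.start, side="left"))
            hi = int(np.searchsorted(pos, iv.end, side="left"))
            n = hi - lo
            if n == 0:
                warnings.warn(f"island {iv.name} contains no CpG; skipped")
                continue
            status = cgi_truth.loc[iv.name, "planted_status"]
            floor = math.ceil(0.2 * n)
            if status == "methylated":
                n_meth = int(
                    np.clip(rng.binomial(n, config.meth_rate_methylated_island), floor, n)
                )
            else:
                n_meth = int(
                    np.clip(
                        rng.binomial(n, config.meth_rate_unmethylated_island),
                        0,
                        max(floor - 1, 0),
                    )
                )
            meth_idx = rng.choice(n, size=n_meth, replace=False)
            lv = rng.uniform(0.0, 0.3, n)
            lv[meth_idx] = rng.uniform(0.7, 1.0, n_meth)
            level[lo:hi] = lv
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "level": level}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Genes, labeled features, signal track


def generate_genes(truth: TruthTable, config: SimConfig) -> List[GeneModel]:
    """Gene models with TSSs preferentially planted at nucleation peaks."""
    rng = config.rng("genes")
    tss_sites: List[Tuple[str, int]] = []
    for label, prob in (
        ("nucleation", config.p_gene_at_nucleation),
        ("control_exclusive", config.p_gene_at_control),
    ):
        sub = truth.peaks[truth.peaks["label"] == label]
        keep = rng.random(len(sub)) < prob
        for (idx, r), k in zip(sub.iterrows(), keep):
            if k:
                mid = (int(r.start) + int(r.end)) // 2
                tss_sites.append((r.chrom, mid + int(rng.integers(-200, 201))))
    for _ in range(config.n_random_genes):
        chrom = config.chrom_names()[rng.integers(config.n_chromosomes)]
        tss_sites.append((chrom, int(rng.integers(50_000, config.chrom_length - 50_000))))

    genes: List[GeneModel] = []
    for i, (chrom, tss) in enumerate(tss_sites):
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(
            np.clip(
                rng.lognormal(math.log(config.gene_length_median), config.gene_length_sigma),
                1_000,
                200_000,
            )
        )
        if strand == "+":
            start = max(0, min(tss, config.chrom_length - length - 1))
            tss = start
            end = start + length
        else:
            end = min(config.chrom_length, max(tss + 1, length + 1))
            tss = end - 1
            start = end - length
        k = int(rng.integers(1, 5))
        cuts = np.sort(rng.choice(np.arange(start + 1, end), size=2 * k, replace=False))
        exons = tuple((int(cuts[2 * j]), int(cuts[2 * j + 1])) for j in range(k))
        genes.append(
            GeneModel(
                gene_id=f"gene_{i:04d}",
                chrom=chrom,
                tss=tss,
                body=GenomicInterval(chrom, start, end),
                strand=strand,
                exons=exons,
            )
        )
    return genes


def generate_features(truth: TruthTable, config: SimConfig) -> Dict[str, PeakSet]:
    """Labeled feature interval sets with planted per-class overlap rates.

    Each named feature covers nucleation / control-exclusive peaks with
    the configured Bernoulli rates (interval jittered around the peak
    midpoint) plus ``n_feature_noise`` random intervals per set.
    """
    rng = config.rng("features")
    half = config.feature_width // 2
    out: Dict[str, PeakSet] = {}
    for fname, (rate_nuc, rate_ctrl) in config.feature_rates.items():
        ivs: List[GenomicInterval] = []
        for label, rate in (
            ("nucleation", rate_nuc),
            ("control_exclusive", rate_ctrl),
        ):
            sub = truth.peaks[truth.peaks["label"] == label]
            keep = rng.random(len(sub)) < rate
            for (idx, r), k in zip(sub.iterrows(), keep):
                if not k:
                    continue
                mid = (int(r.start) + int(r.end)) // 2 + int(rng.integers(-200, 201))
                start = max(0, mid - half)
                ivs.append(
                    GenomicInterval(
                        r.chrom, start, min(start + config.feature_width, config.chrom_length)
                    )
                )
        for _ in range(config.n_feature_noise):
            chrom = config.chrom_names()[rng.integers(config.n_chromosomes)]
            start = int(rng.integers(0, config.chrom_length - config.feature_width))
            ivs.append(GenomicInterval(chrom, start, start + config.feature_width))
        out[fname] = PeakSet(ivs, label=fname)
    return out


def generate_signal_track(config: SimConfig, n_blocks_per_chrom: int = 2000) -> pd.DataFrame:
    """A peak-agnostic bedGraph signal (random blocks, no planted contrast)."""
    rng = config.rng("signal")
    rows = []
    block = 500
    for chrom in config.chrom_names():
        grid = np.arange(0, config.chrom_length - block, block)
        n_blocks = min(n_blocks_per_chrom, len(grid) // 2)
        starts = np.sort(rng.choice(grid, size=n_blocks, replace=False))
        values = rng.lognormal(0.0, 0.5, size=n_blocks)
        for s, v in zip(starts, values):
            rows.append((chrom, int(s), int(s) + block, float(v)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# Loops and contact matrices


def _decay_matrix(n_bins: int, c: float) -> np.ndarray:
    idx = np.arange(n_bins)
    return c / (1.0 + np.abs(idx[:, None] - idx[None, :]))


def generate_loops_and_matrix(
    truth: TruthTable, config: SimConfig
) -> Tuple[List[Loop], Dict[str, ContactMatrix]]:
    """Loops with 0/1/2 nucleation anchors plus focal-enriched contact maps.

    The matrix is the distance-decay background ``c / (1 + |i - j|)``
    with loop pixels set to ``focal_factor`` times the background at the
    same distance; loops spanning fewer than ``min_loop_span_bins`` bins
    are rejected and resampled.  Anchors are bin-aligned intervals of one
    resolution width.
    """
    rng = config.rng("loops")
    res = config.resolution
    n_bins = config.chrom_length // res
    chroms = config.chrom_names()
    nuc = truth.peaks[truth.peaks["label"] == "nucleation"]
    nuc_mids = {
        chrom: np.sort(((sub["start"] + sub["end"]) // 2).to_numpy())
        for chrom, sub in nuc.groupby("chrom")
    }
    nuc_set = truth.peak_set("nucleation")
    nuc_by_chrom = nuc_set.by_chrom()

    def bin_of(pos: int) -> int:
        return min(int(pos) // res, n_bins - 1)

    def anchor_at(chrom: str, pos: int) -> GenomicInterval:
        b = bin_of(pos)
        return GenomicInterval(chrom, b * res, (b + 1) * res)

    def anchor_hits_nucleation(chrom: str, pos: int) -> bool:
        ca = nuc_by_chrom.get(chrom)
        if ca is None:
            return False
        b = bin_of(pos)
        s, e = b * res, (b + 1) * res
        j = int(np.searchsorted(ca.merged_starts, e, side="left")) - 1
        return j >= 0 and ca.merged_ends[j] > s

    min_span = config.min_loop_span_bins * res
    loops: List[Loop] = []

    def draw_span(mean: float) -> int:
        return int(rng.lognormal(math.log(mean), config.loop_span_sigma))

    # two-nucleation-anchor loops: pick a nucleation site, walk a target
    # span toward the nearest other nucleation site
    for _ in range(config.n_loops_two):
        for _attempt in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            mids = nuc_mids.get(chrom)
            if mids is None or len(mids) < 2:
                continue
            a = int(mids[rng.integers(len(mids))])
            target = a + (1 if rng.random() < 0.5 else -1) * draw_span(
                config.loop_span_mean_two
            )
            j = int(np.clip(np.searchsorted(mids, target), 0, len(mids) - 1))
            cand = [mids[k] for k in (j - 1, j) if 0 <= k < len(mids)]
            b = int(min(cand, key=lambda m: abs(m - target)))
            if abs(b - a) >= min_span and bin_of(a) != bin_of(b):
                loops.append(Loop.from_anchors(anchor_at(chrom, a), anchor_at(chrom, b)))
                break
        else:
            raise ConfigError("could not place a two-anchor loop; genome too small")

    def random_non_nucleation_pos(chrom: str) -> Optional[int]:
        pos = int(rng.integers(0, config.chrom_length))
        return pos if not anchor_hits_nucleation(chrom, pos) else None

    # one-anchor loops: one nucleation anchor, one background anchor
    for _ in range(config.n_loops_one):
        for _attempt in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            mids = nuc_mids.get(chrom)
            if mids is None or len(mids) == 0:
                continue
            a = int(mids[rng.integers(len(mids))])
            b = a + (1 if rng.random() < 0.5 else -1) * draw_span(
                config.loop_span_mean_one
            )
            if not (0 <= b < config.chrom_length) or abs(b - a) < min_span:
                continue
            if anchor_hits_nucleation(chrom, b):
                continue
            loops.append(Loop.from_anchors(anchor_at(chrom, a), anchor_at(chrom, b)))
            break
        else:
            raise ConfigError("could not place a one-anchor loop")

    # zero-anchor loops: both anchors off nucleation sites
    for _ in range(config.n_loops_zero):
        for _attempt in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            a = random_non_nucleation_pos(chrom)
            if a is None:
                continue
            b = a + (1 if rng.random() < 0.5 else -1) * draw_span(
                config.loop_span_mean_zero
            )
            if not (0 <= b < config.chrom_length) or abs(b - a) < min_span:
                continue
            if anchor_hits_nucleation(chrom, b):
                continue
            loops.append(Loop.from_anchors(anchor_at(chrom, a), anchor_at(chrom, b)))
            break
        else:
            raise ConfigError("could not place a zero-anchor loop")

    matrices: Dict[str, ContactMatrix] = {}
    values = {chrom: _decay_matrix(n_bins, config.decay_scale) for chrom in chroms}
    for lp in loops:
        m = values[lp.anchor1.chrom]
        b1 = bin_of(lp.anchor1.midpoint)
        b2 = bin_of(lp.anchor2.midpoint)
        bg = config.decay_scale / (1.0 + abs(b2 - b1))
        m[b1, b2] = m[b2, b1] = config.focal_factor * bg
    for chrom in chroms:
        matrices[chrom] = ContactMatrix(
            chrom=chrom,
            resolution=res,
            bin_starts=np.arange(n_bins, dtype=np.int64) * res,
            values=values[chrom],
        )
    return loops, matrices


# ---------------------------------------------------------------------------
# Bundle writer


def write_bundle(config: SimConfig, outdir) -> Dict[str, str]:
    """Generate and write the full fixture bundle; returns a path manifest.

    The planted truth (``truth_peaks.tsv``, ``cgi_truth.tsv``,
    ``truth_size_factors.tsv``) is written alongside the analysis inputs
    but is never consumed by analysis modules.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}

    def p(name: str) -> str:
        paths[name] = str(outdir / name)
        return paths[name]

    truth = generate_truth(config)
    counts = generate_counts(truth, config)
    bin_counts = generate_bin_counts(truth, config)
    calls = generate_condition_calls(truth, config)
    sequences, cgis, cgi_truth = generate_genome(config, truth)
    meth = generate_methylation(cgis, cgi_truth, sequences, config)
    genes = generate_genes(truth, config)
    features = generate_features(truth, config)
    signal = generate_signal_track(config)
    loops, matrices = generate_loops_and_matrix(truth, config)

    truth.peaks.to_csv(p("truth_peaks.tsv"), sep="\t")
    truth.size_factors.to_frame().to_csv(p("truth_size_factors.tsv"), sep="\t")
    cgi_truth.to_csv(p("cgi_truth.tsv"), sep="\t")
    nio.write_counts(counts.counts, p("counts.tsv"))
    nio.write_counts(bin_counts.counts, p("bin_counts.tsv"))
    nio.write_sample_sheet(truth.samples, p("samples.tsv"))
    for cond, ps in calls.items():
        nio.write_narrowpeak(ps, p(f"calls_{cond}.narrowPeak"))
    nio.write_fasta(sequences, p("genome.fa"))
    nio.write_bed(cgis, p("cgi.bed"))
    nio.write_methylation_table(meth, p("methylation.tsv"))
    nio.write_gene_models(genes, p("genes.tsv"))
    for fname, ps in features.items():
        nio.write_bed(ps, p(f"feature_{fname}.bed"))
    signal.to_csv(p("signal.bedgraph"), sep="\t", header=False, index=False)
    nio.write_bedpe(loops, p("loops.bedpe"))
    for chrom, m in matrices.items():
        nio.write_contact_matrix(m, p(f"matrix_{chrom}.tsv"), p(f"bins_{chrom}.bed"))
    with open(outdir / "bundle_manifest.json", "w") as fh:
        json.dump(
            {"seed": config.seed, "paths": sorted(paths)}, fh, indent=2, sort_keys=True
        )
    paths["bundle_manifest.json"] = str(outdir / "bundle_manifest.json")
    return paths
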