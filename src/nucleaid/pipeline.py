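"""End-to-end pipeline: simulate -> diffbind -> classify -> enrich -> cgi -> loops.

Every stage is a plain function over in-memory objects from the other
modules; :func:`run_pipeline` chains them, writes TSV/BED outputs with a
provenance header (tool version, config hash, stage seed) and a run
manifest, and is idempotent: the same config and seed reproduce every
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as nio
from .classify import (
    CONDITIONS,
    ClassifierThresholds,
    PeakClassification,
    annotate_genomic_context,
    classify,
    flag_presence,
    interpeak_distances,
    nearest_gene,
    width_stats,
)
from .diffbind import (
    CountMatrix,
    estimate_dispersion,
    estimate_size_factors,
    merge_union,
    wald_contrast,
)
from .enrichment import fisher_overlap, resample_enrichment, signal_density
from .exceptions import ConfigError, DataError
from .intervals import PeakSet
from .loops import apa, classify_loop_anchors, span_stats, virtual_4c
from .methylation import call_island_status, cgi_enrichment, gc_content, island_calls_frame
from .simulate import SimConfig, write_bundle

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "diffbind", "classify", "enrich", "cgi", "loops")


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    With ``simulate=True`` (default) a synthetic bundle is generated
    under ``<outdir>/sim`` and consumed by the downstream stages; with
    ``simulate=False`` the ``inputs`` mapping must point at existing
    files using the same keys the bundle writer emits (``counts.tsv``,
    ``calls_<condition>.narrowPeak``, ``cgi.bed``, ...).
    """

    seed: int
    outdir: str
    simulate: bool = True
    inputs: Dict[str, str] = field(default_factory=dict)
    sim_overrides: Dict[str, object] = field(default_factory=dict)
    lfc_min: float = 1.5
    padj_max: float = 0.005
    resample_n: int = 1000
    apa_w: int = 5
    promoter_halfwidth: int = 2000
    n_random_gc_regions: int = 10_000
    stages: Tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is required")
        if not (0 < self.padj_max < 1) or self.lfc_min <= 0:
            raise ConfigError("thresholds outside documented ranges")
        if self.resample_n < 1 or self.apa_w < 1 or self.promoter_halfwidth < 0:
            raise ConfigError("thresholds outside documented ranges")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s): {unknown}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir")  # hash the analytic config, not the output location
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        digest = int.from_bytes(stage.encode(), "big") % (2**31)
        ss = np.random.SeedSequence([self.seed, digest])
        return int(ss.generate_state(1)[0] % (2**31))

    def thresholds(self) -> ClassifierThresholds:
        return ClassifierThresholds(lfc_min=self.lfc_min, padj_max=self.padj_max)


def _header(config: PipelineConfig, stage: str) -> str:
    return (
        f"nucleaid v{__version__} config={config.config_hash()} "
        f"stage={stage} seed={config.stage_seed(stage)}"
    )


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index_label="feature") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index_label=index_label, float_format="%.6g")


def _input(config: PipelineConfig, paths: Dict[str, str], key: str) -> str:
    p = paths.get(key) or config.inputs.get(key)
    if p is None or not Path(p).exists():
        raise DataError(f"required input {key!r} missing (looked for {p})")
    return p


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the configured stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    paths: Dict[str, str] = dict(config.inputs)
    state: Dict[str, object] = {}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            rows = _STAGE_FUNCS[stage](config, outdir, paths, state)
            manifest["stages"][stage] = {
                "seed": config.stage_seed(stage),
                "row_counts": rows,
            }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        raise
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _stage_simulate(config, outdir, paths, state) -> Dict[str, int]:
    if not config.simulate:
        return {"skipped": 0}
    sim = SimConfig(seed=config.stage_seed("simulate"), **config.sim_overrides)
    bundle = write_bundle(sim, Path(outdir) / "sim")
    paths.update(bundle)
    state["sim_config"] = sim
    return {"files": len(bundle)}


def _load_counts(config, paths) -> CountMatrix:
    counts = nio.read_counts(_input(config, paths, "counts.tsv"))
    samples = nio.read_sample_sheet(_input(config, paths, "samples.tsv"))
    return CountMatrix(counts=counts, samples=samples.loc[counts.columns])


def _stage_diffbind(config, outdir, paths, state) -> Dict[str, int]:
    calls = {
        cond: nio.read_bed(
            _input(config, paths, f"calls_{cond}.narrowPeak"), label=cond
        )
        for cond in CONDITIONS
    }
    union = merge_union([calls[c] for c in CONDITIONS])
    cm_all = _load_counts(config, paths)
    # union peaks inherit counts from their contributing source peaks
    source_lists = []
    for name in union.names:
        sources = [s for s in union.sources[name] if s in cm_all.counts.index]
        if not sources:
            raise DataError(f"union peak {name} has no counts for its sources")
        source_lists.append(sources)
    if all(len(s) == 1 for s in source_lists):
        counts_union = cm_all.counts.loc[[s[0] for s in source_lists]]
        counts_union.index = pd.Index(union.names, name="feature")
    else:
        counts_union = pd.DataFrame(
            [cm_all.counts.loc[s].sum(axis=0) for s in source_lists],
            index=pd.Index(union.names, name="feature"),
        )
    cm = CountMatrix(counts=counts_union, samples=cm_all.samples)
    # scaling factors come from genome-wide background bins when available:
    # the peak matrix's composition shifts with the global binding loss, so
    # median-of-ratios on peaks alone would absorb the depletion signal
    bin_key = "bin_counts.tsv"
    if bin_key in paths or bin_key in config.inputs:
        bc = CountMatrix(
            counts=nio.read_counts(_input(config, paths, bin_key)),
            samples=cm_all.samples,
        )
        estimate_size_factors(bc)
        cm.size_factors = bc.size_factors
    else:
        estimate_size_factors(cm)
    disp = estimate_dispersion(cm)
    c1 = wald_contrast(cm, "steady_state", "auxin", dispersions=disp)
    c2 = wald_contrast(cm, "auxin", "reintroduction", dispersions=disp)

    h = _header(config, "diffbind")
    nio.write_bed(union, outdir / "union.bed", header=h)
    _write_tsv(
        cm.size_factors.to_frame(), outdir / "size_factors.tsv", h, index_label="sample"
    )
    _write_tsv(c1.table, outdir / "contrast_auxin_vs_steady_state.tsv", h)
    _write_tsv(c2.table, outdir / "contrast_reintroduction_vs_auxin.tsv", h)
    state.update({"calls": calls, "union": union, "cm": cm, "c1": c1, "c2": c2})
    return {"union_peaks": len(union), "samples": cm.counts.shape[1]}


def _stage_classify(config, outdir, paths, state) -> Dict[str, int]:
    union: PeakSet = state["union"]
    presence = flag_presence(union, state["calls"])
    cls = classify(presence, state["c1"], state["c2"], config.thresholds())
    table = cls.table.copy()
    coords = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in union],
            "start": [iv.start for iv in union],
            "end": [iv.end for iv in union],
        },
        index=pd.Index(union.names, name="feature"),
    )
    table = coords.join(table)

    genes_path = paths.get("genes.tsv") or config.inputs.get("genes.tsv")
    if genes_path and Path(genes_path).exists():
        genes = nio.read_gene_models(genes_path)
        table["context"] = annotate_genomic_context(
            union, genes, promoter_halfwidth=config.promoter_halfwidth
        )
        ng = nearest_gene(union, genes)
        table["nearest_gene"] = ng["gene_id"]
        table["tss_distance"] = ng["distance"]

    widths = width_stats(cls, union)
    # interpeak distances are within-class: each class's peaks against
    # their own nearest same-class neighbour
    dist_rows = []
    for label in ("nucleation", "control_exclusive", "persistent"):
        names = cls.names_for(label)
        if len(names) < 2:
            continue
        try:
            d = interpeak_distances(union.subset(names, label=label)).dropna()
        except DataError:
            continue
        dist_rows.append(
            {
                "label": label,
                "count": int(d.count()),
                "median": float(d.median()),
                "mean": float(d.mean()),
            }
        )
    dist_summary = pd.DataFrame(dist_rows).set_index("label")

    h = _header(config, "classify")
    _write_tsv(table, outdir / "classification.tsv", h)
    _write_tsv(widths, outdir / "width_stats.tsv", h, index_label="label")
    _write_tsv(
        dist_summary, outdir / "interpeak_distance_summary.tsv", h, index_label="label"
    )
    for label in ("nucleation", "control_exclusive"):
        names = cls.names_for(label)
        if names:
            nio.write_bed(union.subset(names, label=label), outdir / f"{label}.bed", header=h)
    state["classification"] = cls
    return cls.class_sizes()


def _query_background(state) -> Tuple[PeakSet, PeakSet]:
    cls: PeakClassification = state["classification"]
    union: PeakSet = state["union"]
    query = union.subset(cls.names_for("nucleation"), label="nucleation")
    background = union.subset(cls.names_for("control_exclusive"), label="control_exclusive")
    if len(query) == 0 or len(background) == 0:
        raise DataError("classification produced an empty nucleation or background set")
    return query, background


def _stage_enrich(config, outdir, paths, state) -> Dict[str, int]:
    query, background = _query_background(state)
    seed = config.stage_seed("enrich")
    feature_keys = sorted(
        k for k in paths if k.startswith("feature_") and k.endswith(".bed")
    )
    rows = []
    for i, key in enumerate(feature_keys):
        feature = nio.read_bed(_input(config, paths, key), label=key)
        rr = resample_enrichment(
            query, background, feature, n_draws=config.resample_n, seed=seed + i
        )
        table, fisher_p, oddsr = fisher_overlap(query, background, feature)
        rows.append(
            {
                "feature": key[len("feature_") : -len(".bed")],
                "observed": rr.observed,
                "expected": rr.expected,
                "oe_ratio": rr.oe_ratio,
                "p_empirical": rr.p_empirical,
                "fisher_p": fisher_p,
                "odds_ratio": oddsr,
                "n_draws": rr.n_draws,
                "seed": rr.seed,
            }
        )
    report = pd.DataFrame(rows).set_index("feature")
    h = _header(config, "enrich")
    _write_tsv(report, outdir / "enrichment_report.tsv", h, index_label="feature")

    signal_key = "signal.bedgraph"
    if signal_key in paths or signal_key in config.inputs:
        signal = nio.read_bedgraph(_input(config, paths, signal_key))
        _, mean_query, _ = signal_density(query, signal)
        _, mean_bg, _ = signal_density(background, signal)
        _write_tsv(
            pd.DataFrame(
                {"group": ["nucleation", "control_exclusive"], "mean_signal": [mean_query, mean_bg]}
            ).set_index("group"),
            outdir / "signal_density.tsv",
            h,
            index_label="group",
        )
    state["enrichment_report"] = report
    return {"features": len(report)}


def _stage_cgi(config, outdir, paths, state) -> Dict[str, int]:
    islands = nio.read_bed(_input(config, paths, "cgi.bed"), label="cgi")
    records = nio.read_methylation_table(_input(config, paths, "methylation.tsv"))
    calls = call_island_status(islands, records)
    frame = island_calls_frame(calls)
    query, background = _query_background(state)
    oe = cgi_enrichment(
        query, background, calls, n_draws=config.resample_n, seed=config.stage_seed("cgi")
    )
    report = pd.DataFrame(
        [
            {
                "status": status,
                "observed": rr.observed,
                "expected": rr.expected,
                "oe_ratio": rr.oe_ratio,
                "p_empirical": rr.p_empirical,
                "n_draws": rr.n_draws,
                "seed": rr.seed,
            }
            for status, rr in sorted(oe.items())
        ]
    ).set_index("status")

    h = _header(config, "cgi")
    _write_tsv(frame.set_index("name"), outdir / "island_calls.tsv", h, index_label="name")
    _write_tsv(report, outdir / "cgi_enrichment.tsv", h, index_label="status")

    genome_key = "genome.fa"
    if genome_key in paths or genome_key in config.inputs:
        seqs = nio.read_fasta(_input(config, paths, genome_key))
        rng = np.random.default_rng(config.stage_seed("cgi"))
        gc_rows = []
        for group, ps in (("nucleation", query), ("control_exclusive", background)):
            vals = [
                gc_content(seqs[iv.chrom][iv.start : iv.end])
                for iv in ps
                if iv.chrom in seqs
            ]
            gc_rows.append({"group": group, "n": len(vals), "median_gc": float(np.median(vals))})
        widths = query.widths()
        chroms = sorted(seqs)
        rand_vals = []
        for _ in range(config.n_random_gc_regions):
            w = int(widths[rng.integers(len(widths))])
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, max(1, len(seqs[chrom]) - w)))
            rand_vals.append(gc_content(seqs[chrom][start : start + w]))
        gc_rows.append(
            {
                "group": "random",
                "n": len(rand_vals),
                "median_gc": float(np.median(rand_vals)),
            }
        )
        _write_tsv(
            pd.DataFrame(gc_rows).set_index("group"),
            outdir / "gc_content.tsv",
            h,
            index_label="group",
        )
    state["island_calls"] = calls
    state["cgi_enrichment"] = oe
    return {"islands": len(calls)}


def _stage_loops(config, outdir, paths, state) -> Dict[str, int]:
    loops = nio.read_bedpe(_input(config, paths, "loops.bedpe"))
    query, _ = _query_background(state)
    loops = classify_loop_anchors(loops, query)
    matrices = {}
    for key in sorted(paths):
        if key.startswith("matrix_") and key.endswith(".tsv"):
            chrom = key[len("matrix_") : -len(".tsv")]
            m = nio.read_contact_matrix(
                _input(config, paths, key), _input(config, paths, f"bins_{chrom}.bed")
            )
            matrices[m.chrom] = m
    stats = span_stats(loops)
    span_rows = [
        {
            "n_nucleation_anchors": k,
            "n": stats.group_n[k],
            "mean_span_bp": stats.group_mean[k],
        }
        for k in sorted(stats.groups)
    ]
    apa_rows = []
    if matrices:
        for k in sorted({lp.n_nucleation_anchors for lp in loops}):
            sub = [lp for lp in loops if lp.n_nucleation_anchors == k]
            try:
                res = apa(sub, matrices, w=config.apa_w)
            except DataError:
                continue
            apa_rows.append(
                {
                    "n_nucleation_anchors": k,
                    "n_loops": res.n_loops,
                    "n_excluded": res.n_excluded,
                    "apa_score": res.score,
                }
            )
    h = _header(config, "loops")
    _write_tsv(
        pd.DataFrame(span_rows).set_index("n_nucleation_anchors"),
        outdir / "loop_span_stats.tsv",
        h,
        index_label="n_nucleation_anchors",
    )
    _write_tsv(
        pd.DataFrame(
            [{"F": stats.f_stat, "p_value": stats.p_value}], index=pd.Index(["anova"], name="test")
        ),
        outdir / "loop_span_anova.tsv",
        h,
        index_label="test",
    )
    if apa_rows:
        _write_tsv(
            pd.DataFrame(apa_rows).set_index("n_nucleation_anchors"),
            outdir / "apa_scores.tsv",
            h,
            index_label="n_nucleation_anchors",
        )
    two = [lp for lp in loops if lp.n_nucleation_anchors == 2 and not lp.interchromosomal]
    if two and matrices:
        lp = max(two, key=lambda l: l.span)
        profile = virtual_4c(matrices[lp.anchor1.chrom], lp.anchor1)
        _write_tsv(
            pd.DataFrame(
                {
                    "bin_start": matrices[lp.anchor1.chrom].bin_starts,
                    "contact_fraction": profile,
                }
            ).set_index("bin_start"),
            outdir / "virtual_4c.tsv",
            h,
            index_label="bin_start",
        )
    state["loops"] = loops
    state["span_stats"] = stats
    state["apa_rows"] = apa_rows
    counts = {f"anchors_{k}": v for k, v in sorted(stats.group_n.items())}
    counts["loops_total"] = len(loops)
    return counts


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "diffbind": _stage_diffbind,
    "classify": _stage_classify,
    "enrich": _stage_enrich,
    "cgi": _stage_cgi,
    "loops": _stage_loops,
}
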