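#!/usr/bin/env python
"""Union peaks, normalization and the two NB Wald contrasts.

Merges the per-condition peak calls into a union set, derives per-sample
size factors from background genomic bins, and tests auxin vs steady
state and reintroduction vs auxin over every union peak.  Prints how
many peaks respond in each direction at the classification thresholds.
"""

import argparse

import pandas as pd

from nucleaid.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/run")
    args = ap.parse_args()

    cfg = PipelineConfig(
        seed=args.seed, outdir=args.outdir, stages=("simulate", "diffbind")
    )
    manifest = run_pipeline(cfg)
    n_union = manifest["stages"]["diffbind"]["row_counts"]["union_peaks"]
    print(f"{n_union} union peaks tested in both contrasts")
    for fname, desc in (
        ("contrast_auxin_vs_steady_state.tsv", "auxin vs steady state"),
        ("contrast_reintroduction_vs_auxin.tsv", "reintroduction vs auxin"),
    ):
        t = pd.read_csv(f"{args.outdir}/{fname}", sep="\t", comment="#", index_col=0)
        sig = (t["padj"] < cfg.padj_max) & (t["log2FoldChange"].abs() > cfg.lfc_min)
        down = (sig & (t["log2FoldChange"] < 0)).sum()
        up = (sig & (t["log2FoldChange"] > 0)).sum()
        print(f"{desc}: {down} peaks down, {up} up "
              f"(|log2FC| > {cfg.lfc_min}, padj < {cfg.padj_max})")


if __name__ == "__main__":
    main()
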