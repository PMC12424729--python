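"""Shared fixtures: a session-scoped default pipeline run plus a small
fast simulation config for unit-level tests."""

from __future__ import annotations

import pandas as pd
import pytest

from nucleaid.pipeline import PipelineConfig, run_pipeline
from nucleaid.simulate import SimConfig


SMALL_SIM_OVERRIDES = dict(
    n_nucleation=40,
    n_control_exclusive=80,
    n_persistent=20,
    n_new_in_auxin=10,
    n_new_in_reintro=10,
    n_background=5,
    n_chromosomes=2,
    chrom_length=600_000,
    n_cgi_random=20,
    n_feature_noise=50,
    n_random_genes=30,
    n_loops_zero=30,
    n_loops_one=15,
    n_loops_two=8,
    loop_span_mean_zero=60_000.0,
    loop_span_mean_one=120_000.0,
    loop_span_mean_two=200_000.0,
)


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """A scaled-down bundle config that still exercises every generator."""
    return SimConfig(seed=3, **SMALL_SIM_OVERRIDES)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default study-scale bundle (seed 1), run once.

    Returns (config, manifest, outdir).
    """
    outdir = tmp_path_factory.mktemp("default_run")
    config = PipelineConfig(seed=1, outdir=str(outdir))
    manifest = run_pipeline(config)
    return config, manifest, outdir


@pytest.fixture(scope="session")
def recovery_frame(default_run) -> pd.DataFrame:
    """Classification joined to planted truth on coordinates.

    Columns: label (called), label_true (planted), plus contrast stats.
    """
    _, _, outdir = default_run
    cls = pd.read_csv(outdir / "classification.tsv", sep="\t", comment="#", index_col=0)
    truth = pd.read_csv(outdir / "sim" / "truth_peaks.tsv", sep="\t", index_col=0)
    cls = cls.reset_index()
    truth = truth.reset_index().rename(columns={"label": "label_true"})
    merged = cls.merge(
        truth[["chrom", "start", "end", "label_true"]], on=["chrom", "start", "end"]
    )
    assert len(merged) == len(cls), "coordinate join must be exact for the bundle"
    return merged
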