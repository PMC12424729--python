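# nucleaid

Analysis pipeline for mapping **de novo Polycomb (PRC2) nucleation
sites** from a three-condition degron ChIP-seq design, together with the
downstream analyses that characterize those sites: interval enrichment
against a resampling null, CpG-island methylation status, and chromatin
loop-anchor / Aggregate Peak Analysis (APA).

## The problem

Auxin-inducible degradation of a PRC2 core subunit (Suz12) in mouse
embryonic stem cells gives three conditions: *steady state*, *auxin*
(the protein degraded and the H3K27me3 mark eroded by replication
dilution), and *reintroduction* (an early time point after auxin
washout, before repressive domains re-spread).  A **nucleation site** is
a steady-state binding peak whose signal drops significantly under auxin
and rebounds significantly shortly after washout — the places where the
complex re-finds chromatin without help from its own pre-existing
histone mark.

For each union peak *i* and sample *j*, counts are modelled as negative
binomial with mean `s_j * q_ij` and variance `mu + alpha_i * mu^2`,
where `s_j` is a per-sample size factor (median-of-ratios against a
geometric-mean reference, derived from background genomic bins so that
the global loss of binding under depletion does not distort
normalization) and `alpha_i` a per-peak dispersion (method of moments,
shrunk halfway to the across-peak median).  Two Wald contrasts are
tested over every union peak — auxin vs steady state, and
reintroduction vs auxin — and a peak is called **nucleation** when

```
log2FC(auxin / steady state)     < -1.5   with BH-adjusted p < 0.005, and
log2FC(reintroduction / auxin)   > +1.5   with BH-adjusted p < 0.005
```

(strict inequalities).  Steady-state peaks failing these criteria are
**control-exclusive** (the resampling background for every enrichment
analysis), peaks still called under auxin are **persistent**, and peaks
first appearing under auxin or reintroduction are bookkept as **new**
and excluded from further analysis.

Because the study's raw sequencing data are not bundled, a first-class
synthetic-data generator (`nucleaid.simulate`) produces a complete
fixture bundle with planted ground truth — peak classes with planted
|log2FC| = 3 dynamics, a genome with GC-rich CpG islands preferentially
unmethylated at nucleation sites, labeled cofactor/chromatin-state
features, and loops with 0/1/2 nucleation anchors over distance-decay
contact matrices — so every downstream stage is testable end to end.

## Worked example

```bash
python analysis/01_simulate_bundle.py --seed 1 --outdir results/run
python analysis/03_classify_nucleation.py --seed 1 --outdir results/run
```

prints (abridged):

```
peak classes: {'nucleation': 1099, 'control_exclusive': 3801, 'persistent': 900,
               'new_in_auxin': 370, 'new_in_reintro': 450, 'excluded': 0}

width medians (bp):
                      n  median
nucleation         1099  1336.0
control_exclusive  3801   703.0
```

Of 1,100 planted nucleation peaks, 1,099 are recovered with no false
positives; nucleation sites are roughly twice as broad as
control-exclusive peaks (planted medians 1,342 vs 714 bp).  The
enrichment stage (`analysis/04_feature_enrichment.py`) then reports, for
each labeled feature set, the observed overlap at nucleation sites, the
1,000-draw resampling expectation over control-exclusive peaks, the O/E
ratio with its empirical p-value, and Fisher's exact p with the sample
odds ratio:

```
                    observed  expected  oe_ratio  p_empirical   fisher_p  odds_ratio
cofactor_primary        1046       720      1.45     0.000999  8.72e-105        10.4
state_repressed          883       113      7.83     0.000999          0        35.8
```

`analysis/05_cgi_methylation.py` calls islands methylated when >= 20% of
their covered CpGs exceed level 0.5 (site rule strict, island rule
inclusive) and recovers the planted bias — unmethylated islands are
~4.7-fold enriched at nucleation sites while methylated islands are
depleted.  `analysis/06_loop_architecture.py` shows loops anchored at
two nucleation sites are the longest (mean 0.82 Mb vs 0.20 Mb for
non-nucleation loops; one-way ANOVA p ~ 1e-125) and carry the strongest
APA scores.

The same stages are available as a CLI (`nucleaid run --seed 1 --outdir
out`, plus per-stage subcommands) driven by an optional YAML config.

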