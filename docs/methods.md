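# Methods

## Statistical model

### Counts and normalization

Counts `k_ij` over union peak `i` in sample `j` are modelled as negative
binomial, `Var = mu + alpha_i * mu^2`, with mean `s_j * q_ij`.  Size
factors `s_j` are median-of-ratios estimates: over features with
all-positive counts, the median of `k_ij / geomean_i(k_i.)`.  There is
no pseudo-reference fallback — a matrix with no feature covered in every
sample is rejected rather than silently re-anchored.

In this design most peaks genuinely lose signal under depletion, so
median-of-ratios **on the peak matrix** would absorb the global binding
loss into the auxin samples' size factors and flatten the very fold
changes being tested.  The pipeline therefore estimates `s_j` from a
matrix of background genomic bins (condition-independent coverage) when
one is available, and applies those factors to the peak matrix — the
peak-matrix estimate remains the fallback.  This mirrors standard
practice of deriving scaling factors from genome-wide coverage rather
than from the responding regions themselves.

### Dispersion

Per-feature dispersion is method-of-moments on normalized counts with
condition means removed: with pooled within-condition variance `V_i`
(denominator `n - G`) and overall normalized mean `m_i`,

```
alpha_hat_i = max((V_i - m_i) / m_i^2, 1e-8)
alpha_i     = 0.5 * alpha_hat_i + 0.5 * median(alpha_hat)
```

The 50% shrink toward the across-feature median stabilizes the very
noisy per-feature estimate at 2 replicates/condition (3 residual df)
without borrowing a full empirical-Bayes machinery; the floor `1e-8`
keeps Poisson-like features well-defined.

### Wald contrast

For condition B over A, with normalized group means `mu_A, mu_B` and
pseudo-count `c0 = 0.5`:

```
log2FC = log2((mu_B + c0) / (mu_A + c0))
se^2   = (1/ln 2)^2 * [ (1/n_A)(1/(mu_A + c0) + alpha_i)
                      + (1/n_B)(1/(mu_B + c0) + alpha_i) ]
p      = 2 * Phi(-|log2FC / se|)
```

The `1/(mu + c0) + alpha` term is the delta-method variance of
`log(mean)` for an NB mean of `n_g` replicates.  BH adjustment runs per
contrast across *all* union peaks, zero-count features included at
p = 1, so the multiple-testing family is identical for both contrasts.
The pseudo-count bounds the log fold change for features that drop to
zero counts and costs < 0.01 log2 units of bias at means >= 60.

### Classification

Labels are assigned in priority order over presence flags (a union peak
is "present" in a condition iff it overlaps a peak called in that
condition by >= 1 bp): new-in-auxin and new-in-reintroduction (absent
from steady-state calls) are bookkept and excluded; among steady-state
peaks, nucleation requires both contrasts significant in the expected
directions at strict thresholds (|log2FC| > 1.5, padj < 0.005 —
boundary values fail); non-nucleation peaks still called under auxin are
persistent (presence-based, not test-based: these peaks *were observed*
under depletion, which is the operational meaning of persisting); the
remainder are control-exclusive.  Every union peak receives exactly one
label; peaks present in no condition are `excluded`.

### Enrichment

The resampling null draws `|query|` peaks from the control-exclusive
background uniformly **without replacement** (a peak set cannot contain
a peak twice), re-evaluating the overlap statistic per draw; N = 1,000
draws by default.  Empirical p-values carry the +1 correction,
`(1 + #{null >= obs}) / (N + 1)`, and never return 0.  Fisher's exact
test is two-sided by probability-mass ordering; the reported odds ratio
is the sample `ad/bc` with Haldane-Anscombe +0.5 when any cell is zero
(an exact-test p of literally 0 is impossible; extremely small values
are floating-point underflow).

### CpG islands

A CpG site is methylated iff its level is **strictly** above 0.5; an
island is methylated iff **at least** 20% of its covered CpGs are
methylated.  The asymmetry (site strict, island inclusive) is
deliberate and matched to the stated calling convention.  The island
denominator is the number of CpG records overlapping the island, not a
theoretical CpG count; islands with no covered CpG are `no_data` and
excluded from enrichment denominators.

### Loops and APA

An anchor is a nucleation anchor iff it overlaps >= 1 nucleation
interval by >= 1 bp (boolean per anchor, so an anchor touching two sites
counts once).  Span is the midpoint distance, intrachromosomal only;
spans are compared across the 0/1/2-anchor classes by one-way ANOVA.

APA averages the `(2w+1) x (2w+1)` contact window (default `w = 5`,
i.e. 110 kb at 10 kb resolution) around each loop pixel, anchor1 on
rows.  Loops are excluded when the window leaves the matrix or the
pixel is within `2w` bins of the diagonal.  The score divides the
centre pixel by the mean of the **3x3 lower-left corner** — the
shorter-genomic-distance background quadrant; conventions differ
between tools, so this one is fixed and documented.  The default score
uses raw observed counts with corner normalization only; an
observed/expected distance normalization is deliberately not applied
(the synthetic decay is mild at this scale and corner normalization
suffices), which means absolute scores are not comparable to tools that
do O/E-normalize.  Virtual 4C returns the viewpoint bin's matrix row,
viewpoint masked to zero, normalized to sum 1.

## The synthetic bundle

The generator is a pure function of `(config, seed)`: every output is
byte-identical across runs.  Planted truth is written next to the
bundle (`truth_peaks.tsv`, `cgi_truth.tsv`, `truth_size_factors.tsv`)
and is never read by analysis code.

Defaults define the simulated study conditions:

| parameter | default | rationale |
|---|---|---|
| peak classes | 1,100 nucleation, 3,800 control-exclusive, 900 persistent, 370/450 new, 180 background | mirrors the reported class sizes at desk scale |
| replicates | 2 per condition | peak calling per replicate implies >= 2; 2 is the conservative choice |
| planted effect | &#124;log2FC&#124; = 3 | strong depletion/recovery dynamics, comfortably past the 1.5 threshold |
| baseline mean mu | log-normal, median 500 (low classes 25) | ChIP-scale peak coverage; low baseline keeps "new" peaks un-called at steady state |
| dispersion alpha | uniform 0.01-0.1 | typical well-replicated ChIP-seq range |
| size factors | log-uniform 0.7-1.4 | realistic library-depth spread |
| peak widths | log-normal, medians 1,342 / 714 bp (sigma 0.4) | the reported nucleation vs control-exclusive width medians |
| genome | 4 x 5 Mb, GC 0.42 | smallest genome that comfortably holds ~6,800 peaks plus Mb-scale loops |
| CpG islands | 1 kb, GC >= 0.65, CpG density >= 0.06; at 80% of nucleation / 30% of control peaks; unmethylated with odds 0.9 / 0.5 | plants the unmethylated-CGI bias the enrichment stage must recover |
| loops | 500 / 260 / 102 per anchor class, mean spans 0.18 / 0.33 / 0.86 Mb | reported anchor-class counts and mean interaction distances |
| contact matrix | 10 kb bins, background c/(1+&#124;i-j&#124;), focal factor 5 at loop pixels | the loop-calling resolution; mild decay with unambiguous focal signal |

What the bundle emulates: NB counts with planted condition dynamics and
size factors, presence-based per-condition calls, composition-biased
island sequence and per-CpG methylation, feature sets with planted
per-class overlap rates, and focally enriched contact maps.  What it
does **not** emulate: read-level sequence and mapping artifacts, ChIP
efficiency and input background, fragment-length effects (counts are
generated at peak level; fragment counting is exercised separately on
small fixtures), replication timing, and contact-matrix noise (matrices
are deterministic given the seed).  Passing tests therefore demonstrate
the statistical machinery recovers planted structure under the stated
model — not robustness to alignment- or library-level artifacts.

Background-bin counts are condition-independent pure background; in
real data bins overlapping responsive peaks would dilute this slightly,
but the median across thousands of bins is insensitive to that tail.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere, including the
  methylation table (whose base convention is otherwise ambiguous in
  the wild — documented here once).
- Book-ended intervals (end == start) merge during union construction.
- Interpeak distance is the nearest-neighbour **edge-to-edge gap**
  within a peak set (not consecutive-pair, not midpoint), 0 for
  overlapping neighbours, undefined for a chromosome's sole peak;
  summaries are computed within a class against its own peaks.
- Promoter window is TSS +/- 2 kb (inclusive); annotation priority is
  promoter > exon > intron > intergenic on the peak midpoint; nearest
  gene ties break to the lexicographically smallest gene id.
- Ties in BH adjustment share the adjusted value (step-up with
  monotonicity enforcement, delegated to statsmodels).
- `signal_density` rescales every interval to 100 bins; intervals
  narrower than the bin count are computed with repeated-base windows
  and flagged rather than rejected.
- Degenerate guards: empty peak-set merges, background smaller than
  query, all-singleton chromosomes in distance summaries, zero-CpG
  islands, all-zero virtual-4C rows, and APA with no admissible loop
  all raise typed errors naming the violated precondition.

## Scale of the shipped analyses

The default bundle (~6,800 peaks, 20 Mb genome, ~900k CpGs, 862 loops
over 4 x 500-bin matrices) generates in under 10 s and the full
pipeline runs in ~15 s; the acceptance script's null-error study uses
20 independent 2,000-peak simulations and the calibration study 200
repetitions of a 300-draw resampling test.  These sizes give the
recovery and calibration checks comfortable statistical resolution
(binomial SE < 1% on all rate estimates) while staying desk-scale.

## Known limitations

- The Wald test is a bespoke, fully specified NB test; it is not a
  re-implementation of any published package's GLM/shrinkage estimator,
  and its p-values will differ in detail from such tools even though
  the classification thresholds are the same.
- The multiple-testing family is all union peaks for both contrasts; a
  condition-specific family would change padj values slightly (choice
  documented, kept fixed).
- Presence flags come from per-condition peak calls supplied as inputs;
  the pipeline does not call peaks.
- APA absolute scores depend on the corner convention above and on not
  applying O/E normalization; compare trends across anchor classes, not
  absolute values across tools.
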