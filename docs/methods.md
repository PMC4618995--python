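# Methods

This note documents the statistical models, default parameters, and
numerical choices behind `cnvrscan`, plus the realism assumptions of the
synthetic-cohort generator and known limitations. Any numbers quoted here
are computed by the test suite or by `scripts/acceptance.py`.

## Windowing and read counting

Chromosomes are tiled with fixed, non-overlapping windows (default
3,000 bp); a trailing partial window is dropped. A read is assigned to the
window containing its **leftmost aligned base**, so every counted read
contributes to exactly one window and per-window counts sum to the filtered
read count. Filters: mapping quality ≥ 20; unmapped, secondary,
supplementary, QC-fail and duplicate-flagged reads excluded. Windows are
removed from analysis when their N fraction exceeds 0.5 or when they
overlap an exclusion mask (repeats, organellar insertions) by any amount.
All intervals are 0-based half-open.

## Normalization

Two biases dominate window counts: sample-level coverage and window-level
GC composition (library preparation and mapping depress coverage away from
a preferred GC range).

1. **GC median-ratio adjustment** (per sample). Windows are grouped into GC
   bins of width 0.01; each count is multiplied by
   `median(all windows) / median(its GC bin)`. Bins with fewer than 10
   windows fall back to the global median (factor 1). A sample whose global
   median is 0 is rejected as degenerate. This is a nonparametric version
   of LOESS-style GC correction: it assumes only that the GC effect is
   multiplicative and locally constant within a 1 % GC bin.
2. **Standardization.** Each sample is z-scored (mean 0, SD 1 within
   sample), which removes coverage scale so samples sequenced at 1× and 5×
   are comparable; then each window is centered by its cross-sample median,
   which removes shared positional artifacts (mappability, residual GC)
   while leaving minority copy-number states intact — a median is robust to
   the < 50 % of samples that carry a CNV at any one locus.

Scale invariance (doubling a sample's counts leaves its standardized signal
unchanged) and artifact suppression versus CNV survival are asserted in
`tests/test_normalize.py`.

## Segmentation

Each sample × chromosome standardized signal is segmented by recursive
binary segmentation with a **two-boundary (arc) scan**: at each recursion
the candidate split is the arc `[i, j)` maximizing the pooled-variance
two-sample |t| between values inside and outside the arc. Edge-anchored
arcs (ordinary single change points) are scanned at every length; interior
arcs — which capture a short CNV flanked by normal copy on both sides in a
single step — are scanned up to `max_arc` = 100 windows (300 kb), with both
flanks kept at least `min_width` = 2 windows. The scan is computed from
cumulative sums and sums of squares, vectorized over start positions for
each arc length; a variance floor of 1e-12 keeps the statistic ordered when
a candidate split is noise-free. Ties resolve to the leftmost start, then
the shortest arc (an arc and its complement have equal |t|, so the resolved
boundary pair is checked by statistic value, not arc identity, in tests).

A split is accepted when its statistic exceeds the (1 − α) quantile
(α = 0.01) of maximum statistics obtained by permuting the values within
the current segment (100 permutations), i.e. a within-segment randomization
test against "no structure here". Accepted boundaries recurse on the
resulting pieces. Final segment means, broadcast to member windows, form
the segmentation-score matrix; positive scores mark elevated depth,
negative reduced depth. Missing windows are skipped and re-indexed so
segments span only observed windows.

Localization: a planted single step of height 2.0 in noise SD 0.1 over 100
windows is localized within ±1 window in 100/100 seeded replicates
(`test_segmentation_localizes_planted_changepoint`).

## CNVR calling

**Trimmed SD.** For each window, the cross-sample spread of segmentation
scores is summarized by the standard deviation (n − 1 denominator) after
removing exactly one minimum and one maximum instance (ties: one instance
each; ≥ 4 finite values required). Removing a fixed single extreme on each
side absorbs one outlier sample — e.g. a spurious segment in one
low-coverage sample — while two or more concordant carriers still register.
The scalar implementation sorts and slices; the vectorized track
implementation uses row-centered sums and sums of squares (centering first
keeps the shortcut well-conditioned in the presence of large values). Both
match a brute-force oracle on 1,000 random vectors.

**Permutation FDR.** For each chromosome and each tabulated threshold *t*:

```
FDR(t) = E_perm[ #windows with permuted trimmed SD > t ] / #windows with observed trimmed SD > t
```

clipped to [0, 1], undefined (NaN) when no window exceeds *t*. The
genome-wide curve averages defined per-chromosome FDRs weighted by
chromosome length. Each permutation independently, per sample: shuffles the
order of that chromosome's segments, re-lays them end-to-end, and applies a
uniform circular rotation. Shuffling at segment granularity preserves the
autocorrelation the segmentation induced; the rotation is needed because
with few segments per chromosome a pure end-to-end re-lay pins short
segments to positions reachable as partial sums of the other segments'
lengths (in the degenerate two-segment case, only the chromosome ends),
which piles all samples' extreme segments onto the same windows and
inflates the null count. The rotation preserves each sample's window-value
multiset, every segment's length and score, and their adjacency (one
segment wraps), while making placement uniform.

FDR(t) is a ratio of two survival counts and is **not** guaranteed
monotone in *t*: both numerator and denominator are non-increasing, so
their ratio can locally increase (observed on the reference cohort; see the
FDR curve artifact of any run). The reported curve is therefore tabulated,
not interpolated, and threshold selection picks the smallest tabulated
threshold with genome-wide FDR below the user ceiling.

Calibration: when the observed score matrix is itself a draw from the
shuffling null (random per-sample segment structure, no cross-sample
alignment), every threshold with ≥ 10 observed exceedances has estimated
FDR ≥ 0.8 at 1,000 permutations (`test_fdr_calibration_under_global_null`;
minimum 0.90 in the seed-1 acceptance run).

**Merging.** Windows with trimmed SD **strictly** greater than the
threshold (default 0.25) merge with genomically adjacent qualifying windows
into CNVRs; a removed window between two qualifying windows splits the run
into two regions. Region bounds are the bp extent of member windows, so the
minimum CNVR is one window.

## BAF validation

SNP-array genotyping assumes two copies, so copy-number change distorts the
B-allele frequency away from the diploid clusters {0, ½, 1}: AAB/ABB
duplications cluster near ⅓ and ⅔, hemizygous deletions collapse
heterozygotes to 0/1, homozygous deletions drop out. A SNP is **aberrant**
when its BAF lies in [0.05, 0.35] ∪ [0.65, 0.95] (endpoints inclusive) in
at least ⌈0.10 · n_samples⌉ samples (e.g. 19 of 185, 3 of 30); missing
calls count against the full denominator. Aberrant × in-CNVR status forms a
2×2 Fisher exact test (enrichment expected), and the in-CNVR SNP count is
tested against the CNVR fraction of analyzed bases with a binomial test
(arrays under-ascertain variable regions, so depletion is expected). SNPs
in removed windows are excluded.

## Annotation enrichment

A gene counts as "in CNVRs" when **more than 70 %** of its length overlaps
the merged CNVR union (strict inequality; a gene exactly at 70 % is
outside). Class enrichment (e.g. resistance genes) uses a 2×2 Fisher test
`[[class & in, class & out], [other & in, other & out]]`; the reported fold
is the rate ratio `(a/(a+b)) / (c/(c+d))`. GO-term enrichment tests each
term among in-CNVR genes versus the gene universe with Fisher tests and
Benjamini–Hochberg adjustment. Repeat enrichment counts repeats **entirely
contained** in the merged 10-kb CNVR flanks against an expectation
proportional to the flank share of the genome. Regional GC is the
window-overlap-weighted mean GC, compared between region sets by paired
per-chromosome t-test.

## Two-sided Fisher exact test

The p-value sums hypergeometric point probabilities of all tables with the
observed margins whose probability does not exceed the observed table's
(with a 1 + 1e-7 relative slack for float ties). The implementation is
checked against exhaustive enumeration on **all** 2×2 tables with grand
total ≤ 40 (`test_fisher_exact_matches_enumeration_all_tables_total_le_40`).
The rate-ratio fold and odds ratio are reported separately; zero-margin
tables are flagged degenerate rather than silently given a fold.

## Synthetic cohort generator

The generator aims for the statistical structure the pipeline assumes, not
sequence-level realism:

- **Genome.** Per-window GC drawn from a Beta distribution with mean 0.38
  (plant-like); random exclusion masks (~5 % by default) and optional
  N-rich intervals.
- **CNV plan.** Window-aligned, non-overlapping regions placed away from
  masks with ≥ 1 window separation; each sample is independently a carrier
  with probability 0.15 (population-style allele sharing), carriers draw a
  copy state from {0: 0.1, 1: 0.3, 3: 0.4, 4: 0.2}, and each region is
  forced to keep ≥ 1 diploid and ≥ 1 non-diploid sample.
- **Depth.** Window counts are negative binomial with mean
  `coverage · window / read_length · (copy/2) · gc_bias(GC)` and size
  k = 50, i.e. variance μ + μ²/50 — overdispersion typical of real
  sequencing; `k = inf` gives Poisson. The GC bias is a quadratic
  multiplicative factor peaking at GC 0.40, floored at 0.05. Default
  coverages spread over 0.95–4.96× to mimic an uneven low-coverage cohort.
- **BAF.** Diploid clusters {0, ½, 1} with truncated Gaussian noise
  (SD 0.02); inside CNVRs, carrier heterozygotes move to {⅓, ⅔}
  (duplication) or collapse to {0, 1} (hemizygous deletion); zero-copy
  samples are missing. Distortion occurs only inside true regions.
- **Annotations.** Uniform gene/repeat placement with an odds multiplier
  for resistance genes landing inside true CNVRs.
- **Alignment fixtures.** A SAM emitter places reads wholly inside their
  windows so leftmost-base counting recovers the simulated counts exactly;
  used to test the counting stage end-to-end with controllable duplicate
  and low-MAPQ fractions.

All generators are pure functions of their parameters and a seed; the
reference cohort (`standard_cohort`) spawns independent sub-seeds per stage
from a single `SeedSequence`.

Measured on the reference cohort (30 samples, 3×, twenty 9–60 kb CNVRs on
two 18-Mb chromosomes): base-level recall 0.83–0.85 and precision ≈ 0.99 at
threshold 0.25, with estimated genome-wide FDR ≈ 0.10 (seeds 0 and 1;
asserted ≥ 0.8 / ≥ 0.8 / ≤ 0.15 in `tests/test_acceptance.py`).

## Reproducibility and numerics

- One global seed per run; per-sample × per-chromosome generator streams are
  spawned via `SeedSequence(entropy=seed, spawn_key=...)`, so results do not
  depend on iteration order and reruns are byte-identical.
- Interval arithmetic is integer, half-open throughout.
- The trimmed-SD track and FDR permutation loop are vectorized over
  windows; the segmentation scan is O(n · max_arc) per split test via
  cumulative sums.

## Limitations

- Window resolution: breakpoints are reported at 3-kb granularity; events
  smaller than one window are invisible, and events smaller than ~2 windows
  at 3× coverage are at the edge of the segmentation's power.
- No per-sample genotypes: the trimmed-SD statistic detects *variable*
  regions cohort-wide; it does not call which sample carries which copy
  state, and it deliberately ignores regions where only a single sample
  varies.
- The permutation null conditions on the observed segmentation; segments
  induced by real CNVs are shuffled too, which makes the estimated FDR
  conservative at thresholds below the signal range.
- The empirical FDR curve need not be monotone in the threshold (ratio of
  two survival counts); users should read the tabulated curve rather than
  assume a unique crossing.
- GC correction assumes a multiplicative, within-bin-constant bias; strong
  mappability artifacts not captured by masks or the per-window median
  centering can survive into the score matrix.
- The generator does not model mappability gradients, read pairs, indels,
  or reference errors; alignment fixtures are statistical, not
  sequence-faithful.
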