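# Methods

`tumorgi` re-implements, as a tested library, a genome-instability analysis
for serially allografted tumors with matched larval (host) controls: somatic
copy-number variants are called from binned whole-genome coverage, and
somatic SNPs are summarized by substitution spectrum, positional clustering,
exome rate, passage-to-passage turnover and a read-orientation artifact
check. A first-class synthetic-data generator reproduces the statistical
structure the analysis assumes and provides ground truth for recovery
testing.

## Coverage model and CNV pipeline

Coverage is the mean per-base depth per 1 kb bin. The processing chain for
each tumor/control pair is:

1. **GC correction (per sample).** A generalized linear model of coverage on
   GC with log link and Tweedie variance `Var ∝ μ^1.5` (between Poisson and
   gamma — the standard compromise for binned read counts), fitted by IRLS.
   The smooth is a 10-column cubic B-spline built on the *empirical GC
   quantile* (rank) rather than raw GC. This monotone reparameterization is
   equivalent to placing knots at data quantiles, so every basis interval is
   equally populated and the curve cannot oscillate in data-sparse GC
   ranges; an optional second-derivative penalty is exposed
   (`alpha`, default 0 — for this family the GCV profile over the penalty is
   nearly flat while moderate penalties visibly over-smooth the curve's
   tails). Response-scale residuals carry the signal; the pipeline's
   "corrected" coverage is residual + mean fitted value, which keeps values
   on the coverage scale (and positive in expectation) so that downstream
   ratios are well defined. Deviance residuals are available on the fitted
   model. Bins excluded from the analysis — zero mappability, the Y proxy,
   and any masked (under-replicated/repeat) interval — are also excluded
   from the regression: a polytene control's under-replicated bins sit at
   ~0.3× depth and would otherwise drag that sample's fitted curve relative
   to the tumors', a control-specific distortion that cross-sample
   normalization amplifies into recurrent false gains.
2. **Bin filtering (shared across samples).** Bins with mappability exactly
   0 are dropped; then bins whose GC lies strictly below the 0.08 quantile
   of GC over the remaining bins (strict "below", so an all-tied GC track
   loses nothing). The quantile is computed after the mappability rule
   because unmappable bins have an unreliable GC–coverage relation.
3. **Quantile normalization (all samples of a run).** Classic: each sample's
   sorted values are replaced by the across-sample mean of sorted values;
   ties receive averaged reference values. Marginals become identical;
   within-sample ranks are untouched.
4. **Log ratio.** `log2((tumor+ε)/(control+ε))` per bin against the matched
   donor control, median-centered per genome. ε = 0.5 (half a read per bin,
   the natural quantum of count data).
5. **Segmentation (per arm).** Circular binary segmentation: the arc (i, j]
   maximizing the standardized arc-vs-complement mean difference is tested
   against a permutation null (cutoff p < 0.01, default 1000 permutations);
   accepted splits are recursed into. Wrap-around arcs are complements of
   linear arcs and need no separate scan. Permutations stop early on either
   side of the decision: once exceedances rule significance out, or once
   zero exceedances over > 1/α permutations already put the Monte-Carlo
   p-value (count+1)/(done+1) below α. After splitting, adjacent segments
   whose means differ by less than 3 residual SDs are merged back
   (`undo_sd = 3`); the residual SD is the scaled MAD of bin ratios minus
   segment means, robust to the segments themselves.
6. **Modal re-anchoring.** Segment means are shifted so the mode of the
   bin-weighted segment-mean distribution (located by a weighted Gaussian
   kernel evaluated at the means themselves, bandwidth 0.05 log2 units) sits
   at zero — the diploid baseline, even when most of an arm is aberrant.
7. **Five-state calling.** A segment leaves the diploid state only if
   `|mean| > max(0.2, 2·SD/√n_bins)`. Beyond the margin the call follows
   the sign: ≥ +1.0 is high amplification (≥ 4 copies), ≤ −1.5 double
   deletion, otherwise ±1. Sign-based single-copy boundaries are used
   instead of proximity to the canonical levels ±log2(3/2) and −1 because
   quantile normalization attenuates single-copy segments to a
   burden-dependent fraction (~0.4–0.8) of their canonical level — the same
   reason mixture-based callers fit their levels per sample. Calls of the
   same state separated by ≤ 10 kb are stitched (normalization can leave a
   few rank-junction bins inside a large event at an intermediate level).
8. **Mask-and-recall.** The whole chain re-runs on a grid with bins
   overlapping under-replicated/repeat intervals (≥ 1 bp) removed; reported
   coordinates always refer to original genome positions. Calls are
   reported 1-based inclusive in tables and 0-based half-open in BED.

Sex is inferred from the control: X/autosome mean-coverage ratio < 0.75
together with a covered Y proxy region (> 0.25 of autosomal) calls male;
ratio > 0.75 with an empty Y region (< 0.1) calls female; anything else —
including a ratio of exactly 0.75 — is flagged ambiguous.

## SNP statistics

Variants are SNVs with allele fraction and per-orientation alt read counts.
Substitutions collapse to the six pyrimidine-reference classes (G>T counts
as C>A). The clustering statistic counts SNPs within ±25 kb of each SNP and
computes the upper binomial tail under uniform placement over the effective
genome (the positions informative enough to call a variant, supplied as
input); the focal SNP is conditioned out — `P(X ≥ k−1)` with
`X ~ Binomial(N−1, w/n_eff)` — because the unconditioned form inflates type
I error by roughly `k/(N·w/n_eff)` at sparse densities. Raw p ≤ 0.001 marks
a cluster; no multiplicity correction by default (a Bonferroni option
exists), and overlapping significant windows merge into regions. Regional
enrichment uses the exact binomial upper tail in log space, so tails far
below 1e−12 remain accurate. The exome rate divides AAF ≥ 0.1 exonic
variants by callable exome Mb. Turnover identity across passages is exact
(chrom, pos, ref, alt). The orientation check pools F1R2/F2R1 alt counts
over the C>A class and flags a sample when a two-sided exact binomial test
against 0.5 gives p < 0.01 *and* the skew matches the configured 8-oxo-dG
direction — damage introduced during library preparation is strand-specific
in a way true somatic variants are not.

Group comparisons use the Mann–Whitney test: full enumeration of rank
assignments (midranks for ties) when min(n) ≤ 8, otherwise the
tie-corrected normal approximation.

## Synthetic data generator

The generator emulates the study design, not any particular dataset:

- **Genome.** Six arms totalling 20 Mb at 1 kb bins (full pipeline in
  seconds), plus a 300 kb repeat-free Y proxy (a kl-2-like interval) used
  only for sex inference. GC is a stationary AR(1) track (lag-1
  autocorrelation 0.98) squashed smoothly by tanh into mean ± 2.2 SD —
  compact support without the density gap or boundary point mass of a hard
  clip. 2% of bins get mappability 0. Under-replicated intervals cover 5%
  of the genome (100–400 kb each), repeats 3%; genes tile arms with
  exponential gaps and exomes occupy the central 60% of each gene.
- **Coverage.** Per-bin mean depth from a negative-binomial read count with
  mean `depth·(copy/2)·exp(b(GC))·mappability·binlen/readlen` and a constant
  Fano factor (default 1.2). The GC bias `b` is quadratic on the log scale.
  The explicit GC and mappability terms are themselves the dominant sources
  of real-data overdispersion, so the residual clumping factor is close to
  Poisson, as in good libraries after correction. Controls are polytene:
  their under-replicated intervals are scaled by `ur_factor` (default 0.3).
  Males carry one X and a covered Y proxy; females two X and none.
- **Lineage.** One passage step spans consecutive sampled time points
  (T0 → T5 → T10). Each step brings Poisson numbers of new CNVs and SNPs
  and retains each existing lesion independently with `retention_prob`. A
  split (e.g. at passage 9) divides the last step into a shared fractional
  sub-step and per-subline remainders, so sublines share exactly the
  lesions born before the split. CNVs are log-uniform in size (50–500 kb),
  bin-aligned, placed off masked intervals and at least 50 kb apart —
  same-sign lesions closer than segmentation resolution are not separable
  events for any ratio-based caller, so the generator does not produce
  them. SNPs carry a six-class spectrum (default C>A-heavy, as under
  oxidative stress), a Beta(2,4) allele fraction and binomially split
  orientation counts.

What the generator does **not** emulate: read-level sequence content,
alignment artifacts, polytene band structure, transposable-element
sequences, GC–mappability correlation, subclonal copy-number states, or
inter-tumor-type biological differences. Recovery results on synthetic
cohorts therefore validate the statistical machinery — bias removal,
segmentation, calling, turnover accounting — not cohort-level biology.

## Problem sizes and numerical choices

Recovery tests and the acceptance script run full pipelines on the default
20 Mb genome at 50× with 300 permutations per CBS decision — enough to
resolve the p < 0.01 cutoff for the strong splits involved — and pool 2–3
cohorts per estimate; the library default stays at 1000 permutations.
Degenerate inputs are defined: constant vectors give one segment; constant
GC gives an intercept-only fit; empty variant sets give NaN spectrum
fractions (flagged, not zeroed); a lone SNP has cluster p = 1; identical
constant Mann–Whitney groups give p = 1. Ties: averaged ranks in quantile
normalization and rank tests; strict "<" at the GC-quantile boundary.
Known limitations: single-copy log2 levels are attenuated after quantile
normalization, so calls report the attenuated segment mean, not a purity
estimate; X-linked losses in males are effectively total losses and are not
part of the single-copy recovery claims; very small (< ~5 bin) events at
single-copy amplitude sit below the 3-SD undo rule at 50× noise.
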