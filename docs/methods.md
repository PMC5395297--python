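# Methods

This note documents the models and numerical choices behind each module,
what the synthetic-data generators do and do not emulate, and the known
limitations.

## Coordinates and containers

All intervals are 0-based half-open (BED convention); abutting intervals
(`a.end == b.start`) do not overlap, anywhere. Coverage is held per-base
(`CoverageTrack`, step 1 bp). Repeats have no stable identifiers and are
named `chromosome:start-end`.

## Concave-peak refinement

Broad peak callers merge adjacent binding events; the refinement step finds
the sharp peaks inside them as regions where the smoothed coverage is
concave (negative second derivative).

* **Smoothing kernel.** Boxcar moving average, width = `kernel_bp` rounded
  up to odd (250 → 251 bp); a Gaussian kernel (σ = kernel_bp/4) is
  available via `kernel="gaussian"`. Chromosome ends are reflect-padded.
* **Differencing step.** The second derivative is the central second
  difference at a *quarter-kernel* step h: `(s[i−h] − 2s[i] + s[i+h])/h²`.
  A 1-bp step on a boxcar-smoothed signal depends only on the four
  window-edge bases, so read-level noise would dominate: on Poisson
  background (baseline 10) the 1-bp variant's noise-only curvature minimum
  is ~500× larger in magnitude than the quarter-kernel variant's (~−7700
  vs ~−14 on the scale below). The wide step smooths the derivative as
  well as the signal.
* **Curvature scale.** The output is expressed per kernel length squared
  (per-bp² second difference × kernel_bp²). On this scale a bump of height
  h and width comparable to the kernel has curvature of order −h, so the
  −500 default threshold is commensurate with mapq0 pileup heights: a
  height-400/σ-100 bump scores ≈ −1100, a height-100 bump ≈ −270, noise
  ≈ ±15. The threshold remains a parameter because it is still
  normalization-dependent.
* **Region definition.** Maximal runs of strictly negative curvature are
  intersected with each broad peak; a run is reported iff min(d2) inside
  the intersection is below the threshold. Regions are clipped to their
  parent peak and scored by |curvature index|.
* **Filters.** Score < 100 and width < 100 bp are two independent discard
  rules (failing either removes the peak); blacklist removal is
  any-overlap (≥1 bp), the conservative standard practice.

## Signal enrichment

* **Element signal.** Mean per-base coverage over the element;
  log2FC = log2((mean + pc)/(genome median + pc)), pseudocount 1 signal
  unit by default (0 gives exact ratios). The genome median is over all
  per-base values, computed once.
* **Family test.** A one-sample test against the constant median has no U
  statistic, so the comparison sample is realized as mean signals of
  genome-wide bins at matching resolution (bin size = median element
  width; 10⁵ bins by default, fewer in tests). One-sided Mann–Whitney U
  (members greater), BH-FDR across families. Enriched ⇔ FDR < 0.1 AND
  median fold change > 1.5 AND ≥ 10 members.
* **Telomere counting.** Reads are trimmed to 36 bp and scanned
  non-overlapping for GCCTAA and for its reverse complement TTAGGC; the
  per-read count is the max over the two strands (a read derives from one
  strand; summing could misclassify chimeric sequence). GCCTAA cannot
  overlap itself, so non-overlapping scanning equals total occurrence
  count. 5–6 motifs ⇒ telomeric. Factor-vs-input enrichment is a
  one-sided Mann–Whitney U (typically 2 replicates vs a large input
  panel).
* **H3K9me3 response.** Per-region log2((mutant mean + pc)/(wt mean + pc));
  the set of interest is compared against all genes or all repeats with a
  one-sided (reduction) Mann–Whitney U. Stars: * p<0.1, ** p<0.05,
  *** p<0.001. Control repeats are the exact conjunction of >1.5× wild-type
  H3K9me3 vs genome *average*, <1× genome average for every factor track,
  and not upregulated in any mutant ("average" and "median" are kept
  distinct deliberately).

## Differential expression

* **Normalization.** Median-of-ratios size factors: per sample, the median
  over all-positive features of count / geometric mean across samples.
* **Test.** Per-feature NB Wald test written in-house (no LFC shrinkage —
  reported LFCs are plain normalized-ratio estimates with pseudocount 0.5
  on the group means). Dispersion is method-of-moments per feature,
  `α = (var − μ·mean(1/s))/μ²` on the normalized scale, pooled across the
  two conditions with (n−1) weights and floored at 1e-8. The Wald
  statistic uses the delta-method SE of the log ratio under
  Var(K/s) = μ/s + αμ², referred to a t distribution with n₁+n₂−2 degrees
  of freedom — with a normal reference the moment-estimated SE is
  anticonservative at 2–3 replicates; with the t reference, type-I error
  on null NB simulations (dispersion 0.1, mean 100, n = 3+3) is ≈ 0.049
  at nominal 0.05. Features with all-zero counts get p = 1 and LFC 0 by
  convention. BH-FDR across all features.
* **Calling.** Genes: FDR < 0.01 and |LFC| > 1, minus an externally
  supplied list of genes whose wild-type expression oscillates during
  development (synthetic runs plant this list). Repeats: FDR < 0.01 and
  LFC > 0, then removal of repeats overlapping (≥1 bp) any gene
  upregulated at FDR < 0.05 and LFC > 0; a flag can extend gene intervals
  upstream (e.g. 500 bp) for factor-overlap analyses. Unique-read
  confirmation requires strictly more than 10 raw uniquely mapping reads
  in the mutant (else "not assessable") and a normalized unique-read fold
  change > 1.5, using the same size factors as the main analysis (the
  normalization for this step was an open choice; raw-threshold +
  normalized-FC is the most defensible combination).
* **Annotation enrichment.** fold = (k/n)/(K/N) with a hypergeometric
  upper-tail companion p-value.

## Small RNAs

* piRNA positions are 1-based in the rule ("nt 2–8"); internally the seed
  is 0-based offsets 1..7. Position 1 (the 5′ U) counts against the
  *outside-seed* budget — the rule's source leaves this open, and placing
  nt 1 in the seed would make the seed 8 nt.
* Pairing is classified on the transcript's sense strand: Watson–Crick
  complement = match; piRNA G:target T or piRNA T:target G = G:U wobble;
  else mismatch. A site is accepted iff the seed has 0 mismatches and ≤1
  G:U, and the other 14 positions have ≤2 mismatches and ≤1 G:U. Self
  hits are excluded by feature identifier.
* 22G windows are half-open: read start ∈ [center−50, center+50), center =
  site start + 10; mapping mismatches ≤ 1. Depth matching (subsampling
  every dataset to the smallest unique-position count, without
  replacement) precedes all class counting. Class ratios are
  log2((mutant + 1)/(wt + 1)); a class absent from both conditions is NA.

## Interaction statistics

Expected double-mutant brood under no interaction: a·b/wt. The published
procedure is a one-sample one-sided t-test of the double-mutant broods
against this plug-in constant; that ignores the sampling noise of the
wild-type and single-mutant means, and under a simulated multiplicative
null with 12 animals per genotype and 10% noise it rejects at ≈0.19
instead of 0.05. `interaction_test(..., propagate_uncertainty=True)`
therefore propagates all four group variances into the SE by the delta
method (Welch–Satterthwaite df); its null rejection rate is ≈0.046 over
20,000 simulations. The plug-in variant remains the default `test="t"`
behaviour for compatibility with the published procedure. The
Mann–Whitney variant compares double broods against single-A broods
rescaled by b̄/w̄t — the closest sample-vs-sample realization of the same
null. Ties use scipy's tie-corrected procedures.

## Synthetic data: what it does and does not emulate

Generators are deterministic per integer seed (NumPy PCG64 via
`default_rng`). Defaults define the study conditions: a 2 × 100 kb genome
with a 50-element, 5-family repeat catalog (DNA transposon families carry
transposase-ORF flags; an LTR family is present); coverage is Poisson
background (baseline 10) plus unimodal Gaussian or flat-top bumps; counts
are NB with Var = μ + αμ² (α = dispersion, the DE convention); telomeric
reads are tandem GCCTAA at phase offsets 0–5 (half reverse-complemented)
so motif counting is exercised off-frame; brood noise is normal at 10% of
the group mean, clipped at 0 and rounded.

Not emulated: mappability structure, ChIP fragment-size effects, input
normalization (BEADS-style), GC bias, positional autocorrelation of real
coverage beyond the planted bumps, and sequence homology between repeat
family members. Passing tests therefore demonstrate correctness of the
*computations* under the assumed statistical structure, not robustness to
every artifact of real sequencing data. The Poisson background noise model
is a stand-in: no background model is prescribed for this kind of track.

## Problem sizes

Test and demo fixtures use 20–200 kb of per-base coverage, 50–5000-feature
count matrices with 3–5 replicates per condition, 100-fuzz oracle sweeps,
and 200–1500-replicate calibration simulations — sizes chosen so the whole
suite runs in well under a minute while keeping Monte-Carlo error far
below every asserted tolerance (binomial SE ≈ 0.006 at 1500 null
simulations, ≈ 0.001 on pooled type-I error over 10⁵ null features).
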