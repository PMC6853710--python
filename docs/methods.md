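# Methods

## Model and pipeline

`scsomatic` detects cell-level somatic mutations downstream of variant
calling. Inputs are per-sample SNV tables (VCF or VarScan-style TSV) for
each single cell and for bulk samples, a list of somatic mutation sites
called from bulk tumor-vs-germline DNA ("anchor" or bc-mutation sites), and
a germline variant table. The pipeline:

1. **Retention filter.** An SNV enters the analysis only if, *in at least
   one sample simultaneously*, it has ≥ 5 variant-supporting reads, ≥ 1%
   VAF and ≥ 15 average base quality (all inclusive). "Supporting reads"
   means reads carrying the variant, matching VarScan's `min-reads2`
   semantics. A missing quality value fails the quality criterion.
2. **Germline-zero restriction.** Both the anchor sites and the null pool
   are restricted to sites with zero variant reads in germline DNA at depth
   ≥ `min_germline_depth` (default 10): a true somatic mutation leaves no
   germline trace, and VAF = 0 cannot be asserted on thin coverage. The
   paper-silent case of an uncovered germline site is excluded.
3. **Observed matrix.** Z is the m × n matrix of statistic pairs
   z = (z₁, z₂) = (total reads, VAF) over anchor sites × cells. An entry is
   missing when the cell has no reads there; covered entries with zero
   variant reads are the data point (z₁, 0), not missing.
4. **Monte-Carlo null.** K = 100 replicate m × n matrices are drawn from
   the null pool — retained SNVs minus anchor sites, germline-zero, covered
   in ≥ 1 cell. A replicate draws m *sites* and takes their full per-cell
   vectors, preserving cross-cell dependence within a site; draws are
   without replacement within a replicate when the pool allows (with
   replacement otherwise, logged). The pool and anchor set are disjoint by
   construction and asserted on every run.
5. **Surface estimation and calling** (below).

## The fdr2d estimator

The local fdr of a statistic pair is fdr2d(z) = π₀ f₀(z)/f(z). Dividing two
separately smoothed densities is unstable at the edges, so the target of
smoothing is instead the success proportion r(z) = K f₀/(f + K f₀): null
points are successes, observed points failures, and

    fdr2d(z) = π₀ r(z) / (K (1 − r(z))),  clipped to [0, 1].

π₀ (the proportion of null entries) is fixed at its maximum 1 — no π₀
estimation is attempted — so reported fdr2d values are conservative.

**Smoothing.** r is estimated on a 50 × 50 grid over the transformed space
(t₁, t₂) = (log₁₀ z₁, z₂); coverage spans orders of magnitude, hence the
log scale, while VAF is already bounded. At each node,

    r = (Σ success weights + ½) / (Σ all weights + 1),

with a Gaussian product kernel; the ½ pseudo-count keeps r strictly inside
(0, 1) everywhere, including empty regions where the estimate saturates at
r = ½. The default per-axis bandwidth is a Silverman-type rule,
min(sd, IQR/1.34) · N^(−1/6), on the pooled points; grid size, bandwidth
and the transform are configurable. Off-node queries use bilinear
interpolation with clamping to the grid edges.

**Count dequantization.** Read counts are integers, so statistic pairs pile
up into atoms (every cell with 50 reads and no variant read sits at exactly
(50, 0)). For kernel smoothing and rank-based p-values the counts are
spread over their unit cell by a seeded uniform jitter (z₁ → z₁ + U[0,1),
alt → alt + U[0,1) scaled to respect alt ≤ z₁). The same underlying
(site, cell) entry always receives the same jitter, so copies of a site
resampled into several null replicates stay coincident. Reported counts and
VAFs are always the original integers; only smoothing coordinates are
jittered.

## Calls, tiers and p-values

Every covered entry of Z is scored and returned. Tiers use strict
inequalities: fdr2d < 0.05 is *strict*, < 0.2 *standard* (the working
threshold: among significant calls, fewer than a fifth are expected false),
otherwise *nonsignificant*.

**Leave-self-out scoring.** A data point that contributed to the smoothing
biases r at its own location — an observed point pulls r down, a null point
pulls it up — which would make the two statistics non-exchangeable under
the null. Each data point is therefore scored with its own kernel weight
(exactly, via the interpolated self-contribution, once per copy for pool
sites drawn into several replicates) removed from its side of the ratio.
Kernel sums below 10⁻¹² are flushed to zero so entries in empty regions tie
exactly at the saturated statistic.

**p-values.** The p-value of an entry is the empirical tail probability of
its fdr statistic under the Monte-Carlo null:

    p(z) = (1 + #{null points with statistic ≤ statistic(z)}) / (1 + N),

over all N pooled null points, with ties counted as extreme and an add-one
correction so p > 0. Ranking uses the *unclipped* ratio π₀r/(K(1−r)):
clipping at 1 would tie together the entire deep-null region and put an
atom of p-values at 1. The construction is monotone in fdr2d and, verified
on pure-null simulations, approximately uniform: pooled over many
replicates the residual deviation from uniformity is ≈ 0.005 in
Kolmogorov–Smirnov distance, in the conservative direction, with clean
tails below p = 0.1.

## Cross-method statistics

To compare callers on one scale: Phred-normalised genotype likelihoods
PL map back to linear likelihoods 10^(−PL/10); the wild-type posterior
P(g=0|D) = L₀P(0)/ΣLᵢP(i) uses single-cell priors P(0) = P(2) = (1−θ)/2,
P(1) = θ with θ = 0.001, and is treated as the local FDR of the call,
converted to a p-value by the same null-ranking construction (or returned
as-is, with a warning, when no null set is supplied). Log-odds scores
convert via the χ²₁ approximation of 2·ln(10)·LOD, one-sided (LOD ≤ 0 ⇒
p = 1); records are pre-filtered to normal-sample LOD ≥ 2.3 (inclusive).
Recovery concordance compares, per site, the fraction of tumor cells called
mutated against ploidy·VAF/purity from bulk DNA (defaults: diploid, purity
1 — non-diploid regions should be excluded upstream rather than modelled).

## Synthetic data

The generator emulates the statistical structure of scRNA-seq variant data,
with all randomness from one seed:

| parameter | default | meaning |
|---|---|---|
| n_tumor / n_normal | 60 / 40 | cell counts |
| m_mut / m_null | 50 / 1000 | true mutation and null SNV sites |
| ccf_range | [0.2, 1.0] | per-site cancer-cell fraction, uniform |
| mean_coverage | 50 | negative-binomial depth mean, per site-cell |
| coverage_dispersion | 2.0 | NB size; var = μ + μ²/2 |
| p_mono | 0.2 | monoallelic expression per mutated site-cell |
| error_rate | 0.003 | per-read error (Illumina scale) |
| p_artifact | 0.01 | high-VAF artifact per null site-cell |
| qual_mean | 30 | mean base quality, Normal(·, 2) truncated at 0 |

Mutated entries draw alt reads Binomial(depth, ½(1−e) + e/6) — exactly
Binomial(depth, ½) at e = 0 — except monoallelic events, where all reads
come from one random allele (VAF exactly 0 or 1). Null entries draw
Binomial(depth, e), except artifacts, whose alt fraction is uniform in
[0.9, 1]. Zero-depth entries are omitted. Germline depth uses the same NB
with zero variant reads. Tumor cells carry each mutation independently with
the site's CCF; normal cells never do.

**What it does not model**, and hence what passing tests do not establish
about real data: gene-level expression bursting (monoallelic events are
independent per site-cell), alignment and mapping artifacts, copy-number
variation, strand bias, per-read quality structure, and site-specific error
rates. The null pool in real data is conditioned on the same retention
filter as the simulation applies, but real null sites can harbor genuine
low-level biology (RNA editing, subclonal germline mosaicism) that the
generator treats as artifact spikes.

## Numerical choices and degenerate inputs

- fdr2d is clipped to [0, 1]; the ratio can exceed 1 at noisy edges.
- m = 1 anchor site is allowed with a warning (size-1 null replicates give
  a noisy surface); fewer than 10 observed points is an error, fewer than
  100 a warning.
- Empty null pool, all-missing observed matrix, non-positive bandwidths and
  r outside (0, 1) raise immediately with remedy hints.
- Multi-allelic VCF records split per alternate allele; indels are skipped;
  `chr` prefixes are normalised off chromosome names; VarScan percent
  frequencies are parsed but counts are authoritative.
- Seeded determinism is end-to-end: one run seed spawns the null-draw and
  the two dequantization streams, and reruns produce byte-identical output.

## Problem sizes

The default test and acceptance workloads use the table above (100 cells,
1050 sites, K = 100 ⇒ ~5·10⁵ null points per replicate; a replicate runs in
a few seconds on one CPU). False-discovery control is assessed as the mean
realized FDP over 20 seeded replicates; p-value calibration on pure-null
designs of 160 sites × 25 cells at coverage 200, pooled over 3 replicates.

## Known limitations

Sensitivity is bounded by expression: a mutation in a silent or
reference-monoallelic site-cell is undetectable, so absence of a call never
implies absence of the mutation. The empirical null inherits whatever
systematic artifacts pass the retention filter; if the null pool is small,
replicates resample the same sites and the surface loses resolution (the
pool size is logged for this reason). p-values are rank-based against a
finite null, so their resolution is 1/(N+1).
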