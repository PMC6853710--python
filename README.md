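# scsomatic

Cell-level somatic mutation calling from single-cell RNA sequencing.

## The problem

Bulk tumor/germline DNA sequencing finds *which* somatic mutations a tumor
carries, but not *which cells* carry them. Single-cell RNA-seq covers
expressed mutation sites in individual cells, yet standard variant callers
flood it with false positives: scRNA-seq read counts mix sequencing error,
bursty coverage, and stochastic monoallelic expression (a cell transcribing
only one allele, producing VAFs of exactly 0 or 1 regardless of genotype).
A VAF of 1 — decisive evidence in bulk DNA — is routine noise in a single
cell.

`scsomatic` takes the somatic mutations already called from bulk DNA as
anchors and decides, per cell and per site, whether the cell's statistics
support the mutation, controlling false positives with a two-dimensional
local false discovery rate.

## The statistic

For each anchor site and cell, the statistic pair is z = (z₁, z₂) =
(total reads, variant-allele frequency). The local fdr at z is

    fdr2d(z) = π₀ · f₀(z) / f(z)

with f₀ the density of z under *no mutation* and f the marginal density of
the observed statistics. f₀ is an empirical null: K = 100 replicate
matrices resampled from SNV sites that are not bulk-called mutations and
have VAF = 0 in germline DNA — so the null embodies the real noise of the
platform, including the VAF ≈ 1 artifact cloud. Instead of smoothing two
densities and dividing, a single kernel smooth estimates the success
proportion

    r(z) = K f₀(z) / (f(z) + K f₀(z)),     fdr2d(z) = π₀ r(z) / (K (1 − r(z))),

with null points as successes and observed points as failures. π₀ is fixed
at its conservative maximum of 1. Calls use fdr2d < 0.2 (standard tier) or
< 0.05 (strict); p-values come from the empirical tail of the fdr statistic
over the pooled null points. See `docs/methods.md` for the estimator
details and calibration choices.

## Worked example

```sh
python examples/01_simulate_and_call.py
```

simulates 60 tumor + 40 normal cells over 50 true somatic mutation sites
(cancer-cell fractions uniform in [0.2, 1]) plus 1000 null SNV sites, runs
the full pipeline, and scores against the known truth:

```
observed entries (site x cell with coverage): 4895
significant calls at fdr2d < 0.2:             1675
  from tumor cells:                           1654
  from normal cells:                          21
false discovery proportion:                   0.0209
sensitivity (truth entries recovered):        0.8937
```

Of 4895 covered (site, cell) entries, 1675 are called mutated; almost all
come from tumor cells, the realized false-discovery proportion (2.1%) sits
far below the nominal 20% because π₀ = 1 is conservative, and ~89% of truly
mutated, covered entries are recovered — the remainder mostly hidden by
monoallelic expression of the reference allele. The other examples inspect
the fdr2d surface, convert competing callers' scores (LOD, genotype
likelihoods) to p-values, and check recovery concordance against bulk VAFs
(`examples/02`–`04`).

## Command line

Every stage is also a subcommand on plain TSVs:

```sh
scsomatic simulate --out data --seed 1
scsomatic run --cells data/cells --sites data/sites.tsv \
          --germline data/germline.tsv --out results --seed 1
scsomatic filter|fdr2d|call|summarize|compare ...   # stage-by-stage
```

`run` writes `calls.tsv` (site, cell, counts, fdr2d, p-value, tier),
`surface.tsv` (the fdr2d grid, for contour plots) and `summary.yaml`;
output is byte-identical across reruns with the same config and seed.

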