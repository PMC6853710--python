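"""Place other callers' scores on a common p-value scale.

Mutect-style log-odds (LOD) scores convert to p-values through the
chi-square(1) approximation of the likelihood-ratio statistic; Monovar-style
Phred-scaled genotype likelihoods convert through the wild-type posterior.
The false-positive-rate curve of negative-control cells then shows whether a
caller is biased: an unbiased method tracks the diagonal.
"""

import numpy as np

from scsomatic.comparison import (
    GenotypeLikelihoods,
    LodScore,
    fpr_curve,
    lod_to_pvalue,
    monovar_posterior,
    phred_unscale,
)

# A Mutect-like tumor LOD of 6.3 (its default calling threshold)
for lod in (0.0, 2.3, 6.3):
    p = lod_to_pvalue(LodScore(lod))
    print(f"LOD_T = {lod:4.1f}  ->  p = {p:.3e}")

# Phred-normalised genotype likelihoods PL = (40, 0, 60): the heterozygous
# genotype is best supported; the wild-type posterior is the local FDR of
# calling this a mutation.
gl = phred_unscale(GenotypeLikelihoods(40, 0, 60, scale="phred_normalized"))
post = monovar_posterior(gl, theta=0.001)
print(f"\nPL=(40,0,60): P(wild-type | data) = {post:.4e}")

# FPR curve of uniformly distributed negative-control p-values: close to the
# diagonal, i.e. unbiased.
rng = np.random.default_rng(0)
curve = fpr_curve(rng.uniform(0, 1, 2000), np.linspace(0.05, 0.95, 7))
print("\nthreshold  observed FPR (unbiased caller tracks the diagonal)")
for row in curve.itertuples(index=False):
    print(f"   {row.threshold:5.2f}     {row.fpr:.3f}")
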