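"""Statistics for benchmarking other callers on a common p-value scale.

Competing callers report heterogeneous scores: Mutect-style log-odds (LOD)
scores, Monovar-style Phred-scaled genotype likelihoods, or plain p-values.
This module converts each to a p-value — LOD via the chi-square(1)
approximation of the likelihood-ratio statistic, genotype likelihoods via the
wild-type posterior treated as a local FDR and then rank-transformed against
a null set — and evaluates callers by their false-positive-rate curve on
negative-control cells and by recovery concordance against bulk-DNA VAFs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .fdr2d import CellMutationCall, fdr_to_pvalue
from .variants import VariantSite

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeLikelihoods",
    "LodScore",
    "phred_unscale",
    "monovar_posterior",
    "posterior_to_pvalue",
    "lod_to_pvalue",
    "normal_lod_filter",
    "fpr_curve",
    "recovery_concordance",
]

DEFAULT_THETA = 0.001  # population-level mutation rate for genotype priors
DEFAULT_LOD_N_CUTOFF = 2.3


@dataclass(frozen=True)
class GenotypeLikelihoods:
    """Likelihoods of the three diploid genotypes at a biallelic site.

    L0 is the wild-type (reference) genotype, L1 heterozygous, L2 homozygous
    variant.  ``scale`` is 'linear' for raw likelihoods or 'phred_normalized'
    for PL-style values (best genotype at 0).
    """

    L0: float
    L1: float
    L2: float
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "phred_normalized"):
            raise ValueError(f"unknown scale {self.scale!r}")
        values = (self.L0, self.L1, self.L2)
        if self.scale == "phred_normalized":
            if any(v < 0 for v in values):
                raise ValueError("Phred-scaled likelihoods must be >= 0")
        else:
            if all(v == 0 for v in values):
                raise ValueError("at least one genotype likelihood must be positive")
            if any(v < 0 for v in values):
                raise ValueError("likelihoods must be non-negative")


@dataclass(frozen=True)
class LodScore:
    """A log10 likelihood-ratio score (Mutect's LOD_T or LOD_N)."""

    value: float
    kind: str = "tumor"  # tumor | normal

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("LOD score must be finite")
        if self.kind not in ("tumor", "normal"):
            raise ValueError(f"unknown LOD kind {self.kind!r}")


def phred_unscale(gl: GenotypeLikelihoods) -> GenotypeLikelihoods:
    """Map Phred-normalised likelihoods PL to linear scale 10**(-PL/10)."""
    if gl.scale != "phred_normalized":
        raise ValueError("phred_unscale expects scale='phred_normalized'")
    return GenotypeLikelihoods(
        L0=10.0 ** (-gl.L0 / 10.0),
        L1=10.0 ** (-gl.L1 / 10.0),
        L2=10.0 ** (-gl.L2 / 10.0),
        scale="linear",
    )


def genotype_priors(theta: float = DEFAULT_THETA) -> Tuple[float, float, float]:
    """Single-cell genotype priors P(0) = (1-theta)/2, P(1) = theta, P(2) = (1-theta)/2."""
    if not (0 < theta < 1):
        raise ValueError("theta must lie in (0, 1)")
    p0 = 0.5 * (1.0 - theta)
    priors = (p0, theta, p0)
    assert abs(sum(priors) - 1.0) < 1e-12
    return priors


def monovar_posterior(gl: GenotypeLikelihoods, theta: float = DEFAULT_THETA) -> float:
    """Posterior probability of the wild-type genotype, P(g=0 | D).

    P(g=0|D) = L0 P(0) / sum_i L_i P(i) with the single-cell priors above.
    Downstream this posterior plays the role of the local FDR of the call.
    """
    if gl.scale != "linear":
        gl = phred_unscale(gl)
    p0, p1, p2 = genotype_priors(theta)
    denom = gl.L0 * p0 + gl.L1 * p1 + gl.L2 * p2
    if denom == 0:
        raise ValueError("all genotype likelihoods are zero; posterior undefined")
    return gl.L0 * p0 / denom


def posterior_to_pvalue(
    posteriors, null_posteriors: Optional[np.ndarray] = None
):
    """Convert wild-type posteriors (local FDRs) to p-values by null ranking.

    Uses the same empirical-tail construction as the fdr2d statistic:
    p = (1 + #{null <= value}) / (1 + N).  Without a null set the posterior
    itself is returned unchanged with a warning — it is then a local FDR, not
    a p-value.
    """
    if null_posteriors is None:
        logger.warning(
            "no null posterior set supplied; returning the posterior itself, "
            "which is a local FDR and not a p-value"
        )
        return posteriors
    return fdr_to_pvalue(posteriors, np.sort(np.asarray(null_posteriors, dtype=float)))


def lod_to_pvalue(lod: LodScore) -> float:
    """p-value from a log10 odds score via the chi-square(1) approximation.

    Twice the natural-log likelihood ratio, 2 ln(10) * LOD, is approximately
    chi-square with one degree of freedom; the p-value is its upper tail.
    The test is one-sided: LOD <= 0 maps to p = 1.
    """
    if lod.value <= 0:
        return 1.0
    statistic = 2.0 * math.log(10.0) * lod.value
    return float(stats.chi2.sf(statistic, df=1))


def normal_lod_filter(
    records: Iterable[Tuple], cutoff: float = DEFAULT_LOD_N_CUTOFF
) -> List[Tuple]:
    """Keep (site, cell, LOD_N) records whose normal LOD meets the cutoff.

    The comparison is inclusive (LOD_N >= cutoff): the normal sample must
    confidently lack the variant for a somatic interpretation.
    """
    kept = []
    for rec in records:
        lod_n = rec[-1]
        value = lod_n.value if isinstance(lod_n, LodScore) else float(lod_n)
        if value >= cutoff:
            kept.append(rec)
    return kept


def fpr_curve(
    pvalues_negative: Sequence[float], thresholds: Sequence[float]
) -> pd.DataFrame:
    """Observed false-positive rate of negative-control cells vs p threshold.

    FPR(t) = fraction of negative-control p-values <= t.  An unbiased method
    tracks the diagonal FPR(t) = t.
    """
    p = np.asarray(pvalues_negative, dtype=float)
    if p.size == 0:
        raise ValueError("p-value collection must be non-empty")
    t = np.asarray(thresholds, dtype=float)
    fpr = np.array([(p <= ti).mean() for ti in t])
    return pd.DataFrame({"threshold": t, "fpr": fpr})


def recovery_concordance(
    bulk_vafs: Mapping[VariantSite, float],
    cell_calls: Iterable[CellMutationCall],
    tumor_cells: Set[str],
    threshold: float = 0.2,
    purity: float = 1.0,
    ploidy: int = 2,
) -> Tuple[pd.DataFrame, float]:
    """Per-site expected vs observed mutated-cell fractions and their correlation.

    The bulk-DNA VAF v of a heterozygous diploid somatic mutation in a tumor
    of the given purity implies an expected mutated-cell fraction of
    ploidy * v / purity.  The observed fraction is, per site, the number of
    tumor cells called mutated (fdr2d < threshold) over the number of tumor
    cells with non-missing coverage at the site.  Returns the paired values
    and their Pearson correlation.
    """
    covered: dict = {}
    mutated: dict = {}
    for call in cell_calls:
        if call.cell_id not in tumor_cells:
            continue
        covered[call.site] = covered.get(call.site, 0) + 1
        if call.fdr2d < threshold:
            mutated[call.site] = mutated.get(call.site, 0) + 1
    rows = []
    for site, vaf in bulk_vafs.items():
        if covered.get(site, 0) == 0:
            continue
        expected = min(1.0, ploidy * vaf / purity)
        observed = mutated.get(site, 0) / covered[site]
        rows.append((site, expected, observed))
    if len(rows) < 3:
        raise ValueError(f"need calls at >= 3 sites with bulk VAFs, got {len(rows)}")
    df = pd.DataFrame(rows, columns=["site", "expected_vaf_fraction", "observed_fraction"])
    r = float(np.corrcoef(df["expected_vaf_fraction"], df["observed_fraction"])[0, 1])
    return df, r
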