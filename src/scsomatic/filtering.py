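"""SNV retention filtering and the germline-zero restriction.

An SNV enters the analysis only if, in at least one sample, it simultaneously
has enough variant-supporting reads, a high enough variant-allele frequency
and a high enough average base quality.  Candidate somatic sites and the
empirical-null site pool are both further restricted to loci with zero
variant reads in adequately covered germline DNA, since a true somatic
mutation should leave no trace in the germline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set

from .variants import SampleRole, SampleVariantTable, VariantSite

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "retain_snvs",
    "restrict_germline_zero",
    "build_null_pool",
]


@dataclass(frozen=True)
class FilterConfig:
    """Retention thresholds, all inclusive (>=).

    min_alt_reads
        Minimum variant-supporting reads (reads carrying the alternate
        allele, matching VarScan's min-reads2 semantics).  Default 5.
    min_vaf
        Minimum variant-allele frequency.  Default 0.01 (1%).
    min_qual
        Minimum average base quality in Phred units.  Default 15.
    """

    min_alt_reads: int = 5
    min_vaf: float = 0.01
    min_qual: float = 15.0

    def __post_init__(self) -> None:
        if self.min_alt_reads < 0 or self.min_qual < 0 or not (0 <= self.min_vaf <= 1):
            raise ValueError("filter thresholds must be non-negative with min_vaf <= 1")

    def passes(self, obs) -> bool:
        """True when one observation meets all three criteria at once.

        A NaN quality (format carried no quality information) fails the
        quality criterion — conservative.
        """
        if obs.total_reads == 0:
            return False
        qual_ok = not math.isnan(obs.mean_qual) and obs.mean_qual >= self.min_qual
        return (
            obs.alt_reads >= self.min_alt_reads
            and obs.vaf >= self.min_vaf
            and qual_ok
        )


def retain_snvs(
    tables: Sequence[SampleVariantTable], config: FilterConfig = FilterConfig()
) -> List[VariantSite]:
    """Sites where at least one sample passes all retention criteria together.

    The conjunction binds within a single sample: a site where one sample has
    the reads and another the quality is dropped.  Result order is sorted
    (chrom, pos, ref, alt), hence independent of input table order.
    """
    retained: Set[VariantSite] = set()
    for table in tables:
        for obs in table:
            if obs.site not in retained and config.passes(obs):
                retained.add(obs.site)
    return sorted(retained)


def restrict_germline_zero(
    sites: Iterable[VariantSite],
    germline: SampleVariantTable,
    min_germline_depth: int = 10,
) -> List[VariantSite]:
    """Keep sites confirmed variant-free in the germline sample.

    A site is kept iff the germline observation has zero alt reads and depth
    >= ``min_germline_depth``.  Sites without germline coverage (or with depth
    below the minimum) are excluded: VAF = 0 cannot be asserted there.
    """
    if germline.role is not SampleRole.BULK_GERMLINE:
        raise ValueError(f"expected a bulk_germline table, got role {germline.role.value}")
    kept = []
    for site in sites:
        obs = germline.get(site)
        if obs is None:
            continue
        if obs.alt_reads == 0 and obs.total_reads >= min_germline_depth:
            kept.append(site)
    return kept


def build_null_pool(
    retained_sites: Iterable[VariantSite],
    bc_mutations: Iterable[VariantSite],
    germline: SampleVariantTable,
    cells: Sequence[SampleVariantTable],
    min_germline_depth: int = 10,
) -> List[VariantSite]:
    """Sites eligible for Monte-Carlo null sampling.

    The pool is the retained SNVs minus the bulk-called somatic mutation
    sites, restricted to germline-zero loci, keeping only sites covered
    (total_reads > 0) in at least one cell.  The pool is guaranteed disjoint
    from the bc-mutation set.
    """
    bc_set = set(bc_mutations)
    candidates = [s for s in retained_sites if s not in bc_set]
    candidates = restrict_germline_zero(candidates, germline, min_germline_depth)
    pool = []
    for site in candidates:
        for cell in cells:
            obs = cell.get(site)
            if obs is not None and obs.total_reads > 0:
                pool.append(site)
                break
    if not pool:
        raise ValueError(
            "empty null pool: relax min_germline_depth or supply more retained sites"
        )
    assert not bc_set.intersection(pool), "null pool overlaps bc-mutation sites"
    logger.info("null pool: %d sites (from %d candidates)", len(pool), len(candidates))
    return pool
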