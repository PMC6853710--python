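"""Domain types for SNV sites and per-sample variant observations.

Coordinates are 1-based and fully closed throughout, matching VCF convention.
Chromosome names are normalised on construction: a leading ``chr``/``Chr``
prefix is stripped so site lists and variant tables produced under mixed
naming conventions join correctly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Iterator, Optional

__all__ = [
    "VALID_BASES",
    "normalize_chrom",
    "VariantSite",
    "CellSiteObservation",
    "SampleRole",
    "SampleVariantTable",
]

VALID_BASES = frozenset("ACGT")


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix (case-insensitive) from a chromosome name."""
    if chrom[:3].lower() == "chr":
        return chrom[3:]
    return chrom


@dataclass(frozen=True, order=True)
class VariantSite:
    """A biallelic SNV locus: chromosome, 1-based position, ref and alt base.

    ``(chrom, pos, ref, alt)`` uniquely identifies a site within any table.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(str(self.chrom)))
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"ref/alt must be single bases in ACGT: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    def __str__(self) -> str:  # e.g. "4:55133837 C>T"
        return f"{self.chrom}:{self.pos} {self.ref}>{self.alt}"


class SampleRole(str, Enum):
    """What kind of sample a variant table came from."""

    CELL = "cell"
    BULK_TUMOR = "bulk_tumor"
    BULK_GERMLINE = "bulk_germline"


@dataclass(frozen=True)
class CellSiteObservation:
    """The per-sample statistics at one SNV site.

    ``total_reads`` is the coverage statistic z1 and ``vaf`` the variant-allele
    frequency z2 = alt_reads / total_reads.  ``vaf`` is None when there is no
    coverage.  ``mean_qual`` is the average base quality in Phred units; NaN
    when the source format carried no quality information.
    """

    site: VariantSite
    sample_id: str
    total_reads: int
    alt_reads: int
    mean_qual: float = math.nan

    def __post_init__(self) -> None:
        if self.total_reads < 0:
            raise ValueError("total_reads must be non-negative")
        if not (0 <= self.alt_reads <= self.total_reads):
            raise ValueError(
                f"alt_reads must satisfy 0 <= alt <= total ({self.alt_reads}/{self.total_reads})"
            )
        if not math.isnan(self.mean_qual) and self.mean_qual < 0:
            raise ValueError("mean_qual must be >= 0")

    @property
    def vaf(self) -> Optional[float]:
        if self.total_reads == 0:
            return None
        return self.alt_reads / self.total_reads


@dataclass
class SampleVariantTable:
    """All SNV observations for one sample (a single cell or a bulk sample).

    At most one observation per site; adding a duplicate site raises.
    """

    sample_id: str
    role: SampleRole
    observations: Dict[VariantSite, CellSiteObservation] = field(default_factory=dict)

    def add(self, obs: CellSiteObservation) -> None:
        if obs.site in self.observations:
            raise ValueError(f"duplicate observation at {obs.site} in sample {self.sample_id}")
        self.observations[obs.site] = obs

    def get(self, site: VariantSite) -> Optional[CellSiteObservation]:
        return self.observations.get(site)

    def sites(self) -> Iterable[VariantSite]:
        return self.observations.keys()

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[CellSiteObservation]:
        return iter(self.observations.values())

    def __contains__(self, site: VariantSite) -> bool:
        return site in self.observations
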