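"""Readers and writers for the variant-table formats the pipeline consumes.

Supported inputs are VCF 4.x (via pysam), VarScan-style tab-delimited SNV
tables (``pileup2snp``/``somatic`` flavours), and plain TSV site lists.  All
coordinates are 1-based.  Only single-nucleotide substitutions are kept:
indels and non-ACGT alleles are skipped everywhere, and multi-allelic VCF
records are split into one observation per alternate allele.
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import pandas as pd
import pysam

from .variants import (
    VALID_BASES,
    CellSiteObservation,
    SampleRole,
    SampleVariantTable,
    VariantSite,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_CALL_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "cell_id",
    "total_reads",
    "alt_reads",
    "vaf",
    "fdr2d",
    "p_value",
    "tier",
]


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref.upper() in VALID_BASES and alt.upper() in VALID_BASES


def _record_counts(rec, sample_name: Optional[str]):
    """Extract (ref_reads, per-alt reads, total, mean_qual) from a VCF record.

    Prefers per-sample FORMAT fields (AD, or VarScan's RD/AD pair, with DP for
    depth); falls back to INFO.  Raises ValueError naming the record when no
    depth information is present.
    """
    n_alts = len(rec.alts or ())
    sample = None
    if rec.samples:
        names = list(rec.samples)
        chosen = sample_name if sample_name in names else names[0]
        sample = rec.samples[chosen]

    def _get(container, key):
        try:
            return container[key]
        except (KeyError, AttributeError):
            return None

    ad = _get(sample, "AD") if sample is not None else None
    rd = _get(sample, "RD") if sample is not None else None
    dp = _get(sample, "DP") if sample is not None else None
    if ad is None:
        ad = _get(rec.info, "AD")
    if dp is None:
        dp = _get(rec.info, "DP")

    qual = None
    for key in ("ABQ", "BQ"):
        if sample is not None:
            qual = _get(sample, key)
        if qual is None:
            qual = _get(rec.info, key)
        if qual is not None:
            break
    if isinstance(qual, (tuple, list)):
        qual = qual[0]
    mean_qual = float(qual) if qual is not None else math.nan

    if isinstance(ad, int):
        ad = (ad,)

    if rd is not None and ad is not None and len(ad) == n_alts:
        # VarScan convention: RD = reference reads, AD = alt reads per alt.
        alt_counts = [int(a) for a in ad]
        ref_reads = int(rd)
        total = int(dp) if dp is not None else ref_reads + sum(alt_counts)
        return ref_reads, alt_counts, total, mean_qual

    if ad is not None and len(ad) == n_alts + 1:
        ref_reads = int(ad[0]) if ad[0] is not None else 0
        alt_counts = [int(a) if a is not None else 0 for a in ad[1:]]
        total = int(dp) if dp is not None else ref_reads + sum(alt_counts)
        return ref_reads, alt_counts, total, mean_qual

    raise ValueError(
        f"no usable depth fields (AD/DP or RD/AD) in record {rec.chrom}:{rec.pos}"
    )


def read_vcf(path: PathLike, sample_id: str, role: SampleRole) -> SampleVariantTable:
    """Read a VCF 4.x file into a :class:`SampleVariantTable`.

    One observation per biallelic SNV alternate allele; multi-allelic records
    are split per alt; indels are skipped.  VAF is always recomputed from the
    read counts, never taken from a frequency field.
    """
    role = SampleRole(role)
    table = SampleVariantTable(sample_id=sample_id, role=role)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            _, alt_counts, total, mean_qual = _record_counts(rec, sample_id)
            if total <= 0:
                continue
            for alt, alt_reads in zip(rec.alts, alt_counts):
                if not _is_snv(rec.ref, alt):
                    continue
                site = VariantSite(rec.chrom, rec.pos, rec.ref, alt)
                if site in table:
                    logger.warning("duplicate VCF record at %s; keeping first", site)
                    continue
                table.add(
                    CellSiteObservation(
                        site=site,
                        sample_id=sample_id,
                        total_reads=total,
                        alt_reads=min(int(alt_reads), total),
                        mean_qual=mean_qual,
                    )
                )
    return table


_VARSCAN_ALIASES = {
    "chrom": ("chrom", "chr", "chromosome"),
    "pos": ("position", "pos"),
    "ref": ("ref",),
    "alt": ("var", "alt"),
    "reads1": ("reads1", "ref_reads"),
    "reads2": ("reads2", "var_reads", "alt_reads"),
    "qual": ("qual2", "avgqual", "avg_qual", "qual", "mean_qual"),
}


def _resolve_column(columns: Sequence[str], aliases: Sequence[str]) -> Optional[str]:
    lower = {c.lower(): c for c in columns}
    for alias in aliases:
        if alias in lower:
            return lower[alias]
    return None


def parse_percent(value) -> float:
    """Parse a VarScan frequency value ('25%', '25.0%', or a bare fraction)."""
    if isinstance(value, str) and value.endswith("%"):
        return float(value[:-1]) / 100.0
    return float(value)


def read_varscan_table(path: PathLike, sample_id: str, role: SampleRole) -> SampleVariantTable:
    """Read a VarScan ``pileup2snp``/``somatic`` tab-delimited SNV table.

    ``total_reads`` = reads1 + reads2.  Percent-formatted frequency columns are
    accepted but the VAF is recomputed from the read counts, which are
    authoritative.
    """
    role = SampleRole(role)
    df = pd.read_csv(path, sep="\t", dtype=str)
    resolved = {}
    for field, aliases in _VARSCAN_ALIASES.items():
        col = _resolve_column(df.columns, aliases)
        if col is None and field != "qual":
            raise ValueError(f"VarScan table {path} is missing required column '{aliases[0]}'")
        resolved[field] = col

    table = SampleVariantTable(sample_id=sample_id, role=role)
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        ref = str(row[resolved["ref"]]).upper()
        alt = str(row[resolved["alt"]]).upper()
        if not _is_snv(ref, alt):
            continue
        try:
            pos = int(row[resolved["pos"]])
        except ValueError as exc:
            raise ValueError(f"non-integer position {row[resolved['pos']]!r} in {path}") from exc
        reads1 = int(row[resolved["reads1"]])
        reads2 = int(row[resolved["reads2"]])
        qual = float(row[resolved["qual"]]) if resolved["qual"] else math.nan
        site = VariantSite(str(row[resolved["chrom"]]), pos, ref, alt)
        table.add(
            CellSiteObservation(
                site=site,
                sample_id=sample_id,
                total_reads=reads1 + reads2,
                alt_reads=reads2,
                mean_qual=qual,
            )
        )
    return table


def read_site_list(path: PathLike) -> List[VariantSite]:
    """Read a TSV site list (chrom, pos, ref, alt; optional header).

    Returns a de-duplicated list in file order.  An empty file yields an empty
    list with a logged warning.
    """
    sites: List[VariantSite] = []
    seen = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.strip().split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 4:
                raise ValueError(f"{path}:{line_no}: expected 4 columns (chrom pos ref alt)")
            chrom, pos_str, ref, alt = fields[:4]
            try:
                pos = int(pos_str.replace(",", ""))
            except ValueError:
                if line_no == 1:  # header row
                    continue
                raise ValueError(f"{path}:{line_no}: non-integer position {pos_str!r}")
            site = VariantSite(chrom, pos, ref, alt)
            if site not in seen:
                seen.add(site)
                sites.append(site)
    if not sites:
        logger.warning("site list %s is empty", path)
    return sites


def write_table(table: SampleVariantTable, path: PathLike) -> None:
    """Write a SampleVariantTable to the internal TSV format (exact round-trip)."""
    with open(path, "w", newline="") as fh:
        fh.write(f"#sample_id={table.sample_id}\n#role={table.role.value}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "ref", "alt", "total_reads", "alt_reads", "mean_qual"])
        for obs in sorted(table, key=lambda o: o.site):
            writer.writerow(
                [obs.site.chrom, obs.site.pos, obs.site.ref, obs.site.alt,
                 obs.total_reads, obs.alt_reads, repr(obs.mean_qual)]
            )


def read_table(path: PathLike) -> SampleVariantTable:
    """Read the internal TSV format written by :func:`write_table`."""
    with open(path) as fh:
        header_meta = {}
        pos0 = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos0)
                break
            key, _, value = line[1:].strip().partition("=")
            header_meta[key] = value
            pos0 = fh.tell()
        sample_id = header_meta.get("sample_id", Path(path).stem)
        role = SampleRole(header_meta.get("role", "cell"))
        reader = csv.DictReader(fh, delimiter="\t")
        table = SampleVariantTable(sample_id=sample_id, role=role)
        for row in reader:
            site = VariantSite(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            table.add(
                CellSiteObservation(
                    site=site,
                    sample_id=sample_id,
                    total_reads=int(row["total_reads"]),
                    alt_reads=int(row["alt_reads"]),
                    mean_qual=float(row["mean_qual"]),
                )
            )
    return table


def write_calls(calls: Iterable, path: PathLike) -> None:
    """Write cell-level mutation calls as a TSV.

    Rows are ordered by site (chrom, pos, ref, alt — lexicographic on chrom)
    then by cell id, so output is deterministic for a given call set.
    """
    rows = sorted(calls, key=lambda c: (c.site, c.cell_id))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CALL_COLUMNS)
        for c in rows:
            writer.writerow(
                [c.site.chrom, c.site.pos, c.site.ref, c.site.alt, c.cell_id,
                 c.z1, c.alt_reads, f"{c.z2:.6g}", f"{c.fdr2d:.6g}",
                 f"{c.p_value:.6g}", c.tier]
            )


def read_calls(path: PathLike) -> pd.DataFrame:
    """Read a call table written by :func:`write_calls` into a DataFrame."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "cell_id": str})
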