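"""End-to-end calling pipeline: filter, germline restriction, null sampling,
surface estimation, calling and summary, with deterministic seeded output."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .fdr2d import (
    CellMutationCall,
    DEFAULT_K,
    DEFAULT_THRESHOLDS,
    Fdr2dSurface,
    NullSampleSet,
    ObservedStatMatrix,
    build_observed_matrix,
    call_mutations,
    estimate_r,
    sample_null,
    summarize_calls,
)
from .filtering import FilterConfig, build_null_pool, restrict_germline_zero, retain_snvs
from .variants import SampleVariantTable, VariantSite

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "CallingResult", "call_pipeline", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs.

    Paths may be None when the pipeline is driven in memory.  Defaults follow
    the method's published operating point: K = 100 null replicates, pi0 = 1,
    significance tiers at fdr2d < 0.05 (strict) and < 0.2 (standard).
    """

    cells_dir: Optional[str] = None
    sites_path: Optional[str] = None
    germline_path: Optional[str] = None
    out_dir: str = "scsomatic_out"
    filter: FilterConfig = field(default_factory=FilterConfig)
    min_germline_depth: int = 10
    K: int = DEFAULT_K
    pi0: float = 1.0
    grid_size: Tuple[int, int] = (50, 50)
    bandwidth: Optional[Tuple[float, float]] = None
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS
    seed: int = 0
    keep_intermediates: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        strict, standard = self.thresholds
        if not (0 < strict < standard < 1):
            raise ValueError("thresholds must satisfy 0 < strict < standard < 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "filter" in data and isinstance(data["filter"], dict):
            data["filter"] = FilterConfig(**data["filter"])
        for key in ("grid_size", "bandwidth", "thresholds"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class CallingResult:
    """All artifacts of one pipeline run, for auditing and export."""

    calls: List[CellMutationCall]
    surface: Fdr2dSurface
    observed: ObservedStatMatrix
    nulls: NullSampleSet
    bc_sites_used: List[VariantSite]
    pool: List[VariantSite]
    retained: List[VariantSite]


def call_pipeline(
    cells: Sequence[SampleVariantTable],
    bc_sites: Sequence[VariantSite],
    germline: SampleVariantTable,
    filter_config: FilterConfig = FilterConfig(),
    min_germline_depth: int = 10,
    K: int = DEFAULT_K,
    pi0: float = 1.0,
    grid_size: Tuple[int, int] = (50, 50),
    bandwidth: Optional[Tuple[float, float]] = None,
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS,
    seed: int = 0,
) -> CallingResult:
    """Run the full in-memory calling pipeline.

    Stages: SNV retention across all samples; restriction of the candidate
    (bc-mutation) sites to germline-zero loci; observed matrix construction;
    K-replicate Monte-Carlo null sampling from the retained, non-candidate,
    germline-zero pool; surface estimation; calling with p-values.
    """
    retained = retain_snvs(list(cells) + [germline], filter_config)
    logger.info("retained %d SNVs after filtering", len(retained))
    bc_usable = restrict_germline_zero(bc_sites, germline, min_germline_depth)
    if not bc_usable:
        raise ValueError(
            "germline restriction removed every bc-mutation site; "
            "check germline coverage or lower min_germline_depth"
        )
    pool = build_null_pool(retained, bc_sites, germline, cells, min_germline_depth)
    # One run seed deterministically drives the null draws and the two
    # count-dequantization streams.
    s_draw, s_jit_obs, s_jit_pool = (
        int(x) % (2**31) for x in np.random.SeedSequence(seed).generate_state(3)
    )
    observed = build_observed_matrix(cells, bc_usable, jitter_seed=s_jit_obs)
    logger.info(
        "observed matrix: %d sites x %d cells, %.1f%% entries present",
        len(observed.sites), len(observed.cells),
        100.0 * observed.n_observed / observed.z1.size,
    )
    nulls = sample_null(
        pool, cells, m=len(bc_usable), K=K, seed=s_draw, jitter_seed=s_jit_pool
    )
    surface = estimate_r(observed, nulls, grid_size=grid_size, bandwidth=bandwidth, pi0=pi0)
    logger.info("bandwidth: (%.4f, %.4f)", *surface.bandwidth)
    calls = call_mutations(observed, surface, nulls, thresholds=thresholds)
    return CallingResult(
        calls=calls,
        surface=surface,
        observed=observed,
        nulls=nulls,
        bc_sites_used=bc_usable,
        pool=pool,
        retained=retained,
    )


def surface_to_frame(surface: Fdr2dSurface) -> pd.DataFrame:
    """Long-format (t1, t2, r, fdr2d) table of a surface, e.g. for contour plots."""
    t1, t2 = np.meshgrid(surface.t1_breaks, surface.t2_breaks, indexing="ij")
    return pd.DataFrame(
        {
            "t1": t1.ravel(),
            "t2": t2.ravel(),
            "r": surface.r_grid.ravel(),
            "fdr2d": surface.fdr_grid.ravel(),
        }
    )


def write_surface(surface: Fdr2dSurface, path) -> None:
    """Persist a surface (grid plus metadata) so staged runs can resume."""
    with open(path, "w") as fh:
        fh.write(
            f"#K={surface.K}\n#pi0={float(surface.pi0)!r}\n"
            f"#bandwidth={float(surface.bandwidth[0])!r},{float(surface.bandwidth[1])!r}\n"
            f"#n_success={surface.n_success}\n#n_failure={surface.n_failure}\n"
        )
        fh.write("t1\tt2\tr\traw\tfdr2d\tsucc_w\ttotal_w\n")
        for i, t1 in enumerate(surface.t1_breaks):
            for j, t2 in enumerate(surface.t2_breaks):
                fh.write(
                    f"{float(t1)!r}\t{float(t2)!r}\t{float(surface.r_grid[i, j])!r}\t"
                    f"{float(surface.raw_grid[i, j])!r}\t{float(surface.fdr_grid[i, j])!r}\t"
                    f"{float(surface.succ_grid[i, j])!r}\t{float(surface.total_grid[i, j])!r}\n"
                )


def read_surface(path) -> Fdr2dSurface:
    """Reload a surface written by :func:`write_surface` (exact round-trip)."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key] = value
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    t1_breaks = np.array(sorted(df["t1"].unique()))
    t2_breaks = np.array(sorted(df["t2"].unique()))
    shape = (t1_breaks.size, t2_breaks.size)
    df = df.sort_values(["t1", "t2"])
    h1, h2 = (float(x) for x in meta["bandwidth"].split(","))
    return Fdr2dSurface(
        t1_breaks=t1_breaks,
        t2_breaks=t2_breaks,
        r_grid=df["r"].to_numpy().reshape(shape),
        raw_grid=df["raw"].to_numpy().reshape(shape),
        fdr_grid=df["fdr2d"].to_numpy().reshape(shape),
        K=int(meta["K"]),
        pi0=float(meta["pi0"]),
        bandwidth=(h1, h2),
        n_success=int(meta["n_success"]),
        n_failure=int(meta["n_failure"]),
        succ_grid=df["succ_w"].to_numpy().reshape(shape),
        total_grid=df["total_w"].to_numpy().reshape(shape),
    )


def write_observed(observed: ObservedStatMatrix, path) -> None:
    """Persist the observed statistic matrix in long form (present entries only)."""
    sz1, salt = observed.smooth_arrays
    with open(path, "w") as fh:
        fh.write("#cells=" + ",".join(observed.cells) + "\n")
        fh.write(
            "chrom\tpos\tref\talt\tcell_id\ttotal_reads\talt_reads\t"
            "total_smooth\talt_smooth\n"
        )
        rows, cols = np.nonzero(observed.mask)
        for i, j in zip(rows, cols):
            s = observed.sites[i]
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{observed.cells[j]}\t"
                f"{int(observed.z1[i, j])}\t{int(observed.alt[i, j])}\t"
                f"{float(sz1[i, j])!r}\t{float(salt[i, j])!r}\n"
            )


def read_observed(path) -> ObservedStatMatrix:
    """Reload a matrix written by :func:`write_observed` (exact round-trip)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#cells="):
            raise ValueError(f"{path} is not an observed-matrix file")
        cells = first[len("#cells="):].strip().split(",")
        df = pd.read_csv(
            fh, sep="\t", dtype={"chrom": str, "cell_id": str},
            float_precision="round_trip",
        )
    sites = []
    seen = {}
    for r in df.itertuples():
        site = VariantSite(r.chrom, int(r.pos), r.ref, r.alt)
        if site not in seen:
            seen[site] = len(sites)
            sites.append(site)
    shape = (len(sites), len(cells))
    z1 = np.full(shape, np.nan)
    alt = np.full(shape, np.nan)
    z1s = np.full(shape, np.nan)
    alts = np.full(shape, np.nan)
    cell_index = {c: j for j, c in enumerate(cells)}
    for r in df.itertuples():
        site = VariantSite(r.chrom, int(r.pos), r.ref, r.alt)
        i, j = seen[site], cell_index[r.cell_id]
        z1[i, j] = r.total_reads
        alt[i, j] = r.alt_reads
        z1s[i, j] = r.total_smooth
        alts[i, j] = r.alt_smooth
    return ObservedStatMatrix(
        sites=sites, cells=cells, z1=z1, alt=alt, z1_smooth=z1s, alt_smooth=alts
    )


def run_pipeline(config: RunConfig) -> CallingResult:
    """File-based pipeline: read inputs, run, write calls/surface/summary.

    Outputs (calls.tsv, surface.tsv, summary.yaml) are byte-identical across
    reruns with the same config, including the seed.
    """
    for name, path in (
        ("cells directory", config.cells_dir),
        ("site list", config.sites_path),
        ("germline table", config.germline_path),
    ):
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"input stage: {name} not found at {path!r}")

    cells = [vio.read_table(p) for p in sorted(Path(config.cells_dir).glob("*.tsv"))]
    if not cells:
        raise FileNotFoundError(f"input stage: no cell tables (*.tsv) in {config.cells_dir}")
    bc_sites = vio.read_site_list(config.sites_path)
    germline = vio.read_table(config.germline_path)

    result = call_pipeline(
        cells,
        bc_sites,
        germline,
        filter_config=config.filter,
        min_germline_depth=config.min_germline_depth,
        K=config.K,
        pi0=config.pi0,
        grid_size=config.grid_size,
        bandwidth=config.bandwidth,
        thresholds=config.thresholds,
        seed=config.seed,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vio.write_calls(result.calls, out / "calls.tsv")
    surface_to_frame(result.surface).to_csv(out / "surface.tsv", sep="\t", index=False)
    summary = summarize_calls(result.calls, threshold=config.thresholds[1])
    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "n_cells": len(result.observed.cells),
                "m_sites": len(result.bc_sites_used),
                "pool_size": len(result.pool),
                "n_retained_snvs": len(result.retained),
                "missing_fraction": round(
                    1.0 - result.observed.n_observed / result.observed.z1.size, 4
                ),
                "bandwidth": [round(b, 6) for b in result.surface.bandwidth],
                "K": result.nulls.K,
                "seed": config.seed,
                "n_significant": summary.n_significant,
                "n_mutation_sites": summary.n_sites,
                "cells_per_site": summary.cells_per_site,
            },
            fh,
            sort_keys=False,
        )
    if config.keep_intermediates:
        pd.DataFrame(
            {"chrom": [s.chrom for s in result.pool], "pos": [s.pos for s in result.pool],
             "ref": [s.ref for s in result.pool], "alt": [s.alt for s in result.pool]}
        ).to_csv(out / "null_pool.tsv", sep="\t", index=False)
    return result
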