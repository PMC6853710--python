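"""Seeded synthetic scRNA-seq variant datasets with ground truth.

The generator emulates the statistical structure that makes cell-level
mutation calling from single-cell RNA-seq hard:

* per-site per-cell coverage heterogeneity (negative-binomial depth, with
  zero-depth entries becoming missing observations);
* heterozygous somatic mutations whose VAF concentrates near 0.5 but spikes
  to exactly 0 or 1 with probability ``p_mono`` (stochastic monoallelic
  expression);
* sequencing-error noise at null sites (alt reads ~ Binomial(depth, error
  rate)) plus occasional high-VAF artifacts with probability ``p_artifact``
  (monoallelic mis-expression / editing-like events), reproducing the VAF~1
  cloud at non-mutated sites;
* a tumor / non-tumor cell partition, with each tumor cell carrying each
  mutation independently with that site's cancer-cell fraction (CCF).

All randomness derives from a single integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as vio
from .fdr2d import CellMutationCall
from .variants import (
    CellSiteObservation,
    SampleRole,
    SampleVariantTable,
    VariantSite,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SimulatedDataset",
    "EvalMetrics",
    "simulate_dataset",
    "evaluate_calls",
    "replicate_study",
    "write_dataset",
    "read_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic dataset.

    Defaults describe a desk-scale study: 60 tumor and 40 normal cells, 50
    true somatic mutation sites with CCFs drawn uniformly in [0.2, 1.0], a
    pool of 1000 null SNV sites, negative-binomial coverage with mean 50 and
    size (dispersion) 2, Illumina-scale error rate 0.003, a 20% chance of
    monoallelic expression per mutated site-cell, and a 1% chance of a
    high-VAF artifact per null site-cell.
    """

    n_tumor: int = 60
    n_normal: int = 40
    m_mut: int = 50
    m_null: int = 1000
    ccf_range: Tuple[float, float] = (0.2, 1.0)
    ccf_per_site: Optional[Sequence[float]] = None
    mean_coverage: float = 50.0
    coverage_dispersion: float = 2.0
    p_mono: float = 0.2
    error_rate: float = 0.003
    p_artifact: float = 0.01
    qual_mean: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_mono, self.error_rate, self.p_artifact)
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("p_mono, error_rate and p_artifact must lie in [0, 1]")
        if min(self.n_tumor, self.n_normal, self.m_mut, self.m_null) < 1:
            raise ValueError("cell and site counts must be >= 1")
        if self.mean_coverage <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")
        lo, hi = self.ccf_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("ccf_range must satisfy 0 <= low <= high <= 1")
        if self.ccf_per_site is not None and len(self.ccf_per_site) != self.m_mut:
            raise ValueError("ccf_per_site must have length m_mut")


@dataclass
class TruthTable:
    """Ground truth: which (site, cell) pairs truly carry the mutation."""

    mutated: Set[Tuple[VariantSite, str]]
    tumor_cells: Set[str]
    site_ccf: Dict[VariantSite, float]
    all_cells: Set[str] = field(default_factory=set)


@dataclass
class SimulatedDataset:
    cells: List[SampleVariantTable]
    bc_sites: List[VariantSite]
    germline: SampleVariantTable
    truth: TruthTable
    config: SimulationConfig


def _nb_depth(rng, mean: float, dispersion: float, size) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _random_sites(rng, chrom: str, count: int, spacing: int = 1000) -> List[VariantSite]:
    refs = rng.integers(0, 4, size=count)
    alt_off = rng.integers(1, 4, size=count)  # guarantees alt != ref
    return [
        VariantSite(chrom, spacing * (i + 1), _BASES[refs[i]], _BASES[(refs[i] + alt_off[i]) % 4])
        for i in range(count)
    ]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate cell variant tables, a bulk mutation site list, a germline
    table, and the truth table, all determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_cells = config.n_tumor + config.n_normal
    cell_ids = [f"tumor_{i + 1:03d}" for i in range(config.n_tumor)] + [
        f"normal_{i + 1:03d}" for i in range(config.n_normal)
    ]
    tumor_mask = np.array([cid.startswith("tumor") for cid in cell_ids])

    mut_sites = _random_sites(rng, "1", config.m_mut)
    null_sites = _random_sites(rng, "2", config.m_null)
    sites = mut_sites + null_sites
    n_sites = len(sites)

    if config.ccf_per_site is not None:
        ccf = np.asarray(config.ccf_per_site, dtype=float)
    else:
        ccf = rng.uniform(config.ccf_range[0], config.ccf_range[1], size=config.m_mut)

    # Which tumor cells carry which mutation (normal cells never do).
    carrier = np.zeros((config.m_mut, n_cells), dtype=bool)
    carrier[:, tumor_mask] = rng.random((config.m_mut, tumor_mask.sum())) < ccf[:, None]

    depth = _nb_depth(rng, config.mean_coverage, config.coverage_dispersion, (n_sites, n_cells))

    # Pre-draw every stochastic layer on the full grid; masks select which
    # layer applies to each entry, so the draw order is seed-stable.
    mono = rng.random((n_sites, n_cells)) < config.p_mono
    mono_alt_allele = rng.random((n_sites, n_cells)) < 0.5
    artifact = rng.random((n_sites, n_cells)) < config.p_artifact
    artifact_frac = rng.uniform(0.9, 1.0, (n_sites, n_cells))
    p_het = 0.5 * (1.0 - config.error_rate) + 0.5 * (config.error_rate / 3.0)
    het_alt = rng.binomial(depth, p_het)
    err_alt = rng.binomial(depth, config.error_rate)
    art_alt = rng.binomial(depth, artifact_frac)
    qual = np.clip(rng.normal(config.qual_mean, 2.0, (n_sites, n_cells)), 0.0, None)

    mutated_full = np.zeros((n_sites, n_cells), dtype=bool)
    mutated_full[: config.m_mut] = carrier

    alt = np.where(artifact, art_alt, err_alt)  # null-like layer
    alt = np.where(mutated_full & ~mono, het_alt, alt)
    # Monoallelic expression at a truly mutated entry: every read comes from
    # one randomly chosen allele, so the VAF is exactly 0 or 1.
    alt = np.where(mutated_full & mono, np.where(mono_alt_allele, depth, 0), alt)
    alt = np.minimum(alt, depth)

    cells = []
    for j, cid in enumerate(cell_ids):
        table = SampleVariantTable(sample_id=cid, role=SampleRole.CELL)
        for i in range(n_sites):
            if depth[i, j] == 0:
                continue
            table.add(
                CellSiteObservation(
                    site=sites[i],
                    sample_id=cid,
                    total_reads=int(depth[i, j]),
                    alt_reads=int(alt[i, j]),
                    mean_qual=float(qual[i, j]),
                )
            )
        cells.append(table)

    g_depth = _nb_depth(rng, config.mean_coverage, config.coverage_dispersion, n_sites)
    g_qual = np.clip(rng.normal(config.qual_mean, 2.0, n_sites), 0.0, None)
    germline = SampleVariantTable(sample_id="germline", role=SampleRole.BULK_GERMLINE)
    for i, site in enumerate(sites):
        if g_depth[i] == 0:
            continue
        germline.add(
            CellSiteObservation(
                site=site,
                sample_id="germline",
                total_reads=int(g_depth[i]),
                alt_reads=0,
                mean_qual=float(g_qual[i]),
            )
        )

    truth = TruthTable(
        mutated={
            (mut_sites[i], cell_ids[j])
            for i, j in zip(*np.nonzero(carrier))
        },
        tumor_cells={cid for cid in cell_ids if cid.startswith("tumor")},
        site_ccf={mut_sites[i]: float(ccf[i]) for i in range(config.m_mut)},
        all_cells=set(cell_ids),
    )
    return SimulatedDataset(
        cells=cells, bc_sites=mut_sites, germline=germline, truth=truth, config=config
    )


@dataclass(frozen=True)
class EvalMetrics:
    """Truth-based evaluation of a call set at one fdr2d threshold."""

    fdp: float
    sensitivity: float
    n_significant: int
    n_true: int
    n_false: int
    tumor_calls: int
    normal_calls: int


def evaluate_calls(
    calls: Sequence[CellMutationCall], truth: TruthTable, threshold: float = 0.2
) -> EvalMetrics:
    """False discovery proportion and sensitivity of significant calls.

    FDP = false significant calls / significant calls (0 when none);
    sensitivity = true significant calls / truly mutated pairs with coverage.
    """
    known_sites = set(truth.site_ccf)
    covered_truth = 0
    n_sig = n_true = tumor_calls = normal_calls = 0
    for call in calls:
        if call.site not in known_sites:
            raise ValueError(f"call at {call.site} does not match any truth site")
        if truth.all_cells and call.cell_id not in truth.all_cells:
            raise ValueError(f"call for unknown cell {call.cell_id!r}")
        pair = (call.site, call.cell_id)
        if pair in truth.mutated:
            covered_truth += 1
        if call.fdr2d < threshold:
            n_sig += 1
            if pair in truth.mutated:
                n_true += 1
            if call.cell_id in truth.tumor_cells:
                tumor_calls += 1
            else:
                normal_calls += 1
    n_false = n_sig - n_true
    return EvalMetrics(
        fdp=n_false / n_sig if n_sig else 0.0,
        sensitivity=n_true / covered_truth if covered_truth else 0.0,
        n_significant=n_sig,
        n_true=n_true,
        n_false=n_false,
        tumor_calls=tumor_calls,
        normal_calls=normal_calls,
    )


@dataclass
class StudyResult:
    """Replicate-level metrics and their Monte-Carlo summary."""

    per_replicate: pd.DataFrame
    mean_fdp: float
    se_fdp: float
    mean_sensitivity: float
    se_sensitivity: float


def replicate_study(
    config: SimulationConfig,
    n_reps: int,
    base_seed: int,
    threshold: float = 0.2,
    **pipeline_kwargs,
) -> StudyResult:
    """Run simulate -> filter -> fdr2d -> call -> evaluate over seeded replicates.

    Replicate i uses seed ``base_seed + i``; the simulation and the null
    sampling draw from independent streams spawned from that seed.
    """
    from .pipeline import call_pipeline  # local import to avoid a cycle

    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rows = []
    for i in range(n_reps):
        rep_seed = base_seed + i
        sim_seed, null_seed = (
            int(s) % (2**31) for s in np.random.SeedSequence(rep_seed).generate_state(2)
        )
        sim = simulate_dataset(replace(config, seed=sim_seed))
        result = call_pipeline(
            sim.cells, sim.bc_sites, sim.germline, seed=null_seed, **pipeline_kwargs
        )
        metrics = evaluate_calls(result.calls, sim.truth, threshold=threshold)
        rows.append(
            {
                "seed": rep_seed,
                "fdp": metrics.fdp,
                "sensitivity": metrics.sensitivity,
                "n_significant": metrics.n_significant,
                "normal_calls": metrics.normal_calls,
            }
        )
        logger.info("replicate %d: FDP=%.3f sensitivity=%.3f", i, metrics.fdp, metrics.sensitivity)
    df = pd.DataFrame(rows)
    return StudyResult(
        per_replicate=df,
        mean_fdp=float(df["fdp"].mean()),
        se_fdp=float(df["fdp"].std(ddof=1) / np.sqrt(n_reps)),
        mean_sensitivity=float(df["sensitivity"].mean()),
        se_sensitivity=float(df["sensitivity"].std(ddof=1) / np.sqrt(n_reps)),
    )


def write_dataset(sim: SimulatedDataset, outdir) -> None:
    """Write a simulated dataset as plain TSVs (cells/, sites, germline, truth)."""
    outdir = Path(outdir)
    (outdir / "cells").mkdir(parents=True, exist_ok=True)
    for table in sim.cells:
        vio.write_table(table, outdir / "cells" / f"{table.sample_id}.tsv")
    vio.write_table(sim.germline, outdir / "germline.tsv")
    with open(outdir / "sites.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tccf\n")
        for site in sim.bc_sites:
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.alt}\t"
                f"{sim.truth.site_ccf[site]:.6g}\n"
            )
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tcell_id\n")
        for site, cell in sorted(sim.truth.mutated, key=lambda p: (p[0], p[1])):
            fh.write(f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.alt}\t{cell}\n")
    with open(outdir / "cell_groups.tsv", "w") as fh:
        fh.write("cell_id\tgroup\n")
        for table in sim.cells:
            group = "tumor" if table.sample_id in sim.truth.tumor_cells else "normal"
            fh.write(f"{table.sample_id}\t{group}\n")


def read_dataset(indir) -> Tuple[List[SampleVariantTable], List[VariantSite], SampleVariantTable, TruthTable]:
    """Reload a dataset written by :func:`write_dataset`."""
    indir = Path(indir)
    cells = [vio.read_table(p) for p in sorted((indir / "cells").glob("*.tsv"))]
    germline = vio.read_table(indir / "germline.tsv")
    sites_df = pd.read_csv(indir / "sites.tsv", sep="\t", dtype={"chrom": str})
    bc_sites = [
        VariantSite(r.chrom, int(r.pos), r.ref, r.alt) for r in sites_df.itertuples()
    ]
    site_ccf = {
        VariantSite(r.chrom, int(r.pos), r.ref, r.alt): float(getattr(r, "ccf", np.nan))
        for r in sites_df.itertuples()
    }
    truth_df = pd.read_csv(indir / "truth.tsv", sep="\t", dtype={"chrom": str, "cell_id": str})
    mutated = {
        (VariantSite(r.chrom, int(r.pos), r.ref, r.alt), r.cell_id)
        for r in truth_df.itertuples()
    }
    groups = pd.read_csv(indir / "cell_groups.tsv", sep="\t", dtype=str)
    tumor_cells = set(groups.loc[groups["group"] == "tumor", "cell_id"])
    truth = TruthTable(
        mutated=mutated,
        tumor_cells=tumor_cells,
        site_ccf=site_ccf,
        all_cells=set(groups["cell_id"]),
    )
    return cells, bc_sites, germline, truth
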