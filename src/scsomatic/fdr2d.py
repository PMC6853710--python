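"""Two-dimensional local false discovery rate over (coverage, VAF).

The statistic for each cell at each candidate somatic site is the pair
z = (z1, z2) = (total reads, variant-allele frequency).  The local fdr at z is

    fdr2d(z) = pi0 * f0(z) / f(z),

with f0 the density of z under no mutation and f the marginal density of the
observed statistics.  f0 is an *empirical* null: K Monte-Carlo replicate
matrices are drawn from non-candidate ("null pool") sites with germline
VAF = 0, so the null captures the real noise structure of single-cell RNA-seq
(sequencing error at low VAF, monoallelic-expression artifacts near VAF = 1).

Rather than smoothing two densities and dividing, a single smoothing step
estimates the success proportion

    r(z) = K f0(z) / (f(z) + K f0(z)),

treating null points as successes and observed points as failures, and then

    fdr2d(z) = pi0 * r(z) / (K (1 - r(z))),

clipped to [0, 1].  pi0 defaults to its conservative maximum, 1.

r(z) is estimated on a grid as a kernel-weighted binomial proportion with a
Gaussian product kernel and a 0.5 pseudo-count, which keeps r strictly inside
(0, 1).  Coverage is smoothed on the log10 scale because it spans orders of
magnitude; VAF is smoothed untransformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .variants import SampleVariantTable, VariantSite

logger = logging.getLogger(__name__)

__all__ = [
    "ObservedStatMatrix",
    "NullSampleSet",
    "Fdr2dSurface",
    "CellMutationCall",
    "CallSummary",
    "build_observed_matrix",
    "sample_null",
    "transform_stats",
    "estimate_r",
    "compute_fdr2d",
    "evaluate_surface",
    "point_statistic",
    "null_fdr_values",
    "fdr_to_pvalue",
    "call_mutations",
    "summarize_calls",
]

DEFAULT_K = 100
DEFAULT_THRESHOLDS = (0.05, 0.2)  # (strict, standard) tiers, strict-< comparison


@dataclass
class ObservedStatMatrix:
    """The m x n matrix Z of (z1, z2) statistic pairs with missingness.

    Rows are candidate somatic (bc-mutation) sites, columns are cells.  An
    entry is missing (NaN) when the cell has no reads at the site; a covered
    site with zero alt reads is the data point (z1, 0.0), not missing.
    """

    sites: List[VariantSite]
    cells: List[str]
    z1: np.ndarray  # (m, n) float, NaN = missing
    alt: np.ndarray  # (m, n) float, NaN = missing
    # Dequantized copies used for kernel smoothing and scoring (see
    # dequantize_counts); reported statistics always come from z1/alt.
    z1_smooth: Optional[np.ndarray] = None
    alt_smooth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        m, n = len(self.sites), len(self.cells)
        if self.z1.shape != (m, n) or self.alt.shape != (m, n):
            raise ValueError("matrix dimensions must equal |sites| x |cells|")

    @property
    def smooth_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        if self.z1_smooth is None:
            return self.z1, self.alt
        return self.z1_smooth, self.alt_smooth

    @property
    def mask(self) -> np.ndarray:
        """Boolean (m, n) array, True where an entry is present."""
        return ~np.isnan(self.z1)

    @property
    def z2(self) -> np.ndarray:
        """VAF matrix (NaN where missing)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.alt / self.z1

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())


@dataclass
class NullSampleSet:
    """K replicate m x n matrices drawn from the null site pool.

    Each replicate draws m sites (without replacement when the pool allows,
    with replacement otherwise) and takes their full per-cell statistic
    vectors, preserving cross-cell dependence within a site.  The seed fully
    determines every draw.
    """

    z1: np.ndarray  # (K, m, n)
    alt: np.ndarray  # (K, m, n)
    cells: List[str]
    K: int
    seed: int
    pool_size: int
    with_replacement: bool
    site_indices: np.ndarray = field(repr=False, default=None)  # (K, m) into the pool
    z1_smooth: Optional[np.ndarray] = None
    alt_smooth: Optional[np.ndarray] = None

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.z1)

    @property
    def smooth_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        if self.z1_smooth is None:
            return self.z1, self.alt
        return self.z1_smooth, self.alt_smooth

    @property
    def n_points(self) -> int:
        return int(self.mask.sum())


@dataclass
class Fdr2dSurface:
    """Gridded estimate of r(z) and fdr2d(z) over transformed statistics.

    ``raw_grid`` keeps the unclipped ratio pi0*r/(K(1-r)); it is what ranks
    points for p-values, since clipping at 1 ties together everything in the
    deep-null region.  ``fdr_grid`` is the clipped, reportable fdr2d.
    """

    t1_breaks: np.ndarray
    t2_breaks: np.ndarray
    r_grid: np.ndarray
    raw_grid: np.ndarray
    fdr_grid: np.ndarray
    K: int
    pi0: float
    bandwidth: Tuple[float, float]
    n_success: int
    n_failure: int
    # Kernel-weight sums per node, kept so data points can be scored with
    # their own weight removed (leave-self-out; see point_statistic).
    succ_grid: Optional[np.ndarray] = None
    total_grid: Optional[np.ndarray] = None


@dataclass(frozen=True)
class CellMutationCall:
    """One (site, cell) pair with its fdr2d value, p-value and tier."""

    site: VariantSite
    cell_id: str
    z1: int
    alt_reads: int
    z2: float
    fdr2d: float
    p_value: float
    tier: str  # strict | standard | nonsignificant


def _extract_entries(
    tables: Sequence[SampleVariantTable], sites: Sequence[VariantSite]
) -> Tuple[np.ndarray, np.ndarray]:
    m, n = len(sites), len(tables)
    z1 = np.full((m, n), np.nan)
    alt = np.full((m, n), np.nan)
    for j, table in enumerate(tables):
        for i, site in enumerate(sites):
            obs = table.get(site)
            if obs is not None and obs.total_reads > 0:
                z1[i, j] = obs.total_reads
                alt[i, j] = obs.alt_reads
    return z1, alt


def dequantize_counts(z1: np.ndarray, alt: np.ndarray, seed: int):
    """Continuity correction for integer read counts.

    Kernel smoothing and rank-based p-values behave best on continuous data,
    but read counts are integers: identical (total, alt) pairs pile up into
    atoms.  A seeded uniform jitter of +/- half a read spreads each atom over
    its unit cell while preserving counts' information; the same underlying
    entry always receives the same jitter, so resampled copies of a site
    remain coincident.  Returns jittered (z1, alt) with z1 >= 1 and
    0 <= alt <= z1; NaN (missing) entries stay NaN.
    """
    rng = np.random.default_rng(seed)
    u1 = rng.uniform(0.0, 1.0, z1.shape)
    u2 = rng.uniform(0.0, 1.0, z1.shape)
    # Spread each count upward over its unit cell: clipping a symmetric
    # jitter at the boundaries would pile alt = 0 (or alt = z1) back into an
    # atom, defeating the correction.
    z1j = z1 + u1
    altj = alt + u2 * np.minimum(1.0, z1j - alt)
    nan = np.isnan(z1)
    return np.where(nan, np.nan, z1j), np.where(nan, np.nan, altj)


def build_observed_matrix(
    cells: Sequence[SampleVariantTable],
    bc_sites: Sequence[VariantSite],
    jitter_seed: Optional[int] = None,
) -> ObservedStatMatrix:
    """Assemble the observed statistic matrix over bc-mutation sites x cells.

    With ``jitter_seed`` the matrix also carries dequantized copies of the
    counts for smoothing (see :func:`dequantize_counts`).
    """
    if not bc_sites:
        raise ValueError("bc_sites must be non-empty")
    if not cells:
        raise ValueError("at least one cell table is required")
    z1, alt = _extract_entries(cells, bc_sites)
    z1s = alts = None
    if jitter_seed is not None:
        z1s, alts = dequantize_counts(z1, alt, jitter_seed)
    matrix = ObservedStatMatrix(
        sites=list(bc_sites), cells=[t.sample_id for t in cells],
        z1=z1, alt=alt, z1_smooth=z1s, alt_smooth=alts,
    )
    if matrix.n_observed == 0:
        raise ValueError("no bc-mutation site is covered in any cell")
    return matrix


def sample_null(
    pool: Sequence[VariantSite],
    cells: Sequence[SampleVariantTable],
    m: int,
    K: int = DEFAULT_K,
    seed: int = 0,
    jitter_seed: Optional[int] = None,
) -> NullSampleSet:
    """Draw K replicate null matrices of m sites each from the pool.

    The pool's per-cell count matrix is built once and replicates index into
    it, so a site drawn into several replicates carries identical entries
    (and, with ``jitter_seed``, identical dequantized entries).
    """
    pool = list(pool)
    if not pool:
        raise ValueError("null pool is empty")
    if m < 1 or K < 1:
        raise ValueError("m and K must be >= 1")
    if m == 1:
        logger.warning("m = 1 bc-mutation site: null replicates of size 1 give a noisy surface")
    pool_z1, pool_alt = _extract_entries(cells, pool)
    pool_z1s = pool_alts = None
    if jitter_seed is not None:
        pool_z1s, pool_alts = dequantize_counts(pool_z1, pool_alt, jitter_seed)
    replace = len(pool) < m
    if replace:
        logger.warning(
            "pool size %d < m = %d: sampling with replacement", len(pool), m
        )
    rng = np.random.default_rng(seed)
    indices = np.stack(
        [rng.choice(len(pool), size=m, replace=replace) for _ in range(K)]
    )
    return NullSampleSet(
        z1=pool_z1[indices],
        alt=pool_alt[indices],
        cells=[t.sample_id for t in cells],
        K=K,
        seed=seed,
        pool_size=len(pool),
        with_replacement=replace,
        site_indices=indices,
        z1_smooth=None if pool_z1s is None else pool_z1s[indices],
        alt_smooth=None if pool_alts is None else pool_alts[indices],
    )


def transform_stats(z1, z2):
    """Map (total reads, VAF) to the smoothing scale (log10 reads, VAF).

    The inverse mapping is (10**t1, t2).  z1 must be >= 1: zero-coverage
    entries are marked missing upstream, so z1 = 0 here signals a pipeline
    bug and raises.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if np.any(z1 < 1):
        raise ValueError("z1 < 1 reached transform_stats; zero-coverage entries must be missing")
    if np.any((z2 < 0) | (z2 > 1)):
        raise ValueError("z2 must lie in [0, 1]")
    return np.log10(z1), z2


def _silverman(x: np.ndarray) -> float:
    """Silverman-type per-axis bandwidth for 2D kernel smoothing."""
    n = x.size
    sd = float(np.std(x))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = (q75 - q25) / 1.34
    sigma = min(sd, iqr) if iqr > 0 else sd
    if sigma <= 0:
        sigma = max(abs(float(np.mean(x))), 1.0) * 0.1
    return float(sigma * n ** (-1.0 / 6.0))


def _points(z1: np.ndarray, alt: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    mask = ~np.isnan(z1)
    z1v = z1[mask]
    z2v = alt[mask] / z1v
    return transform_stats(z1v, z2v)


def _node_weights(t1_breaks, t2_breaks, h1, h2, t1_pts, t2_pts) -> np.ndarray:
    """Summed Gaussian product-kernel weights of a point set at grid nodes.

    The kernel is separable, so the (g1 x g2) weight grid is the matrix
    product (A1 @ A2.T) with A1[i, p] = phi((t1_i - t1_p)/h1) etc.
    """
    A1 = np.exp(-0.5 * ((t1_breaks[:, None] - t1_pts[None, :]) / h1) ** 2)
    A2 = np.exp(-0.5 * ((t2_breaks[:, None] - t2_pts[None, :]) / h2) ** 2)
    return A1 @ A2.T


def estimate_r(
    observed: ObservedStatMatrix,
    nulls: NullSampleSet,
    grid_size: Tuple[int, int] = (50, 50),
    bandwidth: Optional[Tuple[float, float]] = None,
    pi0: float = 1.0,
) -> Fdr2dSurface:
    """Estimate the smoothed success proportion r(z) and the fdr2d surface.

    Null points are successes, observed points failures.  At each grid node,
    r = (sum of success kernel weights + 0.5) / (sum of all weights + 1.0);
    the 0.5 pseudo-count keeps r strictly within (0, 1).  The default
    bandwidth is Silverman's rule per axis on the pooled points.
    """
    if observed.cells != nulls.cells:
        raise ValueError("observed matrix and null set must share the cell ordering")
    oz1, oalt = observed.smooth_arrays
    nz1, nalt = nulls.smooth_arrays
    ft1, ft2 = _points(oz1, oalt)  # failures
    st1, st2 = _points(nz1.reshape(-1, nz1.shape[-1]),
                       nalt.reshape(-1, nalt.shape[-1]))  # successes
    n_fail, n_succ = ft1.size, st1.size
    if n_fail < 10:
        raise ValueError(f"only {n_fail} observed points; at least 10 required")
    if n_fail < 100:
        logger.warning("only %d observed points; surface will be noisy", n_fail)

    t1 = np.concatenate([st1, ft1])
    t2 = np.concatenate([st2, ft2])
    if bandwidth is None:
        bandwidth = (_silverman(t1), _silverman(t2))
    h1, h2 = float(bandwidth[0]), float(bandwidth[1])
    if h1 <= 0 or h2 <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")

    g1, g2 = grid_size
    lo1, hi1 = float(t1.min()), float(t1.max())
    lo2, hi2 = float(t2.min()), float(t2.max())
    if lo1 == hi1:
        lo1, hi1 = lo1 - 0.5, hi1 + 0.5
    if lo2 == hi2:
        lo2, hi2 = lo2 - 0.5, hi2 + 0.5
    t1_breaks = np.linspace(lo1, hi1, g1)
    t2_breaks = np.linspace(lo2, hi2, g2)

    # The failure set is small, so compute all-points and failure sums and
    # take the success sum as their difference.
    total_w = _node_weights(t1_breaks, t2_breaks, h1, h2, t1, t2)
    fail_w = _node_weights(t1_breaks, t2_breaks, h1, h2, ft1, ft2)
    succ_w = total_w - fail_w

    r_grid = (succ_w + 0.5) / (total_w + 1.0)
    raw_grid = pi0 * r_grid / (nulls.K * (1.0 - r_grid))
    fdr_grid = np.clip(raw_grid, 0.0, 1.0)
    return Fdr2dSurface(
        t1_breaks=t1_breaks,
        t2_breaks=t2_breaks,
        r_grid=r_grid,
        raw_grid=raw_grid,
        fdr_grid=fdr_grid,
        K=nulls.K,
        pi0=pi0,
        bandwidth=(h1, h2),
        n_success=n_succ,
        n_failure=n_fail,
        succ_grid=succ_w,
        total_grid=total_w,
    )


def compute_fdr2d(r, K: int, pi0: float = 1.0):
    """fdr2d from the success proportion: min(1, pi0 * r / (K * (1 - r))).

    When estimated null and marginal densities coincide, r = K/(K+1) and the
    returned fdr2d equals pi0 (= 1 at the conservative default).
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any((r_arr <= 0) | (r_arr >= 1)):
        raise ValueError("r must lie strictly within (0, 1)")
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must lie in (0, 1]")
    out = np.minimum(1.0, pi0 * r_arr / (K * (1.0 - r_arr)))
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def evaluate_surface(surface: Fdr2dSurface, t1, t2, which: str = "fdr"):
    """Bilinear interpolation of a surface grid at transformed points.

    Points outside the grid are clamped to the nearest edge, so the result
    always lies within the grid's value range.
    """
    grid = {"fdr": surface.fdr_grid, "raw": surface.raw_grid, "r": surface.r_grid}[which]
    return _interp_grid(surface, grid, t1, t2)


def point_statistic(surface: Fdr2dSurface, t1, t2, kind: str, multiplicity=1.0):
    """Unclipped fdr statistic of a *data* point, with its own weight removed.

    A point that contributed to the smoothing biases r at its own location:
    a failure (observed) point pulls r down, a success (null) point pulls it
    up, which would make observed and null statistics non-exchangeable under
    the null and bias the empirical p-values.  Scoring each data point with
    its self kernel-weight (per copy) subtracted from its own side removes
    that bias.  ``multiplicity`` is how many copies of the point entered the
    smoothing — a pool site drawn into several null replicates contributes
    one copy per draw.  ``kind`` is 'failure' for observed points and
    'success' for null points; fresh points not in the smoothing are scored
    by :func:`evaluate_surface` instead.
    """
    if kind == "failure":
        fail_mult, succ_mult = multiplicity, 0.0
    elif kind == "success":
        fail_mult, succ_mult = 0.0, multiplicity
    else:
        raise ValueError(f"kind must be 'failure' or 'success', got {kind!r}")
    if surface.succ_grid is None or surface.total_grid is None:
        raise ValueError("surface lacks weight grids; rebuild with estimate_r")
    return _score_points(
        surface, surface.succ_grid, t1, t2, fail_mult=fail_mult, succ_mult=succ_mult
    )


def _score_points(surface: Fdr2dSurface, succ_grid, t1, t2, fail_mult, succ_mult):
    succ = _interp_grid(surface, succ_grid, t1, t2)
    total = _interp_grid(surface, surface.total_grid, t1, t2)
    fail = np.maximum(total - succ, 0.0)
    self_w = _self_weight(surface, t1, t2)
    fail = np.maximum(fail - np.asarray(fail_mult, dtype=float) * self_w, 0.0)
    succ = np.maximum(succ - np.asarray(succ_mult, dtype=float) * self_w, 0.0)
    # Kernel sums decay to numerical dust far from any data; flush them to an
    # exact zero so points in empty regions tie exactly (the pseudo-count
    # then gives them all the same saturated statistic).
    fail = np.where(fail < 1e-12, 0.0, fail)
    succ = np.where(succ < 1e-12, 0.0, succ)
    r = (succ + 0.5) / (succ + fail + 1.0)
    return surface.pi0 * r / (surface.K * (1.0 - r))


def _self_weight(surface: Fdr2dSurface, t1, t2):
    """Exact contribution of one copy of a point to its own interpolated sum.

    A point at x adds kernel(g - x) to each grid node g; bilinear
    interpolation back at x therefore sees sum_i w_i(x) * kernel(g_i - x)
    over the four bracketing nodes, not 1.
    """
    h1, h2 = surface.bandwidth
    t1c = np.clip(np.asarray(t1, dtype=float), surface.t1_breaks[0], surface.t1_breaks[-1])
    t2c = np.clip(np.asarray(t2, dtype=float), surface.t2_breaks[0], surface.t2_breaks[-1])

    def axis_terms(breaks, x, h):
        hi = np.clip(np.searchsorted(breaks, x), 1, breaks.size - 1)
        lo = hi - 1
        span = breaks[hi] - breaks[lo]
        frac = np.where(span > 0, (x - breaks[lo]) / np.where(span > 0, span, 1.0), 0.0)
        k_lo = np.exp(-0.5 * ((breaks[lo] - x) / h) ** 2)
        k_hi = np.exp(-0.5 * ((breaks[hi] - x) / h) ** 2)
        return (1.0 - frac) * k_lo + frac * k_hi

    return axis_terms(surface.t1_breaks, t1c, h1) * axis_terms(surface.t2_breaks, t2c, h2)


def _interp_grid(surface: Fdr2dSurface, grid: np.ndarray, t1, t2):
    interp = RegularGridInterpolator(
        (surface.t1_breaks, surface.t2_breaks), grid, method="linear"
    )
    t1c = np.clip(np.asarray(t1, dtype=float), surface.t1_breaks[0], surface.t1_breaks[-1])
    t2c = np.clip(np.asarray(t2, dtype=float), surface.t2_breaks[0], surface.t2_breaks[-1])
    scalar = t1c.ndim == 0
    out = interp(np.stack([np.atleast_1d(t1c), np.atleast_1d(t2c)], axis=-1))
    return float(out[0]) if scalar else out


def null_fdr_values(nulls: NullSampleSet, surface: Fdr2dSurface) -> np.ndarray:
    """Sorted leave-self-out fdr statistics of every pooled null point.

    Each point is scored with all copies of itself (a pool site drawn into
    several replicates contributes one copy per draw) removed from the
    success weight, mirroring how observed points are scored with their own
    failure weight removed; under the global null the two statistics are
    then exchangeable and the empirical p-values calibrated.
    """
    if surface.succ_grid is None or surface.total_grid is None:
        raise ValueError("surface lacks weight grids; rebuild with estimate_r")
    nz1, nalt = nulls.smooth_arrays
    flat_z1 = nz1.reshape(-1, nz1.shape[-1])
    flat_alt = nalt.reshape(-1, nalt.shape[-1])
    mask = ~np.isnan(flat_z1)
    if nulls.site_indices is not None:
        c_total = np.bincount(nulls.site_indices.ravel(), minlength=nulls.pool_size)
        mult_rows = c_total[nulls.site_indices.ravel()]
        mult = np.broadcast_to(mult_rows[:, None], flat_z1.shape)[mask]
    else:
        mult = 1.0
    z1v = flat_z1[mask]
    st1, st2 = transform_stats(z1v, flat_alt[mask] / z1v)
    return np.sort(point_statistic(surface, st1, st2, "success", multiplicity=mult))


def fdr_to_pvalue(fdr_values, null_sorted: np.ndarray):
    """Empirical tail probability of the fdr statistic under the null.

    p(z) = (1 + #{null points with statistic <= statistic(z)}) / (1 + N).
    Ties count as extreme (<=), and the add-one correction keeps p > 0.  The
    result is monotone non-decreasing in the fdr statistic.
    """
    values = np.asarray(fdr_values, dtype=float)
    n = null_sorted.size
    counts = np.searchsorted(null_sorted, values, side="right")
    p = (1.0 + counts) / (1.0 + n)
    return float(p) if values.ndim == 0 else p


def _tier(fdr: float, thresholds: Tuple[float, float]) -> str:
    strict, standard = thresholds
    if fdr < strict:
        return "strict"
    if fdr < standard:
        return "standard"
    return "nonsignificant"


def call_mutations(
    observed: ObservedStatMatrix,
    surface: Fdr2dSurface,
    nulls,
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS,
) -> List[CellMutationCall]:
    """One call per non-missing observed entry, with fdr2d, p-value and tier.

    ``nulls`` is the NullSampleSet the surface was built from, or a
    pre-computed sorted array of null fdr statistics (as persisted by the
    staged CLI).  Observed entries are scored with the leave-self-out
    statistic (see :func:`point_statistic`), so reported fdr2d values and
    p-values share one statistic and p is monotone in fdr2d.  Every entry is
    returned, including nonsignificant ones, so downstream summaries can
    compute denominators.  Tiers use strict < comparisons against the
    (strict, standard) thresholds, default (0.05, 0.2).
    """
    strict, standard = thresholds
    if not (0 < strict < standard < 1):
        raise ValueError("thresholds must satisfy 0 < strict < standard < 1")
    mask = observed.mask
    rows, cols = np.nonzero(mask)
    z1v = observed.z1[rows, cols]
    altv = observed.alt[rows, cols]
    sz1, salt = observed.smooth_arrays
    sz1v = sz1[rows, cols]
    t1, t2 = transform_stats(sz1v, salt[rows, cols] / sz1v)
    raw = point_statistic(surface, t1, t2, kind="failure")
    fdr = np.clip(raw, 0.0, 1.0)
    if isinstance(nulls, NullSampleSet):
        null_sorted = null_fdr_values(nulls, surface)
    else:
        null_sorted = np.sort(np.asarray(nulls, dtype=float))
    pvals = fdr_to_pvalue(raw, null_sorted)
    calls = []
    for idx in range(rows.size):
        i, j = rows[idx], cols[idx]
        calls.append(
            CellMutationCall(
                site=observed.sites[i],
                cell_id=observed.cells[j],
                z1=int(z1v[idx]),
                alt_reads=int(altv[idx]),
                z2=float(altv[idx] / z1v[idx]),
                fdr2d=float(fdr[idx]),
                p_value=float(pvals[idx]),
                tier=_tier(float(fdr[idx]), thresholds),
            )
        )
    return calls


@dataclass(frozen=True)
class CallSummary:
    """Counts of significant cell-level mutations at a given fdr2d threshold."""

    n_significant: int
    n_sites: int
    cells_per_site: Optional[float]  # mean cells with a mutation per site, 2 dp
    per_site: dict
    per_cell: dict


def summarize_calls(calls: Iterable[CellMutationCall], threshold: float = 0.2) -> CallSummary:
    """Summarise significant calls: totals, distinct sites, and recurrence.

    ``cells_per_site`` is total significant calls / distinct mutation sites,
    rounded to 2 decimals; None when there are no significant calls.
    """
    per_site: dict = {}
    per_cell: dict = {}
    n = 0
    for call in calls:
        if call.fdr2d < threshold:
            n += 1
            per_site[call.site] = per_site.get(call.site, 0) + 1
            per_cell[call.cell_id] = per_cell.get(call.cell_id, 0) + 1
    n_sites = len(per_site)
    ratio = round(n / n_sites, 2) if n_sites else None
    return CallSummary(
        n_significant=n,
        n_sites=n_sites,
        cells_per_site=ratio,
        per_site=per_site,
        per_cell=per_cell,
    )
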