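"""The 2D local fdr estimator: surface, calls and p-values."""

import numpy as np
import pytest
import sympy

from scsomatic.fdr2d import (
    Fdr2dSurface,
    NullSampleSet,
    ObservedStatMatrix,
    build_observed_matrix,
    call_mutations,
    compute_fdr2d,
    estimate_r,
    evaluate_surface,
    fdr_to_pvalue,
    null_fdr_values,
    sample_null,
    summarize_calls,
    transform_stats,
)
from scsomatic.variants import (
    CellSiteObservation,
    SampleRole,
    SampleVariantTable,
    VariantSite,
)


def make_sites(n, chrom="1"):
    return [VariantSite(chrom, 1000 * (i + 1), "A", "C") for i in range(n)]


def matrix_from(z1, alt):
    z1 = np.asarray(z1, dtype=float)
    alt = np.asarray(alt, dtype=float)
    m, n = z1.shape
    return ObservedStatMatrix(make_sites(m), [f"c{j}" for j in range(n)], z1, alt)


def nulls_from(z1, alt, seed=0):
    z1 = np.asarray(z1, dtype=float)
    alt = np.asarray(alt, dtype=float)
    return NullSampleSet(
        z1=z1, alt=alt, cells=[f"c{j}" for j in range(z1.shape[-1])],
        K=z1.shape[0], seed=seed, pool_size=z1.shape[0] * z1.shape[1],
        with_replacement=False,
    )


def constant_surface(succ, total, K=1, pi0=1.0):
    """Flat weight grids with an effectively infinite bandwidth, so every
    point sees exactly (succ, total) and a self-weight of one."""
    t = np.array([0.0, 10.0])
    s = np.full((2, 2), float(succ))
    tot = np.full((2, 2), float(total))
    r = (s + 0.5) / (tot + 1.0)
    raw = pi0 * r / (K * (1 - r))
    return Fdr2dSurface(
        t1_breaks=t, t2_breaks=t, r_grid=r, raw_grid=raw,
        fdr_grid=np.clip(raw, 0, 1), K=K, pi0=pi0, bandwidth=(1e9, 1e9),
        n_success=int(succ), n_failure=int(total - succ),
        succ_grid=s, total_grid=tot,
    )


class TestTransform:
    @pytest.mark.parametrize(
        "z1,z2,expected",
        [((100, 0.5), None, (2.0, 0.5)), ((1, 0.0), None, (0.0, 0.0)),
         ((1000, 1.0), None, (3.0, 1.0))],
    )
    def test_log10_coverage_identity_vaf(self, z1, z2, expected):
        t1, t2 = transform_stats(*z1) if z2 is None else transform_stats(z1, z2)
        assert (float(t1), float(t2)) == expected

    def test_zero_coverage_reaching_transform_is_a_bug(self):
        with pytest.raises(ValueError, match="missing"):
            transform_stats(0, 0.0)


class TestComputeFdr2d:
    def test_equal_densities_give_pi0(self):
        K = 100
        assert compute_fdr2d(K / (K + 1), K, 1.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("r,K,expected", [(0.5, 100, 0.01), (0.99, 100, 0.99)])
    def test_hand_computed_values(self, r, K, expected):
        assert compute_fdr2d(r, K, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_algebraically_equals_density_ratio_form(self):
        # substituting r = K f0/(f + K f0) into pi0 r/(K(1-r)) recovers pi0 f0/f
        f0, f, K, pi0 = sympy.symbols("f0 f K pi0", positive=True)
        r = K * f0 / (f + K * f0)
        assert sympy.simplify(pi0 * r / (K * (1 - r)) - pi0 * f0 / f) == 0

    def test_strictly_increasing_in_r_before_clipping(self):
        rs = np.linspace(0.01, 0.9, 50)
        vals = compute_fdr2d(rs, 1000, 1.0)
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("bad_r", [0.0, 1.0, -0.2, 1.5])
    def test_domain_error_outside_open_interval(self, bad_r):
        with pytest.raises(ValueError):
            compute_fdr2d(bad_r, 100, 1.0)


class TestObservedMatrix:
    def cells_tables(self):
        sites = make_sites(2)
        t = []
        data = {
            "c0": {sites[0]: (20, 5), sites[1]: (12, 0)},
            "c1": {sites[0]: (8, 8)},  # site 1 uncovered in this cell
            "c2": {sites[0]: (30, 1), sites[1]: (40, 20)},
        }
        for cid, entries in data.items():
            table = SampleVariantTable(cid, SampleRole.CELL)
            for site, (tot, alt) in entries.items():
                table.add(CellSiteObservation(site, cid, tot, alt, 30.0))
            t.append(table)
        return t, sites

    def test_missingness_and_dimensions(self):
        tables, sites = self.cells_tables()
        m = build_observed_matrix(tables, sites)
        assert m.z1.shape == (2, 3)
        assert m.n_observed == 5

    def test_zero_alt_with_coverage_is_data_not_missing(self):
        tables, sites = self.cells_tables()
        m = build_observed_matrix(tables, sites)
        assert m.z1[1, 0] == 12 and m.z2[1, 0] == 0.0

    def test_all_missing_is_an_error(self):
        table = SampleVariantTable("c0", SampleRole.CELL)
        with pytest.raises(ValueError, match="covered"):
            build_observed_matrix([table], make_sites(2))


class TestSampleNull:
    def test_same_seed_reproduces_bitwise(self, small_sim):
        pool = small_sim.bc_sites + make_sites(30, chrom="9")
        a = sample_null(small_sim.bc_sites, small_sim.cells, m=5, K=10, seed=7)
        b = sample_null(small_sim.bc_sites, small_sim.cells, m=5, K=10, seed=7)
        assert np.array_equal(a.z1, b.z1, equal_nan=True)
        assert np.array_equal(a.site_indices, b.site_indices)

    def test_small_pool_falls_back_to_replacement(self, small_sim, caplog):
        nulls = sample_null(small_sim.bc_sites[:4], small_sim.cells, m=10, K=3, seed=1)
        assert nulls.with_replacement
        assert nulls.site_indices.shape == (3, 10)  # full replicate size kept

    def test_exhaustive_draw_covers_pool_exactly_once(self, small_sim):
        pool = small_sim.bc_sites
        nulls = sample_null(pool, small_sim.cells, m=len(pool), K=1, seed=3)
        assert sorted(nulls.site_indices[0].tolist()) == list(range(len(pool)))

    def test_empty_pool_rejected(self, small_sim):
        with pytest.raises(ValueError, match="empty"):
            sample_null([], small_sim.cells, m=5, K=2, seed=0)


class TestEstimateR:
    def test_narrow_bandwidth_recovers_per_node_proportions(self):
        # all points sit exactly on grid nodes; with bandwidth -> 0 the
        # smoothed proportion at a node must equal the shrunken bin count
        # (a + 0.5) / (a + b + 1) computed by direct enumeration
        obs = matrix_from(np.full((4, 3), 10.0), np.full((4, 3), 5.0))  # node (1, .5)
        nz1 = np.full((2, 4, 3), 10.0)
        nalt = np.full((2, 4, 3), 5.0)
        nz1[0, 0, :] = 1.0   # three points at node (0, 0)
        nalt[0, 0, :] = 0.0
        nz1[1, 3, :] = 100.0  # three points at node (2, 1)
        nalt[1, 3, :] = 100.0
        nulls = nulls_from(nz1, nalt)
        surf = estimate_r(obs, nulls, grid_size=(3, 3), bandwidth=(1e-4, 1e-4))
        assert np.array_equal(surf.t1_breaks, [0.0, 1.0, 2.0])
        # node (1, 0.5): successes 2*4*3-6 = 18, failures 12
        assert surf.r_grid[1, 1] == pytest.approx((18 + 0.5) / (18 + 12 + 1), abs=1e-9)
        # node (0, 0): 3 successes, 0 failures
        assert surf.r_grid[0, 0] == pytest.approx((3 + 0.5) / (3 + 0 + 1), abs=1e-9)
        # node (2, 1): 3 successes
        assert surf.r_grid[2, 2] == pytest.approx((3 + 0.5) / (3 + 0 + 1), abs=1e-9)

    def test_pure_null_surface_sits_near_K_over_K_plus_1(self, rng):
        K, m, n = 20, 30, 40
        z1 = 10 ** rng.uniform(0.1, 2, (K + 1, m, n))
        alt = rng.uniform(0, 1, (K + 1, m, n)) * z1
        obs = matrix_from(z1[0], alt[0])
        nulls = nulls_from(z1[1:], alt[1:])
        surf = estimate_r(obs, nulls)
        target = K / (K + 1)
        interior = surf.total_grid > 50  # nodes with real support
        se = np.sqrt(target * (1 - target) / surf.total_grid[interior])
        assert np.all(np.abs(surf.r_grid[interior] - target) < 3 * se + 0.01)

    def test_observed_outlier_pulls_r_below_null_level(self, rng):
        K, m, n = 20, 10, 5
        nz1 = np.full((K, m, n), 10.0)
        nalt = np.zeros((K, m, n))
        oz1 = np.full((m, n), 10.0)
        oalt = np.zeros((m, n))
        oz1[0, :] = 1000.0  # a clump of observed points far from the null cloud
        oalt[0, :] = 1000.0
        obs = matrix_from(oz1, oalt)
        surf = estimate_r(obs, nulls_from(nz1, nalt), bandwidth=(0.1, 0.1))
        # node nearest to (3, 1)
        i = np.argmin(np.abs(surf.t1_breaks - 3.0))
        j = np.argmin(np.abs(surf.t2_breaks - 1.0))
        assert surf.r_grid[i, j] < K / (K + 1)

    def test_too_few_observed_points_rejected(self):
        obs = matrix_from([[10.0, 10.0]], [[1.0, 0.0]])
        nulls = nulls_from(np.full((2, 1, 2), 10.0), np.zeros((2, 1, 2)))
        with pytest.raises(ValueError, match="observed points"):
            estimate_r(obs, nulls)

    def test_degenerate_bandwidth_rejected(self):
        obs = matrix_from(np.full((4, 3), 10.0), np.zeros((4, 3)))
        nulls = nulls_from(np.full((2, 4, 3), 10.0), np.zeros((2, 4, 3)))
        with pytest.raises(ValueError, match="bandwidth"):
            estimate_r(obs, nulls, bandwidth=(0.0, 0.1))

    def test_success_failure_bookkeeping_is_conserved(self, small_sim):
        from scsomatic.pipeline import call_pipeline

        res = call_pipeline(
            small_sim.cells, small_sim.bc_sites, small_sim.germline, seed=5
        )
        assert res.surface.n_failure == res.observed.n_observed
        assert res.surface.n_success == int(res.nulls.mask.sum())


class TestEvaluateSurface:
    def surface(self):
        grid = np.array([[0.1, 0.3], [0.1, 0.3]])
        return Fdr2dSurface(
            t1_breaks=np.array([0.0, 1.0]), t2_breaks=np.array([0.0, 1.0]),
            r_grid=grid, raw_grid=grid, fdr_grid=grid, K=100, pi0=1.0,
            bandwidth=(0.1, 0.1), n_success=0, n_failure=0,
        )

    def test_node_value_returned_exactly(self):
        assert evaluate_surface(self.surface(), 0.0, 0.0) == pytest.approx(0.1)

    def test_outside_points_clamp_to_edge(self):
        s = self.surface()
        assert evaluate_surface(s, -5.0, 2.0) == pytest.approx(0.3)
        assert evaluate_surface(s, 9.0, -1.0) == pytest.approx(0.1)

    def test_midpoint_is_bilinear_average(self):
        # grid values {0.1, 0.1} and {0.3, 0.3} along t2 -> midpoint 0.2
        assert evaluate_surface(self.surface(), 0.5, 0.5) == pytest.approx(0.2)


class TestPvalues:
    def test_minimum_attainable_p_is_one_over_n_plus_one(self):
        null_sorted = np.sort(np.array([0.5, 0.7, 0.9]))
        assert fdr_to_pvalue(0.1, null_sorted) == pytest.approx(1 / 4)

    def test_statistic_above_all_null_values_gives_p_one(self):
        null_sorted = np.sort(np.array([0.5, 0.7, 0.9]))
        assert fdr_to_pvalue(0.9, null_sorted) == 1.0
        assert fdr_to_pvalue(2.0, null_sorted) == 1.0

    def test_ties_count_as_extreme(self):
        null_sorted = np.array([0.5, 0.5, 0.7])
        assert fdr_to_pvalue(0.5, null_sorted) == pytest.approx(3 / 4)

    def test_p_monotone_in_fdr_across_calls(self, small_sim):
        from scsomatic.pipeline import call_pipeline

        res = call_pipeline(
            small_sim.cells, small_sim.bc_sites, small_sim.germline, seed=5
        )
        calls = sorted(res.calls, key=lambda c: c.fdr2d)
        for a, b in zip(calls, calls[1:]):
            if a.fdr2d < b.fdr2d < 1.0:
                assert a.p_value <= b.p_value + 1e-12


class TestCalls:
    def run_with_constant_fdr(self, succ, total):
        surf = constant_surface(succ, total)
        obs = matrix_from(np.full((2, 2), 10.0), np.full((2, 2), 5.0))
        return call_mutations(obs, surf, np.array([0.5, 1.0]), thresholds=(0.05, 0.2))

    def test_strict_tier_below_five_percent(self):
        # succ 0.5, total 26 -> (0.5+0.5)/(25.5-1+0.5) = 0.04
        calls = self.run_with_constant_fdr(succ=0.5, total=26.0)
        assert {c.tier for c in calls} == {"strict"}
        assert calls[0].fdr2d == pytest.approx(0.04)

    def test_exactly_point_two_is_nonsignificant(self):
        # thresholds use strict <, so a value at the boundary is not called
        from scsomatic.fdr2d import _tier

        assert _tier(0.2, (0.05, 0.2)) == "nonsignificant"
        assert _tier(0.19999999, (0.05, 0.2)) == "standard"
        assert _tier(0.05, (0.05, 0.2)) == "standard"
        assert _tier(0.04999999, (0.05, 0.2)) == "strict"

    def test_tier_counts_match_brute_force_re_evaluation(self, small_sim):
        from scsomatic.pipeline import call_pipeline

        res = call_pipeline(
            small_sim.cells, small_sim.bc_sites, small_sim.germline, seed=5
        )
        for call in res.calls:
            expected = (
                "strict" if call.fdr2d < 0.05
                else "standard" if call.fdr2d < 0.2
                else "nonsignificant"
            )
            assert call.tier == expected
        assert len(res.calls) == res.observed.n_observed


class TestSummary:
    def make_call(self, site, cell_id, fdr):
        return type(
            "C", (), {"site": site, "cell_id": cell_id, "fdr2d": fdr}
        )()

    def test_ten_calls_at_one_site(self):
        site = make_sites(1)[0]
        calls = [self.make_call(site, f"c{i}", 0.01) for i in range(10)]
        s = summarize_calls(calls, 0.2)
        assert (s.n_significant, s.n_sites, s.cells_per_site) == (10, 1, 10.0)

    def test_no_significant_calls_has_undefined_ratio(self):
        site = make_sites(1)[0]
        s = summarize_calls([self.make_call(site, "c0", 0.9)], 0.2)
        assert (s.n_significant, s.n_sites, s.cells_per_site) == (0, 0, None)
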