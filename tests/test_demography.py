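"""Mortality, fecundity, dispersal kernels, mating, recruitment, thinning."""
import numpy as np
import pytest
from scipy import integrate, stats

from pdgsim import demography as dem
from pdgsim.demography import (
    AllometryParams,
    DispersalKernel,
    Domain,
    Grid,
    MortalityMode,
    MortalityThresholds,
)


class TestMortality:
    def test_type_one_threshold(self):
        alive, cause = dem.mortality_check(44.0, 0.0)
        assert not alive[0] and cause[0] == dem.CauseOfDeath.TYPE_I

    def test_type_two_threshold(self):
        alive, cause = dem.mortality_check(100.0, 161.0)
        assert not alive[0] and cause[0] == dem.CauseOfDeath.TYPE_II

    def test_survivor(self):
        alive, cause = dem.mortality_check(100.0, 0.0)
        assert alive[0] and cause[0] == 0

    @pytest.mark.parametrize(
        "mode,expect_alive",
        [
            (MortalityMode.TYPE_I_ONLY, True),   # bb breach masked
            (MortalityMode.TYPE_II_ONLY, False),
            (MortalityMode.NONE, True),
            (MortalityMode.BOTH, False),
        ],
    )
    def test_mode_masking(self, mode, expect_alive):
        alive, _ = dem.mortality_check(100.0, 161.0, mode=mode)
        assert alive[0] == expect_alive

    def test_exactly_one_cause(self):
        """A doubly starved tree dies with one recorded cause."""
        alive, cause = dem.mortality_check(10.0, 500.0)
        assert not alive[0]
        assert cause[0] in (dem.CauseOfDeath.TYPE_I, dem.CauseOfDeath.TYPE_II)

    def test_no_budburst_never_type_two(self):
        alive, _ = dem.mortality_check(100.0, np.nan, mode=MortalityMode.TYPE_II_ONLY)
        assert alive[0]


class TestSeedProduction:
    def test_below_threshold(self):
        n, debit = dem.primary_seed_production(90.0, 10.0)
        assert n[0] == 0 and debit[0] == 0.0

    def test_reconstructed_formula(self):
        n, debit = dem.primary_seed_production(200.0, 10.0)
        assert n[0] == 222  # floor(0.05 * 200 * 10 / 0.45)
        assert debit[0] == pytest.approx(222 * 0.45 / 10.0)
        assert debit[0] <= 0.05 * 200.0 + 1e-9

    def test_zero_crown(self):
        n, debit = dem.primary_seed_production(200.0, 0.0)
        assert n[0] == 0


class TestEffectiveFecundity:
    def test_field_rates(self):
        # 1000 * (1 - 0.33) * 0.15 * 0.485
        assert dem.effective_fecundity(1000) == pytest.approx(48.7425)

    def test_edge_cases(self):
        assert dem.effective_fecundity(0) == 0.0
        assert dem.effective_fecundity(1000, r_es=1.0) == 0.0

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            dem.effective_fecundity(10, r_ss=1.2)


class TestDispersalKernel:
    def test_exponential_special_case(self):
        """At shape 1 the kernel is the pure exponential with delta = 2a."""
        k = DispersalKernel(mean_distance=40.0, shape=1.0)
        assert k.scale == pytest.approx(20.0)
        r = np.linspace(0, 50, 5)
        np.testing.assert_allclose(
            k.density(r), np.exp(-r / 20.0) / (2 * np.pi * 20.0**2), rtol=1e-12
        )

    @pytest.mark.parametrize("delta,shape", [(37.9, 0.97), (18.13, 0.31)])
    def test_sampled_mean_distance(self, delta, shape, rng):
        k = DispersalKernel(delta, shape)
        d = k.sample(200_000, rng)
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean() - delta) < 4 * se

    @pytest.mark.parametrize("delta,shape", [(37.9, 0.97), (18.13, 0.31), (40.0, 1.0)])
    def test_density_normalises_over_plane(self, delta, shape):
        k = DispersalKernel(delta, shape)
        total, _ = integrate.quad(lambda r: 2 * np.pi * r * k.density(r), 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            DispersalKernel(37.9, 0.97).density(-1.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            DispersalKernel(-1.0, 0.5)


class TestMating:
    def test_symmetric_candidates_get_equal_probability(self):
        """Two equidistant, equal-sized fathers split the pollen cloud 50/50."""
        x = np.array([100.0, 80.0, 120.0])
        y = np.array([500.0, 500.0, 500.0])
        dbh = np.array([20.0, 30.0, 30.0])
        probs = dem.pollen_contributions(0, x, y, dbh, DispersalKernel(37.9, 0.97))
        assert probs[0] == 0.0
        assert probs[1] == pytest.approx(probs[2])
        assert probs.sum() == pytest.approx(1.0)

    def test_diameter_fertility_power_law(self):
        x = np.array([100.0, 80.0, 120.0])
        y = np.array([500.0, 500.0, 500.0])
        dbh = np.array([20.0, 40.0, 20.0])
        probs = dem.pollen_contributions(0, x, y, dbh, DispersalKernel(37.9, 0.97))
        assert probs[1] / probs[2] == pytest.approx(2.0**0.82)

    def test_selfing_rate_recovered(self, rng):
        probs = np.array([0.0, 0.5, 0.5])
        fathers = dem.sample_fathers(0, probs, 20_000, 0.025, rng)
        frac = (fathers == 0).mean()
        se = np.sqrt(0.025 * 0.975 / 20_000)
        assert abs(frac - 0.025) < 3 * se

    def test_no_candidates_raises(self):
        x = np.array([100.0])
        y = np.array([500.0])
        with pytest.raises(ValueError):
            dem.pollen_contributions(0, x, y, np.array([20.0]), DispersalKernel(37.9, 0.97))


class TestSeedRain:
    def test_zero_fecundity(self):
        grid = Grid()
        tau = dem.seed_rain(100.0, 500.0, 0.0, grid, DispersalKernel(18.13, 0.31))
        assert np.all(tau == 0.0)

    def test_decays_with_distance(self):
        grid = Grid()
        kernel = DispersalKernel(18.13, 0.31)
        tau = dem.seed_rain(105.0, 505.0, 10.0, grid, kernel)
        cx, cy = grid.centers()
        r = np.hypot(cx - 105.0, cy - 505.0)
        near, far = np.argmin(r), np.argmax(r)
        assert tau[near] > tau[far]

    def test_discretised_mass_recovers_fecundity(self):
        """On a fine grid covering the kernel's mass, sum(tau * S) ~ F_j."""
        domain = Domain(x_extent=1200.0, y_extent=1200.0)
        grid = Grid(domain, cell_size=4.0)
        kernel = DispersalKernel(37.9, 0.97)
        tau = dem.seed_rain(600.0, 600.0, 5.0, grid, kernel)
        # mother at the domain centre: mirror images contribute ~nothing
        assert tau.sum() * grid.cell_area == pytest.approx(5.0, rel=0.02)

    def test_reflecting_border_conserves_mass(self):
        """A border mother keeps her seed rain inside the domain via mirrors."""
        domain = Domain(x_extent=1200.0, y_extent=1200.0)
        grid = Grid(domain, cell_size=4.0)
        kernel = DispersalKernel(37.9, 0.97)
        tau = dem.seed_rain(2.0, 600.0, 5.0, grid, kernel)
        assert tau.sum() * grid.cell_area == pytest.approx(5.0, rel=0.05)


class TestRecruitment:
    def test_poisson_mean(self, rng):
        counts = dem.recruit_counts(np.full(10_000, 3.0 / 400.0), 400.0, rng)
        se = np.sqrt(3.0 / counts.size)
        assert abs(counts.mean() - 3.0) < 3 * se

    def test_placement_uniform_when_mother_elsewhere(self, rng):
        grid = Grid()
        cell = 17
        xs = np.array([
            dem.place_recruit(cell, grid, rng, mother_xy=(190.0, 900.0))[0]
            for _ in range(5000)
        ])
        ox, _ = grid.cell_origin(cell)
        u = (xs - ox) / grid.cell_size
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_placement_near_in_cell_mother(self, rng):
        grid = Grid()
        mx, my = 110.0, 510.0
        cell = int(grid.cell_of(np.array([mx]), np.array([my]))[0])
        pts = np.array([
            dem.place_recruit(cell, grid, rng, mother_xy=(mx, my)) for _ in range(4000)
        ])
        assert pts[:, 0].mean() == pytest.approx(mx, abs=0.5)
        assert pts[:, 1].mean() == pytest.approx(my, abs=0.5)
        assert np.all(grid.domain.contains(pts[:, 0], pts[:, 1]))


class TestThinning:
    def test_coincident_crowns_one_survives(self, rng):
        keep = dem.crown_overlap_thinning(
            np.array([5.0, 5.0]), np.array([5.0, 5.0]), np.array([10.0, 10.0]), rng
        )
        assert keep.sum() == 1

    def test_disjoint_crowns_all_survive(self, rng):
        x = np.arange(10) * 50.0
        keep = dem.crown_overlap_thinning(x, np.zeros(10), np.full(10, 10.0), rng)
        assert keep.all()

    def test_survivors_pass_exhaustive_audit(self, rng):
        n = 300
        x = rng.uniform(0.0, 100.0, n)
        y = rng.uniform(0.0, 100.0, n)
        area = rng.uniform(5.0, 20.0, n)
        keep = dem.crown_overlap_thinning(x, y, area, rng)
        idx = np.flatnonzero(keep)
        radius = np.sqrt(area / np.pi)
        for a_i, i in enumerate(idx):
            for j in idx[a_i + 1:]:
                d = float(np.hypot(x[i] - x[j], y[i] - y[j]))
                inter = dem.circle_overlap_area(d, radius[i], radius[j])
                small = np.pi * min(radius[i], radius[j]) ** 2
                assert inter <= 0.3 * small + 1e-9

    def test_circle_overlap_against_monte_carlo(self, rng):
        r1, r2, d = 3.0, 2.0, 2.5
        pts = rng.uniform(-3.0, 3.0, (200_000, 2))
        inside = (np.hypot(pts[:, 0], pts[:, 1]) < r1) & (
            np.hypot(pts[:, 0] - d, pts[:, 1]) < r2
        )
        mc = inside.mean() * 36.0
        assert dem.circle_overlap_area(d, r1, r2) == pytest.approx(mc, rel=0.05)


class TestAllometryAndGrowth:
    def test_zero_carbon_no_growth(self):
        assert dem.dbh_growth(13.8, 9.0, 0.0) == pytest.approx(13.8)

    def test_growth_positive_and_concave(self):
        d1 = dem.dbh_growth(13.8, 9.0, 5000.0) - 13.8
        d2 = dem.dbh_growth(13.8, 9.0, 10_000.0) - 13.8
        assert d1 > 0
        assert d2 < 2 * d1

    def test_recruit_scale_allometries(self):
        allom = AllometryParams()
        assert dem.height_from_dbh(13.8, allom) == pytest.approx(9.0, rel=0.05)
        assert dem.crown_area_from_dbh(13.8, allom) == pytest.approx(14.0, rel=0.1)

    def test_negative_carbon_rejected(self):
        with pytest.raises(ValueError):
            dem.dbh_growth(13.8, 9.0, -1.0)


class TestGrid:
    def test_standard_grid_geometry(self):
        grid = Grid()
        assert grid.n_cells == 500
        assert grid.cell_area == 400.0
        assert grid.nx == 10 and grid.ny == 50

    def test_cell_lookup_round_trip(self, rng):
        grid = Grid()
        x = rng.uniform(0, 200, 100)
        y = rng.uniform(0, 1000, 100)
        cells = grid.cell_of(x, y)
        ox, oy = grid.cell_origin(cells)
        assert np.all((x >= ox) & (x <= ox + 20.0))
        assert np.all((y >= oy) & (y <= oy + 20.0))

    def test_elevation_mapping(self):
        dom = Domain()
        assert dom.elevation(0.0) == 700.0
        assert dom.elevation(1000.0) == 1700.0
        assert dom.elevation(500.0) == 1200.0
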