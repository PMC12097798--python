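"""Dynamic-programming boundary optimization against exhaustive enumeration."""

import itertools

import numpy as np
import pytest

import stratopt as sp
from stratopt.errors import BudgetExceededError, InfeasibleError


def neyman_objective_fn(dens):
    """Single-stratum W·S objective for one density (vectorized)."""

    def fn(lo, hi):
        w, _, v = dens.moments(lo, hi)
        return w * np.sqrt(v)

    return fn


def brute_force_univariate(objective_fn, support, L, grid_points):
    """Independent exhaustive oracle over all monotone grid partitions."""
    points = np.linspace(support[0], support[1], grid_points + 1)
    best_val, best_cuts = np.inf, None
    for inner in itertools.combinations_with_replacement(range(grid_points + 1), L - 1):
        idx = (0, *inner, grid_points)
        val = sum(
            float(objective_fn(np.array(points[i]), np.array(points[j])))
            for i, j in zip(idx[:-1], idx[1:])
        )
        if val < best_val - 1e-15:
            best_val, best_cuts = val, points[list(idx)]
    return best_val, best_cuts


class TestUnivariateDP:
    def test_single_stratum_returns_endpoints(self):
        fn = neyman_objective_fn(sp.uniform_density(0, 1))
        res = sp.optimize_univariate(fn, (0, 1), L=1, grid_points=50)
        assert np.allclose(res.cuts, [0, 1])
        assert res.objective == pytest.approx(float(fn(np.array(0.0), np.array(1.0))))

    def test_uniform_symmetry_cut_at_midpoint(self):
        fn = neyman_objective_fn(sp.uniform_density(0, 1))
        res = sp.optimize_univariate(fn, (0, 1), L=2, grid_points=200)
        assert abs(res.cuts[1] - 0.5) <= 1 / 200 + 1e-12

    @pytest.mark.parametrize(
        "dens",
        [
            sp.uniform_density(0, 1),
            sp.power_density(3.0, 1.0),
            sp.cauchy_density(0.0, 1.0),
        ],
        ids=["uniform", "power", "cauchy"],
    )
    @pytest.mark.parametrize("L,grid", [(2, 40), (3, 30), (4, 25)])
    def test_dp_equals_exhaustive(self, dens, L, grid):
        fn = neyman_objective_fn(dens)
        res = sp.optimize_univariate(fn, (dens.support_lo, dens.support_hi), L, grid)
        val, cuts = brute_force_univariate(
            fn, (dens.support_lo, dens.support_hi), L, grid
        )
        assert res.objective == pytest.approx(val, rel=1e-12, abs=1e-15)
        # cut vectors agree up to exact objective ties among symmetric optima
        val_at_dp_cuts = sum(
            float(fn(np.array(a), np.array(b)))
            for a, b in zip(res.cuts[:-1], res.cuts[1:])
        )
        assert val_at_dp_cuts == pytest.approx(val, rel=1e-12, abs=1e-15)

    def test_infeasible_when_grid_smaller_than_l(self):
        fn = neyman_objective_fn(sp.uniform_density(0, 1))
        with pytest.raises(InfeasibleError):
            sp.optimize_univariate(fn, (0, 1), L=5, grid_points=3)

    def test_width_constraint_holds_exactly(self):
        dens = sp.power_density(2.0, 1.0)
        fn = neyman_objective_fn(dens)
        res = sp.optimize_univariate(fn, (0, 1), L=4, grid_points=80)
        assert res.cuts[0] == 0.0 and res.cuts[-1] == 1.0
        assert np.diff(res.cuts).sum() == pytest.approx(1.0, abs=1e-15)


class TestBivariateDP:
    def test_trivial_single_cell(self, cauchy_power_design, unit_model):
        costs = sp.equal_costs(1, 1)
        res = sp.optimize_bivariate(
            cauchy_power_design, unit_model, costs, L=1, M=1, grid_points=10
        )
        grid = sp.StrataGrid([0, 1], [0, 1])
        expected = sp.total_objective(cauchy_power_design, unit_model, grid, costs)
        assert res.objective == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "design_name", ["uniform_uniform", "cauchy_power"]
    )
    def test_alternating_dp_matches_exhaustive_2x2(
        self, design_name, unit_uniform_design, cauchy_power_design, unit_model
    ):
        design = (
            unit_uniform_design
            if design_name == "uniform_uniform"
            else cauchy_power_design
        )
        costs = sp.CostModel(0.0, np.array([[1.0, 2.0], [3.0, 4.0]]), 1.0)
        dp = sp.optimize_bivariate(
            design, unit_model, costs, L=2, M=2, grid_points=20
        )
        ex = sp.exhaustive_search(design, unit_model, costs, L=2, M=2, grid_points=20)
        assert dp.objective == pytest.approx(ex.objective, rel=1e-12)
        assert np.allclose(dp.grid.cuts1, ex.grid.cuts1)
        assert np.allclose(dp.grid.cuts2, ex.grid.cuts2)

    def test_univariate_case_matches_exhaustive_exactly(
        self, cauchy_power_design, unit_model
    ):
        costs = sp.equal_costs(3, 1)
        dp = sp.optimize_bivariate(
            cauchy_power_design, unit_model, costs, L=3, M=1, grid_points=25
        )
        ex = sp.exhaustive_search(
            cauchy_power_design, unit_model, costs, L=3, M=1, grid_points=25
        )
        assert dp.objective == pytest.approx(ex.objective, rel=1e-12)
        assert np.allclose(dp.grid.cuts1, ex.grid.cuts1)

    def test_objective_no_worse_than_equal_width_start(
        self, cauchy_power_design, unit_model, worked_example_costs
    ):
        res = sp.optimize_bivariate(
            cauchy_power_design, unit_model, worked_example_costs, 2, 3, 100
        )
        init = sp.equal_width_grid(cauchy_power_design, 2, 3)
        v0 = sp.total_objective(
            cauchy_power_design, unit_model, init, worked_example_costs
        )
        assert res.objective <= v0 + 1e-12
        assert res.converged

    def test_monotone_in_L_under_equal_costs(self, cauchy_power_design, unit_model):
        vals = [
            sp.optimize_bivariate(
                cauchy_power_design, unit_model, sp.equal_costs(L, 2), L, 2, 60
            ).objective
            for L in (1, 2, 3, 4)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_grid_refinement_never_increases_value(
        self, cauchy_power_design, unit_model, worked_example_costs
    ):
        coarse = sp.optimize_bivariate(
            cauchy_power_design, unit_model, worked_example_costs, 2, 3, 50
        )
        fine = sp.optimize_bivariate(
            cauchy_power_design, unit_model, worked_example_costs, 2, 3, 100
        )
        assert fine.objective <= coarse.objective + 1e-12

    def test_deterministic_across_runs(self, cauchy_power_design, unit_model):
        costs = sp.equal_costs(2, 2)
        a = sp.optimize_bivariate(cauchy_power_design, unit_model, costs, 2, 2, 40)
        b = sp.optimize_bivariate(cauchy_power_design, unit_model, costs, 2, 2, 40)
        assert np.array_equal(a.grid.cuts1, b.grid.cuts1)
        assert np.array_equal(a.grid.cuts2, b.grid.cuts2)
        assert a.objective == b.objective


class TestExhaustiveSearch:
    def test_refuses_oversized_enumeration(self, unit_uniform_design, unit_model):
        with pytest.raises(BudgetExceededError):
            sp.exhaustive_search(
                unit_uniform_design,
                unit_model,
                sp.equal_costs(6, 6),
                L=6,
                M=6,
                grid_points=200,
            )

    def test_uniform_symmetric_cut_near_midpoint(self, unit_uniform_design, unit_model):
        res = sp.exhaustive_search(
            unit_uniform_design, unit_model, sp.equal_costs(2, 1), 2, 1, 10
        )
        assert res.grid.cuts1[1] == pytest.approx(0.5, abs=0.05 + 1e-12)


class TestStrataGrid:
    def test_rejects_decreasing_cuts(self):
        with pytest.raises(Exception):
            sp.StrataGrid([0, 0.7, 0.3, 1], [0, 1])

    def test_collapse_empty_drops_duplicates(self):
        g = sp.StrataGrid([0, 0.5, 0.5, 1], [0, 1, 1])
        c = g.collapse_empty()
        assert c.L == 2 and c.M == 1
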