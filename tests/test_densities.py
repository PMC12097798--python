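"""Cell weights, means and variances: analytic fast paths vs quadrature."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stratopt as sp
from stratopt.errors import (
    ConfigurationError,
    DomainError,
    InputError,
    UndefinedMomentError,
)


class TestCellWeight:
    @pytest.mark.parametrize(
        "cell, expected",
        [
            (sp.Cell(0, 1, 0, 1), 1.0),
            (sp.Cell(0.25, 0.75, 0, 1), 0.5),
            (sp.Cell(0, 0, 0, 1), 0.0),  # zero-width cell
        ],
    )
    def test_uniform_mass_is_proportional(self, unit_uniform_design, cell, expected):
        assert sp.cell_weight(unit_uniform_design, cell) == pytest.approx(expected)

    def test_cauchy_power_unit_square(self, cauchy_power_design):
        # (arctan 1 − arctan 0)/π · (1³ − 0³) = 1/4
        w = sp.cell_weight(cauchy_power_design, sp.Cell(0, 1, 0, 1))
        assert w == pytest.approx(0.25, rel=1e-12)

    def test_cauchy_power_quarter_cell(self, cauchy_power_design):
        cell = sp.Cell(0, 0.5, 0, 0.5)
        expected = np.arctan(0.5) / np.pi * 0.125
        assert sp.cell_weight(cauchy_power_design, cell) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.018448, abs=5e-7)

    def test_cell_outside_support_raises(self, unit_uniform_design):
        with pytest.raises(DomainError):
            sp.cell_weight(unit_uniform_design, sp.Cell(-0.5, 0.5, 0, 1))


class TestAxisMoments:
    def test_uniform_slice_mean_is_midpoint(self, unit_uniform_design):
        cell = sp.Cell(0.2, 0.6, 0, 1)
        assert sp.cell_axis_mean(unit_uniform_design, cell, 1) == pytest.approx(0.4)

    def test_power_mean_full_support(self, cauchy_power_design):
        # δ/(δ+1) with δ=3
        cell = sp.Cell(0, 1, 0, 1)
        assert sp.cell_axis_mean(cauchy_power_design, cell, 2) == pytest.approx(0.75)

    def test_cauchy_mean_unit_interval(self, cauchy_power_design):
        cell = sp.Cell(0, 1, 0, 1)
        expected = np.log(2) / (2 * np.arctan(1))
        got = sp.cell_axis_mean(cauchy_power_design, cell, 1)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.441271, abs=5e-7)

    @pytest.mark.parametrize(
        "cell, expected",
        [
            (sp.Cell(0, 1, 0, 1), 1 / 12),
            (sp.Cell(0, 0.5, 0, 1), 0.25 / 12),
        ],
    )
    def test_uniform_variance(self, unit_uniform_design, cell, expected):
        assert sp.cell_axis_variance(unit_uniform_design, cell, 1) == pytest.approx(
            expected
        )

    def test_power_variance_full_support(self, cauchy_power_design):
        # 3/5 − (3/4)²
        cell = sp.Cell(0, 1, 0, 1)
        assert sp.cell_axis_variance(cauchy_power_design, cell, 2) == pytest.approx(
            0.0375
        )

    def test_zero_weight_cell_moment_raises(self, unit_uniform_design):
        with pytest.raises(UndefinedMomentError):
            sp.cell_axis_mean(unit_uniform_design, sp.Cell(0.3, 0.3, 0, 1), 1)


class TestClosedFormCauchyPower:
    def test_matches_quadrature(self, cauchy_power_design, rng):
        for _ in range(20):
            l1, h1 = np.sort(rng.uniform(0, 1, 2))
            l2, h2 = np.sort(rng.uniform(0, 1, 2))
            cell = sp.Cell(l1, h1, l2, h2)
            cf = sp.closed_form_cauchy_power_weight(cauchy_power_design, cell)
            assert cf == pytest.approx(
                sp.cell_weight(cauchy_power_design, cell), rel=1e-10, abs=1e-14
            )

    def test_zero_width_gives_zero(self, cauchy_power_design):
        assert (
            sp.closed_form_cauchy_power_weight(
                cauchy_power_design, sp.Cell(0, 0, 0, 1)
            )
            == 0.0
        )

    def test_wrong_family_raises(self, unit_uniform_design):
        with pytest.raises(ConfigurationError):
            sp.closed_form_cauchy_power_weight(
                unit_uniform_design, sp.Cell(0, 1, 0, 1)
            )


class TestQuadratureOracle:
    """Analytic moments agree with adaptive quadrature on random cells."""

    @pytest.mark.parametrize(
        "dens",
        [
            sp.uniform_density(0, 1),
            sp.power_density(3.0, 1.0),
            sp.cauchy_density(0.0, 1.0),
            sp.cauchy_density(0.0, 1.0, normalize=True),
            sp.power_density(1.7, 2.5),
            sp.cauchy_density(-1.0, 2.0, location=0.3, scale=0.8),
        ],
        ids=["uniform", "power3", "cauchy", "cauchy-norm", "power-frac", "cauchy-loc"],
    )
    def test_analytic_equals_quadrature(self, dens, rng):
        for _ in range(10):
            lo, hi = np.sort(
                rng.uniform(dens.support_lo, dens.support_hi, 2)
            )
            wq, mq, vq = dens.moments_quad(lo, hi)
            w, m, v = (float(x) for x in dens.moments(lo, hi))
            assert w == pytest.approx(wq, rel=1e-8, abs=1e-12)
            if wq > 1e-9:
                assert m == pytest.approx(mq, rel=1e-8, abs=1e-10)
                assert v == pytest.approx(vq, rel=1e-6, abs=1e-12)

    def test_partition_additivity(self, rng):
        for dens, total in [
            (sp.uniform_density(0, 1), 1.0),
            (sp.power_density(3.0, 1.0), 1.0),
            (sp.cauchy_density(0.0, 1.0), np.arctan(1.0) / np.pi),
            (sp.cauchy_density(0.0, 1.0, normalize=True), 1.0),
        ]:
            cuts = np.concatenate(
                [[dens.support_lo], np.sort(rng.uniform(0, 1, 6)), [dens.support_hi]]
            )
            w = dens.mass(cuts[:-1], cuts[1:])
            assert w.sum() == pytest.approx(total, abs=1e-8)

    def test_variance_bounded_by_width(self, rng):
        for dens in [
            sp.uniform_density(0, 1),
            sp.power_density(3.0, 1.0),
            sp.cauchy_density(0.0, 1.0),
        ]:
            lo = rng.uniform(0, 1, 50)
            hi = lo + rng.uniform(0, 1 - lo)
            _, _, v = dens.moments(lo, hi)
            assert np.all(v <= (hi - lo) ** 2 / 4 + 1e-12)


class TestMassProperties:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        bounds=st.tuples(
            st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
        ).map(sorted)
    )
    def test_mass_is_additive_and_variance_bounded(self, bounds):
        lo, mid, hi = bounds
        for dens in (
            sp.power_density(3.0, 1.0),
            sp.cauchy_density(0.0, 1.0),
            sp.uniform_density(0.0, 1.0),
        ):
            left = float(dens.mass(lo, mid))
            right = float(dens.mass(mid, hi))
            whole = float(dens.mass(lo, hi))
            assert left + right == pytest.approx(whole, abs=1e-12)
            _, _, v = dens.moments(lo, hi)
            assert float(v) <= (hi - lo) ** 2 / 4 + 1e-12


class TestEmpiricalCellMoments:
    def test_hand_counted_cell(self):
        cell = sp.Cell(1.5, 4, 0, 2)
        sm = sp.empirical_cell_moments([1, 2, 3, 4], [1, 1, 1, 1], cell)
        assert sm.weight == pytest.approx(0.75)
        assert sm.n_units == 3
        assert sm.mean1 == pytest.approx(3.0)
        assert sm.var1 == pytest.approx(1.0)  # ((−1)²+0²+1²)/2

    def test_full_range_captures_all(self, rng):
        x1 = rng.normal(size=40)
        x2 = rng.normal(size=40)
        cell = sp.Cell(x1.min(), x1.max(), x2.min(), x2.max())
        sm = sp.empirical_cell_moments(x1, x2, cell)
        assert sm.weight == pytest.approx(1.0)
        assert sm.n_units == 40

    def test_singleton_cell_zero_variance(self):
        sm = sp.empirical_cell_moments([1.0, 5.0], [1.0, 5.0], sp.Cell(0, 2, 0, 2))
        assert sm.n_units == 1
        assert sm.var1 == 0.0 and sm.var2 == 0.0

    def test_partition_assigns_each_unit_once(self, rng):
        x1 = rng.uniform(0, 1, 200)
        x2 = rng.uniform(0, 1, 200)
        cuts1 = [0, 0.3, 0.7, 1.0]
        cuts2 = [0, 0.5, 1.0]
        total = 0
        for h in range(3):
            for k in range(2):
                cell = sp.Cell(cuts1[h], cuts1[h + 1], cuts2[k], cuts2[k + 1])
                sm = sp.empirical_cell_moments(
                    x1, x2, cell, support1=(0, 1), support2=(0, 1)
                )
                total += sm.n_units
        assert total == 200

    def test_length_mismatch_raises(self):
        with pytest.raises(InputError):
            sp.empirical_cell_moments([1, 2], [1], sp.Cell(0, 2, 0, 2))

    def test_uniform_sample_matches_analytic_within_3se(self, rng):
        # 50,000 uniform(a, b) draws: cell mean/variance near the analytic values
        a, b = 0.002, 1.92
        xs = rng.uniform(a, b, 50_000)
        cell = sp.Cell(0.5, 1.0, a, b)
        sm = sp.empirical_cell_moments(
            xs, xs, cell, support1=(a, b), support2=(a, b)
        )
        n = sm.n_units
        width = 0.5
        true_mean, true_var = 0.75, width**2 / 12
        se_mean = np.sqrt(true_var / n)
        assert abs(sm.mean1 - true_mean) < 3 * se_mean
        # SE of the sample variance of a uniform slice: sqrt((m4 − var²)/n)
        m4 = width**4 / 80
        se_var = np.sqrt((m4 - true_var**2) / n)
        assert abs(sm.var1 - true_var) < 3 * se_var


class TestDensitySpecValidation:
    def test_bad_support_rejected(self):
        with pytest.raises(ConfigurationError):
            sp.DensitySpec("uniform", 1.0, 0.0)

    def test_empirical_needs_sample_inside_support(self):
        with pytest.raises(ConfigurationError):
            sp.DensitySpec("empirical", 0.0, 1.0, sample=np.array([0.5, 2.0]))

    def test_draw_is_deterministic_and_in_support(self):
        dens = sp.power_density(3.0, 1.0)
        a = dens.draw(100, np.random.default_rng(5))
        b = dens.draw(100, np.random.default_rng(5))
        assert np.array_equal(a, b)
        assert a.min() >= 0 and a.max() <= 1
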