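"""Spline design blocks: shapes, null spaces, constraints, periodicity."""

import numpy as np
import pytest

from pammkit.basis import (
    cubic_regression_basis,
    cyclic_cubic_basis,
    random_intercept_block,
    sum_to_zero,
    tensor_product,
    tprs_basis,
    varying_coefficient,
)


def _psd_min_eig(S):
    return float(np.linalg.eigvalsh((S + S.T) / 2).min())


@pytest.fixture(scope="module")
def tgrid():
    return np.linspace(0.0, 728.0, 50)


class TestTPRS:
    def test_shape_and_psd(self, tgrid):
        blk = tprs_basis(tgrid, 10)
        assert blk.design.shape == (50, 10)
        assert len(blk.penalties) == 1 and blk.penalties[0].shape == (10, 10)
        assert _psd_min_eig(blk.penalties[0]) >= -1e-8

    def test_linear_functions_unpenalized(self, tgrid):
        """A straight line lies in the penalty null space."""
        blk = tprs_basis(tgrid, 10)
        target = 0.3 - 0.002 * tgrid
        beta, res, *_ = np.linalg.lstsq(blk.design, target, rcond=None)
        assert np.allclose(blk.design @ beta, target, atol=1e-8)
        assert float(beta @ blk.penalties[0] @ beta) == pytest.approx(0.0, abs=1e-10)

    def test_k_too_small_or_large(self, tgrid):
        with pytest.raises(ValueError):
            tprs_basis(tgrid, 2)
        with pytest.raises(ValueError):
            tprs_basis(np.array([1.0, 2.0, 3.0]), 5)

    def test_deterministic(self, tgrid):
        a = tprs_basis(tgrid, 10).design
        b = tprs_basis(tgrid, 10).design
        assert np.array_equal(a, b)

    def test_evaluate_matches_design(self, tgrid):
        blk = tprs_basis(tgrid, 8)
        assert np.allclose(blk.evaluate(tgrid), blk.design, atol=1e-12)


class TestCyclic:
    def test_periodic_rows(self):
        x = np.linspace(1.0, 365.0, 40)
        blk = cyclic_cubic_basis(x, 8)
        assert np.allclose(blk.evaluate(np.array([1.0])), blk.evaluate(np.array([366.0])), atol=1e-10)

    def test_derivative_continuity(self):
        """f, f' and f'' agree across the period ends (day 365 -> day 1)."""
        x = np.linspace(1.0, 365.0, 40)
        blk = cyclic_cubic_basis(x, 9)
        rng = np.random.default_rng(3)
        beta = rng.normal(size=blk.n_coef)

        def f(v):
            return blk.evaluate(np.atleast_1d(v)) @ beta

        h = 1e-4
        end, start = 366.0, 1.0
        for deriv in (1, 2):
            if deriv == 1:
                d_end = (f(end) - f(end - h)) / h
                d_start = (f(start + h) - f(start)) / h
            else:
                d_end = (f(end) - 2 * f(end - h) + f(end - 2 * h)) / h**2
                d_start = (f(start + 2 * h) - 2 * f(start + h) + f(start)) / h**2
            assert d_end == pytest.approx(d_start, abs=1e-3 * max(1, abs(d_end)))
        assert f(end) == pytest.approx(f(start), abs=1e-10)

    def test_constant_unpenalized(self):
        x = np.linspace(1.0, 365.0, 30)
        blk = cyclic_cubic_basis(x, 7)
        one = np.ones(blk.n_coef)  # value-parameterized: constant = equal knot values
        assert np.allclose(blk.design @ one, 1.0, atol=1e-10)
        assert float(one @ blk.penalties[0] @ one) == pytest.approx(0.0, abs=1e-12)

    def test_domain_validation(self):
        with pytest.raises(ValueError, match="outside"):
            cyclic_cubic_basis(np.array([0.5, 100.0]), 6)
        with pytest.raises(ValueError):
            cyclic_cubic_basis(np.linspace(1, 365, 20), 3)


class TestSumToZero:
    def test_constraint_and_dimension(self, tgrid):
        raw = tprs_basis(tgrid, 10)
        blk = sum_to_zero(raw, grid_design=raw.evaluate(tgrid))
        assert blk.n_coef == raw.n_coef - 1
        # column sums over the grid vanish
        assert np.max(np.abs(blk.evaluate(tgrid).sum(axis=0))) < 1e-10
        # hence any fitted curve sums to zero over the grid
        rng = np.random.default_rng(0)
        beta = rng.normal(size=blk.n_coef)
        assert float((blk.evaluate(tgrid) @ beta).sum()) == pytest.approx(0.0, abs=1e-8)

    def test_double_constraint_rejected(self, tgrid):
        blk = sum_to_zero(tprs_basis(tgrid, 8))
        with pytest.raises(ValueError):
            sum_to_zero(blk)


class TestVaryingCoefficient:
    def test_zero_rows_and_group1(self, tgrid):
        raw = tprs_basis(tgrid, 8)
        tb = sum_to_zero(raw, grid_design=raw.evaluate(tgrid))
        x = (np.arange(50) % 2).astype(float)
        vc = varying_coefficient(x, tb)
        assert np.all(vc.design[x == 0] == 0.0)
        assert np.allclose(vc.design[x == 1], tb.design[x == 1])

    def test_requires_binary_and_constraint(self, tgrid):
        tb = sum_to_zero(tprs_basis(tgrid, 8))
        with pytest.raises(ValueError, match="0/1"):
            varying_coefficient(np.linspace(0, 2, 50), tb)
        with pytest.raises(ValueError, match="constrained"):
            varying_coefficient(np.zeros(50), tprs_basis(tgrid, 8))


class TestTensor:
    def _margins(self):
        t = np.linspace(0, 728, 60)
        doy = np.linspace(1, 365, 60)
        return cubic_regression_basis(t, 8), cyclic_cubic_basis(doy, 9)  # 8 x 8 columns

    def test_shape_two_penalties(self):
        tm, sm = self._margins()
        te = tensor_product(tm, sm)
        assert te.design.shape[1] == 64
        assert len(te.penalties) == 2
        assert all(_psd_min_eig(P) >= -1e-8 for P in te.penalties)

    def test_season_constant_escapes_season_penalty(self):
        """Coefficients constant along the season margin are only penalized
        in the time direction."""
        tm, sm = self._margins()
        te = tensor_product(tm, sm)
        rng = np.random.default_rng(1)
        c = rng.normal(size=8)  # arbitrary time profile
        alpha = np.kron(c, np.ones(8))  # constant across season index
        P_time, P_season = te.penalties
        assert float(alpha @ P_season @ alpha) == pytest.approx(0.0, abs=1e-10)
        assert float(alpha @ P_time @ alpha) > 1e-6

    def test_periodic_in_season_margin(self):
        tm, sm = self._margins()
        te = tensor_product(tm, sm)
        t_fix = np.array([100.0, 400.0])
        a = te.evaluate(t_fix, np.array([1.0, 1.0]))
        b = te.evaluate(t_fix, np.array([366.0, 366.0]))
        assert np.allclose(a, b, atol=1e-10)

    def test_dimension_cap(self):
        tm, sm = self._margins()
        with pytest.raises(ValueError, match="cap"):
            tensor_product(tm, sm, max_dim=10)


class TestRandomIntercept:
    def test_indicator_structure(self):
        ids = np.array(["a", "b", "a", "c", "b"])
        blk = random_intercept_block(ids)
        assert blk.design.shape == (5, 3)
        assert np.allclose(blk.design.sum(axis=1), 1.0)
        assert np.array_equal(blk.design[0], blk.design[2])  # same subject, same column
        assert np.array_equal(blk.penalties[0], np.eye(3))
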