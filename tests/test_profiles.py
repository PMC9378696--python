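"""Activity profiles, jump kernel, moments and sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from colloidjump.profiles import (
    Geometry,
    ParametricField,
    ProfileParams,
    TabulatedField,
    eval_L,
    eval_lambda,
    jump_kernel_cdf,
    jump_kernel_density,
    kernel_moments,
    rescale_rate_to_reference,
    sample_jump,
)


def _fixed_field(Lp, Lm, lam=0.3):
    """Homogeneous field with prescribed L+ and L- (possibly unequal)."""

    class _F:
        geometry = Geometry(half_width=50.0, colloid_radius=5.0)

        def lambda_at(self, y):
            return np.full_like(np.asarray(y, float), lam)

        def L_plus_at(self, y):
            return np.full_like(np.asarray(y, float), Lp)

        def L_minus_at(self, y):
            return np.full_like(np.asarray(y, float), Lm)

        def bulk_L(self):
            return 0.5 * (Lp + Lm)

        def bulk_lambda(self):
            return lam

    return _F()


class TestEvalProfiles:
    def test_wall_and_bulk_rate_limits(self, table1):
        assert eval_lambda(table1, 5.0) == pytest.approx(0.237, abs=1e-12)
        assert eval_lambda(table1, 1e9) == pytest.approx(0.315, rel=1e-9)

    def test_rate_one_decay_length_from_wall(self, table1):
        # independent arithmetic oracle for the relaxation law
        expected = 0.315 + (0.237 - 0.315) / math.e
        assert eval_lambda(table1, 5.0 + 8.20) == pytest.approx(expected, rel=1e-12)

    def test_length_wall_and_bulk_limits(self, table1):
        for sign in ("away", "toward"):
            assert eval_L(table1, 5.0, sign) == pytest.approx(0.375)
            assert eval_L(table1, 1e9, sign) == pytest.approx(3.70, rel=1e-9)

    def test_net_drift_outward_between_wall_and_bulk(self, table1):
        # L- relaxes more slowly than L+, so L+ > L- at intermediate y:
        # the kernel's first moment is positive (drift away from the wall)
        y = np.linspace(5.0, 50.0, 200)
        m1 = kernel_moments(table1, y, 1)
        assert np.all(m1 >= -1e-12)
        assert m1.max() > 0.5

    def test_positions_below_wall_offset_clamp(self, table1):
        assert eval_lambda(table1, 2.0) == eval_lambda(table1, 5.0)

    def test_non_finite_position_rejected(self, table1):
        with pytest.raises(ValueError):
            eval_lambda(table1, np.nan)

    def test_unknown_sign_tag_rejected(self, table1):
        with pytest.raises(ValueError):
            eval_L(table1, 10.0, "sideways")

    def test_monotone_relaxation(self, table1):
        y = np.linspace(5.0, 60.0, 300)
        lam = eval_lambda(table1, y)
        Lp = eval_L(table1, y, "away")
        assert np.all(np.diff(lam) > 0) and lam[0] >= 0.237 and lam[-1] <= 0.315
        assert np.all(np.diff(Lp) > 0) and Lp[0] >= 0.375 and Lp[-1] <= 3.70


class TestKernel:
    def test_symmetric_density_at_zero(self):
        f = _fixed_field(2.0, 2.0)
        assert jump_kernel_density(f, 10.0, 0.0) == pytest.approx(1.0 / 4.0)

    @given(
        Lp=st.floats(0.1, 10.0),
        Lm=st.floats(0.1, 10.0),
    )
    def test_normalization(self, Lp, Lm):
        f = _fixed_field(Lp, Lm)
        val, _ = quad(lambda u: float(jump_kernel_density(f, 10.0, u)), -np.inf, np.inf)
        assert val == pytest.approx(1.0, abs=1e-8)

    @given(
        Lp=st.floats(0.1, 10.0),
        Lm=st.floats(0.1, 10.0),
        order=st.sampled_from([1, 2]),
    )
    def test_moments_match_quadrature(self, Lp, Lm, order):
        f = _fixed_field(Lp, Lm)
        closed = float(kernel_moments(f, 10.0, order))
        num = sum(
            quad(lambda u: u**order * float(jump_kernel_density(f, 10.0, u)), a, b)[0]
            for a, b in [(-np.inf, 0.0), (0.0, np.inf)]
        )
        assert closed == pytest.approx(num, rel=1e-6, abs=1e-9)

    def test_moment_examples(self):
        f = _fixed_field(2.0, 1.0)
        assert float(kernel_moments(f, 10.0, 1)) == pytest.approx(1.0)
        assert float(kernel_moments(f, 10.0, 2)) == pytest.approx(6.0)
        sym = _fixed_field(3.0, 3.0)
        assert float(kernel_moments(sym, 10.0, 1)) == 0.0
        assert float(kernel_moments(sym, 10.0, 2)) == pytest.approx(18.0)

    def test_variance_nonnegative_everywhere(self, table1):
        y = np.linspace(5.0, 50.0, 100)
        m1 = kernel_moments(table1, y, 1)
        m2 = kernel_moments(table1, y, 2)
        assert np.all(m2 - m1**2 >= 0)

    def test_higher_order_rejected(self, table1):
        with pytest.raises(ValueError):
            kernel_moments(table1, 10.0, 3)


class TestSampler:
    def test_sign_and_moments_within_monte_carlo_error(self):
        f = _fixed_field(2.0, 1.0)
        rng = np.random.default_rng(4)
        n = 100_000
        s = sample_jump(f, 10.0, rng, size=n)
        p_plus = (s > 0).mean()
        assert abs(p_plus - 2.0 / 3.0) < 3 * math.sqrt(2 / 9 / n)
        m1, m2 = float(kernel_moments(f, 10.0, 1)), float(kernel_moments(f, 10.0, 2))
        assert abs(s.mean() - m1) < 3 * s.std() / math.sqrt(n)
        sq = s**2
        assert abs(sq.mean() - m2) < 3 * sq.std() / math.sqrt(n)

    def test_symmetric_sampler_balanced(self):
        f = _fixed_field(3.0, 3.0)
        rng = np.random.default_rng(5)
        n = 100_000
        s = sample_jump(f, 10.0, rng, size=n)
        assert abs((s > 0).mean() - 0.5) < 3 * 0.5 / math.sqrt(n)

    def test_kolmogorov_smirnov_against_kernel_cdf(self, table1):
        rng = np.random.default_rng(6)
        n = 100_000
        y = 12.0
        s = np.sort(sample_jump(table1, y, rng, size=n))
        cdf = np.asarray(jump_kernel_cdf(table1, y, s))
        emp_hi = (np.arange(n) + 1) / n
        emp_lo = np.arange(n) / n
        ks = max(np.max(np.abs(emp_hi - cdf)), np.max(np.abs(cdf - emp_lo)))
        assert ks < 1.628 / math.sqrt(n)  # alpha = 0.01 critical value


class TestRescaleAndTypes:
    def test_rescale_identity_and_roundtrip(self):
        lam = np.array([0.2, 0.3])
        assert np.allclose(rescale_rate_to_reference(lam, 2.0, 2.0), lam)
        assert np.allclose(rescale_rate_to_reference(rescale_rate_to_reference(lam, 2.0, 5.0), 5.0, 2.0), lam)

    def test_rescale_linear_in_concentration(self):
        assert rescale_rate_to_reference(0.4, 2.0, 1.0) == pytest.approx(0.2)

    def test_rescale_rejects_nonpositive_concentration(self):
        with pytest.raises(ValueError):
            rescale_rate_to_reference(0.3, 0.0, 1.0)

    def test_param_invariants(self):
        with pytest.raises(ValueError):
            ProfileParams(L_bulk=0.2, l_plus=5.0, l_minus=10.0, lambda_wall=0.2, lambda_bulk=0.3, l_lambda=8.0, L_wall=0.375)
        with pytest.raises(ValueError):
            Geometry(half_width=4.0, colloid_radius=5.0)

    def test_tabulated_field_interpolates(self, table1):
        y = np.array([5.0, 10.0, 20.0, 40.0, 50.0])
        tab = TabulatedField(y, table1.lambda_at(y), table1.L_plus_at(y), table1.L_minus_at(y), table1.geometry)
        assert float(tab.lambda_at(10.0)) == pytest.approx(float(table1.lambda_at(10.0)))
        assert float(tab.L_plus_at(60.0)) == pytest.approx(float(table1.L_plus_at(50.0)), rel=0.05)
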