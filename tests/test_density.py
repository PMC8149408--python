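"""Closed-form transition density: coefficient formulas, compound-symmetric
linear algebra, and reductions to known scalar processes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import dblquad, quad

from glca import (
    DegenerateCovarianceError,
    DimensionError,
    DomainError,
    ModelParams,
    conditional_mean,
    evidence_to_log,
    joint_log_pdf,
    log_to_evidence,
    marginal_pdf,
    omega_inverse_logdet,
    transition,
    wei_norman_coefficients,
)

from .conftest import scalar_ou_logpdf, scalar_ou_mean_var


class TestWeiNormanCoefficients:
    def test_linear_coefficients(self, params_n2):
        c = wei_norman_coefficients(params_n2, 0.5)
        assert c.b3 == pytest.approx(-(4 - 1) * 0.5)  # -(kappa-beta)*tau
        assert c.b4 == pytest.approx(-1 * 0.5)  # -beta*tau

    def test_all_vanish_at_zero_lag(self, params_n3):
        c = wei_norman_coefficients(params_n3, 0.0)
        assert (c.b1, c.b2, c.b3, c.b4, c.b5, c.b6) == (0, 0, 0, 0, 0, 0)

    def test_b1_closed_form(self, params_n2):
        # b1 = (e^{(kappa-beta) tau} - 1)/(kappa-beta), independent scalar arithmetic
        c = wei_norman_coefficients(params_n2, 1.0)
        assert c.b1 == pytest.approx((np.e**3 - 1) / 3, rel=1e-14)

    def test_equal_rates_limit(self):
        # kappa = beta: contrast rate vanishes, b1 -> tau and b5 -> xi^2 tau / 2
        p = ModelParams(kappa=2.0, beta=2.0, inputs=(1.0, 1.0), xi=0.25)
        c = wei_norman_coefficients(p, 0.7)
        assert c.b1 == pytest.approx(0.7, rel=1e-12)
        assert c.b5 == pytest.approx(0.25**2 * 0.7 / 2, rel=1e-12)

    @pytest.mark.parametrize("eps", [1e-8, -1e-8])
    def test_series_branch_agrees_with_generic(self, eps):
        # the removable-singularity branch must match direct evaluation just
        # outside the switch threshold
        p_limit = ModelParams(kappa=2.0, beta=2.0, inputs=(0.9, 1.1), xi=0.25)
        p_near = ModelParams(kappa=2.0 + eps, beta=2.0, inputs=(0.9, 1.1), xi=0.25)
        c0 = wei_norman_coefficients(p_limit, 0.7)
        c1 = wei_norman_coefficients(p_near, 0.7)
        for name in ("b1", "b2", "b5", "b6"):
            assert getattr(c1, name) == pytest.approx(getattr(c0, name), rel=1e-6)

    def test_collective_rate_singularity(self):
        # kappa + beta(N-1) = 0 is the other removable singularity (b2, b6)
        p_limit = ModelParams(kappa=1.0, beta=-0.5, inputs=(0.9, 1.1, 1.0), xi=0.3)
        p_near = ModelParams(kappa=1.0 + 1e-8, beta=-0.5, inputs=(0.9, 1.1, 1.0), xi=0.3)
        c0 = wei_norman_coefficients(p_limit, 0.4)
        c1 = wei_norman_coefficients(p_near, 0.4)
        assert c1.b2 == pytest.approx(c0.b2, rel=1e-6)
        assert c1.b6 == pytest.approx(c0.b6, rel=1e-6)

    @given(tau=st.floats(1e-12, 1e-6))
    def test_continuous_into_zero_lag(self, tau):
        p = ModelParams(kappa=4.0, beta=1.0, inputs=(0.9, 1.1), xi=0.25)
        c = wei_norman_coefficients(p, tau)
        for name in ("b1", "b2", "b3", "b4", "b5", "b6"):
            assert abs(getattr(c, name)) < 1e-4

    @given(
        kappa=st.floats(-2.0, 6.0),
        beta=st.floats(-1.0, 3.0),
        tau=st.floats(1e-4, 2.0),
    )
    def test_covariance_positive_definite_for_any_rates(self, kappa, beta, tau):
        # no stationarity restriction: b5 > 0, b5+b6 > 0, b5+N*b6 > 0 for
        # every real (kappa, beta) at positive lag
        p = ModelParams(kappa=kappa, beta=beta, inputs=(0.9, 1.1, 1.0), xi=0.25)
        c = wei_norman_coefficients(p, tau)
        assert c.b5 > 0
        assert c.b5 + c.b6 > 0
        assert c.b5 + p.n * c.b6 > 0

    def test_domain_errors(self, params_n2):
        with pytest.raises(DomainError):
            wei_norman_coefficients(params_n2, -0.1)
        with pytest.raises(DomainError):
            wei_norman_coefficients(params_n2, np.nan)


class TestConditionalMean:
    def test_identity_at_zero_lag(self, params_n3, rng):
        c = wei_norman_coefficients(params_n3, 0.0)
        x0 = rng.normal(size=3)
        np.testing.assert_allclose(conditional_mean(params_n3, c, x0), x0)

    def test_no_inhibition_reduces_to_scalar_ou(self):
        # beta = 0 decouples the accumulators into independent OU processes
        p = ModelParams(kappa=4.0, beta=0.0, inputs=(0.9, 1.1), xi=0.25)
        tau, x0 = 0.37, np.array([-5.0, -2.0])
        c = wei_norman_coefficients(p, tau)
        mean = conditional_mean(p, c, x0)
        for i in range(2):
            expected, _ = scalar_ou_mean_var(
                x0[i], tau, rate=4.0, level=p.inputs[i] / 4.0, sigma=0.25
            )
            assert mean[i] == pytest.approx(expected, rel=1e-12)

    def test_symmetric_inputs_give_symmetric_mean(self):
        p = ModelParams(kappa=4.0, beta=1.0, inputs=(1.0, 1.0, 1.0), xi=0.25)
        c = wei_norman_coefficients(p, 0.5)
        mean = conditional_mean(p, c, np.full(3, -5.0))
        assert np.ptp(mean) == pytest.approx(0.0, abs=1e-14)

    def test_dimension_mismatch(self, params_n2):
        c = wei_norman_coefficients(params_n2, 0.5)
        with pytest.raises(DimensionError):
            conditional_mean(params_n2, c, np.zeros(3))


class TestOmegaInverse:
    def _coeffs(self, b5, b6):
        from glca import WeiNormanCoefficients

        return WeiNormanCoefficients(tau=1.0, b1=0, b2=0, b3=0, b4=0, b5=b5, b6=b6)

    def test_diagonal_case(self):
        inv_diag, inv_off, logdet = omega_inverse_logdet(self._coeffs(0.2, 0.0), 4)
        assert inv_diag == pytest.approx(1 / 0.2)
        assert inv_off == 0.0
        assert logdet == pytest.approx(4 * np.log(0.2))

    def test_two_by_two_against_dense_inverse(self):
        inv_diag, inv_off, logdet = omega_inverse_logdet(self._coeffs(0.1, 0.05), 2)
        omega = np.array([[0.15, 0.05], [0.05, 0.15]])
        dense_inv = np.linalg.inv(omega)
        assert np.exp(logdet) == pytest.approx(0.1 * 0.2, rel=1e-12)
        assert inv_diag == pytest.approx(dense_inv[0, 0], rel=1e-12)
        assert inv_off == pytest.approx(dense_inv[0, 1], rel=1e-12)

    @given(
        b5=st.floats(1e-3, 10.0),
        ratio=st.floats(-0.09, 5.0),
        n=st.integers(2, 6),
    )
    def test_reconstruction_against_dense_linear_algebra(self, b5, ratio, n):
        # generic dense oracle: Omega @ Omega^-1 = I to 1e-12 and the
        # log-determinant matches numpy's slogdet
        b6 = ratio * b5 / n
        inv_diag, inv_off, logdet = omega_inverse_logdet(self._coeffs(b5, b6), n)
        omega = np.full((n, n), b6) + b5 * np.eye(n)
        inv = np.full((n, n), inv_off) + (inv_diag - inv_off) * np.eye(n)
        np.testing.assert_allclose(omega @ inv, np.eye(n), atol=1e-12)
        sign, dense_logdet = np.linalg.slogdet(omega)
        assert sign == 1.0
        assert logdet == pytest.approx(dense_logdet, abs=1e-10)

    @pytest.mark.parametrize("b5, b6", [(0.0, 0.1), (-0.1, 0.1), (0.1, -0.06)])
    def test_degenerate_covariance_rejected(self, b5, b6):
        with pytest.raises(DegenerateCovarianceError):
            omega_inverse_logdet(self._coeffs(b5, b6), 2)


class TestJointLogPdf:
    def test_value_at_mode(self, params_n3):
        tau, x0 = 0.5, np.full(3, -5.0)
        c = wei_norman_coefficients(params_n3, tau)
        mode = conditional_mean(params_n3, c, x0)
        _, _, logdet = omega_inverse_logdet(c, 3)
        expected = -1.5 * np.log(4 * np.pi) - 0.5 * logdet
        assert joint_log_pdf(params_n3, mode, x0, tau) == pytest.approx(expected)

    def test_no_inhibition_factorizes_into_scalar_ou(self, rng):
        # beta = 0: joint log-density is the sum of independent scalar OU
        # log transition densities, to 1e-10 in log space
        p = ModelParams(kappa=4.0, beta=0.0, inputs=(0.9, 1.1), xi=0.25)
        tau = 0.31
        for _ in range(20):
            x0 = rng.normal(scale=2, size=2)
            x = rng.normal(scale=2, size=2)
            expected = sum(
                scalar_ou_logpdf(
                    x[i], x0[i], tau, rate=4.0, level=p.inputs[i] / 4.0, sigma=0.25
                )
                for i in range(2)
            )
            assert joint_log_pdf(p, x, x0, tau) == pytest.approx(expected, abs=1e-10)

    def test_quadrature_normalization(self, params_n2):
        tau, x0 = 0.5, np.array([-5.0, -5.0])
        tr = transition(params_n2, x0, tau)
        sd = np.sqrt(tr.var_diag)
        lo, hi = tr.mean - 8 * sd, tr.mean + 8 * sd
        total, err = dblquad(
            lambda y, x: np.exp(joint_log_pdf(params_n2, np.array([x, y]), x0, tau)),
            lo[0],
            hi[0],
            lo[1],
            hi[1],
            epsabs=1e-9,
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_difference_process_is_scalar_ou(self, params_n2):
        # for two alternatives, x1 - x2 reverts at rate kappa-beta toward
        # (I1-I2)/(kappa-beta) with noise sqrt(2)*xi
        tau, x0 = 0.8, np.array([-5.0, -4.0])
        tr = transition(params_n2, x0, tau)
        diff_mean = tr.mean[0] - tr.mean[1]
        diff_var = 2 * (tr.var_diag - tr.cov_off)
        c = wei_norman_coefficients(params_n2, tau)
        assert diff_var == pytest.approx(4 * c.b5, rel=1e-12)
        rate = params_n2.kappa - params_n2.beta
        ou_mean, ou_var = scalar_ou_mean_var(
            x0[0] - x0[1],
            tau,
            rate=rate,
            level=(params_n2.inputs[0] - params_n2.inputs[1]) / rate,
            sigma=np.sqrt(2) * params_n2.xi,
        )
        assert diff_mean == pytest.approx(ou_mean, abs=1e-10)
        assert diff_var == pytest.approx(ou_var, abs=1e-10)

    @given(seed=st.integers(0, 10_000))
    def test_permutation_equivariance(self, seed):
        # permuting (I_i, x_0i, x_i) jointly leaves the density unchanged
        rng = np.random.default_rng(seed)
        p = ModelParams(kappa=4.0, beta=1.0, inputs=rng.normal(1, 0.3, 4), xi=0.25)
        x0, x = rng.normal(size=4), rng.normal(size=4)
        perm = rng.permutation(4)
        p_perm = ModelParams(kappa=4.0, beta=1.0, inputs=p.inputs[perm], xi=0.25)
        base = joint_log_pdf(p, x, x0, 0.5)
        assert joint_log_pdf(p_perm, x[perm], x0[perm], 0.5) == pytest.approx(
            base, rel=1e-12
        )

    def test_zero_and_negative_lag_rejected(self, params_n2):
        x = np.zeros(2)
        with pytest.raises(DegenerateCovarianceError):
            joint_log_pdf(params_n2, x, x, 0.0)
        with pytest.raises(DomainError):
            joint_log_pdf(params_n2, x, x, -0.5)


class TestMarginalPdf:
    def test_peak_value(self, params_n3):
        tau, x0 = 0.5, np.full(3, -5.0)
        c = wei_norman_coefficients(params_n3, tau)
        mode = conditional_mean(params_n3, c, x0)
        expected = 1 / np.sqrt(4 * np.pi * (c.b5 + c.b6))
        assert marginal_pdf(params_n3, 1, mode[1], x0, tau) == pytest.approx(expected)

    def test_matches_numerical_marginalization_n2(self, params_n2):
        # closed-form marginal vs integrating the joint over the other
        # coordinate (quadrature oracle)
        tau, x0 = 0.5, np.array([-5.0, -4.5])
        tr = transition(params_n2, x0, tau)
        sd = np.sqrt(tr.var_diag)
        for x1 in tr.mean[0] + np.array([-2.0, 0.0, 1.0]) * sd:
            numeric, _ = quad(
                lambda y: np.exp(joint_log_pdf(params_n2, np.array([x1, y]), x0, tau)),
                tr.mean[1] - 9 * sd,
                tr.mean[1] + 9 * sd,
                epsabs=1e-10,
            )
            assert marginal_pdf(params_n2, 0, x1, x0, tau) == pytest.approx(
                numeric, abs=1e-6
            )

    def test_matches_numerical_marginalization_n3(self, params_n3):
        tau, x0 = 0.4, np.array([-5.0, -4.5, -4.0])
        tr = transition(params_n3, x0, tau)
        sd = np.sqrt(tr.var_diag)
        lo, hi = tr.mean - 8 * sd, tr.mean + 8 * sd
        x2 = tr.mean[2] + 0.5 * sd
        numeric, _ = dblquad(
            lambda y, x: np.exp(
                joint_log_pdf(params_n3, np.array([x, y, x2]), x0, tau)
            ),
            lo[0],
            hi[0],
            lo[1],
            hi[1],
            epsabs=1e-9,
        )
        assert marginal_pdf(params_n3, 2, x2, x0, tau) == pytest.approx(
            numeric, abs=1e-6
        )

    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_normalizes_to_one(self, n):
        p = ModelParams(kappa=4.0, beta=1.0, inputs=np.linspace(0.5, 1.2, n), xi=0.25)
        tau, x0 = 0.5, np.full(n, -5.0)
        c = wei_norman_coefficients(p, tau)
        mean_i = conditional_mean(p, c, x0)[0]
        sd = np.sqrt(2 * (c.b5 + c.b6))
        total, _ = quad(
            lambda x: marginal_pdf(p, 0, x, x0, tau),
            mean_i - 10 * sd,
            mean_i + 10 * sd,
            epsabs=1e-10,
        )
        assert total == pytest.approx(1.0, abs=1e-6)


class TestEvidenceTransform:
    def test_reference_points(self):
        assert log_to_evidence(0.0) == pytest.approx(1.0)
        # the protocol's initial log-evidence of -5 is evidence e^-5
        assert log_to_evidence(-5.0) == pytest.approx(np.exp(-5), rel=1e-12)

    def test_round_trip(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(
            evidence_to_log(log_to_evidence(x)), x, rtol=1e-12, atol=1e-14
        )
        assert np.all(log_to_evidence(x) > 0)

    def test_nonpositive_evidence_rejected(self):
        with pytest.raises(DomainError):
            evidence_to_log(np.array([1.0, 0.0]))
        with pytest.raises(DomainError):
            evidence_to_log(np.array([-0.5]))
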