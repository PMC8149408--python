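"""Closed-form transition density of the Gompertz-modified LCA model.

For the log-evidence process ``x`` the transition density over a lag ``tau``
is an N-dimensional Gaussian.  Its mean and covariance are expressed through
six scalar coefficients ``b1(tau) .. b6(tau)`` obtained by disentangling the
propagator of the backward Kolmogorov equation (Wei-Norman product form of
the Lie-algebra exponential).  The covariance is compound symmetric,

    Cov = 2 * Omega,    Omega_ij = b5 * delta_ij + b6,

which admits an O(N) inverse and determinant via the rank-one (Sherman-
Morrison) identity; the joint log-density never materialises the N x N
matrix.

Two rate combinations control everything: the contrast rate ``kappa - beta``
(relaxation of differences between accumulators) and the collective rate
``kappa + beta*(N-1)`` (relaxation of the mean).  Both appear in denominators
of ``(exp(a*tau)-1)/a`` type factors whose singularities at ``a -> 0`` are
removable; near zero they are evaluated by series expansion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateCovarianceError, DimensionError, DomainError
from .params import ModelParams

__all__ = [
    "WeiNormanCoefficients",
    "GaussianTransition",
    "wei_norman_coefficients",
    "conditional_mean",
    "omega_inverse_logdet",
    "transition",
    "joint_log_pdf",
    "marginal_pdf",
    "log_to_evidence",
    "evidence_to_log",
]

# below this |rate| the (exp(a*tau)-1)/a factors switch to a 3rd-order series
_SERIES_SWITCH = 1e-6


def _expm1_over(a: float, tau: float) -> float:
    """(exp(a*tau) - 1) / a, continuous through a = 0."""
    if abs(a) < _SERIES_SWITCH:
        u = a * tau
        return tau * (1.0 + u / 2.0 + u * u / 6.0 + u * u * u / 24.0)
    return np.expm1(a * tau) / a


def _one_minus_exp_neg2_over(a: float, tau: float) -> float:
    """(1 - exp(-2*a*tau)) / a, continuous through a = 0 (limit 2*tau)."""
    if abs(a) < _SERIES_SWITCH:
        u = 2.0 * a * tau
        return 2.0 * tau * (1.0 - u / 2.0 + u * u / 6.0 - u * u * u / 24.0)
    return -np.expm1(-2.0 * a * tau) / a


@dataclass(frozen=True)
class WeiNormanCoefficients:
    """The six lag-dependent coefficients of the disentangled propagator.

    ``b1`` (time) and ``b2`` (evidence) build the deterministic part of the
    transition mean, ``b3``/``b4`` (dimensionless) are the contrast and
    inhibition decay exponents, and ``b5``/``b6`` (evidence^2) build the
    compound-symmetric covariance.  All six vanish at ``tau = 0``.
    """

    tau: float
    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    b6: float


def wei_norman_coefficients(params: ModelParams, tau: float) -> WeiNormanCoefficients:
    """Evaluate b1(tau) .. b6(tau) for the given parameters.

    With contrast rate ``c = kappa - beta`` and collective rate
    ``g = kappa + beta*(N-1)``:

        b1 = (e^{c tau} - 1) / c
        b2 = Ibar (e^{g tau} - 1) / g
        b3 = -c tau,   b4 = -beta tau
        b5 = xi^2/4 * (1 - e^{-2 c tau}) / c
        b6 = xi^2/(4N) * [ (1 - e^{-2 g tau})/g - (1 - e^{-2 c tau})/c ]

    The ``c -> 0`` and ``g -> 0`` singularities are removable and handled by
    series expansion, so the result is continuous in all parameters.
    """
    tau = float(tau)
    if not np.isfinite(tau) or tau < 0:
        raise DomainError(f"tau must be finite and >= 0, got {tau}")
    n = params.n
    c = params.kappa - params.beta
    g = params.kappa + params.beta * (n - 1)
    xi2_4 = 0.25 * params.xi**2

    fc = _one_minus_exp_neg2_over(c, tau)
    fg = _one_minus_exp_neg2_over(g, tau)
    return WeiNormanCoefficients(
        tau=tau,
        b1=_expm1_over(c, tau),
        b2=params.mean_input * _expm1_over(g, tau),
        b3=-c * tau,
        b4=-params.beta * tau,
        b5=xi2_4 * fc,
        b6=(xi2_4 / n) * (fg - fc),
    )


def conditional_mean(
    params: ModelParams, coeffs: WeiNormanCoefficients, x0: np.ndarray
) -> np.ndarray:
    """Conditional mean of x(tau) given x(0) = x0.

    Component i:

        X_i0 = [x_i0 + b2 e^{N b4} + b1 dI_i + ((e^{N b4} - 1)/N) sum_j x_j0] e^{b3}
    """
    x0 = np.asarray(x0, dtype=float)
    n = params.n
    if x0.shape != (n,):
        raise DimensionError(f"x0 must have shape ({n},), got {x0.shape}")
    e_nb4 = np.exp(n * coeffs.b4)
    shift = coeffs.b2 * e_nb4 + (e_nb4 - 1.0) / n * x0.sum()
    return (x0 + shift + coeffs.b1 * params.delta_inputs) * np.exp(coeffs.b3)


def omega_inverse_logdet(
    coeffs: WeiNormanCoefficients, n: int
) -> tuple[float, float, float]:
    """Closed-form inverse and log-determinant of Omega = b5*I + b6*J.

    Returns ``(inv_diag, inv_off, logdet)`` where Omega^-1 has diagonal
    entries ``inv_diag`` and off-diagonal entries ``inv_off`` (Sherman-
    Morrison rank-one update), and ``logdet = log det Omega`` with
    ``det Omega = b5^{N-1} (b5 + N b6)``.

    Raises
    ------
    DegenerateCovarianceError
        If Omega is not positive definite (eigenvalues ``b5`` and
        ``b5 + N b6`` must both be positive); signals tau too small / zero
        or invalid parameters.
    """
    b5, b6 = coeffs.b5, coeffs.b6
    tail = b5 + n * b6
    if b5 <= 0 or tail <= 0:
        raise DegenerateCovarianceError(
            f"Omega not positive definite (b5={b5:g}, b5+N*b6={tail:g}); "
            "tau may be zero/too small or parameters invalid"
        )
    correction = b6 / (b5 * tail)
    inv_diag = 1.0 / b5 - correction
    inv_off = -correction
    logdet = (n - 1) * np.log(b5) + np.log(tail)
    return inv_diag, inv_off, float(logdet)


@dataclass(frozen=True)
class GaussianTransition:
    """Gaussian transition law of x(tau) | x(0): mean and compound-symmetric
    covariance ``2*Omega`` with per-component variance ``2*(b5+b6)`` and
    pairwise covariance ``2*b6``."""

    mean: np.ndarray
    var_diag: float
    cov_off: float
    n: int

    def covariance_matrix(self) -> np.ndarray:
        """Materialise the dense N x N covariance (for diagnostics/tests)."""
        cov = np.full((self.n, self.n), self.cov_off)
        np.fill_diagonal(cov, self.var_diag)
        return cov


def transition(params: ModelParams, x0: np.ndarray, tau: float) -> GaussianTransition:
    """Full transition law (mean and covariance structure) over lag tau > 0."""
    if tau <= 0:
        raise DegenerateCovarianceError(
            f"transition law requires tau > 0 (got {tau}); at tau = 0 the "
            "density degenerates to a product of delta functions"
        )
    coeffs = wei_norman_coefficients(params, tau)
    mean = conditional_mean(params, coeffs, x0)
    return GaussianTransition(
        mean=mean,
        var_diag=2.0 * (coeffs.b5 + coeffs.b6),
        cov_off=2.0 * coeffs.b6,
        n=params.n,
    )


def joint_log_pdf(
    params: ModelParams, x: np.ndarray, x0: np.ndarray, tau: float
) -> float:
    """Log of the joint transition density P(x, tau | x0).

        log P = -(N/2) log(4 pi) - (1/2) log det Omega
                - (1/4) sum_ij (X_i0 - x_i) (Omega^-1)_ij (X_j0 - x_j)

    Evaluated entirely in log space with the O(N) compound-symmetric
    quadratic form.
    """
    if tau < 0:
        raise DomainError(f"tau must be positive, got {tau}")
    if tau == 0:
        raise DegenerateCovarianceError(
            "tau = 0: the transition density is a product of delta functions"
        )
    x = np.asarray(x, dtype=float)
    n = params.n
    if x.shape != (n,):
        raise DimensionError(f"x must have shape ({n},), got {x.shape}")
    coeffs = wei_norman_coefficients(params, tau)
    mean = conditional_mean(params, coeffs, x0)
    inv_diag, inv_off, logdet = omega_inverse_logdet(coeffs, n)
    d = mean - x
    # d' Omega^-1 d  with  Omega^-1 = (inv_diag - inv_off) I + inv_off J
    quad = (inv_diag - inv_off) * float(d @ d) + inv_off * float(d.sum()) ** 2
    return float(-0.5 * n * np.log(4.0 * np.pi) - 0.5 * logdet - 0.25 * quad)


def marginal_pdf(
    params: ModelParams, i: int, x_i: float, x0: np.ndarray, tau: float
) -> float:
    """Marginal transition density of component ``i`` (0-based).

        p_i(x_i) = (4 pi (b5+b6))^{-1/2} exp{ -(X_i0 - x_i)^2 / (4 (b5+b6)) }

    i.e. a 1-D Gaussian with mean ``X_i0`` and variance ``2*(b5+b6)``.
    """
    if tau < 0:
        raise DomainError(f"tau must be positive, got {tau}")
    if tau == 0:
        raise DegenerateCovarianceError("tau = 0: the marginal is a delta function")
    n = params.n
    if not 0 <= i < n:
        raise DimensionError(f"component index must be in [0, {n}), got {i}")
    coeffs = wei_norman_coefficients(params, tau)
    s = coeffs.b5 + coeffs.b6
    if s <= 0:
        raise DegenerateCovarianceError(f"marginal variance 2*(b5+b6) = {2*s:g} <= 0")
    mean_i = conditional_mean(params, coeffs, x0)[i]
    return float(
        np.exp(-((mean_i - x_i) ** 2) / (4.0 * s)) / np.sqrt(4.0 * np.pi * s)
    )


def log_to_evidence(x: np.ndarray) -> np.ndarray:
    """Map log-evidence x to evidence y = exp(x) (strictly positive)."""
    return np.exp(np.asarray(x, dtype=float))


def evidence_to_log(y: np.ndarray) -> np.ndarray:
    """Map evidence y > 0 back to log-evidence x = ln y."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise DomainError("evidence must be strictly positive componentwise")
    return np.log(y)
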