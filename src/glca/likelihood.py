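"""Exact Markov likelihood and maximum-likelihood calibration.

A simulated series is a discretely observed diffusion on a uniform grid, so
its likelihood is the product of one-step transition densities.  Because the
transition density is an exact closed-form Gaussian, no discretisation
approximation enters: the log-likelihood of a series x_0 .. x_{T-1} is

    sum_k log P(x_{k+1} | x_k; dt)

with the Wei-Norman coefficients evaluated once at the single lag dt.

The transition mean is affine in the previous state, X0 = A x_k + m with
A = e^{b3} (I + g J) compound symmetric, and the precision is compound
symmetric too.  The total quadratic form therefore depends on the series
only through a fixed set of second-order cross moments, which are computed
once per series; each likelihood evaluation afterwards costs O(N^2)
regardless of the series length.  This is what makes Nelder-Mead calibration
of 20 000-point series take milliseconds rather than minutes.

Calibration follows the iterated-restart rule: Nelder-Mead is re-run from
its own output until no parameter moves by more than ``restart_tol``
(default 1e-6) between successive runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .density import omega_inverse_logdet, wei_norman_coefficients
from .exceptions import (
    DimensionError,
    DomainError,
    InsufficientDataError,
    NonUniformGridError,
)
from .params import ModelParams

__all__ = [
    "TransitionStats",
    "transition_stats",
    "series_log_likelihood",
    "FitSettings",
    "FitResult",
    "AggregateResult",
    "auto_initial_params",
    "fit_mle",
    "aggregate_estimates",
]


@dataclass(frozen=True)
class TransitionStats:
    """Second-order cross moments of the (previous, next) state pairs of one
    series — the sufficient statistics of the Gaussian Markov likelihood."""

    m: int  # number of transitions (T - 1)
    n: int  # dimension N
    spp: np.ndarray  # (N, N)  sum_k p_k p_k'
    spq: np.ndarray  # (N, N)  sum_k p_k q_k'
    sum_p: np.ndarray  # (N,)
    sum_q: np.ndarray  # (N,)
    tr_qq: float  # sum_k |q_k|^2
    row_pp: float  # sum_k (1'p_k)^2
    row_pq: float  # sum_k (1'p_k)(1'q_k)
    row_qq: float  # sum_k (1'q_k)^2


def transition_stats(states: np.ndarray) -> TransitionStats:
    """Compute the likelihood sufficient statistics of one (T, N) series."""
    states = np.asarray(states, dtype=float)
    if states.ndim != 2 or states.shape[0] < 2:
        raise DimensionError(
            f"series must be a (T, N) array with T >= 2, got shape {states.shape}"
        )
    p, q = states[:-1], states[1:]
    sp, sq = p.sum(axis=1), q.sum(axis=1)
    return TransitionStats(
        m=p.shape[0],
        n=p.shape[1],
        spp=p.T @ p,
        spq=p.T @ q,
        sum_p=p.sum(axis=0),
        sum_q=q.sum(axis=0),
        tr_qq=float(np.einsum("ij,ij->", q, q)),
        row_pp=float(sp @ sp),
        row_pq=float(sp @ sq),
        row_qq=float(sq @ sq),
    )


def _loglik_from_stats(params: ModelParams, dt: float, stats: TransitionStats) -> float:
    """Exact Markov log-likelihood from precomputed sufficient statistics."""
    n, m = stats.n, stats.m
    if n != params.n:
        raise DimensionError(f"series dimension {n} != model dimension {params.n}")
    coeffs = wei_norman_coefficients(params, dt)
    inv_diag, inv_off, logdet = omega_inverse_logdet(coeffs, n)
    u, v = inv_diag - inv_off, inv_off  # Omega^-1 = u I + v J

    e3 = np.exp(coeffs.b3)
    e_nb4 = np.exp(n * coeffs.b4)
    g = (e_nb4 - 1.0) / n  # A = e3 (I + g J)
    mvec = e3 * (coeffs.b2 * e_nb4 + coeffs.b1 * params.delta_inputs)
    c0 = float(mvec.sum())  # = e3 * N * b2 * e^{N b4}
    alpha = e3 * e_nb4  # 1'A = alpha 1'

    sum_sp = float(stats.sum_p.sum())
    sum_sq = float(stats.sum_q.sum())

    # sum_k |A p_k + mvec - q_k|^2
    trace_term = (
        e3**2 * (np.trace(stats.spp) + (2.0 * g + n * g * g) * stats.row_pp)
        + 2.0 * e3 * (float(mvec @ stats.sum_p) + g * c0 * sum_sp)
        - 2.0 * e3 * (np.trace(stats.spq) + g * stats.row_pq)
        + m * float(mvec @ mvec)
        - 2.0 * float(mvec @ stats.sum_q)
        + stats.tr_qq
    )
    # sum_k (1'(A p_k + mvec - q_k))^2 = sum_k (alpha sp_k + c0 - sq_k)^2
    row_term = (
        alpha**2 * stats.row_pp
        + m * c0**2
        + stats.row_qq
        + 2.0 * alpha * c0 * sum_sp
        - 2.0 * alpha * stats.row_pq
        - 2.0 * c0 * sum_sq
    )
    quad = u * trace_term + v * row_term
    return float(-0.5 * m * n * np.log(4.0 * np.pi) - 0.5 * m * logdet - 0.25 * quad)


def _validate_grid(times: np.ndarray) -> float:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise DimensionError("times must be a 1-D array with at least 2 entries")
    diffs = np.diff(times)
    dt = float(diffs[0])
    if dt <= 0 or not np.allclose(diffs, dt, rtol=1e-6, atol=1e-12):
        raise NonUniformGridError(
            "time grid must be uniform and strictly increasing; the single-lag "
            "likelihood is undefined otherwise"
        )
    return dt


def series_log_likelihood(
    params: ModelParams,
    states: np.ndarray,
    dt: float | None = None,
    *,
    times: np.ndarray | None = None,
) -> float:
    """Exact log-likelihood of one observed series under the model.

    Parameters
    ----------
    params : ModelParams
    states : (T, N) array
        Log-evidence trajectory sampled on a uniform grid.
    dt : float, optional
        Grid spacing; give either ``dt`` or ``times``.
    times : (T,) array, optional
        Explicit grid; validated for uniformity.
    """
    if times is not None:
        dt_from_times = _validate_grid(times)
        if dt is not None and not np.isclose(dt, dt_from_times):
            raise NonUniformGridError(
                f"dt={dt} inconsistent with time grid spacing {dt_from_times}"
            )
        dt = dt_from_times
    if dt is None:
        raise DomainError("either dt or times must be provided")
    if dt <= 0:
        raise DomainError(f"dt must be > 0, got {dt}")
    return _loglik_from_stats(params, dt, transition_stats(states))


@dataclass(frozen=True)
class FitSettings:
    """Controls for the Nelder-Mead maximum-likelihood calibration.

    ``init`` is either "auto" (moment-matched starting values from the
    series itself) or an explicit :class:`ModelParams`.  The optimizer is
    re-run from its own output until the largest absolute change over all
    natural parameters (kappa, beta, I, xi) between successive runs drops
    below ``restart_tol``.
    """

    init: ModelParams | str = "auto"
    restart_tol: float = 1e-6
    max_restarts: int = 50
    xatol: float = 1e-8
    fatol: float = 1e-7
    maxiter_per_run: int | None = None  # default: 400 * n_free_params

    def __post_init__(self):
        if self.restart_tol <= 0:
            raise DomainError("restart_tol must be > 0")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one per-series maximum-likelihood fit."""

    estimates: ModelParams | None
    loglik: float
    n_restarts: int
    converged: bool
    series_id: str | int | None = None
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "estimates": None if self.estimates is None else self.estimates.to_dict(),
            "loglik": self.loglik,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
            "series_id": self.series_id,
            "message": self.message,
        }


@dataclass(frozen=True)
class AggregateResult:
    """Across-series summary of per-parameter estimates.

    For each parameter: the sample mean over the M converged series, the
    standard error ``se`` (the sample standard deviation of the per-series
    estimates — the dispersion convention used in published recovery
    tables), the standard error of the mean ``se_mean = se / sqrt(M)``, and
    the z-score ``z = mean / se``.
    """

    names: tuple[str, ...]
    mean: np.ndarray
    se: np.ndarray
    se_mean: np.ndarray
    z: np.ndarray
    n_series: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"mean": self.mean, "se": self.se, "se_mean": self.se_mean, "z": self.z},
            index=list(self.names),
        )


def parameter_names(n: int) -> tuple[str, ...]:
    return ("kappa", "beta", *[f"I{i + 1}" for i in range(n)], "xi")


def auto_initial_params(states: np.ndarray, dt: float) -> ModelParams | None:
    """Moment-matched starting values from the series itself.

    Lag-1 regression of each coordinate on itself gives an effective
    relaxation rate (a proxy for kappa - beta), the residual variance gives
    xi, and the implied stationary means give the inputs.  beta starts at
    half the relaxation-rate scale (the data determine it during the fit).
    Returns None when the series is degenerate (no usable variance).
    """
    states = np.asarray(states, dtype=float)
    p, q = states[:-1], states[1:]
    var_p = p.var(axis=0)
    if np.any(var_p < 1e-12):
        return None
    rho = ((p - p.mean(axis=0)) * (q - q.mean(axis=0))).mean(axis=0) / var_p
    rho = np.clip(rho, 1e-6, 1.0 - 1e-8)
    lam = -np.log(rho) / dt  # per-coordinate effective rate
    resid = q - q.mean(axis=0) - rho * (p - p.mean(axis=0))
    resid_var = resid.var(axis=0)
    if np.all(resid_var < 1e-16):
        return None
    xi2 = np.mean(2.0 * lam * resid_var / np.clip(1.0 - rho**2, 1e-12, None))
    xi0 = float(np.sqrt(max(xi2, 1e-12)))
    lam_bar = float(lam.mean())
    beta0 = 0.5 * lam_bar
    kappa0 = lam_bar + beta0
    mu = states.mean(axis=0)  # long-run level proxy
    inputs0 = (kappa0 - beta0) * mu + beta0 * mu.sum()
    return ModelParams(kappa=kappa0, beta=beta0, inputs=inputs0, xi=xi0)


def _pack(params: ModelParams) -> np.ndarray:
    """(kappa, beta, I_1..I_N, log xi) — xi on the log scale for positivity."""
    return np.concatenate([[params.kappa, params.beta], params.inputs, [np.log(params.xi)]])


def _unpack(theta: np.ndarray) -> ModelParams:
    return ModelParams(kappa=theta[0], beta=theta[1], inputs=theta[2:-1], xi=np.exp(theta[-1]))


def fit_mle(
    states: np.ndarray,
    dt: float,
    settings: FitSettings = FitSettings(),
    series_id: str | int | None = None,
) -> FitResult:
    """Maximum-likelihood calibration of one series by iterated Nelder-Mead.

    The N + 3 free parameters (kappa, beta, I_1..I_N, log xi) maximise the
    exact Markov log-likelihood.  Each optimizer run starts from the
    previous run's output; the loop stops once the largest absolute change
    over all natural parameters is below ``settings.restart_tol``, or
    ``settings.max_restarts`` runs have been made (then ``converged`` is
    False).  A degenerate series (no variance) yields a non-converged
    result rather than an exception.
    """
    states = np.asarray(states, dtype=float)
    if dt <= 0:
        raise DomainError(f"dt must be > 0, got {dt}")
    stats = transition_stats(states)

    if isinstance(settings.init, ModelParams):
        init = settings.init
    elif settings.init == "auto":
        init = auto_initial_params(states, dt)
        if init is None:
            return FitResult(
                estimates=None,
                loglik=np.nan,
                n_restarts=0,
                converged=False,
                series_id=series_id,
                message="degenerate series: no usable variance for initialization",
            )
    else:
        raise DomainError(f"init must be 'auto' or ModelParams, got {settings.init!r}")

    def neg_loglik(theta: np.ndarray) -> float:
        with np.errstate(over="ignore", invalid="ignore"):
            try:
                ll = _loglik_from_stats(_unpack(theta), dt, stats)
            except (ValueError, FloatingPointError):
                return np.inf
        return np.inf if not np.isfinite(ll) else -ll

    theta = _pack(init)
    if not np.isfinite(neg_loglik(theta)):
        raise DomainError(
            "log-likelihood is not finite at the initial guess; supply a "
            "different init via FitSettings(init=...)"
        )

    maxiter = settings.maxiter_per_run or 400 * theta.size
    natural_prev = _unpack(theta).to_vector()
    n_runs = 0
    converged = False
    res = None
    while n_runs < settings.max_restarts:
        res = minimize(
            neg_loglik,
            theta,
            method="Nelder-Mead",
            options={
                "xatol": settings.xatol,
                "fatol": settings.fatol,
                "maxiter": maxiter,
                "maxfev": 2 * maxiter,
            },
        )
        n_runs += 1
        theta = res.x
        natural = _unpack(theta).to_vector()
        if n_runs > 1 and np.max(np.abs(natural - natural_prev)) < settings.restart_tol:
            converged = True
            break
        natural_prev = natural

    estimates = _unpack(theta)
    return FitResult(
        estimates=estimates,
        loglik=float(-res.fun),
        n_restarts=n_runs,
        converged=converged,
        series_id=series_id,
        message="" if converged else "restart rule not satisfied within max_restarts",
    )


def aggregate_estimates(results: list[FitResult]) -> AggregateResult:
    """Summarise converged per-series fits into mean / SE / z-score rows.

    SE is the sample standard deviation (one delta degree of freedom) of the
    per-series estimates and z = mean / SE, matching the convention of
    published recovery tables; the standard error of the mean, SE/sqrt(M),
    is also reported.  Parameters whose estimates are identical across
    series get SE = 0 and z = inf.
    """
    conv = [r for r in results if r.converged and r.estimates is not None]
    if len(conv) < 2:
        raise InsufficientDataError(
            f"need >= 2 converged fits to aggregate, got {len(conv)}"
        )
    n = conv[0].estimates.n
    if any(r.estimates.n != n for r in conv):
        raise DimensionError("all fits must share the same number of alternatives")
    mat = np.stack([r.estimates.to_vector() for r in conv])
    m = mat.shape[0]
    mean = mat.mean(axis=0)
    se = mat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, mean / se, np.inf * np.sign(mean))
    return AggregateResult(
        names=parameter_names(n),
        mean=mean,
        se=se,
        se_mean=se / np.sqrt(m),
        z=z,
        n_series=m,
    )
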