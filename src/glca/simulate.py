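"""Monte Carlo simulation of log-evidence trajectories.

The log-evidence process has linear drift and additive noise, so the strong
order-1.5 Taylor scheme needs only the drift, its (constant) Jacobian and
the pair of correlated Gaussian increments (dW, dZ) per component:

    x' = x + a dt + xi dW
         - 1/2 [ (kappa-beta) a_i + beta sum_j a_j ] dt^2
         - xi [ (kappa-beta) dZ_i + beta sum_j dZ_j ]

with drift a_i = I_i - (kappa-beta) x_i - beta sum_j x_j.  A plain
Euler-Maruyama scheme is included as an independent cross-validation oracle.

Noise is independent across components and across series.  Each series gets
its own child seed derived deterministically from the master seed, so any
single series can be regenerated bit-identically in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError, DomainError, SimulationDivergedError
from .params import ModelParams

__all__ = [
    "SimulationConfig",
    "SeriesSet",
    "drift",
    "draw_increments",
    "taylor15_step",
    "euler_step",
    "simulate_series",
]

#: a trajectory whose log-evidence leaves [-DIVERGENCE_BOUND, DIVERGENCE_BOUND]
#: is considered diverged (unstable parameter regime) and aborts loudly
DIVERGENCE_BOUND = 1e3

# cap on the noise buffer per simulation chunk (bytes); series are processed
# in chunks small enough to stay under it
_CHUNK_BYTES = 1 << 27


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol for one batch of simulated series.

    Defaults follow the reference protocol: step size 0.01, 20 000 points
    per series, every component started at log-evidence -5 (evidence
    e^-5 ~ 0.0067, i.e. close to zero), 128 independent series.
    """

    dt: float = 0.01
    n_steps: int = 20_000
    x0: float | np.ndarray = -5.0
    n_series: int = 128
    seed: int = 0
    scheme: str = "taylor15"

    def __post_init__(self):
        if self.dt <= 0:
            raise DomainError(f"dt must be > 0, got {self.dt}")
        if self.n_steps < 2:
            raise DomainError(f"n_steps must be >= 2, got {self.n_steps}")
        if self.n_series < 1:
            raise DomainError(f"n_series must be >= 1, got {self.n_series}")
        if self.scheme not in ("taylor15", "euler"):
            raise DomainError(f"unknown scheme {self.scheme!r}")

    def initial_state(self, n: int) -> np.ndarray:
        x0 = np.asarray(self.x0, dtype=float)
        if x0.ndim == 0:
            return np.full(n, float(x0))
        if x0.shape != (n,):
            raise DimensionError(f"x0 must be scalar or shape ({n},), got {x0.shape}")
        return x0.copy()

    def to_dict(self) -> dict:
        x0 = np.asarray(self.x0, dtype=float)
        return {
            "dt": self.dt,
            "n_steps": self.n_steps,
            "x0": float(x0) if x0.ndim == 0 else x0.tolist(),
            "n_series": self.n_series,
            "seed": self.seed,
            "scheme": self.scheme,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        x0 = d.get("x0", -5.0)
        return cls(
            dt=d["dt"],
            n_steps=d["n_steps"],
            x0=np.asarray(x0, dtype=float) if isinstance(x0, list) else float(x0),
            n_series=d.get("n_series", 1),
            seed=d.get("seed", 0),
            scheme=d.get("scheme", "taylor15"),
        )


@dataclass(frozen=True)
class SeriesSet:
    """A batch of simulated log-evidence trajectories on a shared uniform grid."""

    times: np.ndarray  # (n_steps,)
    states: np.ndarray  # (n_series, n_steps, N)
    params_used: ModelParams
    config_used: SimulationConfig
    seed_per_series: tuple[int, ...] = field(default=())

    @property
    def n_series(self) -> int:
        return self.states.shape[0]

    @property
    def n_steps(self) -> int:
        return self.states.shape[1]

    @property
    def n(self) -> int:
        return self.states.shape[2]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def series(self, i: int) -> np.ndarray:
        """The (n_steps, N) state array of series i."""
        return self.states[i]


def drift(params: ModelParams, x: np.ndarray) -> np.ndarray:
    """Drift vector a_i = I_i - (kappa-beta) x_i - beta sum_j x_j.

    The sum runs over all j including i; the self-inhibition term is
    compensated by the (kappa - beta) coefficient, so this is identical to
    the conventional form I_i - kappa x_i - beta sum_{j != i} x_j.
    Broadcasts over leading axes of ``x``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.n:
        raise DimensionError(f"x last axis must be {params.n}, got {x.shape}")
    kmb = params.kappa - params.beta
    return params.inputs - kmb * x - params.beta * x.sum(axis=-1, keepdims=True)


def draw_increments(
    n: int, dt: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the correlated Gaussian increment pair (dW, dZ) for one step.

        dW_i = U_i1 sqrt(dt)
        dZ_i = 1/2 dt^{3/2} (U_i1 + U_i2 / sqrt(3))

    with U_i1, U_i2 iid standard normal, so that E(dZ^2) = dt^3 / 3 and
    E(dZ dW) = dt^2 / 2, independently across components.
    """
    if dt <= 0:
        raise DomainError(f"dt must be > 0, got {dt}")
    u1 = rng.standard_normal(n)
    u2 = rng.standard_normal(n)
    dw = u1 * np.sqrt(dt)
    dz = 0.5 * dt**1.5 * (u1 + u2 / np.sqrt(3.0))
    return dw, dz


def taylor15_step(
    params: ModelParams,
    x: np.ndarray,
    dt: float,
    dw: np.ndarray,
    dz: np.ndarray,
) -> np.ndarray:
    """One strong order-1.5 Taylor step.  Broadcasts over leading axes."""
    x = np.asarray(x, dtype=float)
    a = drift(params, x)
    kmb = params.kappa - params.beta
    beta = params.beta
    corr_drift = kmb * a + beta * a.sum(axis=-1, keepdims=True)
    corr_noise = kmb * dz + beta * np.sum(dz, axis=-1, keepdims=True)
    return x + a * dt + params.xi * dw - 0.5 * corr_drift * dt**2 - params.xi * corr_noise


def euler_step(
    params: ModelParams, x: np.ndarray, dt: float, dw: np.ndarray
) -> np.ndarray:
    """One Euler-Maruyama step (order-0.5 cross-validation oracle)."""
    x = np.asarray(x, dtype=float)
    return x + drift(params, x) * dt + params.xi * dw


def _per_series_seeds(master_seed: int, n_series: int) -> tuple[int, ...]:
    """Deterministic child seeds, one per series (recorded for refits)."""
    root = np.random.SeedSequence(master_seed)
    return tuple(int(s) for s in root.generate_state(n_series, dtype=np.uint32))


def simulate_series(params: ModelParams, config: SimulationConfig) -> SeriesSet:
    """Simulate ``config.n_series`` independent trajectories.

    Every trajectory starts at ``config.x0``, has ``config.n_steps`` points
    (including the initial state) spaced ``config.dt`` apart, and draws its
    noise from its own child generator, so results are reproducible per
    series and independent of internal batching.

    Raises
    ------
    SimulationDivergedError
        If any |x| exceeds ``DIVERGENCE_BOUND`` (unstable kappa/beta
        regime), naming the offending series and step.
    """
    n = params.n
    n_steps, n_series, dt = config.n_steps, config.n_series, config.dt
    x0 = config.initial_state(n)
    seeds = _per_series_seeds(config.seed, n_series)

    times = np.arange(n_steps) * dt
    states = np.empty((n_series, n_steps, n))
    states[:, 0, :] = x0

    use_taylor = config.scheme == "taylor15"
    sqrt_dt = np.sqrt(dt)
    half_dt32 = 0.5 * dt**1.5
    inv_sqrt3 = 1.0 / np.sqrt(3.0)

    bytes_per_series = (n_steps - 1) * 2 * n * 8
    chunk = max(1, min(n_series, _CHUNK_BYTES // max(1, bytes_per_series)))

    for start in range(0, n_series, chunk):
        idx = range(start, min(start + chunk, n_series))
        # (m, n_steps-1, 2, n): per step, the first n draws are U1, then U2 —
        # the same stream order as repeated draw_increments calls
        u = np.stack(
            [
                np.random.default_rng(seeds[i]).standard_normal((n_steps - 1, 2, n))
                for i in idx
            ]
        )
        x = np.broadcast_to(x0, (len(idx), n)).copy()
        for k in range(n_steps - 1):
            dw = u[:, k, 0, :] * sqrt_dt
            if use_taylor:
                dz = half_dt32 * (u[:, k, 0, :] + inv_sqrt3 * u[:, k, 1, :])
                x = taylor15_step(params, x, dt, dw, dz)
            else:
                x = euler_step(params, x, dt, dw)
            bad = ~np.all(np.abs(x) <= DIVERGENCE_BOUND, axis=-1)
            if bad.any():
                raise SimulationDivergedError(
                    series_index=start + int(np.argmax(bad)),
                    step=k + 1,
                    bound=DIVERGENCE_BOUND,
                )
            states[start : start + len(idx), k + 1, :] = x

    return SeriesSet(
        times=times,
        states=states,
        params_used=params,
        config_used=config,
        seed_per_series=seeds,
    )
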