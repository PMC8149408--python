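"""Model parameters of the Gompertz-modified leaky competing accumulator.

The model describes ``N`` competing evidence accumulators.  Each accumulator's
evidence ``y_i`` follows a multivariate stochastic Gompertz law, so its
logarithm ``x_i = ln y_i`` obeys the coupled linear SDEs

    dx_i = (I_i - kappa * x_i - beta * sum_{j != i} x_j) dt + xi dW_i

with input ``I_i``, leakage rate ``kappa``, lateral inhibition ``beta`` and
additive noise amplitude ``xi``.  Working in ``x`` keeps the evidence ``y_i``
strictly positive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError, DomainError

__all__ = ["ModelParams"]


@dataclass(frozen=True, eq=False)
class ModelParams:
    """Full parameter vector of the N-alternative model.

    Parameters
    ----------
    kappa : float
        Leakage (decay) rate of each accumulator, in 1/time.
    beta : float
        Lateral inhibition rate exerted by every competitor, in 1/time.
    inputs : array-like of float
        External input ``I_i`` to each accumulator (evidence/time); its
        length fixes the number of alternatives ``N >= 2``.
    xi : float
        Diffusion coefficient of the additive noise (evidence/sqrt(time));
        must be strictly positive.
    """

    kappa: float
    beta: float
    inputs: np.ndarray
    xi: float
    n_alternatives: int = field(init=False)

    def __post_init__(self):
        inputs = np.asarray(self.inputs, dtype=float)
        if inputs.ndim != 1 or inputs.size < 2:
            raise DimensionError(
                f"inputs must be a 1-D vector with N >= 2 entries, got shape {inputs.shape}"
            )
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "n_alternatives", int(inputs.size))
        for name in ("kappa", "beta", "xi"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise DomainError(f"{name} must be finite, got {v}")
            object.__setattr__(self, name, v)
        if not np.all(np.isfinite(inputs)):
            raise DomainError("all inputs must be finite")
        if self.xi <= 0:
            raise DomainError(f"xi must be > 0, got {self.xi}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModelParams):
            return NotImplemented
        return (
            self.kappa == other.kappa
            and self.beta == other.beta
            and self.xi == other.xi
            and np.array_equal(self.inputs, other.inputs)
        )

    @property
    def n(self) -> int:
        """Number of alternatives N."""
        return self.n_alternatives

    @property
    def mean_input(self) -> float:
        """Average input across accumulators, Ibar = (1/N) sum_i I_i."""
        return float(np.mean(self.inputs))

    @property
    def delta_inputs(self) -> np.ndarray:
        """Input deviations dI_i = I_i - Ibar (sum to zero)."""
        return self.inputs - self.mean_input

    def to_vector(self) -> np.ndarray:
        """Flatten to (kappa, beta, I_1..I_N, xi)."""
        return np.concatenate([[self.kappa, self.beta], self.inputs, [self.xi]])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ModelParams":
        """Inverse of :meth:`to_vector`."""
        vec = np.asarray(vec, dtype=float)
        if vec.size < 5:
            raise DimensionError("parameter vector needs at least 5 entries (N >= 2)")
        return cls(kappa=vec[0], beta=vec[1], inputs=vec[2:-1], xi=vec[-1])

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "beta": self.beta,
            "inputs": self.inputs.tolist(),
            "xi": self.xi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(kappa=d["kappa"], beta=d["beta"], inputs=d["inputs"], xi=d["xi"])
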