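# glca — Gompertz-modified leaky competing accumulator toolkit

`glca` implements a multi-alternative evidence-accumulation model for
decision-making research in which the classic leaky competing accumulator
(LCA) is reformulated through the stochastic Gompertz law, so that the
evidence of every accumulator stays strictly positive and — crucially — the
model acquires an exact closed-form likelihood.  The package is aimed at
computational/cognitive neuroscientists and modellers who want to fit
multi-alternative accumulator models to trajectory data by maximum
likelihood instead of slow simulation-based approximations.

## The model

Each of the N alternatives carries an evidence level `y_i > 0`.  Its
logarithm `x_i = ln y_i` follows the coupled Itô SDEs

    dx_i = ( I_i − κ x_i − β Σ_{j≠i} x_j ) dt + ξ dW_i ,

with input `I_i`, leakage rate `κ`, lateral inhibition `β`, and additive
noise amplitude `ξ` on independent Wiener processes `W_i`.  Working with
`x = ln y` makes positivity of the evidence automatic, and the resulting
process is a coupled multivariate Ornstein–Uhlenbeck system whose transition
density over a lag `τ` is an N-dimensional Gaussian in closed form:

    P({x_i}; {x_i0}, τ) = (4π)^{−N/2} det(Ω)^{−1/2}
        exp{ −¼ Σ_ij (X_i0 − x_i) (Ω^{−1})_ij (X_j0 − x_j) } ,

where the conditional mean `X_i0` and the compound-symmetric matrix
`Ω_ij = b₅ δ_ij + b₆` are built from six lag-dependent coefficients
`b₁(τ) … b₆(τ)` obtained by disentangling the propagator of the backward
Kolmogorov equation (a Wei–Norman product form over the generators of the
underlying Lie algebra).  The covariance of the transition is `2Ω`, with
eigenstructure governed by the contrast rate `κ − β` and the collective rate
`κ + β(N−1)`; compound symmetry gives an O(N) inverse and determinant, so
likelihood evaluation never touches an N×N solve.

On top of the density the package provides

- an **order-1.5 strong Taylor simulator** of the log-evidence SDEs (with a
  plain Euler–Maruyama scheme as an independent cross-check),
- the **exact Markov likelihood** of a discretely observed series, evaluated
  through sufficient statistics so a 20 000-point likelihood costs O(N²)
  per evaluation after a single pass over the data,
- **Nelder–Mead maximum-likelihood calibration** with an iterated-restart
  convergence rule (re-run from the optimum until no parameter moves by
  more than 10⁻⁶),
- **parameter-recovery studies** for two, three and ten alternatives, with
  the published reference tables bundled for comparison.

A central scientific point: for two alternatives the conventional reduction
to the difference process `x₁ − x₂` is an OU process that only identifies
`κ − β`.  The full-likelihood fit of this model resolves leakage and
inhibition *separately* — the recovery study demonstrates exactly that.

## Worked example

```python
from glca import ModelParams, SimulationConfig, fit_mle, simulate_series

truth = ModelParams(kappa=4.0, beta=1.0, inputs=(0.9, 1.1), xi=0.25)
config = SimulationConfig(dt=0.01, n_steps=20_000, x0=-5.0, n_series=1, seed=42)
series_set = simulate_series(truth, config)
result = fit_mle(series_set.series(0), config.dt)
```

Running `python examples/fit_single_series.py` (the script around this
snippet) prints:

```
converged: True after 2 optimizer runs
log-likelihood at the optimum: 91512.66
 parameter     true   estimate
     kappa    4.000     4.0275
      beta    1.000     1.0347
        I1    0.900     0.9047
        I2    1.100     1.1036
        xi    0.250     0.2505
```

One 200-second series (20 000 points at Δt = 0.01, both accumulators
started at log-evidence −5, i.e. evidence ≈ 0.0067) pins every parameter to
a few percent, and κ and β are recovered individually.  The other scripts
in `examples/` walk through the closed-form density, the simulator-vs-
density cross-check, and a scaled-down recovery study; a thin CLI
(`glca simulate|fit|recover|pdf`) exposes the same operations on CSV files.

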