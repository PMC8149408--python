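"""Calibrate the model on one simulated series by maximum likelihood.

Simulates a single 20 000-point series from known parameters, then recovers
them by Nelder-Mead maximisation of the exact Markov likelihood with the
iterated-restart convergence rule.
"""

from glca import ModelParams, SimulationConfig, fit_mle, simulate_series

truth = ModelParams(kappa=4.0, beta=1.0, inputs=(0.9, 1.1), xi=0.25)
config = SimulationConfig(dt=0.01, n_steps=20_000, x0=-5.0, n_series=1, seed=42)

series_set = simulate_series(truth, config)
result = fit_mle(series_set.series(0), config.dt)

est = result.estimates
print(f"converged: {result.converged} after {result.n_restarts} optimizer runs")
print(f"log-likelihood at the optimum: {result.loglik:.2f}")
print(f"{'parameter':>10} {'true':>8} {'estimate':>10}")
for name, true, hat in [
    ("kappa", truth.kappa, est.kappa),
    ("beta", truth.beta, est.beta),
    ("I1", truth.inputs[0], est.inputs[0]),
    ("I2", truth.inputs[1], est.inputs[1]),
    ("xi", truth.xi, est.xi),
]:
    print(f"{name:>10} {true:>8.3f} {hat:>10.4f}")
print(
    "\nA single series already pins every parameter to a few percent; note "
    "that leakage (kappa) and inhibition (beta) are identified separately, "
    "which the two-alternative difference-process reduction cannot do."
)
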