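# Methods

## Model and transition density

The package models N-alternative evidence accumulation as a multivariate
stochastic Gompertz process.  Evidence `y_i` of accumulator `i` satisfies
`dy_i / y_i = (Ĩ_i − κ ln y_i − β Σ_{j≠i} ln y_j) dt + ξ dW_i`, so the
log-evidence `x_i = ln y_i` follows the linear system

    dx_i = ( I_i − κ x_i − β Σ_{j≠i} x_j ) dt + ξ dW_i .

All computation happens in x-space; `log_to_evidence`/`evidence_to_log`
map between the two representations and positivity of `y` is automatic.

The drift matrix `−[(κ−β) I + β J]` (J the all-ones matrix) has two
eigenvalues: the *contrast rate* `c = κ − β` on the (N−1)-dimensional space
of differences between accumulators, and the *collective rate*
`g = κ + β(N−1)` on the mean direction.  The transition density over a lag
τ is Gaussian with mean and covariance assembled from six coefficients
(`wei_norman_coefficients`):

    b1 = (e^{cτ} − 1)/c                 b2 = Ī (e^{gτ} − 1)/g
    b3 = −cτ                            b4 = −βτ
    b5 = ξ²/4 · (1 − e^{−2cτ})/c        b6 = ξ²/(4N) [ (1−e^{−2gτ})/g − (1−e^{−2cτ})/c ]

with `Ī` the mean input.  The conditional mean is
`X_i0 = [x_i0 + b2 e^{Nb4} + b1 ΔI_i + ((e^{Nb4}−1)/N) Σ_j x_j0] e^{b3}`
(`ΔI_i = I_i − Ī`), and the covariance is `2Ω` with
`Ω_ij = b5 δ_ij + b6` — note the density's quadratic form carries a ¼
factor, not ½, which is why the covariance is `2Ω` and not `Ω`; every
moment computation and every oracle in the test suite uses `2Ω`.

### Numerical choices

- **Removable singularities.**  `(e^{aτ}−1)/a`-type factors are evaluated
  with `expm1`; for `|a| < 10⁻⁶` (a = c or g) they switch to a 3rd-order
  series in `aτ`, making every coefficient continuous through κ = β and
  κ = −β(N−1).  The branch agreement is tested at `a = ±10⁻⁸` to 10⁻⁶
  relative.
- **Compound-symmetric linear algebra.**  `Ω⁻¹ = (1/b5)(I − b6/(b5+Nb6) J)`
  and `det Ω = b5^{N−1}(b5+Nb6)` (rank-one update identities), so the joint
  log-density is O(N) and the N×N matrix is never materialised on the hot
  path.  Densities are computed in log space throughout.
- **Positive-definiteness, not stationarity.**  For τ > 0 and ξ > 0 the
  functions `(1−e^{−2aτ})/a` are positive for *every real* a, so `b5 > 0`,
  `b5+b6 > 0` and `b5+Nb6 > 0` hold for any (κ, β) — the density (and hence
  the likelihood) is well defined even in non-stationary parameter regions
  the optimizer may traverse.  Only genuine degeneracy (τ = 0, or
  numerically zero covariance) raises `DegenerateCovarianceError`; a zero
  lag deliberately raises rather than returning a delta-function object.

## Simulator

Trajectories are generated by the strong order-1.5 Taylor scheme

    x' = x + a Δt + ξ ΔW − ½[(κ−β) a_i + β Σ_j a_j] Δt²
         − ξ[(κ−β) ΔZ_i + β Σ_j ΔZ_j] ,
    a_i = I_i − (κ−β) x_i − β Σ_j x_j ,
    ΔW_i = U_{i,1} √Δt ,   ΔZ_i = ½ Δt^{3/2} (U_{i,1} + U_{i,2}/√3) ,

with `U_{i,1}, U_{i,2}` iid standard normal, so `E(ΔZ²) = Δt³/3` and
`E(ΔZΔW) = Δt²/2`.  Because the noise is additive, the mixed
double-integral terms of a general order-1.5 scheme vanish and this update
is complete.  Noise is independent across components (the standard Wiener
assumption for the diagonal diffusion) and across series.

- **Seeding.**  A master seed generates one 32-bit child seed per series;
  each series draws from its own `numpy` Generator, so any series can be
  regenerated in isolation and results are independent of internal
  batching (series are processed in memory-bounded chunks, vectorised over
  series within a chunk).
- **Divergence guard.**  A series aborts with `SimulationDivergedError`
  (naming series and step) if any |x| exceeds 10³ — unstable (κ, β)
  combinations fail loudly instead of silently producing infinities.
- **Euler oracle.**  `scheme="euler"` runs plain Euler–Maruyama from the
  same per-series noise streams.  At Δt = 0.01 the Euler terminal mean
  carries a visible O(Δt) bias while the Taylor mean sits inside Monte
  Carlo error of the closed form, so the cross-validation tests compare
  each scheme's distance to the analytic moments (and assert the Taylor
  scheme is strictly closer) rather than demanding the two schemes agree
  within Monte Carlo error alone.  The terminal-mean bias is exactly the
  noise-free iteration error (the scheme is linear and the noise terms are
  mean-zero), which is how the step-halving convergence test is made
  deterministic.

## Likelihood and calibration

A simulated series is a discretely observed diffusion on a uniform grid,
so its exact log-likelihood is the Markov product
`Σ_k log P(x^{(k+1)} | x^{(k)}; Δt)` with the coefficients evaluated once
at the single lag Δt.  Because `X_0` is affine in the previous state with a
compound-symmetric structure (`A = e^{b3}(I + (e^{Nb4}−1)/N · J)`) and the
precision is compound symmetric, the total quadratic form depends on the
data only through a fixed set of second-order cross moments
(`transition_stats`).  These are computed once per series in O(T N²); each
subsequent likelihood evaluation is O(N²) regardless of series length.
The sufficient-statistic path is verified against a brute-force per-step
dense multivariate-normal evaluation to 10⁻⁸ on random series.

Calibration (`fit_mle`) maximises this likelihood over the N+3 free
parameters `(κ, β, I₁…I_N, log ξ)` — ξ on the log scale to keep it
positive; κ, β and the inputs are unconstrained — using Nelder–Mead with
`xatol = 10⁻⁸`, `fatol = 10⁻⁷`.  The optimizer is re-run from its own
output until the largest absolute change over the natural parameters
(κ, β, I, ξ) between successive runs is below 10⁻⁶, or 50 runs have been
made (then the fit is flagged non-converged; it never raises).  The inner
tolerances are deliberately tighter than the restart criterion so the loop
typically terminates after the second run.

- **"auto" initialisation.**  Lag-1 regression of each coordinate on
  itself gives an effective relaxation rate λ (a proxy for the contrast
  rate), the regression residual variance gives ξ via the OU stationary
  relation, and the empirical long-run levels are inverted through the
  drift to give the inputs; β starts at λ/2 and κ at 3λ/2.  Users can
  override with an explicit `ModelParams`.  A series with no usable
  variance returns a non-converged result.
- **Aggregation convention.**  For M converged per-series fits,
  `aggregate_estimates` reports the sample mean, the *across-series sample
  standard deviation* as the "standard error" (this is the dispersion
  convention of the published recovery tables — their printed z-scores
  equal calibrated mean / SD), the standard error of the mean SD/√M as a
  secondary field, and z = mean/SE.  Identical estimates across series
  give SE = 0 and an infinite-z marker.

## Recovery studies and the synthetic protocol

The built-in study cases generate data under the standard protocol: every
component starts at `x(0) = −5` (evidence e⁻⁵ ≈ 0.0067, emulating
near-zero initial evidence), Δt = 0.01, 20 000 points per series, 128
series per case, and

| case | κ | β | inputs | ξ |
|------|---|---|--------|---|
| N2  | 4 | 1 | 0.9, 1.1 | 0.25 |
| N3  | 4 | 1 | 0.9, 1.1, 0.98 | 0.25 |
| N10 | 4 | 1 | 0.9, 1.1, 0.95, 1.2, 0.5, 0.75, 0.8, 1, 1, 1 | 0.25 |

What the generator emulates — and does not: it produces trajectories of
the *model itself*, so passing recovery tests demonstrates internal
consistency (simulate → fit returns the truth) and estimator precision at
this design; it says nothing about behavioural realism, model
misspecification, decision thresholds or reaction times, none of which are
modelled here.

Problem sizes used by the test suite and `scripts/acceptance.py`: the two-
and three-alternative studies run at the full published scale (128 series ×
20 000 points); the ten-alternative study runs at 32 series, a quarter
scale chosen because across-series means are unbiased under subsampling
while the comparison tolerance is doubled accordingly; the
simulator-vs-density moment check uses 10⁴ trajectories.  The full 128-series
ten-alternative run is available via
`run_case(get_case("N10"), seed=...)` or `glca recover --case N10`.

## Known limitations

- The likelihood assumes uniformly sampled series (one shared lag);
  non-uniform grids are rejected rather than handled per-step.
- Standard errors are across-series dispersions; per-series observed-
  information (Hessian) standard errors are not computed.
- No decision-threshold/first-passage readout: the package models and fits
  the latent accumulation process only.
- Time-varying parameters are out of scope; all rates and inputs are
  constant within a series.
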