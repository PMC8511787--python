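# Methods

## Model

Given a uniformly sampled scalar signal `x(kΔt)`, `k = 0 … q−1`, the
delay embedding is the Hankel matrix `H[i, j] = x[(i+j)Δt]` of shape
`m × n`, `n = q − m + 1`, with `m ≪ n`. Centring subtracts the middle
delay row `h0` (row `(m−1)/2`; `m` must be odd) from every row. The
package always decomposes the *transpose* of the (centred) matrix,
`H̄ᵀ = V Σ Uᵀ`, so that `V` (`n × r`) holds the temporal coordinates
`v(t)` and `U` (`m × r`) the delay-direction modes.

Two views of the same data justify the structure of the fitted model.
Viewed column-wise, `H̄` is an m-dimensional trajectory over a long time
span — the usual delay-coordinate picture. Viewed row-wise, `H̄ᵀ` is an
n-dimensional trajectory `h(t)` over the *short* window `m·Δt`, which a
Taylor expansion about the centre row approximates as long as

```
m·Δt  ≪  2‖h0′‖/‖h0″‖  ≤  3‖h0″‖/‖h0‴‖  ≤  …
```

In that regime the temporal singular vectors converge to the
Frenet–Serret frame of `h(t)` (Gram–Schmidt on `h0′, h0″, …`), the
delay-direction modes to a family of discrete orthogonal polynomials,
and the generator of `v(t)` to `A = ‖h0′‖ K` with `K` antisymmetric
tridiagonal carrying the intrinsic curvatures `κ₁ … κ_{r−1}` on its
off-diagonals. Curvatures are therefore read off a fitted model as the
super-diagonal magnitudes of `K = A/‖h0′‖`, where `‖h0′‖` is the norm of
the finite-difference first derivative of the centre row. The
super-diagonal (not the sub-diagonal) is used because the single-SVD fit
reproduces the true curvatures markedly better there; for the split-SVD
fit the two are equal to high precision, so the choice is immaterial.

### Estimators

* **HAVOK** (single SVD): slice `V` into `V₁ = V[:−1]`, `V₂ = V[1:]`,
  solve `Â = V₂ᵀ(V₁ᵀ)⁺` by least squares, convert to continuous time at
  first order, `A = (Â − I)/Δt`. The slices are not orthonormal, which
  is exactly what degrades the structure on short records.
* **sHAVOK** (split SVD): split `H̄` into column-shifted halves, take two
  independent rank-r SVDs, sign-align the second temporal basis to the
  first (flip any column pair whose overlap is negative; a near-zero
  overlap is an error, since the modes are then not in correspondence),
  and set `A = (V₂ᵀV₁ − I)/Δt`. Both bases are orthonormal by
  construction. A forward difference is used for the derivative; a
  central-difference refinement exists but is out of scope.
* **Forced variants**: the state is the first `r−1` coordinates and the
  r-th acts as a scalar exogenous forcing, `v̇ = Av + Bv_r` with
  `A ∈ R^{(r−1)×(r−1)}`, `B ∈ R^{r−1}`; the regression simply keeps all
  r regressor coordinates and drops the last response row. Online, the
  forcing coordinate of a new length-m window is `σ_r⁻¹ u_rᵀ w̄` with the
  window centred on its middle sample.

The curvature oracle, used to validate fitted models, is the
generalized Frenet formula `κᵢ = D_{i+1}D_{i−1}/(Dᵢ²‖γ′‖)` with
`Dᵢ = √det(Gram(γ′ … γ⁽ⁱ⁾))`, `D₀ = 1`; for i = 1 it reduces to the
classical `‖γ′∧γ″‖/‖γ′‖³`.

## Parameters that matter

| parameter | meaning | default / guidance |
|---|---|---|
| `m` | delay count (Hankel rows), window `m·Δt` | user-chosen; no general rule exists. Must be odd for centring. The sampling check reports whether `m·Δt` is small against the first derivative ratio (margin 0.1 operationalises "much smaller"; configurable). |
| `r` | truncation rank = model dimension | user-chosen; `default_rank` suggests the count of σᵢ/σ₁ > 1e−8, which suits noise-free closed examples. Under measurement noise, keep only modes whose σᵢ/σ₁ sit above the noise floor. |
| `Δt` | sampling period (time units) | supplied by the user, never inferred from timestamp columns. Sparsely sampled records should be spline-resampled finer before embedding. |
| `centred` | subtract middle delay row | `true` (aligns modes with derivative directions; required for curvature extraction). |
| `closed` | no forcing channel | `false` by default (forced), the configuration recommended for real data; closed fits suit exactly low-rank signals. |

Units: `A` and `B` are 1/time; curvatures are 1/length in trajectory
space (the scale of `h0`); `‖h0′‖` is trajectory-length/time.

## Numerical choices

* SVD orientation is fixed (decompose `H̄ᵀ`); the per-mode sign
  ambiguity is removed by making the largest-magnitude entry of each `U`
  column positive, so runs are bit-reproducible. `align_bases` overrides
  this canon pairwise where two independent SVDs must be multiplied.
  Tied singular values keep the order the decomposition returns.
* Pseudo-inverses use an SVD cutoff of 1e−12·σ₁; a regressor condition
  number above 1e12, or a numerically zero retained singular value
  (e.g. a constant series after centring), is an error naming the mode.
* Discrete→continuous conversion is first order, `A = (Â − I)/Δt`; the
  matrix-logarithm path is available for spectra (`discrete_log`,
  ω = ln λ/Δt) and removes the O(Δt) bias Re ω ≈ −|ω|²Δt/2 that the
  first-order path leaves in eigenvalue real parts. The forcing vector
  converts as `B = B̂/Δt` (it has no identity to subtract).
* Derivatives are repeated second-order central differences
  (one-sided second-order stencils at the two ends). The spline
  resampler uses not-a-knot end conditions (reproduces cubics exactly)
  and never extrapolates past the final sample.
* `simulate_model` integrates with fixed-step RK4 at the model `Δt`,
  holding each forcing sample constant over its step (zero-order hold;
  no interpolation rule for the forcing is assumed).
* Degenerate inputs: derivative vectors whose Gram matrix is singular
  (straight-line trajectories) and windows of the wrong length are
  errors, not silently handled; curvature magnitudes are reported
  unsigned because the SVD sign ambiguity makes signed entries
  non-reproducible.

## Synthetic data

The generators reproduce the study conditions exactly and are fully
deterministic (identical specifications give bit-identical output):

* **Two-tone sinusoid** `x = sin t + sin 2t`, t ∈ [0, 10], Δt = 0.001
  (q = 10001; with m = 41 the centre grid is t = 0.02 … 9.98, n = 9961),
  with closed-form derivative vectors of every order (the signal solves
  `x⁗ + 5ẍ + 4x = 0`, so `h0⁽⁵⁾ = −5h0‴ − 4h0′`).
* **Lorenz-63** σ = 10, ρ = 28, β = 8/3; reference fixture 3000 samples
  at Δt = 0.001 from [−8, 8, 27]; long runs (60k–300k samples) for
  convergence and window suites.
* **Rössler** a = b = 0.1, c = 14 from (1, 1, 1); fixtures of 70k and
  300k samples at Δt = 0.001.
* **Double pendulum** point masses m at the ends of massless rods of
  length l (m = l = 1, g = 10), equations of motion derived from the
  Lagrangian by Euler–Lagrange; 1200 samples at Δt = 0.001 from
  θ₁ = θ₂ = π/2, θ̇₁ = −0.01, θ̇₂ = −0.005, observable sin θ₁.

All ODEs use fixed-step RK4. A variational integrator would preserve
energy structurally; RK4 was chosen for uniformity, and its adequacy is
checked by an energy-drift test (≈5e−10 absolute over the pendulum
fixture, against the scale mgl = 10) and a fourth-order convergence test
on Lorenz. Measurement noise, where a test calls for it, is additive
Gaussian scaled to the signal RMS with an explicit seed.

What the generators do *not* emulate: observation noise correlated in
time, irregular or missing sampling, drifting parameters, and the
distributed-mass physics of laboratory pendulums. Passing tests
therefore certify the estimators under ideal uniform sampling; on real
data the interpolation/smoothing step and the sampling check are the
user's responsibility (presets for two real-data layouts ship with the
CLI: pendulum m = 101, r = 5; measles m = 51, r = 6 with resampling to
Δt = 0.0018 years).

### Test-suite study conditions

Problem sizes were chosen so the whole suite runs in well under a minute
of CPU:

* The noise-robustness suite fits both estimators on 20 Lorenz records
  of 3000 samples from random initial conditions [−8, 8, 27] + N(0, 1)
  with 1% RMS measurement noise, at m = 201, r = 4 (forced). m follows
  the Lorenz delay count used for the interpolation study; r = 4 is the
  largest rank whose singular values sit above the 1% noise floor
  (σ₅/σ₁ ≈ 1.1% at this m). The split-SVD fit is expected to be more
  antisymmetric in ≥ 18 of 20 runs and in the median.
* The noise-free window suite draws 20 random 3000-sample windows of a
  60-time-unit trajectory at m = 41, r = 6.
* The parameter-recovery oracle builds an exactly linear trajectory
  rotating under a known 4×4 antisymmetric generator: two harmonic
  planes at whole-period frequencies 2π/140 and 4π/140 rad/time over
  1.4e6 samples at Δt = 1e−4, so the discrete trigonometric family is
  exactly orthonormal. The generator is deliberately slow because the
  first-order conversion biases the fit by G²Δt/2; at these frequencies
  that bias (≈6e−7 Frobenius) sits below the 1e−6 acceptance bound.
  Recovery is checked after removing the per-mode sign ambiguity
  against the known trajectory.
* Long-data convergence of the two estimators is checked on the
  sinusoid extended to t ∈ [0, 100] (1% Frobenius agreement).

## Known limitations

* The closed sHAVOK spectrum on the worked example has a frequency
  ratio of 2.16 rather than 2.00: the split fit prioritises the
  antisymmetric structure, and at m = 41 its curvature *products*
  (which set the eigenfrequencies) deviate slightly; the single-SVD
  fit pins the frequencies but not the structure. Spectrum-sensitive
  work should use the `discrete_log` eigenvalue path.
* Curvatures are constant-coefficient: time-varying curvature tracking
  along a long trajectory is out of scope, as are multivariate delay
  embeddings, randomized SVD backends and the rank-one SVD update that
  would accelerate the second decomposition.
* The singular-value-ratio curvature estimator (curvature from σᵢ₊₁/σᵢ
  alone) is not implemented; its scale constants could not be pinned
  down reliably, and the Gram-determinant oracle covers validation.
* Forecasting a chaotic signal through the fixed linear model degrades
  with horizon (R² ≈ 0.98 at 0.2 time units, ≈ 0.93 at 3 on the Lorenz
  fixture); the forcing channel must be supplied or held, not predicted.
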