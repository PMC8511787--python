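# shavok

Structured time-delay models (HAVOK / sHAVOK) of scalar time series, with
Frenet–Serret curvature extraction and structure diagnostics.

## The problem

Many systems — epidemic case counts, mechanical rigs, chaotic attractors —
are observed through a single scalar measurement `x(t)`. Stacking
time-shifted copies of the signal into a Hankel matrix

```
H[i, j] = x[(i + j) Δt],       H ∈ R^{m×n}
```

and taking an SVD yields *eigen-time-delay coordinates* `v(t)` (the
temporal factor `V`) on which a linear model with a scalar forcing term
can be regressed:

```
v̇(t) = A v(t) + B v_r(t)
```

(HAVOK: DMD on the delay coordinates). Empirically the fitted `A` is
antisymmetric and tridiagonal. This package implements the explanation
and the improved estimator built on it:

* **Frenet–Serret correspondence.** After *centring* (subtracting the
  middle delay row `h0`), the temporal singular vectors approximate the
  moving orthonormal frame obtained by Gram–Schmidt on the derivatives
  `h0′, h0″, …`, and the dynamics matrix satisfies `A = ‖h0′‖ K`, where
  `K` is the antisymmetric tridiagonal Frenet matrix whose off-diagonals
  are the intrinsic curvatures `κ₁ … κ_{r−1}`. The delay-direction
  singular vectors are a family of discrete orthogonal polynomials
  (Legendre-like; exactly Legendre without centring).
* **sHAVOK.** Slicing one SVD's `V` into time-shifted halves breaks
  their orthonormality, which blurs this structure on short or noisy
  records. The structured variant instead splits the Hankel matrix
  itself into column-shifted copies `H̄₁, H̄₂`, takes two independent
  rank-r SVDs (so both bases are exactly orthonormal) and sets
  `A = (V₂ᵀV₁ − I)/Δt`, recovering the antisymmetric tridiagonal form —
  and with it accurate curvatures and stable spectra — from far less data.
* **Diagnostics.** A sampling-adequacy check (`m·Δt` must be small
  against `2‖h0′‖/‖h0″‖`), cubic-spline resampling for sparsely sampled
  records, antisymmetry/tridiagonality indices, and a Gram-determinant
  curvature oracle `κᵢ = D_{i+1}D_{i−1}/(Dᵢ²‖γ′‖)` for validation
  against exact derivatives.

Simulators for the study systems (two-tone sinusoid with analytic
derivative closures, Lorenz-63, Rössler, a point-mass double pendulum)
generate every input internally.

## Worked example

`python examples/worked_sinusoid.py` runs the closed-form example
`x(t) = sin t + sin 2t` (t ∈ [0, 10], Δt = 0.001, m = 41, r = 4) and
prints:

```
Hankel embedding: 41 x 9961 (centred)
sampling check: window m*dt = 0.041, first derivative ratio = 1.073 -> pass

exact curvatures (Gram determinants on analytic derivatives):
  kappa = [0.012048 0.004457 0.006616]

HAVOK  super-diagonal |K| = [0.012047 0.004458 0.006617]
HAVOK  sub-diagonal   |K| = [0.012239 0.003467 0.007451]
HAVOK  antisymmetry index = 9.25e-02 (0 = exactly antisymmetric)

sHAVOK super-diagonal |K| = [0.012048 0.004458 0.006616]
sHAVOK sub-diagonal   |K| = [0.012048 0.004458 0.006616]
sHAVOK antisymmetry index = 9.36e-04 (0 = exactly antisymmetric)
```

The super-diagonal of the curvature-scale matrix `K = A/‖h0′‖` matches
the exact curvatures to about three decimal places for both fits; the
split-SVD fit additionally makes sub- and super-diagonal equal (the
model is antisymmetric to one part in a thousand).

The other scripts in `examples/` each demonstrate one capability:
short-data Lorenz structure, interpolation of sparsely sampled records,
forced-model forecasting, and the orthogonal-polynomial delay modes.

## Command line

A thin CLI wraps the same pipeline:

```sh
shavok simulate --system lorenz --dt 0.001 --steps 3000 --out-dir run/
shavok fit --input run/observable.csv --column x --dt 0.001 \
           --m 201 --r 4 --variant shavok --out-dir run/
shavok report --model run/model.json
```

Presets for real-world data layouts ship with the package
(`--preset pendulum`, `--preset measles`); the user supplies the data
file. Every run writes a `runlog.json` sufficient to re-execute it.

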