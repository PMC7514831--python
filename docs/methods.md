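# Methods

## Model and data reduction

Raw data are `X_{jl} ~ i.i.d. N(μ, σ²)`, `j = 1..J` within block
`l = 1..B`. Each block is multiplied by an `S × J` sensing matrix
`R^{(l)}` of i.i.d. nonnegative weights `R_{ij}` with `E[R] = 1`,
drawn independently per block. Only the triplets

- `ỹ_{il} = Σ_j R_{ij} X_{jl}`,
- `r_{il} = Σ_j R_{ij}`,
- `ω_{il} = (Σ_j R_{ij}²)^{1/2}`

are stored (channel `i`, block `l`); raw values and sensing matrices
are discarded. Conditional on the weights, the residual

```
U_{il}(μ) = (ỹ_{il} − μ · r_{il}) / ω_{il}
```

is exactly `N(0, σ²)` when `μ` is the true location — for any weight
distribution and any `J`. This conditional exactness is what makes
`(μ, σ)` estimable after non-invertible compression.

Weight families:

| family | weights | notes |
|---|---|---|
| `gaussian` | `N(1, γ₀²)` | `γ₀ = 0` collapses to `degenerate` |
| `gamma` | shape `1/v`, scale `v` | mean 1, variance `v` |
| `bernoulli` | `Bernoulli(p)`, default `p = S/J` | sparse selection |
| `degenerate` | all 1 | plain block sums (no privacy) |

For Bernoulli weights with small `p`, an all-zero row (`ω = 0`) is a
legitimate draw; such records are stored but carry no residual and are
skipped during estimation. Redrawing zero rows instead would condition
the weights on being nonzero, changing the marginal variance of the
stored values and measurably shifting the scale estimate; the
keep-zero-rows convention reproduces the reference Bernoulli
summaries.

## Estimation

For channel `i`, the parameter-dependent kernel density estimate of
the residuals is

```
g_B(y | μ) = (1 / (B_i h)) Σ_l K( (y − U_{il}(μ)) / h ),
```

with `B_i` the number of usable (ω > 0) records. The estimate of
`θ = (μ, σ)` maximizes the Hellinger affinity

```
A(θ) = ∫ sqrt( g_B(y | μ) · φ(y; 0, σ²) ) dy
```

— equivalently minimizes the squared Hellinger distance `2(1 − A)`.
With `S > 1` channels, each channel is fitted separately from a common
initializer and the estimates are averaged.

Kernels: `gaussian` and `epanechnikov` (`0.75(1 − u²)₊`).

### Bandwidth

`h = c_B · s_B` with `c_B = 0.3` by default and the robust scale

```
s_B = 1.48 · MAD(ỹ, pooled over channels and blocks) / B
```

for mean-1 weight families; for Bernoulli sensing the `/B` divisor is
dropped (the stored values are already on the single-observation
scale). The `1/B` divisor is a deliberate part of the procedure being
implemented: it ties the smoothing ratio `h/σ` to `√J / B`, so the
method is calibrated for designs with `√J ≈ B` (e.g. `J = 10⁴`,
`B = 100`). Designs far from that regime under- or over-smooth — see
Limitations.

### Initial values

- `μ₀ = median(ỹ)/J` and `σ₀ = 1.48·MAD(ỹ)/B` (Bernoulli: no
  divisors).
- A moment-based alternative `initial_sigma_moment` inverts the
  marginal-variance identity
  `Var(ỹ)/J = σ²(1 + γ₀²) + μ²γ₀²`, falling back to the MAD rule
  (with a warning) when the radicand is nonpositive.

### Optimization

A quasi-Newton BFGS iteration on `Ψ(θ) = −A(θ)`:

- inverse-Hessian form of the BFGS update, `H₀⁻¹ = I`, with a
  curvature guard (updates skipped when `sᵀy` is numerically tiny) and
  a steepest-descent reset if a direction fails to be descent;
- backtracking Armijo line search: accept step `t` when
  `Ψ(θ + t d) ≤ Ψ(θ) + ζ t ∇Ψᵀd`, else `t ← κ t`, with `ζ = 0.25`,
  `κ = 0.5`;
- gradients by central finite differences with step
  `10⁻⁵ · max(1, |θᵢ|)`;
- stop when `|ΔΨ| < 10⁻⁸` between accepted iterates, cap 200
  iterations;
- positivity of `σ` via a floor (default `10⁻⁴ · s_B`) enforced by
  rejecting infeasible trial points inside the line search.

The stopping threshold matters in small-`B` designs: loosening it to
`10⁻⁴` leaves the iteration near the (biased) initializer and changes
small-`B` scale summaries materially, so the tight default is part of
the method, not a tuning knob.

### Quadrature

The affinity integral uses the trapezoid rule on a grid of 1025 points
spanning the residual range padded by `6h` on both sides, union
`±8σ_hint`; the grid is rebuilt at every objective evaluation from the
current `μ`'s residuals with `σ_hint` the current `σ` candidate.

### Uncertainty

Wald intervals from the asymptotic variances

```
se(μ̂) = σ̂ / sqrt(B · J_eff),  J_eff = mean over records of (r/ω)²,
se(σ̂) = σ̂ / sqrt(2B).
```

`J_eff = J` exactly for degenerate sensing. The intervals refuse to
report when any channel failed to converge.

## Robustness

Two complementary views:

- **Empirical.** `contaminate` adds `η` to each stored `ỹ`
  independently with probability `α` (contamination acts on the
  compressed records, after compression). The finite-sample influence
  is `(θ̂(contaminated) − θ̂(clean))/α`.
- **Model-level.** The α-influence of the Hellinger functional `T` is
  `(T(f_mix) − θ)/α` with
  `f_mix = (1 − α) N(μ, σ²) + α · Uniform(z − ε, z + ε)`, `ε = 0.5`
  by default. `T(f_mix)` is computed with the same quasi-Newton
  machinery on the exact mixture density; the piecewise-smooth
  integrand is integrated segment-by-segment so the uniform
  component's jumps fall on panel boundaries, and the quadrature
  spacing is halved until the functional is stable.

The α-influence is bounded and redescending in the outlier location
`z`, while its `α → 0` limit equals the maximum-likelihood influence
`I(θ)⁻¹ ∫ η_z u` with components
`(z − μ, ((z − μ)² + ε²/3 − σ²)/(2σ))` — unbounded in `z`. Robustness
at fixed `α > 0` therefore coexists with full efficiency in the limit.

## Monte-Carlo engine

`simstudy.run_experiment` repeats simulate → compress → (contaminate)
→ estimate and reports per parameter the average (Ave), standard
deviation (StD) and mean squared error about the truth (MSE), the
latter two conventionally displayed ×10³. Variances use the
divisor-`n` convention so `MSE = StD² + bias²` holds as an exact
identity. Seeding is hierarchical: replicate `k` of an experiment with
seed `s` draws its raw-data, sensing and contamination streams from
independent children of `SeedSequence(s, spawn_key=(k,))`, so any
replicate is reproducible in isolation and experiments are
embarrassingly parallel in principle (the implementation runs them
serially). Replicates that raise are logged and excluded; more than 5%
failures aborts the experiment.

The named reference designs (`table2` … `table10`) all share
`J = 10⁴`, `B = 100`, `S = 1`, `c_B = 0.3`, Gaussian sensing with
`γ₀ = 0.1`, Gaussian kernel, truth `(2, 1)`, 500 replications — each
preset sweeps one knob (sensing noise, bandwidth, block count, weight
family, contamination, kernel).

## Preprocessing pipeline

For raw positive, heavy-tailed observations the `interface` module
provides the transformation chain used before compression: drop
non-positive values and keep natural logs in a window (default
`(6.1, 13.0)`), apply the scaled Box-Cox map `(L^λ − 1)/d` (defaults
`λ = 2`, `d = 19.9091`), then split randomly into `B` equal blocks
(leftovers dropped). The CLI command `cmhde pipeline` chains
preprocessing, compression and estimation with full seed logging.

## Scope of the generators

All simulation utilities draw raw data from the normal location–scale
model only; the estimator itself consumes any compressed-triplet
dataset regardless of origin. Contamination generators cover additive
gross errors on stored records (empirical) and uniform gross-error
mixtures (model-level); other contamination shapes are out of scope.

## Limitations

- The bandwidth rule's `1/B` divisor calibrates the method for
  `√J ≈ B`. Far outside that regime the KDE is under-smoothed
  (`√J ≪ B`) or over-smoothed (`√J ≫ B`), inflating the variance or
  the bias of `σ̂` respectively; the block-count and bandwidth sweeps
  in the test suite quantify the direction of these effects.
- `σ̂` carries finite-sample bias that grows with the sensing-weight
  variance and with `c_B`; `μ̂` is essentially unbiased across all
  exercised designs.
- Wald intervals rely on asymptotics in `B`; at small `B` (tens of
  blocks) they should not be trusted, and mild undercoverage is
  measurable in under-smoothed designs.
- The finite-difference BFGS assumes a smooth objective; with very few
  usable records (small `B`, or sparse Bernoulli sensing leaving few
  nonzero rows) the affinity surface is rough and individual channels
  may fail to converge (reported, and excluded from intervals).
- Contamination of the *raw* data before compression is not modelled;
  a single corrupted raw value perturbs its block's triplet only
  through the weighted sum, which is a milder (and design-dependent)
  effect than the stored-record contamination implemented here.
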