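# compressed-mhde

Robust estimation of a normal location–scale model from randomly
projected (compressed) data, using minimum Hellinger distance
estimation (MHDE).

## The problem

Suppose a large dataset of `n = J × B` values `X ~ N(μ, σ²)` is too big
to store, or too sensitive to keep in raw form. Split it into `B`
blocks of `J` values each and compress every block with a random
*sensing matrix* `R` of i.i.d. nonnegative weights with mean 1 — only
three numbers per retained channel survive per block:

```
ỹ = Σⱼ Rⱼ xⱼ        (the projected value)
r = Σⱼ Rⱼ           (the weight sum)
ω = sqrt(Σⱼ Rⱼ²)    (the weight norm)
```

The raw data are gone; the compression is not invertible. Yet
conditional on the weights, the centered and scaled residual
`U = (ỹ − μ·r)/ω` is *exactly* `N(0, σ²)`, so `(μ, σ)` remain fully
estimable from the `B` stored triplets.

The estimator is the minimum Hellinger distance estimator: build a
kernel density estimate `g_B(·| μ)` of the residuals (which depend on
the candidate `μ`), and choose `(μ, σ)` to maximize the Hellinger
affinity

```
A(θ) = ∫ sqrt( g_B(y | μ) · φ(y; 0, σ²) ) dy ,
```

equivalently to minimize the squared Hellinger distance
`HD² = 2(1 − A)`. MHDE is first-order efficient at the model yet robust
to gross errors: the influence of an outlier is bounded and
*redescending* — extreme corruption of the stored records barely moves
the fit.

Supported sensing-weight families: `gaussian` (N(1, γ₀²)), `gamma`
(mean 1, chosen variance), `bernoulli` (sparse 0/1 weights with
p = S/J by default), and `degenerate` (all weights 1, i.e. plain block
sums).

## Worked example

Python API — compress one million draws into 100 triplets, then fit:

```python
import numpy as np
from compressed_mhde import SensingSpec, compress_stream, estimate, confidence_interval

rng = np.random.default_rng(0)
blocks = rng.normal(2.0, 1.0, size=(100, 10_000))      # B=100 blocks of J=10^4
spec = SensingSpec.gaussian(0.1, S=1, J=10_000)        # weights ~ N(1, 0.01)
ds = compress_stream(blocks, spec, seed=1)             # keeps 100 triplets
fit = estimate(ds, kernel="gaussian", c_B=0.3)
print(fit.averaged)
print(confidence_interval(fit, ds))
```

prints

```
LocationScaleParams(mu=2.00099770333777, sigma=0.8883410636154121)
{'mu': (1.9992478946728585, 2.002747512002682), 'sigma': (0.7652255358762661, 1.0114565913545581)}
```

The same workflow on the command line (`cmhde` is installed as a
console script), including gross-error contamination of the stored
records:

```sh
cmhde simulate --mu 2 --sigma 1 -B 100 -J 10000 --gamma0 0.1 --seed 7 -o compressed.csv
cmhde estimate compressed.csv
#   "averaged": { "mu": 1.9993516173144048, "sigma": 1.0848938676467013 }
#   "ci": { "mu": [1.9972146816602268, 2.0014885529685826],
#           "sigma": [0.9345380116281936, 1.235249723665209] }

cmhde contaminate compressed.csv --alpha 0.2 --eta 1000 --seed 3 -o dirty.csv
cmhde estimate dirty.csv
#   "averaged": { "mu": 1.99992521112943, "sigma": 1.144742147559917 }
```

Shifting 20% of the stored records by 1000 moves the fit from
(1.999, 1.085) to (2.000, 1.145) — the location is untouched and the
scale inflates mildly, instead of exploding as a moment estimate would.

The model-level α-influence shows the redescending behaviour directly:

```sh
cmhde influence --mode model --alpha 0.1 --z 5
#   "influence": { "mu": 1.876..., "sigma": 2.022... }
cmhde influence --mode model --alpha 0.1 --z 52
#   "influence": { "mu": 0.0, "sigma": ~5.6e-10 }
```

An outlier near the bulk (z = 5) has influence of order one; a distant
one (z = 52) has essentially none.

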