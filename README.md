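# iriscap

**Capacity bounds for iris-texture biometrics via auto-regressive spectral
models.**

How many distinct irises can a recognition system tell apart, and how does
that number depend on image quality?  `iriscap` answers this by treating
each iris class as a stationary zero-mean Gaussian process: the texture of
a vectorized, Gabor-filtered iris image is fitted with an AR(p) model

```
X_t = Σ_{i=1..p} α_i X_{t−i} + η_t,    η_t ~ N(0, σ_η²),
```

whose power spectral density S(f) = σ_η² / |1 − Σ α_k e^{−j2πfk}|² is the
class signature.  Two classes m and k are compared through the asymptotic
(Whittle) log-likelihood ratio of their spectra,

```
Λ(m,k) = −Σ_i [ (1/S_m(f_i) − 1/S_k(f_i)) · Î(f_i) + ln(S_m(f_i)/S_k(f_i)) ],
```

with Î the average periodogram of the query images, and through its
expectation, the spectral relative entropy
d(m,k) = Σ_i [S_m/S_k − ln(S_m/S_k) − 1].

Pooling d (or Λ) over all cross-class pairs gives the **imposter
distribution**, which is well approximated by an Erlang density with
integer shape K and scale P — the distribution of a sum of K iid squared
complex Gaussians of variance P.  K and P, fitted by least squares on the
imposter histogram, define a space of length-K Gaussian codewords in which
two population bounds become elementary:

* **sphere packing** — with authentication noise of variance N per
  dimension, `M ≤ (1 + P/N)^{K/2}`;
* **enrollment (Daugman-like)** — with a minimum codeword distance τ and a
  tolerated collision probability δ,
  `M ≤ ln(1 − δ) / ln(1 − FMR(τ))`, FMR being the imposter cumulative.

The package implements the whole chain — preprocessing, Burg spectral
estimation with AIC order selection, exact and asymptotic likelihood
statistics, Erlang fitting, and both bounds — plus a synthetic cohort
generator so every stage can be exercised and validated without access to
proprietary iris databases.

## Who is this for

Researchers in biometric system evaluation who want principled,
data-quality-aware estimates of maximum population size from modest
datasets, and anyone studying Gaussian-process discrimination with Whittle
likelihoods.

## Worked example

```python
from iriscap import ImposterFit, sphere_packing_table
fit = ImposterFit(K=4, P=252.0, sse=0.0)   # interval-camera relative-entropy fit
print(sphere_packing_table(fit, noise_grid=[1, 10, 50, 100]).to_string(index=False))
```

```
 noise_variance        M_raw  M_reported
              1 64009.000000       64009
             10   686.440000         686
             50    36.481600          36
            100    12.390400          12
```

At near-noiseless quality (N = 1) the fitted codeword geometry supports
about 6.40×10⁴ distinguishable classes; by N = 100 the same dataset
supports only 12.  The enrollment bound behaves analogously in τ and δ —
see `examples/enrollment_bound.py`, which prints, e.g., a maximum
population of 2.43×10⁷ at τ = 1, δ = 0.001 for the same fit.

The `examples/` directory holds one short narrative script per capability:

| script | shows |
| --- | --- |
| `sphere_packing_bound.py` | capacity vs noise variance for a fitted (K, P) |
| `enrollment_bound.py` | capacity vs (τ, δ) under the unit-grid FMR convention |
| `pairwise_discrimination.py` | Whittle vs exact LLR, relative entropy, MC error rates |
| `preprocess_and_fit.py` | raster → Gabor → zigzag vector → AIC/Burg spectrum |
| `synthetic_cohort_pipeline.py` | full cohort → imposter fit → capacity tables |

A thin CLI mirrors the main entry points
(`iriscap capacity sphere --k 4 --p 252 --noise 1,10`,
`iriscap run-all --config config.yaml`, plus `simulate`, `preprocess`,
`fit-ar`, `enroll`, `score`, `fit-imposter`).

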