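# Methods

This note records the statistical model, the conventions the implementation
commits to, and what the synthetic validation does and does not establish.

## Model and assumptions

Each iris class is a zero-mean stationary Gaussian process; a finite
realization of length n (a vectorized, Gabor-filtered iris image) carries
the class's second-order signature.  The working parameterization is an
AR(p) model in regression form, X_t = Σ α_i X_{t−i} + η_t with white
Gaussian innovations.  Note a sign convention trap: many references and
toolboxes write the AR filter denominator as A(z) = 1 + Σ a_k z^{−k};
those a_k equal −α_i here.  `ARModel` stores α, and every polynomial-based
computation (roots, filtering, FFT of the denominator) converts internally.
Stationarity is enforced as all characteristic roots strictly inside the
unit circle (margin 1e−9).

Spectra are stored two-sided on the n-point DFT grid f_i = i/n, so the mean
of the samples equals the process variance r₀ (up to aliasing r_{ln}, which
is negligible once n is a few correlation lengths; tests use n = 2048 with
pole radii ≲ 0.95).

## Statistic scale convention

The per-frequency likelihood component and all derived quantities are
summed over the *full* two-sided grid i = 0..n−1.  For a real process the
conjugate pairs are counted twice, so Λ, the exact matrix LLR, and the
relative entropy d are all **twice** the natural-log LLR / KL divergence of
the underlying real Gaussian vector.  This is deliberate: it keeps Λ, d,
the Erlang component law, the imposter fits, and the τ axis of the
enrollment bound on a single consistent scale.  `exact_gaussian_llr`
is therefore defined as −(1/N) Σ_j y_jᵀ(K_m⁻¹−K_k⁻¹)y_j − ln det(K_m K_k⁻¹)
(no ½ factors), which matches the Whittle statistic asymptotically; tests
that cross-check d against the textbook matrix KL formula multiply the
latter by two.  Decisions are invariant to the common scale.

The periodogram is |DFT(x)_i|²/n, which makes E[I(f_i)] = S(f_i) under this
PSD convention — the scaling the asymptotic statistic leaves implicit.
Spectra entering ratio computations are clipped below at 1e−12 × their
maximum (clipping events are logged) to keep estimated near-zero PSD values
from blowing up the ratio terms.

## Preprocessing

The Gabor kernel is a 2-D complex filter: isotropic Gaussian envelope of
standard deviation σ/f₀ pixels, horizontal (angular-direction) modulation
at f₀ cycles/pixel, truncated at ±3 envelope SDs, applied by
reflect-padded convolution.  Defaults f₀ = 1/9, σ = 0.5 follow standard
iris-encoding practice; σ is interpreted as a fraction of the wavelength
1/f₀, a documented choice since envelope-unit conventions vary across the
literature.  The kernel is DC-compensated (a scaled envelope is subtracted
so it integrates to zero), making the response to constant images vanish.

Only the ⌈H/2⌉ rows adjacent to the pupil edge are kept (iris texture
concentrates radially near the pupil); which edge is the pupil is explicit
configuration because unwrapping conventions differ.  Real and imaginary
parts are each flattened by a JPEG-style zigzag scan (reduces
raster-direction periodicity in the spectrum), concatenated, and the
overall mean is removed once, after concatenation.

## Spectral estimation and order selection

Burg's lattice recursion (harmonic-mean reflection-coefficient update, no
windowing, prediction-error power initialised at Σx²/n) estimates the AR
model; |k_m| < 1 by construction guarantees stability.  The per-order
residual powers from a single pass feed AIC(p) = n ln(σ̂_p²) + 2p.

Order selection returns the smallest candidate whose AIC lies within Δ = 2
of the minimum (Burnham–Anderson's "substantial support" band), not the
strict argmin.  Rationale: AIC's overfitting probability with many
candidate orders is ≈ 0.2–0.3 asymptotically, so the argmin frequently
lands one or two orders high even at n in the thousands, whereas the
parsimony rule recovers a true AR(4) at n = 4800 in ≳ 90% of runs and
matches the practice of reading the flattening point of an AIC-vs-order
curve.  Δ is a parameter; Δ = 0 restores the argmin with ties broken toward
the smaller order.

Per-class enrollment spectra are pointwise arithmetic means of the Burg
PSDs of the enrollment half of a class's images (fraction 0.5 by default;
selection order is input order, shuffling is the caller's concern so runs
stay seed-reproducible).

## Imposter model and fit

Imposter scores are computed for all **ordered** cross-class pairs
(relative entropy is asymmetric; unordered deduplication is a flag).  The
default histogram uses 50 equal-width bins spanning [0, max score];
fits are stable to ±1 in K across 30–70 bins.  The Erlang density
f(x; K, P) = x^{K−1}e^{−x/P}/(P^K(K−1)!) is fitted by unweighted least
squares on bin centers over K ∈ {1..12} and 200 log-spaced P values from
max/1000 to max, followed by bounded scalar refinement of P at the winning
K; ties break toward smaller K, then smaller P.  An Erlang with integer
shape K and scale P is exactly a (P/2)-scaled chi-square with 2K real
degrees of freedom — the "chi-square with K complex degrees of freedom"
family.

Whether imposter scoring should use enrollment-vs-enrollment spectra or
enrollment-vs-held-out queries is genuinely open; both are provided
(`metric="relative_entropy"` uses enrollment spectra only, and
`metric="whittle"` scores pair (m, k) with class m's held-out vectors).

## Capacity conventions

* Display rounding: `M_reported = max(2, floor(M_raw))`.  This mirrors how
  such tables are conventionally printed (analytic values below 2 appear
  as 2); both raw and reported values are returned.
* FMR discretization: `fmr_continuous` is the Erlang CDF (regularized
  incomplete gamma).  `fmr_unit_grid` sums the pdf at integer distances
  1..⌊τ⌋ — a unit-step Riemann sum.  The two differ enormously at small τ
  (at τ = 1 the sum is a single pdf value ~4×10⁻¹¹ for K=4, P=252, while
  the CDF is ~1.6×10⁻¹⁰) and converge within 2% once τ/P ≳ 0.2.  The
  unit-grid variant is the convention that reproduces the reference
  enrollment tables and is labeled a reconstruction of tabulated practice,
  not a distributional identity.
* Natural logarithms throughout the enrollment bound.
* One published reference cell (K=4, P=383, τ=50, δ=0.1, printed 2.30×10³)
  is inconsistent with the convention that reproduces the other three
  entries of its row (which give 9.30×10³, suggesting a single-digit
  transcription slip); it is excluded from parity checks without guessing
  the original intent.
* The decision tie Λ = threshold resolves toward the competing class k
  (conservative for enrollment); with *identical* class spectra the
  statistic is identically zero, so the tie rule degenerately assigns every
  query to k — near-identical rather than identical classes exhibit the
  intuitive coin-flip error rates.

## Synthetic data

`CohortSpec`/`generate_cohort` emulate a balanced study cohort: M classes,
each a random stable AR(p) Gaussian process (reflection coefficients
uniform in (−r, r), inverse-Levinson converted, hence stable by
construction), with N independent realizations per class.  Defaults —
21 classes × 10 images, vectors of 4800 samples — mirror a small
high-quality interval-camera cohort; the AR order defaults to 4 rather
than the order ≈ 100 appropriate for real iris vectors, keeping desk-scale
runtimes while preserving smooth, mutually distinct low-order spectra
(order is configurable).  `sample_spectral_realizations` additionally
provides the circulant (spectral-domain) sampler whose periodogram
ordinates have exactly the target mean — the idealized codeword model used
for distributional checks of the per-frequency component law.

What the synthetic cohort does **not** emulate: occlusions and eyelashes,
illumination and focus variation, segmentation errors, intra-class
deformation between acquisitions, and the long-order, low-frequency
structure of real Gabor-filtered iris vectors.  Passing tests therefore
establish the correctness and internal consistency of the estimation and
bounding machinery — not that real iris data satisfy the AR-Gaussian
assumptions or yield any particular (K, P).

## Simulation and numerical choices

* AR simulation discards a burn-in of max(100, 10p) samples; all
  randomness flows through explicit seeds / numpy Generators, never global
  state.
* Exact LLR covariances are built from exact Yule–Walker autocovariances
  (genuine Toeplitz, not circulant approximations) and factorized by
  Cholesky; log-determinants come from the factor diagonals.  Intended for
  n ≲ 2048.
* Monte-Carlo error rates report 95% Wilson intervals.
* Pipeline artifacts serialize floats at 17 significant digits and carry
  the seed plus a SHA-256 config hash, so reruns are bit-identical.
* Union-bound values above 1 are logged as vacuous, not errors.

## Problem sizes used in validation

The test suite runs at sizes chosen for seconds-scale feedback: Burg
recovery at n = 10⁵; AIC order-recovery over 50 seeded runs at n = 4800;
Whittle-vs-exact agreement at n = 512 with 100 queries; expectation and
component-law checks at 10⁴ draws; Erlang fit recovery from 10⁵ samples
over 20 seeded (K, P) draws; cohort self-identification at M = 6,
n = 4096.  The capacity parity checks are analytic and instantaneous.

## Known limitations

* The AR-Gaussian class model is a modeling convenience; real iris texture
  is at best piece-wise stationary, and the framework's capacity numbers
  inherit whatever misfit the model has.
* The Erlang family is an empirical approximation to the imposter law; no
  closed form exists for the full statistic Λ (its components are
  independent but not identically distributed), and only its fitted
  approximation enters the bounds.
* Uncertainty in (K̂, P̂) is not propagated into the capacity bounds.
* log/exponential pre-transforms of the data are a configuration hook
  only; ARMA/ARIMA variants are out of scope.
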