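"""Auto-regressive Gaussian models of iris texture and their power spectra.

Each iris class is modeled as a zero-mean stationary Gaussian AR(p) process

    X_t = sum_{i=1}^{p} alpha_i X_{t-i} + eta_t,      eta_t ~ N(0, sigma_eta^2),

whose power spectral density (PSD) on the two-sided n-point DFT grid
f_i = i/n is

    S(f_i) = sigma_eta^2 / |1 - sum_k alpha_k exp(-j 2 pi f_i k)|^2.

Coefficients are stored in *regression* form (the ``+alpha`` convention of
the difference equation above).  Most polynomial-based tooling (numpy roots,
scipy.signal filters, Burg implementations that return an ``A(z) = 1 +
sum a_k z^{-k}`` denominator) uses ``a_k = -alpha_k``; the mapping is applied
internally wherever such a representation is needed.

Model fitting uses Burg's maximum-entropy lattice recursion, which minimizes
the summed forward+backward prediction-error power and is stable by
construction (all reflection coefficients have magnitude < 1).  Order
selection uses AIC(p) = n ln(sigma_p^2) + 2 p with the Burg residual power.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .errors import DegenerateSignalError, StabilityError

__all__ = [
    "ARModel",
    "PowerSpectrum",
    "AICCurve",
    "burg_fit",
    "ar_psd",
    "ar_autocovariance",
    "aic_sweep",
    "select_order",
    "simulate_ar",
    "random_stable_ar",
    "sample_spectral_realizations",
]

_STABILITY_MARGIN = 1e-9


@dataclass(frozen=True)
class ARModel:
    """Stationary AR(p) description of one iris class.

    Parameters
    ----------
    order
        Model order p >= 0.
    coeffs
        Regression coefficients (alpha_1, ..., alpha_p).
    noise_variance
        Innovation variance sigma_eta^2 >= 0 (power units).  Zero is the
        degenerate deterministic limit, accepted for simulation edge cases;
        spectral evaluation requires a strictly positive value.
    """

    order: int
    coeffs: tuple[float, ...]
    noise_variance: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", tuple(float(c) for c in self.coeffs))
        if self.order < 0:
            raise ValueError(f"order must be >= 0, got {self.order}")
        if len(self.coeffs) != self.order:
            raise ValueError(
                f"len(coeffs)={len(self.coeffs)} does not match order={self.order}"
            )
        if not np.isfinite(self.coeffs).all():
            raise ValueError("coeffs must be finite")
        if not np.isfinite(self.noise_variance) or self.noise_variance < 0:
            raise ValueError(f"noise_variance must be >= 0, got {self.noise_variance}")

    @property
    def polynomial(self) -> np.ndarray:
        """Characteristic polynomial [1, -alpha_1, ..., -alpha_p] (a-form)."""
        return np.concatenate(([1.0], -np.asarray(self.coeffs)))

    def is_stable(self, margin: float = _STABILITY_MARGIN) -> bool:
        """True when all characteristic roots lie inside the unit circle."""
        if self.order == 0:
            return True
        roots = np.roots(self.polynomial)
        return bool(np.all(np.abs(roots) < 1.0 - margin))

    def require_stable(self) -> None:
        if not self.is_stable():
            raise StabilityError(
                "AR model is not stationary: characteristic roots reach the unit circle"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "order": self.order,
                "coeffs": list(self.coeffs),
                "noise_variance": self.noise_variance,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ARModel":
        d = json.loads(text)
        return cls(int(d["order"]), tuple(d["coeffs"]), float(d["noise_variance"]))


@dataclass(frozen=True)
class PowerSpectrum:
    """Two-sided PSD sampled on the n-point DFT grid f_i = i/n."""

    n_grid: int
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.n_grid <= 0 or vals.shape != (self.n_grid,):
            raise ValueError("values must be a 1-D array of length n_grid")
        if not np.isfinite(vals).all() or np.any(vals <= 0):
            raise ValueError("PSD values must be positive and finite")

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(self.n_grid) / self.n_grid

    @property
    def process_variance(self) -> float:
        """r_0 implied by the spectrum (Parseval: mean of the PSD samples)."""
        return float(self.values.mean())

    def to_json(self) -> str:
        return json.dumps({"n_grid": self.n_grid, "values": self.values.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "PowerSpectrum":
        d = json.loads(text)
        return cls(int(d["n_grid"]), np.asarray(d["values"], dtype=float))

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.frequencies, self.values]),
            delimiter=",",
            header="frequency,value",
            comments="",
            fmt="%.17g",
        )


@dataclass(frozen=True)
class AICCurve:
    """AIC score as a function of candidate AR order."""

    orders: tuple[int, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.orders) != len(self.scores):
            raise ValueError("orders and scores must have the same length")
        if not np.isfinite(self.scores).all():
            raise ValueError("AIC scores must be finite")


def _validate_signal(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise DegenerateSignalError("signal must contain at least two samples")
    if not np.isfinite(x).all():
        raise DegenerateSignalError("signal contains non-finite values")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("signal is constant; Burg recursion is undefined")
    return x


def _burg_recursion(x: np.ndarray, p_max: int):
    """One pass of the Burg lattice up to order p_max.

    Returns (reflection coefficients k_1..k_pmax, per-order polynomial
    a-coefficient arrays, per-order prediction-error powers).  The harmonic
    mean reflection update k = -2 f.b / (f.f + b.b) guarantees |k| < 1.
    """
    n = x.size
    fwd = x[1:].copy()
    bwd = x[:-1].copy()
    energy = float(np.dot(x, x)) / n
    ks: list[float] = []
    sigmas: list[float] = []
    a = np.zeros(0)
    a_per_order: list[np.ndarray] = []
    for _ in range(p_max):
        denom = np.dot(fwd, fwd) + np.dot(bwd, bwd)
        if denom <= 0:
            raise DegenerateSignalError("prediction error vanished before target order")
        k = -2.0 * float(np.dot(fwd, bwd)) / float(denom)
        a = np.concatenate([a + k * a[::-1], [k]])
        a_per_order.append(a.copy())
        energy *= 1.0 - k * k
        ks.append(k)
        sigmas.append(energy)
        fwd, bwd = fwd + k * bwd, bwd + k * fwd
        fwd = fwd[1:]
        bwd = bwd[:-1]
    return np.asarray(ks), a_per_order, np.asarray(sigmas)


def burg_fit(x: Sequence[float], p: int) -> ARModel:
    """Fit an AR(p) model with Burg's maximum-entropy method.

    The returned coefficients follow the regression convention
    (X_t = sum alpha_i X_{t-i} + eta_t); ``noise_variance`` is the final
    Burg prediction-error power.  Stability is guaranteed by construction.
    """
    x = _validate_signal(x)
    if p < 1:
        raise ValueError(f"order p must be >= 1, got {p}")
    if p > x.size // 2:
        raise ValueError(f"order p={p} too large for signal length n={x.size}")
    _, a_per_order, sigmas = _burg_recursion(x, p)
    return ARModel(order=p, coeffs=tuple(-a_per_order[-1]), noise_variance=float(sigmas[-1]))


def ar_psd(model: ARModel, n_grid: int) -> PowerSpectrum:
    """Evaluate the model PSD on the two-sided n_grid-point DFT grid.

    S(f_i) = sigma^2 / |1 - sum_k alpha_k e^{-j 2 pi f_i k}|^2, f_i = i/n.
    """
    model.require_stable()
    if n_grid <= model.order:
        raise ValueError("n_grid must exceed the model order")
    if model.noise_variance <= 0:
        raise ValueError("spectral evaluation requires noise_variance > 0")
    denom = np.abs(np.fft.fft(model.polynomial, n_grid)) ** 2
    return PowerSpectrum(n_grid=n_grid, values=model.noise_variance / denom)


def ar_autocovariance(model: ARModel, max_lag: int) -> np.ndarray:
    """Exact autocovariances r_0..r_max_lag via the Yule-Walker relations.

    Solves the (p+1)-dimensional linear system
    r_j - sum_i alpha_i r_{|j-i|} = sigma^2 delta_{j0}, then extends with the
    recursion r_j = sum_i alpha_i r_{j-i} for j > p.
    """
    model.require_stable()
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    p = model.order
    sigma2 = model.noise_variance
    if p == 0:
        r = np.zeros(max_lag + 1)
        r[0] = sigma2
        return r
    alpha = np.asarray(model.coeffs)
    A = np.eye(p + 1)
    for j in range(p + 1):
        for i in range(1, p + 1):
            A[j, abs(j - i)] -= alpha[i - 1]
    rhs = np.zeros(p + 1)
    rhs[0] = sigma2
    r_head = np.linalg.solve(A, rhs)
    r = np.zeros(max(max_lag, p) + 1)
    r[: p + 1] = r_head
    for j in range(p + 1, max_lag + 1):
        r[j] = np.dot(alpha, r[j - 1 : j - 1 - p if j - 1 - p >= 0 else None : -1][:p])
    return r[: max_lag + 1]


def aic_sweep(x: Sequence[float], orders: Sequence[int]) -> AICCurve:
    """AIC(p) = n ln(sigma_p^2) + 2p over candidate orders (Burg residuals)."""
    x = _validate_signal(x)
    orders = [int(p) for p in orders]
    if not orders:
        raise ValueError("orders must be nonempty")
    if min(orders) < 1 or max(orders) > x.size // 2:
        raise ValueError("every candidate order must be feasible for burg_fit")
    _, _, sigmas = _burg_recursion(x, max(orders))
    n = x.size
    scores = tuple(n * float(np.log(sigmas[p - 1])) + 2.0 * p for p in orders)
    return AICCurve(orders=tuple(orders), scores=scores)


def select_order(curve: AICCurve, tol: float = 2.0) -> int:
    """Most parsimonious order whose AIC is within ``tol`` of the minimum.

    ``tol=2.0`` is the conventional "substantial support" band of Burnham &
    Anderson; models inside it are statistically indistinguishable, so the
    smallest such order is preferred (this is also where an AIC-vs-order
    curve visibly flattens).  ``tol=0`` recovers the strict argmin with ties
    broken toward the smaller order.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    scores = np.asarray(curve.scores)
    orders = np.asarray(curve.orders)
    idx = np.argsort(orders, kind="stable")
    scores, orders = scores[idx], orders[idx]
    cutoff = scores.min() + tol
    return int(orders[np.nonzero(scores <= cutoff)[0][0]])


def simulate_ar(
    model: ARModel,
    n: int,
    n_realizations: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Simulate realizations of the AR process (rows are realizations).

    White Gaussian innovations are filtered through the difference equation;
    a burn-in of max(100, 10 p) leading samples is discarded so the output is
    effectively stationary.  Identical seeds give bit-identical output.
    """
    model.require_stable()
    if n < 1 or n_realizations < 1:
        raise ValueError("n and n_realizations must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    burn = max(100, 10 * model.order)
    noise = rng.standard_normal((n_realizations, n + burn)) * np.sqrt(model.noise_variance)
    out = lfilter([1.0], model.polynomial, noise, axis=1)
    return out[:, burn:]


def random_stable_ar(
    p: int,
    seed: int | np.random.Generator,
    max_pole_radius: float = 0.95,
    noise_variance: float = 1.0,
) -> ARModel:
    """Draw a random stable AR(p) model.

    Reflection coefficients are drawn uniformly in
    (-max_pole_radius, max_pole_radius) and converted to regression
    coefficients through the inverse Levinson recursion, so the result is
    stable by construction.
    """
    if not 0 < max_pole_radius < 1:
        raise ValueError("max_pole_radius must lie in (0, 1)")
    if p < 1:
        raise ValueError("p must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ks = rng.uniform(-max_pole_radius, max_pole_radius, size=p)
    a = np.zeros(0)
    for k in ks:
        a = np.concatenate([a + k * a[::-1], [k]])
    return ARModel(order=p, coeffs=tuple(-a), noise_variance=noise_variance)


def sample_spectral_realizations(
    psd: PowerSpectrum,
    n_realizations: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Sample real Gaussian series whose periodogram has mean exactly S(f_i).

    This is the circulant (spectral-domain) Gaussian sampler: independent
    complex-normal DFT ordinates with Hermitian symmetry are inverse
    transformed, so E[|DFT(x)_i|^2 / n] = S(f_i) holds exactly at every grid
    point — the idealized codeword model underlying the per-frequency
    likelihood components.  Rows are realizations of length n_grid.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = psd.n_grid
    s = psd.values
    half = n // 2
    m = n_realizations
    spec = np.zeros((m, half + 1), dtype=complex)
    spec[:, 0] = np.sqrt(n * s[0]) * rng.standard_normal(m)
    hi = half if n % 2 else half - 1
    if hi >= 1:
        re = rng.standard_normal((m, hi))
        im = rng.standard_normal((m, hi))
        spec[:, 1 : hi + 1] = np.sqrt(n * s[1 : hi + 1] / 2.0) * (re + 1j * im)
    if n % 2 == 0:
        spec[:, half] = np.sqrt(n * s[half]) * rng.standard_normal(m)
    return np.fft.irfft(spec, n=n, axis=1)
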