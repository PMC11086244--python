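"""Imposter score distributions and the Erlang ("chi-square") family fit.

Cross-class (imposter) scores — spectral relative entropies or Whittle
log-likelihood statistics over all ordered pairs of enrolled classes — are
histogrammed and fitted with the Erlang density

    f(x; K, P) = x^{K-1} e^{-x/P} / (P^K (K-1)!),   x >= 0,

the law of a sum of K iid squared complex Gaussians of variance P (i.e. K
iid exponentials of mean P; equivalently a (P/2)-scaled chi-square with 2K
real degrees of freedom — the "chi-square with K complex degrees of
freedom" phrasing).  K and P are found by exhaustive least squares on the
histogram: K indexes the length of the hypothetical Gaussian codewords and
P the per-component variance, the two numbers the capacity bounds consume.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special

from .ar import PowerSpectrum
from .detection import relative_entropy, whittle_llr
from .errors import GridMismatchError

__all__ = [
    "ImposterHistogram",
    "ImposterFit",
    "enrollment_spectrum",
    "imposter_scores",
    "erlang_pdf",
    "sample_erlang",
    "fit_erlang_lsq",
]


@dataclass(frozen=True)
class ImposterHistogram:
    """Density-normalized histogram of imposter scores."""

    bin_edges: np.ndarray
    densities: np.ndarray
    n_scores: int
    metric_name: str = "relative_entropy"

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        dens = np.asarray(self.densities, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "densities", dens)
        if edges.ndim != 1 or dens.ndim != 1 or edges.size != dens.size + 1:
            raise ValueError("need len(bin_edges) == len(densities) + 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(dens < 0):
            raise ValueError("densities must be nonnegative")
        mass = float(np.sum(dens * np.diff(edges)))
        if dens.any() and abs(mass - 1.0) > 1e-6:
            raise ValueError(f"densities must integrate to 1 (got {mass})")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @classmethod
    def from_scores(
        cls, scores: Sequence[float], bins: int = 50, metric_name: str = "relative_entropy"
    ) -> "ImposterHistogram":
        """Equal-width histogram over [0, max(scores)], density normalized."""
        scores = np.asarray(scores, dtype=float)
        if scores.size == 0:
            raise ValueError("no scores to histogram")
        hi = float(scores.max())
        if hi <= 0:
            raise ValueError("scores must contain positive values")
        dens, edges = np.histogram(scores, bins=bins, range=(0.0, hi), density=True)
        return cls(edges, dens, n_scores=scores.size, metric_name=metric_name)


@dataclass(frozen=True)
class ImposterFit:
    """Fitted Erlang parameters: codeword length K, component variance P."""

    K: int
    P: float
    sse: float
    metric_name: str = "relative_entropy"
    n_scores: int = 0
    n_bins: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.P <= 0:
            raise ValueError("P must be > 0")
        if self.sse < 0:
            raise ValueError("sse must be >= 0")

    def to_json(self) -> str:
        return json.dumps(
            {
                "metric": self.metric_name,
                "K": self.K,
                "P": self.P,
                "sse": self.sse,
                "n_scores": self.n_scores,
                "bins": self.n_bins,
            }
        )


def enrollment_spectrum(
    per_image_psds: Sequence[PowerSpectrum], enroll_fraction: float = 0.5
) -> tuple[PowerSpectrum, list[PowerSpectrum]]:
    """Average the enrollment share of per-image PSDs into one class spectrum.

    The first ceil(fraction * count) spectra (input order; shuffle upstream
    with a seed if needed) are averaged pointwise into the enrollment
    spectrum; the remainder is returned for authentication use.  The default
    fraction 0.5 enrolls half of a class's images.
    """
    if len(per_image_psds) < 2:
        raise ValueError("need at least two per-image PSDs")
    if not 0 < enroll_fraction < 1:
        raise ValueError("enroll_fraction must lie in (0, 1)")
    n_grid = per_image_psds[0].n_grid
    if any(p.n_grid != n_grid for p in per_image_psds):
        raise GridMismatchError("per-image PSDs must share one frequency grid")
    n_enroll = math.ceil(enroll_fraction * len(per_image_psds))
    stacked = np.stack([p.values for p in per_image_psds[:n_enroll]])
    enroll = PowerSpectrum(n_grid=n_grid, values=stacked.mean(axis=0))
    return enroll, list(per_image_psds[n_enroll:])


def imposter_scores(
    class_spectra: Mapping[str, PowerSpectrum],
    metric: str = "relative_entropy",
    queries: Mapping[str, Sequence] | None = None,
    ordered: bool = True,
) -> list[float]:
    """Score every cross-class pair of enrollment spectra.

    With M classes this yields M(M-1) ordered scores (the relative entropy
    is asymmetric), or M(M-1)/2 with ``ordered=False``.  ``metric`` is
    ``"relative_entropy"`` or ``"whittle"``; the Whittle metric scores pair
    (m, k) with the held-out query vectors of class m (``queries[m]``).
    """
    labels = list(class_spectra)
    if len(labels) < 2:
        raise ValueError("need at least two classes")
    n_grid = class_spectra[labels[0]].n_grid
    if any(class_spectra[lb].n_grid != n_grid for lb in labels):
        raise GridMismatchError("class spectra must share one frequency grid")
    if metric not in ("relative_entropy", "whittle"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "whittle" and queries is None:
        raise ValueError("the whittle metric needs held-out queries per class")
    if ordered:
        pairs = [(m, k) for m in labels for k in labels if k != m]
    else:
        pairs = [(m, k) for a, m in enumerate(labels) for k in labels[a + 1 :]]
    scores: list[float] = []
    for m, k in pairs:
        if metric == "relative_entropy":
            scores.append(relative_entropy(class_spectra[m], class_spectra[k]))
        else:
            stat = whittle_llr(
                class_spectra[m], class_spectra[k], queries[m], class_m=m, class_k=k
            )
            scores.append(stat.lambda_total)
    return scores


def erlang_pdf(x, K: int, P: float):
    """Erlang density with integer shape K and scale P (zero for x < 0)."""
    if int(K) != K or K < 1:
        raise ValueError("K must be a positive integer")
    if P <= 0:
        raise ValueError("P must be positive")
    K = int(K)
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    xp = x[pos]
    out[pos] = np.exp(
        (K - 1) * np.log(xp) - xp / P - K * np.log(P) - special.gammaln(K)
    )
    if K == 1:
        out[x == 0] = 1.0 / P
    return out if out.ndim else float(out)


def sample_erlang(K: int, P: float, size: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw Erlang(K, P) samples (sum of K exponentials of mean P)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.gamma(shape=K, scale=P, size=size)


def fit_erlang_lsq(
    hist: ImposterHistogram,
    K_candidates: Iterable[int] = range(1, 13),
    P_grid: np.ndarray | None = None,
) -> ImposterFit:
    """Exhaustive least-squares Erlang fit to an imposter histogram.

    Minimizes sum_b (density_b - f(center_b; K, P))^2 over the Cartesian
    grid of K candidates and P values (default: 200 log-spaced points from
    max(edge)/1000 to max(edge)), then refines P by bounded golden-section
    search at the winning K.  Ties break toward smaller K, then smaller P.
    The objective is unweighted, matching a plain least-squares histogram
    fit.
    """
    centers = hist.centers
    dens = hist.densities
    if centers.size == 0:
        raise ValueError("histogram is empty")
    K_candidates = sorted({int(k) for k in K_candidates})
    if not K_candidates or K_candidates[0] < 1:
        raise ValueError("K_candidates must be positive integers")
    if P_grid is None:
        top = float(hist.bin_edges[-1])
        P_grid = np.geomspace(top / 1000.0, top, 200)
    else:
        P_grid = np.asarray(P_grid, dtype=float)
        if P_grid.size == 0 or np.any(P_grid <= 0):
            raise ValueError("P_grid must be nonempty and positive")
        P_grid = np.sort(P_grid)

    log_c = np.log(centers)

    def _sse_matrix(K: int) -> np.ndarray:
        # pdf matrix over (P, bins) without per-point python loops
        logpdf = (
            (K - 1) * log_c[None, :]
            - centers[None, :] / P_grid[:, None]
            - K * np.log(P_grid)[:, None]
            - special.gammaln(K)
        )
        resid = np.exp(logpdf) - dens[None, :]
        return np.sum(resid**2, axis=1)

    best = None  # (sse, K, P)
    for K in K_candidates:
        sse_vec = _sse_matrix(K)
        j = int(np.argmin(sse_vec))  # first minimum -> smallest P on ties
        if best is None or sse_vec[j] < best[0]:
            best = (float(sse_vec[j]), K, float(P_grid[j]), j)

    sse_best, K_best, P_best, j_best = best
    lo = P_grid[max(0, j_best - 1)]
    hi = P_grid[min(P_grid.size - 1, j_best + 1)]

    def _sse_at(P: float) -> float:
        return float(np.sum((erlang_pdf(centers, K_best, P) - dens) ** 2))

    if hi > lo:
        res = optimize.minimize_scalar(_sse_at, bounds=(lo, hi), method="bounded")
        if res.fun < sse_best:
            sse_best, P_best = float(res.fun), float(res.x)
    return ImposterFit(
        K=K_best,
        P=P_best,
        sse=sse_best,
        metric_name=hist.metric_name,
        n_scores=hist.n_scores,
        n_bins=dens.size,
    )
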