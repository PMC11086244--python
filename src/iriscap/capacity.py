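"""Population capacity bounds from a fitted (K, P) imposter model.

Two bounds convert the fitted codeword geometry into a maximum number of
distinguishable iris classes:

* Sphere packing: codewords of M classes live in a K-dimensional Gaussian
  sphere of radius sqrt(K(P+N)); authentication noise occupies spheres of
  radius sqrt(KN).  Dividing volumes gives M <= (1 + P/N)^{K/2}, a
  decreasing function of the noise variance N (a data-quality axis).

* Enrollment (Daugman-like): a new class collides with an enrolled one when
  their distance falls below tau, which happens with probability FMR(tau)
  (the imposter CDF).  Keeping the chance of any collision among M classes
  below delta gives M <= ln(1 - delta) / ln(1 - FMR(tau)).

Two FMR conventions are provided.  ``fmr_continuous`` is the Erlang CDF
(regularized incomplete gamma).  ``fmr_unit_grid`` is a unit-step Riemann
sum of the Erlang pdf over integer distances 1..floor(tau) — a discretized
cumulative whose small-tau behavior differs markedly from the CDF and which
is the convention used for the reference enrollment tables; it is a
reconstruction of tabulated practice, not a distributional identity.

Reported populations use the display convention max(2, floor(M_raw)):
analytic values below 2 print as 2 and all others as floors.  Both raw and
reported values are kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import special

from .imposter import ImposterFit, erlang_pdf

__all__ = [
    "CapacityResult",
    "sphere_packing_capacity",
    "fmr_continuous",
    "fmr_unit_grid",
    "enrollment_capacity",
    "error_to_enroll",
    "sphere_packing_table",
    "enrollment_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CapacityResult:
    """One evaluated capacity bound (raw and display-rounded populations)."""

    bound_type: str  # "sphere_packing" | "enrollment"
    K: int | None
    P: float | None
    M_raw: float
    noise_variance: float | None = None
    tau: float | None = None
    delta: float | None = None
    fmr: float | None = None

    @property
    def M_reported(self) -> float:
        """Display convention: max(2, floor(M_raw)); infinite bounds pass through."""
        if math.isinf(self.M_raw):
            return math.inf
        return max(2, math.floor(self.M_raw))


def sphere_packing_capacity(K: int, P: float, noise_variance: float) -> CapacityResult:
    """Sphere-packing bound M <= (1 + P/N)^{K/2} at noise variance N.

    P = 0 is the zero-signal limit (M_raw = 1); K and N must be positive.
    """
    if int(K) != K or K < 1:
        raise ValueError("K must be a positive integer")
    if P < 0:
        raise ValueError("P must be >= 0")
    if noise_variance <= 0:
        raise ValueError("noise_variance must be positive")
    m_raw = (1.0 + P / noise_variance) ** (K / 2.0)
    return CapacityResult(
        bound_type="sphere_packing", K=int(K), P=float(P), M_raw=m_raw,
        noise_variance=float(noise_variance),
    )


def fmr_continuous(tau: float, K: int, P: float) -> float:
    """Erlang CDF at tau: 1 - e^{-tau/P} sum_{j<K} (tau/P)^j / j!.

    Evaluated through the regularized lower incomplete gamma function for
    numerical stability.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if int(K) != K or K < 1 or P <= 0:
        raise ValueError("need integer K >= 1 and P > 0")
    return float(special.gammainc(int(K), tau / P))


def fmr_unit_grid(tau: float, K: int, P: float) -> float:
    """Unit-grid cumulative: sum of the Erlang pdf at integer x = 1..floor(tau)."""
    if int(K) != K or K < 1 or P <= 0:
        raise ValueError("need integer K >= 1 and P > 0")
    top = math.floor(tau)
    if top < 1:
        return 0.0
    xs = range(1, top + 1)
    return float(sum(erlang_pdf(float(x), int(K), P) for x in xs))


def enrollment_capacity(
    delta: float, fmr: float, K: int | None = None, P: float | None = None,
    tau: float | None = None,
) -> CapacityResult:
    """Daugman-like bound M <= ln(1 - delta) / ln(1 - FMR(tau)).

    ``fmr`` is the false match rate at the chosen codeword distance
    threshold; ``delta`` the tolerated probability that a new class collides
    with any enrolled class.  fmr = 0 yields an infinite (flagged) bound.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    if fmr < 0 or fmr >= 1:
        raise ValueError("fmr must lie in [0, 1)")
    if fmr == 0:
        logger.warning("FMR is exactly 0: enrollment capacity is unbounded")
        m_raw = math.inf
    else:
        m_raw = math.log1p(-delta) / math.log1p(-fmr)
    return CapacityResult(
        bound_type="enrollment", K=K, P=P, M_raw=m_raw,
        tau=tau, delta=float(delta), fmr=float(fmr),
    )


def error_to_enroll(M: int, fmr: float) -> float:
    """Probability 1 - (1 - FMR)^M that enrolling into M classes collides."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if not 0 <= fmr <= 1:
        raise ValueError("fmr must lie in [0, 1]")
    return float(-math.expm1(M * math.log1p(-fmr))) if fmr < 1 else 1.0


def sphere_packing_table(fit: ImposterFit, noise_grid) -> pd.DataFrame:
    """Sphere-packing bound over a noise-variance grid (one row per N)."""
    rows = []
    for nv in noise_grid:
        res = sphere_packing_capacity(fit.K, fit.P, nv)
        rows.append(
            {"noise_variance": nv, "M_raw": res.M_raw, "M_reported": res.M_reported}
        )
    return pd.DataFrame(rows)


def enrollment_table(
    fit: ImposterFit, tau_grid, delta_grid, fmr_mode: str = "unit_grid"
) -> pd.DataFrame:
    """Enrollment bound over tau x delta (long format, one row per cell)."""
    if fmr_mode not in ("unit_grid", "continuous"):
        raise ValueError("fmr_mode must be 'unit_grid' or 'continuous'")
    fmr_fn = fmr_unit_grid if fmr_mode == "unit_grid" else fmr_continuous
    rows = []
    for tau in tau_grid:
        fmr = fmr_fn(tau, fit.K, fit.P)
        for delta in delta_grid:
            if 0 < fmr < 1:
                res = enrollment_capacity(delta, fmr, K=fit.K, P=fit.P, tau=tau)
                m_raw, m_rep = res.M_raw, res.M_reported
            else:
                m_raw, m_rep = math.inf, math.inf
            rows.append(
                {
                    "tau": tau,
                    "delta": delta,
                    "fmr": fmr,
                    "M_raw": m_raw,
                    "M_reported": m_rep,
                }
            )
    return pd.DataFrame(rows)
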