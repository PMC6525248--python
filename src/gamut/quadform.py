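"""Tail probabilities for weighted mixtures of independent 1-df chi-square variables.

The asymptotic null distribution of every kernel test in this package is a
quadratic form in Gaussian variables,

    Q = sum_k c_k * chi^2_{1,k},   c_k >= 0,

and a gene-level p-value is P(Q >= q) for an observed statistic q.  The primary
evaluation path inverts the characteristic function numerically (the
Davies/Imhof representation, integrated adaptively); when the integrator
reports trouble the module falls back to the Liu-Tang-Zhang moment-matching
approximation, and the result records which path produced it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

__all__ = ["QuadFormSpec", "PvalueResult", "davies_pvalue", "mixture_sample"]

#: relative threshold under which mixture coefficients are treated as zero
COEFF_TRUNCATION = 1e-10


@dataclass
class QuadFormSpec:
    """Coefficients of a nonnegative chi-square mixture plus an evaluation point.

    Coefficients are sorted in descending order on construction and entries
    below ``COEFF_TRUNCATION * max(coeffs)`` are dropped (eigenvalue products
    of projection matrices carry exact zeros plus float noise); the number
    removed is kept for diagnostics.
    """

    coeffs: np.ndarray
    q: float
    n_truncated: int = field(default=0)

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float).ravel()
        if c.size == 0:
            raise ValueError("quadratic form needs at least one coefficient")
        if np.any(c < 0):
            raise ValueError("mixture coefficients must be nonnegative")
        cmax = c.max()
        if cmax <= 0:
            raise ValueError("at least one coefficient must be positive")
        keep = c >= COEFF_TRUNCATION * cmax
        self.n_truncated = int(c.size - keep.sum())
        self.coeffs = np.sort(c[keep])[::-1]
        self.q = float(self.q)
        if self.q < 0:
            raise ValueError(f"evaluation point must be >= 0, got {self.q}")


@dataclass
class PvalueResult:
    """A tail probability plus the method that produced it."""

    p: float
    method: str  # "davies" | "moment_fallback"
    abserr: float
    n_truncated: int

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p-value outside (0, 1]: {self.p}")


def _imhof_integrand(u: np.ndarray, coeffs: np.ndarray, q: float) -> np.ndarray:
    # theta(u) = 0.5 * sum arctan(c_k u) - 0.5 q u ; rho(u) = prod (1 + c_k^2 u^2)^{1/4}
    cu = np.multiply.outer(coeffs, u)
    theta = 0.5 * np.arctan(cu).sum(axis=0) - 0.5 * q * u
    log_rho = 0.25 * np.log1p(cu * cu).sum(axis=0)
    return np.sin(theta) * np.exp(-log_rho) / u


def _amplitude(u: np.ndarray, coeffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # slowly-varying part of the integrand: sin(phi)/(u rho), cos(phi)/(u rho)
    cu = np.multiply.outer(coeffs, u)
    phi = 0.5 * np.arctan(cu).sum(axis=0)
    log_rho = 0.25 * np.log1p(cu * cu).sum(axis=0)
    amp = np.exp(-log_rho) / u
    return np.sin(phi) * amp, np.cos(phi) * amp


def _imhof_integral(coeffs: np.ndarray, q: float, epsabs: float) -> tuple[float, float]:
    """Integral of sin(theta(u))/(u rho(u)) over (0, inf).

    The integrand oscillates at frequency q/2 and its envelope decays only as
    u^{-(k/2+1)}, so a plain adaptive rule on the full half-line stalls for
    small k.  Split at U beyond the arctan transition region and integrate the
    tail with Fourier-weighted (QAWF) quadrature:
    sin(phi - qu/2) = sin(phi)cos(qu/2) - cos(phi)sin(qu/2).
    """
    # Split where either the arctan phases have saturated (cu >> 1) or the
    # envelope exp(-0.25 sum log1p(c^2 u^2))/u has decayed to negligibility —
    # whichever comes first, so the head interval stays a few hundred
    # oscillation periods at most even for many small coefficients.
    u_sat = 10.0 / coeffs[-1]
    grid = np.logspace(-3, np.log10(max(u_sat, 1.0)) + 1.0, 400)
    cu2 = np.multiply.outer(coeffs, grid) ** 2
    env = np.exp(-0.25 * np.log1p(cu2).sum(axis=0)) / grid
    dead = np.nonzero(env < 1e-20)[0]
    u_split = min(u_sat, grid[dead[0]]) if dead.size else u_sat
    head, err_h = integrate.quad(
        _imhof_integrand, 0.0, u_split, args=(coeffs, q),
        epsabs=epsabs / 2.0, epsrel=1e-12, limit=500,
    )
    w = q / 2.0
    sin_amp = lambda u: _amplitude(np.atleast_1d(u), coeffs)[0][0]
    cos_amp = lambda u: _amplitude(np.atleast_1d(u), coeffs)[1][0]
    t1, err_1 = integrate.quad(
        sin_amp, u_split, np.inf, weight="cos", wvar=w, epsabs=epsabs / 4.0, limit=500,
    )
    t2, err_2 = integrate.quad(
        cos_amp, u_split, np.inf, weight="sin", wvar=w, epsabs=epsabs / 4.0, limit=500,
    )
    return head + t1 - t2, err_h + err_1 + err_2


def _liu_pvalue(coeffs: np.ndarray, q: float) -> float:
    """Liu-Tang-Zhang four-moment match to a (non)central chi-square."""
    c1 = coeffs.sum()
    c2 = (coeffs**2).sum()
    c3 = (coeffs**3).sum()
    c4 = (coeffs**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    mu_q = c1
    sigma_q = np.sqrt(2.0 * c2)
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
        a = np.sqrt(df)
    mu_x = df + delta
    sigma_x = np.sqrt(2.0) * np.sqrt(df + 2.0 * delta)
    t = (q - mu_q) / sigma_q
    x = t * sigma_x + mu_x
    return float(stats.ncx2.sf(x, df, delta))


def davies_pvalue(spec: QuadFormSpec, accuracy: float = 1e-9) -> PvalueResult:
    """P(sum_k c_k chi^2_1 >= q) by characteristic-function inversion.

    Parameters
    ----------
    spec
        Mixture coefficients and the observed statistic ``q``.
    accuracy
        Absolute target accuracy for the numerical inversion, in (0, 1e-3].
        Returned p-values are floored at this value (never exactly 0).

    Returns
    -------
    PvalueResult
        The tail probability, the evaluation path taken (``davies`` for the
        inversion integral, ``moment_fallback`` for the Liu approximation),
        and the integrator's absolute-error estimate.
    """
    if not 0.0 < accuracy <= 1e-3:
        raise ValueError("accuracy must lie in (0, 1e-3]")
    coeffs = spec.coeffs
    if spec.q == 0.0:
        return PvalueResult(1.0, "davies", 0.0, spec.n_truncated)

    # Scale invariance: normalize so the largest coefficient is 1.  This keeps
    # the integrand's frequency content in a numerically comfortable range.
    scale = coeffs[0]
    c = coeffs / scale
    q = spec.q / scale

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        try:
            val, abserr = _imhof_integral(c, q, epsabs=accuracy * np.pi / 2.0)
        except Exception:  # integrator blow-up: defer to the moment match
            val, abserr = np.nan, np.inf

    p = 0.5 + val / np.pi
    perr = abserr / np.pi
    ok = np.isfinite(p) and perr < max(accuracy * 10.0, 1e-8) and -1e-6 <= p <= 1.0 + 1e-6
    if ok:
        p = min(max(p, accuracy), 1.0)
        return PvalueResult(float(p), "davies", float(perr), spec.n_truncated)

    p = _liu_pvalue(coeffs, spec.q)
    p = min(max(p, accuracy), 1.0)
    return PvalueResult(float(p), "moment_fallback", float("nan"), spec.n_truncated)


def mixture_sample(spec: QuadFormSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` independent realizations of the chi-square mixture.

    A Monte-Carlo oracle for :func:`davies_pvalue`: each draw is
    ``sum_k c_k z_k^2`` with ``z`` standard normal.  Reproducible under a
    fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    k = spec.coeffs.size
    out = np.zeros(n)
    # chunk so the normal draws never exceed ~5e7 doubles at once
    chunk = max(1, int(5e7) // max(k, 1))
    done = 0
    while done < n:
        m = min(chunk, n - done)
        z = rng.standard_normal((m, k))
        out[done : done + m] = (z * z) @ spec.coeffs
        done += m
    return out
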