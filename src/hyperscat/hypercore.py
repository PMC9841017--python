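"""Evaluation of the confluent hypergeometric limit function 0F1 for the
scattering amplitudes of rotationally symmetric bodies.

The volume-normalized scattering amplitude of a body that is rotationally
symmetric in ``d`` dimensions is

    F_d(x) = 0F1((d+2)/2; -x**2/4),      x = q*R,

which reduces to the textbook forms sin(x)/x (d=1, lamella), 2*J1(x)/x
(d=2, cylinder cross-section) and 3*(sin x - x cos x)/x**3 (d=3, sphere).

Three evaluation routes are provided:

* a series expansion with recursive coefficient generation (Regime I),
* an asymptotic (Hankel-type) expansion for large argument (Regime II),
* the closed forms, used as the in-module oracle.

The series route suffers catastrophic cancellation at large ``x`` and the
asymptotic route is invalid at small ``x``; :func:`regime_boundaries`
locates the switch points where the two routes overlap within a tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from .errors import ConvergenceError, DomainError, PrecisionLossError

__all__ = [
    "HyperArg",
    "SeriesCoefficients",
    "RegimeBoundaries",
    "pochhammer",
    "f01_closed",
    "f01_series",
    "f01_asymptotic",
    "asymptotic_coefficients",
    "regime_boundaries",
]

#: default cap on the number of series terms
N_MAX_DEFAULT = 200
#: default dynamic-range guard before the series is declared unusable
GUARD_FACTOR_DEFAULT = 1e12
#: smallest argument accepted by the asymptotic expansion
ASYMPTOTIC_FLOOR = 1e-3


@dataclass(frozen=True)
class HyperArg:
    """Argument of the amplitude function: dimensionality and x = q*R."""

    d: int
    x: float

    def __post_init__(self) -> None:
        if self.d not in (1, 2, 3):
            raise DomainError(f"dimensionality d must be 1, 2 or 3, got {self.d}")
        if self.x < 0:
            raise DomainError(f"x = qR must be non-negative, got {self.x}")


@dataclass
class SeriesCoefficients:
    """Ordered series coefficients c[n] multiplying q**(2n) (or the
    shape-specific power), with the truncation order and build tolerance."""

    c: np.ndarray
    n_max: int
    tol: float

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if not np.all(np.isfinite(self.c)):
            raise ValueError("series coefficients must be finite")


@dataclass
class RegimeBoundaries:
    """Switch points between the three evaluation regimes (units of the
    evaluator grid, nm^-1 for q-grids, dimensionless for x-grids).

    At q == q12 the lower regime (series) is used; at q == q23 Regime II
    is used.  ``precision`` records the achieved relative mismatch of the
    two overlapping evaluators at each boundary.
    """

    q12: float
    q23: float
    precision: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.q12 <= self.q23):
            raise ValueError(f"need 0 < q12 <= q23, got {self.q12}, {self.q23}")


def pochhammer(u: float, n: int) -> float:
    """Rising factorial (u)_n = u (u+1) ... (u+n-1), by recursion.

    Never evaluated through the Gamma function; the empty product is 1.
    Raises :class:`DomainError` on a pole (a non-positive integer factor
    reached inside the product).
    """
    if n < 0:
        raise DomainError("pochhammer order n must be >= 0")
    out = 1.0
    for k in range(n):
        factor = u + k
        if factor == 0.0:
            raise DomainError(f"pochhammer pole: u + {k} = 0 for u = {u}")
        out *= factor
    return out


def f01_closed(d: int, x):
    """Closed-form 0F1((d+2)/2; -x**2/4); exact, removable singularity at 0.

    Accepts scalars or arrays; used as the in-module oracle for the series
    and asymptotic routes.
    """
    if d not in (1, 2, 3):
        raise DomainError(f"d must be 1, 2 or 3, got {d}")
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    # short Taylor form below x = 0.05: the closed forms cancel
    # catastrophically there (sin x - x cos x ~ x³/3)
    s = (x > 1e-100) & (x < 0.05)
    t = x[s] * x[s]
    taylor = {
        1: (-1.0 / 6.0, 1.0 / 120.0, -1.0 / 5040.0),
        2: (-1.0 / 8.0, 1.0 / 192.0, -1.0 / 9216.0),
        3: (-1.0 / 10.0, 1.0 / 280.0, -1.0 / 15120.0),
    }[d]
    out[s] = 1.0 + t * (taylor[0] + t * (taylor[1] + t * taylor[2]))
    m = x >= 0.05
    xm = x[m]
    if d == 1:
        out[m] = np.sin(xm) / xm
    elif d == 2:
        out[m] = 2.0 * special.j1(xm) / xm
    else:
        out[m] = 3.0 * (np.sin(xm) - xm * np.cos(xm)) / xm**3
    if out.ndim == 0:
        return float(out)
    return out


def f01_series(
    d: int,
    x: float,
    tol: float = 1e-10,
    n_max: int = N_MAX_DEFAULT,
    guard_factor: float = GUARD_FACTOR_DEFAULT,
) -> float:
    """Series evaluation of 0F1((d+2)/2; -x**2/4) with recursive terms.

    Terms are generated by the two-term recursion
    term_n = term_{n-1} * (-x^2/4) / ((b+n-1) n), b = (d+2)/2 — no
    factorial or Gamma evaluations.  Summation stops once two consecutive
    terms are below ``tol`` relative to the partial sum (a single small
    term of an alternating series can be accidental).

    Raises :class:`PrecisionLossError` when the largest intermediate term
    exceeds ``guard_factor`` times the partial sum (the caller must use the
    asymptotic regime), and :class:`ConvergenceError` when ``n_max`` terms
    do not suffice.
    """
    if tol <= 0:
        raise DomainError("tol must be positive")
    HyperArg(d, x)  # validate
    b = (d + 2) / 2.0
    z = -(x * x) / 4.0
    term = 1.0
    total = 1.0
    max_abs = 1.0
    small_streak = 0
    for n in range(1, n_max + 1):
        term *= z / ((b + n - 1.0) * n)
        total += term
        max_abs = max(max_abs, abs(term))
        if abs(term) < tol * max(abs(total), 1e-300):
            small_streak += 1
            if small_streak >= 2:
                if max_abs > guard_factor * max(abs(total), 1e-300):
                    raise PrecisionLossError(
                        f"series dynamic range {max_abs / max(abs(total), 1e-300):.2e} "
                        f"exceeds guard {guard_factor:.0e} at d={d}, x={x:g}"
                    )
                return total
        else:
            small_streak = 0
    raise ConvergenceError(f"0F1 series not converged in {n_max} terms at d={d}, x={x:g}")


def asymptotic_coefficients(d: int, k_terms: int) -> np.ndarray:
    """Coefficients c_k of the large-argument expansion

        0F1((d+2)/2; -x^2/4) ~ Gamma((d+2)/2)/sqrt(pi) (x/2)^nu
                               * sum_k c_k cos(x + pi (nu-k)/2) x^-k

    with nu = -(d+1)/2.  Generated by the recursion
    a_k = a_{k-1} (4 m^2 - (2k-1)^2) / (8 k), m = d/2, c_k = (-1)^k a_k.
    The expansion terminates for odd d (c_k = 0 for k > d - 1 when d is
    1 or 3), so two terms are exact there; for d = 2 it is a genuine
    asymptotic series.
    """
    if d not in (1, 2, 3):
        raise DomainError(f"d must be 1, 2 or 3, got {d}")
    if k_terms < 1:
        raise DomainError("k_terms must be >= 1")
    m = d / 2.0
    a = np.empty(k_terms)
    a[0] = 1.0
    for k in range(1, k_terms):
        a[k] = a[k - 1] * (4.0 * m * m - (2 * k - 1) ** 2) / (8.0 * k)
    signs = (-1.0) ** np.arange(k_terms)
    return signs * a


def f01_asymptotic(d: int, x, k_terms: int = 2):
    """Asymptotic evaluation of 0F1((d+2)/2; -x**2/4), truncated at
    ``k_terms`` terms (two suffice for d=1,3 where the expansion
    terminates exactly).

    Vectorized over ``x``.  Raises :class:`DomainError` for x below
    ``ASYMPTOTIC_FLOOR`` where the expansion is meaningless.
    """
    xarr = np.asarray(x, dtype=float)
    if np.any(xarr < ASYMPTOTIC_FLOOR):
        raise DomainError(
            f"asymptotic expansion invalid for x < {ASYMPTOTIC_FLOOR:g}"
        )
    b = (d + 2) / 2.0
    nu = -b + 0.5
    cs = asymptotic_coefficients(d, k_terms)
    pref = special.gamma(b) / math.sqrt(math.pi) * (xarr / 2.0) ** nu
    acc = np.zeros_like(xarr)
    for k, ck in enumerate(cs):
        acc += ck * np.cos(xarr + math.pi * (nu - k) / 2.0) * xarr ** (-float(k))
    out = pref * acc
    if out.ndim == 0:
        return float(out)
    return out


def regime_boundaries(
    series_eval,
    asym_eval,
    porod_eval=None,
    q_lo: float = 0.3,
    q_hi: float = 80.0,
    n_scan: int = 400,
    tol: float = 1e-5,
) -> RegimeBoundaries:
    """Locate the Regime I->II and II->III switch points on a log q-grid.

    ``series_eval(q)`` must raise :class:`PrecisionLossError` /
    :class:`ConvergenceError` once cancellation makes it unusable;
    ``asym_eval(q)`` is assumed valid at large q.  q12 is the largest scan
    point where both evaluate and agree relatively within ``tol``.  q23 is
    the smallest scan point beyond which the non-oscillating Porod term
    ``porod_eval`` stays within ``tol`` of the full Regime II value over
    the following decade; +inf when ``porod_eval`` is None (monodisperse:
    oscillations never die out, Regime III does not exist).

    When no overlap window exists at ``tol``, the search is retried at
    10*tol with a warning; failing that a :class:`ConvergenceError` is
    raised.
    """
    grid = np.geomspace(q_lo, q_hi, n_scan)

    def _find_q12(t):
        best = None
        best_mis = None
        for q in grid:
            try:
                s = series_eval(q)
            except (PrecisionLossError, ConvergenceError):
                break
            a = asym_eval(q)
            scale = max(abs(s), abs(a), 1e-300)
            mis = abs(s - a) / scale
            if mis < t:
                best, best_mis = q, mis
        return best, best_mis

    q12, mis12 = _find_q12(tol)
    used_tol = tol
    if q12 is None:
        warnings.warn(
            f"no Regime I/II overlap at tol={tol:g}; retrying at {10 * tol:g}",
            stacklevel=2,
        )
        used_tol = 10 * tol
        q12, mis12 = _find_q12(used_tol)
        if q12 is None:
            raise ConvergenceError("no Regime I/II overlap window found")

    if porod_eval is None:
        return RegimeBoundaries(q12, math.inf, (mis12, 0.0))

    q23 = None
    mis23 = None
    for q in grid[grid > q12]:
        decade = np.geomspace(q, 10.0 * q, 16)
        a2 = np.array([asym_eval(v) for v in decade])
        a3 = np.array([porod_eval(v) for v in decade])
        mism = np.max(np.abs(a2 - a3) / np.maximum(np.abs(a3), 1e-300))
        if mism < used_tol:
            q23, mis23 = q, mism
            break
    if q23 is None:
        # Porod term never matches within the scan: Regime III disabled
        return RegimeBoundaries(q12, math.inf, (mis12, math.inf))
    return RegimeBoundaries(q12, max(q23, q12), (mis12, mis23))
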