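"""Regime-switched, size-averaged one-dimensional form-factor profiles.

A :class:`SizeAveragedProfile` evaluates the Schulz–Zimm averages

    P_d(q) = ⟨F_d(qR)²⟩      and      F̄_d(q) = ⟨F_d(qR)⟩

for a single characteristic dimension R with mean R̄ and polydispersity σ,
switching between three regimes:

* Regime I  (q <= q12): a single-sum power series in q² with q-independent
  coefficients built once by recursion (powers, Pochhammer ratios and size
  moments all advance by two-term recursions — no special functions).
* Regime II (q12 < q <= q23): the squared asymptotic expansion of F_d,
  averaged term by term over the size law in closed form (damped cosines
  and arctan terms).  For d = 1, 3 the expansion terminates, so Regime II
  is exact; for d = 2 three terms are kept.
* Regime III (q > q23): only the non-oscillating part of Regime II — the
  Porod tail.  It exists only for polydisperse sizes (monodisperse
  oscillations never damp out; q23 = inf then).

The switch points are located at build time by scanning for the overlap
window of the regimes, so a profile evaluation touches only elementary
functions and the pre-computed coefficient tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .distributions import SizeDistribution, damped_cos, neg_moment
from .errors import ConvergenceError, DomainError, PrecisionLossError
from .hypercore import (
    GUARD_FACTOR_DEFAULT,
    RegimeBoundaries,
    SeriesCoefficients,
    asymptotic_coefficients,
    regime_boundaries,
)

__all__ = ["SizeAveragedProfile"]


def _series_scalar(coeffs: np.ndarray, q: float, tol: float, guard: float) -> float:
    """Sum sum_n coeffs[n] q^{2n} with the termination and cancellation
    rules of the series regime (two consecutive small terms; dynamic-range
    guard)."""
    t = q * q
    total = 0.0
    power = 1.0
    max_abs = 0.0
    small = 0
    for n, c in enumerate(coeffs):
        term = c * power
        total += term
        power *= t
        max_abs = max(max_abs, abs(term))
        if n >= 1 and abs(term) < tol * max(abs(total), 1e-300):
            small += 1
            if small >= 2:
                if max_abs > guard * max(abs(total), 1e-300):
                    raise PrecisionLossError(
                        f"series cancellation guard fired at q={q:g}"
                    )
                return total
        else:
            small = 0
    raise ConvergenceError(f"series not converged within {len(coeffs)} terms at q={q:g}")


class SizeAveragedProfile:
    """Size-averaged P and mean amplitude of one F_d factor.

    Parameters
    ----------
    d : 1, 2 or 3 — dimensionality of the rotational symmetry.
    size : SizeDistribution — mean R̄ (nm) and relative width σ (σ=0 is
        monodisperse).
    tol : series build / truncation tolerance.
    boundary_tol : required relative overlap mismatch at the regime
        switch points.
    """

    def __init__(
        self,
        d: int,
        size: SizeDistribution,
        tol: float = 1e-6,
        boundary_tol: float = 1e-5,
        n_max: int = 220,
        guard_factor: float = GUARD_FACTOR_DEFAULT,
    ) -> None:
        if d not in (1, 2, 3):
            raise DomainError(f"d must be 1, 2 or 3, got {d}")
        self.d = d
        self.size = size
        self.tol = tol
        self.guard_factor = guard_factor
        self.n_asym = 3 if d == 2 else 2
        self._build_series(n_max)
        self._build_asym_tables()
        self._locate_boundaries(boundary_tol)

    # -- construction ------------------------------------------------------

    def _build_series(self, n_max: int) -> None:
        d, b = self.d, (self.d + 2) / 2.0
        z = self.size.z
        R = self.size.mean_size
        mono = self.size.monodisperse
        cP = np.empty(n_max + 1)
        cF = np.empty(n_max + 1)
        cP[0] = cF[0] = 1.0
        ratio_base = -(R * R) / 4.0
        for n in range(1, n_max + 1):
            # squared-amplitude single-sum coefficient recursion
            aratio = (d + 2 * n) * (d + 2 * n - 1.0) / ((d + n) * n * (b + n - 1.0) ** 2)
            # size-moment ratio <R^{2n}>/<R^{2n-2}> / R̄² = (z+2n-1)(z+2n)/(z+1)²
            if mono:
                mratio = 1.0
            else:
                mratio = (z + 2 * n - 1.0) * (z + 2 * n) / (z + 1.0) ** 2
            cP[n] = cP[n - 1] * aratio * mratio * ratio_base
            cF[n] = cF[n - 1] * mratio * ratio_base / ((b + n - 1.0) * n)
        self._cP_full = cP
        self._cF_full = cF
        self.coefficients = SeriesCoefficients(cP, n_max, self.tol)

    def _build_asym_tables(self) -> None:
        """Term table of the squared asymptotic expansion.

        P_II(q) = pref * sum_{j<=k} (qR̄)^{-kk} [ A_const_{jk} +
                  w_{jk} <(R/R̄)^{-kk} cos(2qR + φ_{jk})> ],
        kk = (d+1) + j + k, φ = πν - π(j+k)/2, ν = -(d+1)/2.
        """
        d = self.d
        b = (d + 2) / 2.0
        nu = -b + 0.5
        cs = asymptotic_coefficients(d, self.n_asym)
        self._nu = nu
        self._asym_cs = cs
        self._pref_P = (special.gamma(b) / math.sqrt(math.pi)) ** 2 * 2.0 ** (-2.0 * nu)
        self._pref_F = special.gamma(b) / math.sqrt(math.pi) * 2.0 ** (-nu)
        kk_list, wosc, wconst, phases = [], [], [], []
        for j in range(self.n_asym):
            for k in range(j, self.n_asym):
                w = (1.0 if j == k else 2.0) / 2.0 * cs[j] * cs[k]
                kk_list.append((d + 1.0) + j + k)
                wosc.append(w)
                wconst.append(w * math.cos(math.pi * (k - j) / 2.0))
                phases.append(math.pi * nu - math.pi * (j + k) / 2.0)
        self._kk = np.array(kk_list)
        self._wosc = np.array(wosc)
        self._wconst = np.array(wconst)
        self._phases = np.array(phases)
        if self.size.monodisperse:
            self._nm = np.ones_like(self._kk)
            self._porod_ok = False
        else:
            z = self.size.z
            kk_needed = self._kk.max()
            if z + 1.0 - kk_needed <= 0.0:
                raise DomainError(
                    f"polydispersity too large for the d={self.d} asymptotic "
                    f"regime: need z > {kk_needed - 1:g}, got z = {z:g}"
                )
            self._nm = np.array([neg_moment(self.size, kk) for kk in self._kk])
            # Porod (Regime III) needs the leading negative moment to exist,
            # which the check above already guarantees.
            self._porod_ok = True

    def _locate_boundaries(self, boundary_tol: float) -> None:
        R = self.size.mean_size

        def series_eval(q):
            return _series_scalar(self._cP_full, q, self.tol, self.guard_factor)

        def asym_eval(q):
            return float(self.asym_P(np.asarray([q]))[0])

        porod_eval = None
        if self._porod_ok:
            def porod_eval(q):  # noqa: E306
                return float(self.porod_P(np.asarray([q]))[0])

        self.boundaries: RegimeBoundaries = regime_boundaries(
            series_eval,
            asym_eval,
            porod_eval,
            q_lo=0.3 / R,
            q_hi=80.0 / R,
            n_scan=300,
            tol=boundary_tol,
        )
        # trim the stored series to the order needed at q12, and bin the
        # series region so small arguments use short polynomials (the hot
        # path of oriented patterns); lengths from a log-term estimate
        # (the raw terms overflow long before they matter)
        n_arr = np.arange(len(self._cP_full))

        def keep_at(q):
            log_t = 2.0 * math.log(q)
            with np.errstate(divide="ignore"):  # underflowed tail coefficients
                log_terms = np.log(np.abs(self._cP_full)) + n_arr * log_t
            k = int(np.max(np.nonzero(log_terms > log_terms.max() - 40.0)[0]))
            return min(max(8, k + 3), len(self._cP_full) - 1)

        keep = keep_at(self.boundaries.q12)
        self._cP = self._cP_full[: keep + 1]
        self._cF = self._cF_full[: keep + 1]
        self._bin_edges = self.boundaries.q12 * np.array([0.125, 0.25, 0.5, 1.0])
        self._bin_ncoef = [keep_at(q) + 1 for q in self._bin_edges]

    # -- regime evaluators (vectorized over q) -----------------------------

    def _binned_polyval(self, q, coeffs):
        q = np.asarray(q, dtype=float)
        out = np.empty_like(q)
        done = np.zeros(q.shape, dtype=bool)
        for edge, n in zip(self._bin_edges, self._bin_ncoef):
            m = ~done & (q <= edge)
            if m.any():
                out[m] = np.polynomial.polynomial.polyval(q[m] * q[m], coeffs[:n])
                done |= m
        if not done.all():
            m = ~done
            out[m] = np.polynomial.polynomial.polyval(q[m] * q[m], coeffs)
        return out

    def series_P(self, q):
        return self._binned_polyval(q, self._cP)

    def series_F(self, q):
        return self._binned_polyval(q, self._cF)

    def asym_P(self, q):
        # shared transcendentals across the (j,k) term table: one pow, one
        # log1p/arctan, then an exp+cos per term — this is the hot path of
        # oriented 2D patterns
        q = np.asarray(q, dtype=float)
        x = q * self.size.mean_size
        invx = 1.0 / x
        kk0 = float(self._kk.min())
        power = invx**kk0
        mono = self.size.monodisperse
        if not mono:
            z = self.size.z
            y = 2.0 * x / (z + 1.0)
            lb = np.log1p(y * y)
            at = np.arctan(y)
        out = np.zeros_like(x)
        order = np.argsort(self._kk, kind="stable")
        cur = kk0
        for i in order:
            kk = float(self._kk[i])
            while cur < kk - 0.5:
                power = power * invx
                cur += 1.0
            if mono:
                osc = np.cos(2.0 * x + self._phases[i])
                out += power * (self._wconst[i] + self._wosc[i] * osc)
            else:
                m = self.size.z + 1.0 - kk
                osc = np.exp(-0.5 * m * lb) * np.cos(m * at + self._phases[i])
                out += power * self._nm[i] * (self._wconst[i] + self._wosc[i] * osc)
        return self._pref_P * out

    def porod_P(self, q):
        """Non-oscillating part of Regime II (Porod tail and corrections)."""
        q = np.asarray(q, dtype=float)
        x = q * self.size.mean_size
        out = np.zeros_like(x)
        for kk, wc, nm in zip(self._kk, self._wconst, self._nm):
            if wc != 0.0:
                out += wc * nm * x ** (-kk)
        return self._pref_P * out

    def asym_F(self, q):
        q = np.asarray(q, dtype=float)
        x = q * self.size.mean_size
        nu = self._nu
        out = np.zeros_like(x)
        for k, ck in enumerate(self._asym_cs):
            s = k - nu  # positive real inverse power
            ph = math.pi * (nu - k) / 2.0
            out += ck * x ** (-s) * damped_cos(self.size, q, s, 1.0, ph)
        return self._pref_F * out

    # -- public piecewise evaluators ---------------------------------------

    def P(self, q):
        """⟨F_d(qR)²⟩, regime-switched; accepts arrays of any shape."""
        q = np.abs(np.asarray(q, dtype=float))
        scalar = q.ndim == 0
        q = np.atleast_1d(q)
        out = np.empty_like(q)
        b = self.boundaries
        m1 = q <= b.q12
        m3 = q > b.q23
        m2 = ~m1 & ~m3
        if m1.any():
            out[m1] = self.series_P(q[m1])
        if m2.any():
            out[m2] = self.asym_P(q[m2])
        if m3.any():
            out[m3] = self.porod_P(q[m3])
        return float(out[0]) if scalar else out

    def F(self, q):
        """⟨F_d(qR)⟩, regime-switched (series below q12, damped asymptotic
        above; the mean amplitude has no non-oscillating tail)."""
        q = np.abs(np.asarray(q, dtype=float))
        scalar = q.ndim == 0
        q = np.atleast_1d(q)
        out = np.empty_like(q)
        m1 = q <= self.boundaries.q12
        if m1.any():
            out[m1] = self.series_F(q[m1])
        if (~m1).any():
            out[~m1] = self.asym_F(q[~m1])
        return float(out[0]) if scalar else out

    def porod_coefficient(self) -> float:
        """K with lim q⁴R̄⁴ P(q) = K for d=3 (the classic Porod constant);
        for d=1,2 the leading tail is K (qR̄)^{-(d+1)} instead."""
        if not self._porod_ok:
            raise DomainError("Porod tail undefined for a monodisperse profile")
        lead = int(np.argmin(self._kk))
        return float(self._pref_P * self._wconst[lead] * self._nm[lead])
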