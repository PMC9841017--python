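"""Size and orientation distributions.

Sizes follow the Schulz–Zimm (Gamma) law

    h(R) ∝ R^z exp(-(z+1) R / R̄),   z = 1/σ² - 1,

whose moments are Pochhammer ratios ⟨R^k⟩/R̄^k = (z+1)_k/(z+1)^k and whose
averages of damped trigonometric terms ⟨R^{-k} cos(c q R + φ)⟩ have closed
forms in powers of (1+y²) and arctan(y), y = c q R̄/(z+1).  These closed
forms are what make the asymptotic regimes of the form-factor engine
analytic.  σ = 0 is accepted as the monodisperse (z → ∞) limit, for which
every average degenerates to the plain trigonometric value.

Orientations are uniaxial: a deviation angle δ ∈ [0, π/2] from a director,
with density h(δ) and solid-angle weight sin δ.  The q-independent moments

    H_{2l,2m} = ⟨cos^{2l}δ sin^{2m}δ⟩

feed the oriented form-factor coefficients, and S = (3 H_{2,0} - 1)/2 is
the orientational order parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, special

from .errors import ConvergenceError, DomainError

__all__ = [
    "SizeDistribution",
    "OrientationDistribution",
    "HMatrix",
    "moment_ratio",
    "neg_moment",
    "damped_cos",
    "avg_trig",
    "h_integrals",
    "order_parameter",
]


@dataclass(frozen=True)
class SizeDistribution:
    """Schulz–Zimm size law with mean ``mean_size`` (nm) and relative
    standard deviation ``sigma``; ``sigma = 0`` means monodisperse."""

    mean_size: float
    sigma: float

    def __post_init__(self) -> None:
        if self.mean_size <= 0:
            raise DomainError("mean_size must be positive")
        if not (0.0 <= self.sigma < 1.0):
            raise DomainError(f"sigma must lie in [0, 1), got {self.sigma}")

    @property
    def z(self) -> float:
        """Polydispersity parameter z = 1/sigma**2 - 1 (inf if monodisperse)."""
        if self.sigma == 0.0:
            return math.inf
        return 1.0 / self.sigma**2 - 1.0

    @property
    def monodisperse(self) -> bool:
        return self.sigma == 0.0

    @classmethod
    def from_z(cls, mean_size: float, z: float) -> "SizeDistribution":
        if z <= 0:
            raise DomainError("z must be positive")
        return cls(mean_size, 1.0 / math.sqrt(z + 1.0))

    def pdf(self, r):
        """Number-weighted density on r > 0 (delta handled by callers)."""
        if self.monodisperse:
            raise DomainError("monodisperse distribution has no density")
        z = self.z
        a = (z + 1.0) / self.mean_size
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        m = r > 0
        logp = z * np.log(r[m]) - a * r[m] + (z + 1) * math.log(a) - special.gammaln(z + 1)
        out[m] = np.exp(logp)
        return out


def moment_ratio(dist: SizeDistribution, k: int) -> float:
    """⟨R^k⟩ / R̄^k = (z+1)_k / (z+1)^k for integer k >= 0."""
    if k < 0:
        raise DomainError("k must be >= 0")
    if dist.monodisperse:
        return 1.0
    z = dist.z
    out = 1.0
    for j in range(k):
        out *= (z + 1.0 + j) / (z + 1.0)
    return out


def neg_moment(dist: SizeDistribution, k: float) -> float:
    """⟨(R/R̄)^{-k}⟩ = (z+1)^k Γ(z+1-k)/Γ(z+1), real k; needs z > k-1."""
    if dist.monodisperse:
        return 1.0
    z = dist.z
    if z + 1.0 - k <= 0.0:
        raise DomainError(
            f"negative moment of order {k} does not exist for z = {z:g} (need z > k-1)"
        )
    return math.exp(special.gammaln(z + 1.0 - k) - special.gammaln(z + 1.0) + k * math.log(z + 1.0))


def damped_cos(dist: SizeDistribution, q, k: float, freq: float = 2.0, phase: float = 0.0):
    """⟨(R/R̄)^{-k} cos(freq·q·R + phase)⟩ in closed form (vectorized in q).

    For the Gamma law this is the modulus–arctan representation
    ⟨(R/R̄)^{-k}⟩ (1+y²)^{-(z+1-k)/2} cos((z+1-k) arctan y + phase)
    with y = freq q R̄/(z+1); in the monodisperse limit it degenerates to
    cos(freq q R̄ + phase).
    """
    q = np.asarray(q, dtype=float)
    if dist.monodisperse:
        out = np.cos(freq * q * dist.mean_size + phase)
        return float(out) if out.ndim == 0 else out
    z = dist.z
    m = z + 1.0 - k
    if m <= 0.0:
        raise DomainError(f"damped average of order {k} needs z > k-1 (z = {z:g})")
    nm = neg_moment(dist, k)
    y = freq * q * dist.mean_size / (z + 1.0)
    out = nm * (1.0 + y * y) ** (-m / 2.0) * np.cos(m * np.arctan(y) + phase)
    return float(out) if out.ndim == 0 else out


_AVG_KINDS = ("const", "cos2", "sin2", "sincos", "cos", "sin")


def avg_trig(dist: SizeDistribution, q, k: float, kind: str):
    """Closed-form ⟨trig(qR) / (qR)^k⟩ over the Schulz–Zimm law.

    kind ∈ {'const','cos2','sin2','sincos','cos','sin'} selects
    1, cos²(qR), sin²(qR), sin(qR)cos(qR), cos(qR), sin(qR).
    Vectorized in q (q > 0 required for k > 0).
    """
    if kind not in _AVG_KINDS:
        raise DomainError(f"unknown kind {kind!r}; choose from {_AVG_KINDS}")
    q = np.asarray(q, dtype=float)
    if k > 0 and np.any(q <= 0):
        raise DomainError("q must be positive for inverse-power averages")
    scale = (q * dist.mean_size) ** (-float(k)) if k != 0 else np.ones_like(q)
    nm = neg_moment(dist, k)
    if kind == "const":
        out = scale * nm
    elif kind == "cos2":
        out = 0.5 * scale * (nm + damped_cos(dist, q, k, 2.0, 0.0))
    elif kind == "sin2":
        out = 0.5 * scale * (nm - damped_cos(dist, q, k, 2.0, 0.0))
    elif kind == "sincos":
        # sin cos = sin(2qR)/2 = cos(2qR - pi/2)/2
        out = 0.5 * scale * damped_cos(dist, q, k, 2.0, -0.5 * math.pi)
    elif kind == "cos":
        out = scale * damped_cos(dist, q, k, 1.0, 0.0)
    else:  # sin
        out = scale * damped_cos(dist, q, k, 1.0, -0.5 * math.pi)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# orientation distributions


@dataclass(frozen=True)
class OrientationDistribution:
    """Uniaxial distribution of the deviation angle δ from the director.

    kind: 'delta' (perfect alignment), 'uniform_isotropic', or
    'gaussian_cone' with density h(δ) ∝ exp(-δ²/(2 width²)) on [0, π/2]
    (width in radians).
    """

    kind: str
    width: float = 0.0

    _KINDS = ("delta", "uniform_isotropic", "gaussian_cone")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise DomainError(f"unknown orientation kind {self.kind!r}")
        if self.kind == "gaussian_cone" and self.width <= 0:
            raise DomainError("gaussian_cone needs width > 0")

    def density(self, delta):
        """Unnormalized h(δ) on [0, π/2] (no sin δ weight)."""
        delta = np.asarray(delta, dtype=float)
        if self.kind == "uniform_isotropic":
            return np.ones_like(delta)
        if self.kind == "gaussian_cone":
            return np.exp(-(delta**2) / (2.0 * self.width**2))
        raise DomainError("delta distribution has no density")


@dataclass
class HMatrix:
    """Orientation moments H_{2l,2m} = ⟨cos^{2l}δ sin^{2m}δ⟩ for l+m <= n.

    entry(l, m) indexes by half-order, i.e. entry(1, 0) is H_{2,0}.
    """

    order: int
    h: np.ndarray  # shape (order+1, order+1); h[l, m] valid for l+m <= order

    def entry(self, l: int, m: int) -> float:
        if l < 0 or m < 0 or l + m > self.order:
            raise DomainError(f"H entry ({l},{m}) outside order {self.order}")
        return float(self.h[l, m])


def _h_quadrature(odist: OrientationDistribution, l: int, m: int) -> float:
    def num(d):
        return np.cos(d) ** (2 * l) * np.sin(d) ** (2 * m) * odist.density(d) * np.sin(d)

    def den(d):
        return odist.density(d) * np.sin(d)

    top, etop = integrate.quad(num, 0.0, math.pi / 2.0, epsabs=1e-12, epsrel=1e-10, limit=200)
    bot, ebot = integrate.quad(den, 0.0, math.pi / 2.0, epsabs=1e-12, epsrel=1e-10, limit=200)
    if bot <= 0 or etop > 1e-8 * max(abs(top), 1e-12) + 1e-10:
        raise ConvergenceError(f"H-integral quadrature failed at (l,m)=({l},{m})")
    return top / bot


@lru_cache(maxsize=64)
def _h_integrals_cached(kind: str, width: float, n_max: int) -> HMatrix:
    odist = OrientationDistribution(kind, width)
    h = np.zeros((n_max + 1, n_max + 1))
    for l in range(n_max + 1):
        for m in range(n_max + 1 - l):
            if kind == "delta":
                h[l, m] = 1.0 if m == 0 else 0.0
            else:
                h[l, m] = _h_quadrature(odist, l, m)
    return HMatrix(n_max, h)


def h_integrals(odist: OrientationDistribution, n_max: int) -> HMatrix:
    """All H_{2l,2m} with l+m <= n_max; q-independent pre-computation.

    'delta' is returned analytically (H = 1 if m == 0 else 0); other kinds
    use adaptive quadrature at 1e-10 tolerance.  Results are cached per
    (distribution, n_max).
    """
    if n_max < 1:
        raise DomainError("n_max must be >= 1")
    return _h_integrals_cached(odist.kind, odist.width, n_max)


def order_parameter(odist: OrientationDistribution) -> float:
    """Uniaxial order parameter S = ⟨(3 cos²δ - 1)/2⟩ = (3 H_{2,0} - 1)/2."""
    if odist.kind == "delta":
        return 1.0
    h20 = h_integrals(odist, 1).entry(1, 0)
    return (3.0 * h20 - 1.0) / 2.0
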