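"""Shape catalogue: size- and orientation-averaged form factors.

Every supported body is assembled from one to three
:class:`~hyperscat.profiles.SizeAveragedProfile` factors evaluated at
direction-dependent arguments, with the orientational average carried out
on a fixed Gauss–Legendre node set that is computed once (q-independent):

========================  ========================================  =========
kind                      factors (d, characteristic size)          nodes
========================  ========================================  =========
sphere                    (3, R)                                    —
cylinder                  (2, R) × (1, L/2)                         u = cos α
disk_lamella (2 sizes)    (2, D/2) × (1, T/2)                       u = cos α
disk_lamella (1 size)     (1, T/2)   [lamellar normal direction]    —
biaxial_ellipsoid         (3, 1) at q·R_eff(θ)                      u = cos θ
triaxial_ellipsoid        (3, 1) at q·R_eff(θ,φ)                    (u, φ)
cube_parallelepiped       (1, a/2) × (1, b/2) × (1, c/2)            (u, φ)
========================  ========================================  =========

Polydispersity convention: each independent characteristic dimension of a
factorizing shape (cylinder radius and length, parallelepiped edges)
carries its own Schulz–Zimm factor; ellipsoids are polydispersed by a
single shape-preserving scale factor (one Gamma law multiplying all
semi-axes).  The oracle module integrates exactly the same model.

For oriented assemblies the uniaxial phase average of the cylinder
(director along x) is provided both as the pre-computed double-series in
(q_x², q_y²) — the a_n, b_{l,n} coefficient tables built from the
orientation moments H_{2l,2m} — and as a joint average of the factor
product over pre-computed (δ, χ) nodes valid at all q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .distributions import (
    HMatrix,
    OrientationDistribution,
    SizeDistribution,
    h_integrals,
)
from .errors import DomainError
from .hypercore import RegimeBoundaries
from .profiles import SizeAveragedProfile

__all__ = [
    "ShapeSpec",
    "FormFactorModel",
    "PorodLimit",
    "precompute",
    "pq_iso",
    "fq_mean",
    "porod_limit",
    "pq_oriented",
    "oriented_longitudinal",
]

SHAPE_KINDS = (
    "sphere",
    "cylinder",
    "disk_lamella",
    "biaxial_ellipsoid",
    "triaxial_ellipsoid",
    "cube_parallelepiped",
)

#: Gauss–Legendre orders of the orientational average (1-angle / 2-angle)
N_NODES_1D = 96
N_NODES_2D = 80


@dataclass(frozen=True)
class ShapeSpec:
    """Geometry of one body.

    sizes (nm): sphere: (R,); cylinder: (R, L) with L the full length;
    disk_lamella: (thickness,) or (thickness, diameter);
    biaxial_ellipsoid: (a, c) semi-axes (a equatorial, c polar);
    triaxial_ellipsoid: (a, b, c) semi-axes;
    cube_parallelepiped: (a,) or (a, b, c) full edge lengths.
    """

    kind: str
    sizes: tuple

    def __post_init__(self) -> None:
        if self.kind not in SHAPE_KINDS:
            raise DomainError(f"unknown shape kind {self.kind!r}")
        sizes = tuple(float(s) for s in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        if any(s <= 0 for s in sizes):
            raise DomainError("all sizes must be positive")
        arity = {
            "sphere": (1,),
            "cylinder": (2,),
            "disk_lamella": (1, 2),
            "biaxial_ellipsoid": (2,),
            "triaxial_ellipsoid": (3,),
            "cube_parallelepiped": (1, 3),
        }[self.kind]
        if len(sizes) not in arity:
            raise DomainError(
                f"{self.kind} takes {arity} size(s), got {len(sizes)}"
            )

    @property
    def d(self) -> int:
        """Dimensionality class of the underlying amplitude."""
        return {
            "sphere": 3,
            "cylinder": 2,
            "disk_lamella": 1,
            "biaxial_ellipsoid": 3,
            "triaxial_ellipsoid": 3,
            "cube_parallelepiped": 1,
        }[self.kind]


@dataclass
class PorodLimit:
    """High-q tail constant K = lim q⁴ R̄⁴ ⟨P⟩; ``estimated`` marks a
    numerical estimate (anisometric shapes) vs the closed form (spheres)."""

    value: float
    estimated: bool


@dataclass
class _OrientedTables:
    hmat: HMatrix
    a_n: np.ndarray
    b_ln: np.ndarray  # b_ln[n, l]
    delta_nodes: np.ndarray
    chi_nodes: np.ndarray
    weights: np.ndarray  # joint (delta, chi) weights, normalized


@dataclass
class FormFactorModel:
    """Pre-computed evaluator state for one shape."""

    shape: ShapeSpec
    size_dists: list
    profiles: list
    node_weights: np.ndarray  # (M,)
    node_args: np.ndarray  # (n_profiles, M) multipliers of q
    boundaries: RegimeBoundaries
    tol: float
    oriented: dict = field(default_factory=dict)

    @property
    def is_compound(self) -> bool:
        return self.node_args.shape[1] > 1


def _gl_nodes(n: int, a: float, b: float):
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (b - a) * x + 0.5 * (b + a), 0.5 * (b - a) * w


def precompute(
    shape: ShapeSpec,
    dists,
    tol: float = 1e-4,
    series_tol: float = 1e-6,
    boundary_tol: float = 1e-5,
    n_nodes: int | None = None,
) -> FormFactorModel:
    """Build all q-independent coefficients for a shape.

    ``dists`` is either a single :class:`SizeDistribution` applied to the
    first characteristic dimension (the remaining ones get the same σ) or
    a list with one distribution per independent dimension.  The scale
    σ's enter the series coefficients through the Schulz moments; the
    orientation nodes are a fixed Gauss–Legendre set.
    """
    if tol <= 0:
        raise DomainError("tol must be positive")
    if isinstance(dists, SizeDistribution):
        dists = [dists]
    sigmas = [d.sigma for d in dists]

    def prof(d, mean, sigma):
        return SizeAveragedProfile(
            d,
            SizeDistribution(mean, sigma),
            tol=series_tol,
            boundary_tol=boundary_tol,
        )

    kind, sizes = shape.kind, shape.sizes
    if kind == "sphere":
        profiles = [prof(3, sizes[0], sigmas[0])]
        weights = np.ones(1)
        args = np.ones((1, 1))
    elif kind in ("cylinder", "disk_lamella"):
        if kind == "cylinder":
            radius, half_len = sizes[0], sizes[1] / 2.0
        elif len(sizes) == 2:
            radius, half_len = sizes[1] / 2.0, sizes[0] / 2.0
        else:
            # bare lamella: single d=1 factor along the layer normal
            profiles = [prof(1, sizes[0] / 2.0, sigmas[0])]
            weights = np.ones(1)
            args = np.ones((1, 1))
            return _finish(shape, dists, profiles, weights, args, tol)
        s_r = sigmas[0]
        s_l = sigmas[1] if len(sigmas) > 1 else sigmas[0]
        profiles = [prof(2, radius, s_r), prof(1, half_len, s_l)]
        u, w = _gl_nodes(n_nodes or N_NODES_1D, 0.0, 1.0)  # u = cos α
        weights = w
        args = np.vstack([np.sqrt(1.0 - u * u), u])
    elif kind == "biaxial_ellipsoid":
        a, c = sizes
        profiles = [prof(3, 1.0, sigmas[0])]
        u, w = _gl_nodes(n_nodes or N_NODES_1D, 0.0, 1.0)  # u = cos θ
        reff = np.sqrt(a * a * (1.0 - u * u) + c * c * u * u)
        weights = w
        args = reff[None, :]
    elif kind == "triaxial_ellipsoid":
        a, b, c = sizes
        profiles = [prof(3, 1.0, sigmas[0])]
        nn = n_nodes or N_NODES_2D
        u, wu = _gl_nodes(nn, 0.0, 1.0)
        phi, wp = _gl_nodes(nn, 0.0, math.pi / 2.0)
        uu, pp = np.meshgrid(u, phi, indexing="ij")
        s2 = 1.0 - uu * uu
        reff = np.sqrt(
            a * a * s2 * np.cos(pp) ** 2 + b * b * s2 * np.sin(pp) ** 2 + c * c * uu * uu
        )
        weights = np.outer(wu, wp).ravel() / (math.pi / 2.0)
        args = reff.ravel()[None, :]
    elif kind == "cube_parallelepiped":
        edges = sizes * 3 if len(sizes) == 1 else sizes
        sig = sigmas if len(sigmas) == 3 else [sigmas[0]] * 3
        profiles = [prof(1, e / 2.0, s) for e, s in zip(edges, sig)]
        nn = n_nodes or N_NODES_2D
        u, wu = _gl_nodes(nn, 0.0, 1.0)
        phi, wp = _gl_nodes(nn, 0.0, math.pi / 2.0)
        uu, pp = np.meshgrid(u, phi, indexing="ij")
        st = np.sqrt(1.0 - uu * uu)
        mu = np.stack([st * np.cos(pp), st * np.sin(pp), uu])  # (3, nn, nn)
        weights = np.outer(wu, wp).ravel() / (math.pi / 2.0)
        args = mu.reshape(3, -1)
    else:  # pragma: no cover — guarded by ShapeSpec
        raise DomainError(kind)
    return _finish(shape, dists, profiles, weights, args, tol)


def _finish(shape, dists, profiles, weights, args, tol) -> FormFactorModel:
    b = profiles[0].boundaries
    return FormFactorModel(
        shape=shape,
        size_dists=dists,
        profiles=profiles,
        node_weights=weights,
        node_args=args,
        boundaries=b,
        tol=tol,
    )


def _node_average(model: FormFactorModel, q, attr: str):
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    qf = np.atleast_1d(q).ravel()
    acc = np.ones((qf.size, model.node_weights.size))
    for p, arg in zip(model.profiles, model.node_args):
        vals = getattr(p, attr)(qf[:, None] * arg[None, :])
        acc *= vals
    out = acc @ model.node_weights
    out = out.reshape(np.atleast_1d(q).shape)
    return float(out[0]) if scalar else out


def pq_iso(model: FormFactorModel, q):
    """Isotropically orientation- and size-averaged form factor ⟨P(q)⟩.

    Vectorized over q; exactly 1 at q = 0."""
    return _node_average(model, q, "P")


def fq_mean(model: FormFactorModel, q):
    """Averaged amplitude ⟨F(q)⟩ for the decoupling approximation;
    same regime machinery applied to the un-squared series."""
    return _node_average(model, q, "F")


def porod_limit(model: FormFactorModel, n_probe: int = 24) -> PorodLimit:
    """Porod constant K = lim q⁴ R̄⁴ ⟨P⟩.

    Spheres use the closed form 9 (z+1)⁴ / (2 z (z-1)(z-2)(z-3)) (exact
    for the Schulz law, z > 3); anisometric shapes are estimated from the
    non-oscillating high-q evaluator.  A bare lamella has a q⁻² tail and
    no q⁻⁴ constant.
    """
    shape = model.shape
    if shape.kind == "sphere":
        dist = model.size_dists[0]
        if dist.monodisperse:
            return PorodLimit(4.5, False)  # z → ∞ limit of the closed form
        z = dist.z
        if z <= 3.0:
            raise DomainError(
                f"sphere Porod constant needs z > 3 (pole at z = 3); got z = {z:g}"
            )
        K = 9.0 * (z + 1.0) ** 4 / (2.0 * z * (z - 1.0) * (z - 2.0) * (z - 3.0))
        return PorodLimit(K, False)
    if shape.kind == "disk_lamella" and len(shape.sizes) == 1:
        raise DomainError("unoriented lamella decays as q^-2; no q^-4 Porod constant")
    for d in model.size_dists:
        if d.monodisperse:
            raise DomainError("anisometric Porod estimate needs polydispersity in every dimension")
    r_ref = model.shape.sizes[0]
    q23 = max(
        p.boundaries.q23 / float(np.median(np.abs(a[np.abs(a) > 1e-9])))
        for p, a in zip(model.profiles, model.node_args)
    )
    qs = np.geomspace(2.0 * q23, 8.0 * q23, n_probe)
    k_est = np.mean(qs**4 * r_ref**4 * pq_iso(model, qs))
    return PorodLimit(float(k_est), True)


# ---------------------------------------------------------------------------
# oriented assemblies (uniaxial director along the x axis)


def _oriented_tables(model: FormFactorModel, odist: OrientationDistribution,
                     n_max: int = 40, n_delta: int = 48, n_chi: int = 48) -> _OrientedTables:
    key = (odist.kind, odist.width)
    if key in model.oriented:
        return model.oriented[key]
    if model.shape.kind not in ("cylinder", "disk_lamella"):
        raise DomainError(
            f"oriented evaluation supports cylinders/disks, not {model.shape.kind}"
        )
    long_prof = model.profiles[-1]
    L = long_prof.size.mean_size  # half-length
    dist = long_prof.size
    hmat = h_integrals(odist, n_max)
    # a_n: series coefficient of the longitudinal factor with the phase
    # power pulled out:  a_n = S_n (2n)! L^{2n} / 4^n, where S_n is the
    # d=1 squared-series coefficient divided by (-R̄²/4)^n moment scaling.
    z = dist.z
    a_n = np.empty(n_max + 1)
    b_ln = np.zeros((n_max + 1, n_max + 1))
    Sn = 1.0  # series coefficient of (qL)^{2n}: A_n^{(1)} * mom_{2n} * (-1/4)^n
    fact2n = 1.0  # (2n)!
    for n in range(n_max + 1):
        if n > 0:
            aratio = (1 + 2 * n) * (2 * n) / ((1 + n) * n * (1.5 + n - 1.0) ** 2)
            mratio = 1.0 if dist.monodisperse else (z + 2 * n - 1.0) * (z + 2 * n) / (z + 1.0) ** 2
            Sn *= aratio * mratio * (-0.25)
            fact2n *= (2 * n - 1.0) * (2 * n)
        a_n[n] = Sn * fact2n * L ** (2 * n) / 4.0**n
        for l in range(n + 1):
            b_ln[n, l] = (
                4.0**l / (math.factorial(2 * l) * math.factorial(n - l) ** 2)
                * hmat.entry(l, n - l)
            )
    # joint (delta, chi) nodes for the all-q evaluator
    dnodes, dw = _gl_nodes(n_delta, 0.0, math.pi / 2.0)
    if odist.kind == "delta":
        dnodes, dw = np.zeros(1), np.ones(1)
        wd = np.ones(1)
    else:
        wd = odist.density(dnodes) * np.sin(dnodes) * dw
        wd = wd / wd.sum()
    chi = 2.0 * math.pi * (np.arange(n_chi) + 0.5) / n_chi
    wj = np.repeat(wd, chi.size) / chi.size
    tables = _OrientedTables(
        hmat=hmat,
        a_n=a_n,
        b_ln=b_ln,
        delta_nodes=np.repeat(dnodes, chi.size),
        chi_nodes=np.tile(chi, dnodes.size),
        weights=wj,
    )
    model.oriented[key] = tables
    return tables


def oriented_longitudinal(model: FormFactorModel, qx, qy,
                          odist: OrientationDistribution):
    """Longitudinal factor ⟨P_∥(q_x, q_y)⟩ of an oriented cylinder as the
    pre-computed double series sum_n a_n sum_l b_{l,n} (q_x²)^l (q_y²)^{n-l}
    built from the orientation moments H.  Valid while the phase series
    converges (low to intermediate q L)."""
    t = _oriented_tables(model, odist)
    qx2 = np.asarray(qx, dtype=float) ** 2
    qy2 = np.asarray(qy, dtype=float) ** 2
    qx2, qy2 = np.broadcast_arrays(qx2, qy2)
    out = np.zeros_like(qx2)
    for n in range(t.a_n.size):
        inner = np.zeros_like(qx2)
        for l in range(n + 1):
            inner += t.b_ln[n, l] * qx2**l * qy2 ** (n - l)
        out += t.a_n[n] * inner
    return out if out.ndim else float(out)


def pq_oriented(model: FormFactorModel, qx, qy, odist: OrientationDistribution):
    """Oriented form factor of a cylinder/disk assembly with director
    along x, averaged over sizes (analytically) and over the uniaxial
    orientation distribution (pre-computed (δ, χ) nodes).

    For each node the longitudinal phase is q·L(δ,χ) = q_x cos δ − q_y
    sin χ sin δ (per unit half-length) and the cross-section argument is
    the transverse component √(q² − (q·L̂)²); both factors are the
    analytically size-averaged profiles, so the per-pixel work is a
    weighted sum of elementary evaluations.
    """
    t = _oriented_tables(model, odist)
    cs_prof, long_prof = model.profiles[0], model.profiles[1]
    qx = np.asarray(qx, dtype=float)
    qy = np.asarray(qy, dtype=float)
    qx, qy = np.broadcast_arrays(qx, qy)
    shp = qx.shape
    qxf, qyf = qx.ravel(), qy.ravel()
    cd = np.cos(t.delta_nodes)[None, :]
    ssd = (np.sin(t.chi_nodes) * np.sin(t.delta_nodes))[None, :]
    out = np.empty(qxf.size)
    chunk = max(1, 4_000_000 // max(t.weights.size, 1))  # bounded temporaries
    for lo in range(0, qxf.size, chunk):
        xs = qxf[lo:lo + chunk, None]
        ys = qyf[lo:lo + chunk, None]
        qpar = xs * cd - ys * ssd
        qperp = np.sqrt(np.maximum(xs * xs + ys * ys - qpar * qpar, 0.0))
        vals = long_prof.P(np.abs(qpar)) * cs_prof.P(qperp)
        out[lo:lo + chunk] = vals @ t.weights
    out = out.reshape(shp)
    return out if out.ndim else float(out)


def fq_oriented(model: FormFactorModel, qx, qy, odist: OrientationDistribution):
    """Oriented mean amplitude ⟨F(q_x, q_y)⟩ over the same (δ, χ) nodes
    as :func:`pq_oriented` (decoupling-approximation numerator)."""
    t = _oriented_tables(model, odist)
    cs_prof, long_prof = model.profiles[0], model.profiles[1]
    qx = np.asarray(qx, dtype=float)
    qy = np.asarray(qy, dtype=float)
    qx, qy = np.broadcast_arrays(qx, qy)
    shp = qx.shape
    qxf, qyf = qx.ravel(), qy.ravel()
    cd = np.cos(t.delta_nodes)[None, :]
    ssd = (np.sin(t.chi_nodes) * np.sin(t.delta_nodes))[None, :]
    out = np.empty(qxf.size)
    chunk = max(1, 4_000_000 // max(t.weights.size, 1))  # bounded temporaries
    for lo in range(0, qxf.size, chunk):
        xs = qxf[lo:lo + chunk, None]
        ys = qyf[lo:lo + chunk, None]
        qpar = xs * cd - ys * ssd
        qperp = np.sqrt(np.maximum(xs * xs + ys * ys - qpar * qpar, 0.0))
        vals = long_prof.F(np.abs(qpar)) * cs_prof.F(qperp)
        out[lo:lo + chunk] = vals @ t.weights
    out = out.reshape(shp)
    return out if out.ndim else float(out)
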