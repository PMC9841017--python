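"""Crystallographic machinery: unit cell → reciprocal basis, reflection
lists with structure-factor extinction rules, peak shapes, Debye–Waller
damping, and the lattice factor Z(q).

Conventions: the 2π (q-space) convention for reciprocal vectors, so a
cubic cell of edge a has |a*| = 2π/a; the beam axis is +z and the cell is
rotated so that the requested (uvw) lattice direction is beam-parallel.
Z is normalized so that it tends to 1 far from every reflection, which
makes the (⟨Z⟩ − 1) correlation term of the decoupling approximation
vanish away from peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = [
    "UnitCell",
    "ReciprocalBasis",
    "PeakShape",
    "Reflection",
    "reciprocal_basis",
    "enumerate_reflections",
    "lattice_factor_2d",
    "lattice_factor_1d_iso",
    "powder_rings",
    "debye_waller",
]

LATTICE_TYPES = ("SC", "BCC", "FCC", "custom")


@dataclass(frozen=True)
class UnitCell:
    """Unit cell: edges a, b, c (nm), angles alpha, beta, gamma (degrees),
    centering type, beam direction (uvw) in cell coordinates, and an
    optional explicit basis (fractional positions) for 'custom'."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    lattice_type: str = "SC"
    uvw: tuple = (0, 0, 1)
    basis: tuple = ()

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise DomainError("cell edges must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not (0.0 < ang < 180.0):
                raise DomainError("cell angles must lie in (0°, 180°)")
        if self.lattice_type not in LATTICE_TYPES:
            raise DomainError(f"unknown lattice type {self.lattice_type!r}")
        if tuple(self.uvw) == (0, 0, 0):
            raise DomainError("uvw must not be the zero vector")

    @classmethod
    def cubic(cls, a: float, lattice_type: str = "SC", uvw=(0, 0, 1)) -> "UnitCell":
        return cls(a, a, a, 90.0, 90.0, 90.0, lattice_type, tuple(uvw))

    def basis_positions(self) -> np.ndarray:
        """Fractional atomic positions of the centering type."""
        if self.lattice_type == "SC":
            return np.array([[0.0, 0.0, 0.0]])
        if self.lattice_type == "BCC":
            return np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.5]])
        if self.lattice_type == "FCC":
            return np.array(
                [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]
            )
        if not self.basis:
            raise DomainError("custom lattice type needs explicit basis positions")
        return np.asarray(self.basis, dtype=float)

    def real_vectors(self) -> np.ndarray:
        """Rows a_E, b_E, c_E in an orthonormal lab frame (before the uvw
        rotation): the standard crystallographic Cartesian setting."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        ca, cb, cg, sg = np.cos(al), np.cos(be), np.cos(ga), np.sin(ga)
        av = np.array([self.a, 0.0, 0.0])
        bv = self.b * np.array([cg, sg, 0.0])
        cx = cb
        cy = (ca - cb * cg) / sg
        cz2 = 1.0 - cx * cx - cy * cy
        if cz2 <= 0:
            raise DomainError("degenerate cell angles (zero volume)")
        cv = self.c * np.array([cx, cy, math.sqrt(cz2)])
        return np.vstack([av, bv, cv])


@dataclass
class ReciprocalBasis:
    """Reciprocal vectors a*, b*, c* (nm⁻¹, rows) with the real-space rows
    used to build them; satisfies a_i · a*_j = 2π δ_ij."""

    astar: np.ndarray
    bstar: np.ndarray
    cstar: np.ndarray
    real_rows: np.ndarray

    def matrix(self) -> np.ndarray:
        return np.vstack([self.astar, self.bstar, self.cstar])

    def q_of_hkl(self, hkl) -> np.ndarray:
        return np.asarray(hkl, dtype=float) @ self.matrix()


def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit(v) to +z (Rodrigues)."""
    v = v / np.linalg.norm(v)
    zhat = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, zhat))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, zhat)
    s = np.linalg.norm(axis)
    axis /= s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def reciprocal_basis(cell: UnitCell) -> ReciprocalBasis:
    """Reciprocal basis of the cell, rotated so r_uvw is beam-parallel.

    Built by inverting the rotated real-space basis matrix (2π duality);
    raises :class:`DomainError` for degenerate cells.
    """
    Mreal = cell.real_vectors()
    r_uvw = np.asarray(cell.uvw, dtype=float) @ Mreal
    R = _rotation_to_z(r_uvw)
    rows = Mreal @ R.T  # rotated a_Er, b_Er, c_Er
    vol = float(np.linalg.det(rows))
    if abs(vol) < 1e-12:
        raise DomainError("singular cell: zero volume")
    recip = 2.0 * math.pi * np.linalg.inv(rows).T
    return ReciprocalBasis(recip[0], recip[1], recip[2], rows)


@dataclass(frozen=True)
class Reflection:
    """One Bragg reflection: Miller indices, reciprocal vector (nm⁻¹),
    multiplicity (1 for individually enumerated reflections) and the
    normalized squared structure factor."""

    hkl: tuple
    q_star: np.ndarray
    multiplicity: int
    f2: float


def _f2(cell: UnitCell, h: int, k: int, l: int) -> float:
    pos = cell.basis_positions()
    phase = 2.0 * math.pi * (pos @ np.array([h, k, l], dtype=float))
    f = np.exp(1j * phase).sum()
    return float(abs(f) ** 2) / len(pos) ** 2


def enumerate_reflections(
    basis: ReciprocalBasis, cell: UnitCell, qmax: float
) -> list[Reflection]:
    """All reflections with |q*_hkl| <= qmax and non-zero structure factor.

    FCC keeps (hkl) of uniform parity, BCC keeps h+k+l even, SC keeps all;
    'custom' evaluates |Σ_j exp(i q*·r_j)|² over the basis.  (000) is
    excluded.  The index ranges are conservative bounds from the real-space
    row lengths, so the list is complete up to qmax.
    """
    if qmax <= 0:
        raise DomainError("qmax must be positive")
    M = basis.matrix()
    lens = np.linalg.norm(basis.real_rows, axis=1)
    hmax = np.ceil(qmax * lens / (2.0 * math.pi)).astype(int) + 1
    out: list[Reflection] = []
    f2_cache: dict[tuple, float] = {}
    for h in range(-hmax[0], hmax[0] + 1):
        for k in range(-hmax[1], hmax[1] + 1):
            for l in range(-hmax[2], hmax[2] + 1):
                if h == 0 and k == 0 and l == 0:
                    continue
                key = (h % 2, k % 2, l % 2) if cell.lattice_type != "custom" else (h, k, l)
                if key not in f2_cache:
                    f2_cache[key] = _f2(cell, *((h, k, l) if cell.lattice_type == "custom" else key))
                f2 = f2_cache[key]
                if f2 < 1e-12:
                    continue
                q = np.array([h, k, l], dtype=float) @ M
                if np.dot(q, q) <= qmax * qmax:
                    out.append(Reflection((h, k, l), q, 1, f2))
    return out


@dataclass(frozen=True)
class PeakShape:
    """Bragg peak profile: 'gaussian', 'lorentzian' or 'pseudo_voigt'
    (eta = Lorentz fraction); sigma_q is the width (nm⁻¹).  The profile is
    normalized to unit integral over 3D q-space.  debye_waller_sigma (nm)
    is carried along for the intensity assembly."""

    kind: str = "pseudo_voigt"
    sigma_q: float = 0.02
    eta: float = 0.0
    debye_waller_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise DomainError(f"unknown peak shape {self.kind!r}")
        if self.sigma_q <= 0:
            raise DomainError("sigma_q must be positive")
        if not (0.0 <= self.eta <= 1.0):
            raise DomainError("eta must lie in [0, 1]")
        if self.debye_waller_sigma < 0:
            raise DomainError("debye_waller_sigma must be >= 0")

    def _mix(self) -> float:
        return {"gaussian": 0.0, "lorentzian": 1.0, "pseudo_voigt": self.eta}[self.kind]

    def cutoff(self) -> float:
        """Support radius beyond which the profile is treated as zero:
        8.5σ for a pure Gaussian (tail < e⁻³⁶), 60σ when a Lorentzian
        fraction is present (tail < 1e-7 of the peak height)."""
        return (8.5 if self._mix() == 0.0 else 60.0) * self.sigma_q

    def profile3d(self, dq2):
        """Unit-integral 3D profile as a function of |Δq|²."""
        s2 = self.sigma_q**2
        eta = self._mix()
        g = (2.0 * math.pi * s2) ** -1.5 * np.exp(-0.5 * dq2 / s2)
        if eta == 0.0:
            return g
        lo = self.sigma_q / (math.pi**2 * (dq2 + s2) ** 2)
        return (1.0 - eta) * g + eta * lo

    def ring_average(self, q, q_c):
        """Spherical average of profile3d centered at radius q_c, evaluated
        at radius q — the analytic powder line shape (exact for both the
        Gaussian and Lorentzian components, with the same finite support
        radius :meth:`cutoff` as the 2D evaluator)."""
        q = np.asarray(q, dtype=float)
        s2 = self.sigma_q**2
        eta = self._mix()
        cut = self.cutoff()
        out = np.zeros_like(q)
        m = (q > 0) & (np.abs(q - q_c) < cut)
        qm = q[m]
        near2 = (qm - q_c) ** 2
        far2 = np.minimum(qm + q_c, cut) ** 2
        if eta < 1.0:
            g = (
                (2.0 * math.pi * s2) ** -1.5
                * s2
                / (2.0 * qm * q_c)
                * (np.exp(-0.5 * near2 / s2) - np.exp(-0.5 * far2 / s2))
            )
            out[m] += (1.0 - eta) * g
        if eta > 0.0:
            lo = (
                self.sigma_q
                / (4.0 * math.pi**2 * qm * q_c)
                * (1.0 / (near2 + s2) - 1.0 / (far2 + s2))
            )
            out[m] += eta * lo
        return out


def lattice_factor_2d(reflections: list[Reflection], peak: PeakShape, qvec):
    """Z(q) = 1 + Σ_hkl f²_hkl L(q, q*_hkl) on arbitrary q vectors.

    ``qvec``: array of shape (..., 3).  The baseline 1 makes Z → 1 far
    from every reflection.  Z >= 0 everywhere by construction.
    """
    q = np.asarray(qvec, dtype=float)
    out = np.ones(q.shape[:-1])
    flat = q.reshape(-1, 3)
    lo = flat.min(axis=0)
    hi = flat.max(axis=0)
    cut = peak.cutoff()
    cut2 = cut * cut
    oflat = out.reshape(-1)
    for refl in reflections:
        qs = refl.q_star
        # bounding-box pre-filter: the peak support never reaches the grid
        if np.any(qs < lo - cut) or np.any(qs > hi + cut):
            continue
        dq = flat - qs
        dq2 = np.einsum("ij,ij->i", dq, dq)
        m = dq2 < cut2
        if m.any():
            oflat[m] += refl.multiplicity * refl.f2 * peak.profile3d(dq2[m])
    return out


def powder_rings(cell: UnitCell, qmax: float, tol: float = 1e-9):
    """Ring table (q_hkl, Σ multiplicity·f²) for the isotropic average,
    pre-computed once (q-independent)."""
    basis = reciprocal_basis(cell)
    refl = enumerate_reflections(basis, cell, qmax)
    mags = np.array([np.linalg.norm(r.q_star) for r in refl])
    weights = np.array([r.multiplicity * r.f2 for r in refl])
    order = np.argsort(mags)
    rings: list[list[float]] = []
    for qm, w in zip(mags[order], weights[order]):
        if rings and abs(qm - rings[-1][0]) < tol * max(qm, 1.0):
            rings[-1][1] += w
        else:
            rings.append([qm, w])
    return np.array(rings)


def lattice_factor_1d_iso(cell: UnitCell, peak: PeakShape, q, qmax: float | None = None):
    """Azimuthally (spherically) averaged lattice factor for a powder:
    1 + Σ_rings (Σ f² over the ring) × spherical ring profile.

    The ring table is pre-computed; ``qmax`` defaults to max(q) plus an
    8σ margin so no truncated ring leaks into the window."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise DomainError("q must be positive")
    if qmax is None:
        qmax = float(q.max()) + peak.cutoff()
    rings = powder_rings(cell, qmax)
    out = np.ones_like(q)
    for q_c, w in rings:
        out += w * peak.ring_average(q, q_c)
    return out


def debye_waller(q, sigma_dw: float):
    """Debye–Waller damping G(q) = exp(-σ_DW² q²) ∈ [0, 1]."""
    if sigma_dw < 0:
        raise DomainError("sigma_dw must be >= 0")
    q = np.asarray(q, dtype=float)
    out = np.exp(-(sigma_dw**2) * q * q)
    return float(out) if out.ndim == 0 else out
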