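"""Named parameter presets used throughout the tests, the validation mode
and the documentation examples: polydisperse spheres and triaxial
ellipsoids, an oriented-cylinder series spanning order parameters S≈1→0,
FCC-ordered spheres, and a BCC film for grazing incidence."""

from __future__ import annotations

from .distributions import OrientationDistribution, SizeDistribution
from .errors import ConfigError
from .formfactors import ShapeSpec
from .lattice import PeakShape, UnitCell
from .pattern import DetectorGeometry, GISASFilm, LatticeModel

__all__ = ["FIXTURES", "get_fixture", "benchmark_shapes"]


def _sphere_r3():
    return {
        "shape": ShapeSpec("sphere", (3.0,)),
        "dists": [SizeDistribution(3.0, 0.08)],
    }


def _triaxial_246():
    return {
        "shape": ShapeSpec("triaxial_ellipsoid", (2.0, 4.0, 6.0)),
        "dists": [SizeDistribution(1.0, 0.08)],
    }


def _cylinder_oriented():
    # widths (rad) spanning near-perfect alignment to near-isotropic
    widths = [0.08, 0.25, 0.45, 0.9, 1.6]
    odists = [OrientationDistribution("delta")] + [
        OrientationDistribution("gaussian_cone", w) for w in widths
    ] + [OrientationDistribution("uniform_isotropic")]
    return {
        "shape": ShapeSpec("cylinder", (2.0, 30.0)),
        "dists": [SizeDistribution(2.0, 0.1), SizeDistribution(15.0, 0.1)],
        "odists": odists,
    }


def _fcc_spheres():
    return {
        "shape": ShapeSpec("sphere", (14.0,)),
        "dists": [SizeDistribution(14.0, 0.08)],
        "lattice": LatticeModel(
            UnitCell.cubic(35.0, "FCC", (0, 0, 1)),
            PeakShape("pseudo_voigt", sigma_q=0.012, eta=0.0, debye_waller_sigma=1.0),
        ),
        "detector": DetectorGeometry(256, 256, 1.0, 0.1, 4000.0),
    }


def _bcc_film_gisas():
    return {
        "shape": ShapeSpec("sphere", (10.0,)),
        "dists": [SizeDistribution(10.0, 0.08)],
        "lattice": LatticeModel(
            UnitCell.cubic(22.0, "BCC", (0, 0, 1)),
            PeakShape("pseudo_voigt", sigma_q=0.02, eta=0.0, debye_waller_sigma=0.8),
        ),
        # film critical scattering vector q_zc = 2 k sin(alpha_c) ≈ 0.23 nm^-1
        "film": GISASFilm(alpha_i=0.25, delta=1.67e-5, beta=2e-7),
        "detector": DetectorGeometry(256, 256, 1.0, 0.1, 4000.0, beam_center=(128.0, 16.0)),
    }


FIXTURES = {
    "sphere_r3": _sphere_r3,
    "triaxial_246": _triaxial_246,
    "cylinder_oriented": _cylinder_oriented,
    "fcc_spheres": _fcc_spheres,
    "bcc_film_gisas": _bcc_film_gisas,
}


def get_fixture(name: str) -> dict:
    try:
        return FIXTURES[name]()
    except KeyError:
        raise ConfigError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None


def benchmark_shapes() -> dict:
    """Shape/distribution pairs of the timing benchmark: moderate axial
    ratios (3–8) and σ = 0.1 for every dimension."""
    return {
        "sphere": ({"shape": ShapeSpec("sphere", (3.0,)),
                    "dists": [SizeDistribution(3.0, 0.1)]}),
        "biaxial_ellipsoid": ({"shape": ShapeSpec("biaxial_ellipsoid", (2.0, 6.0)),
                               "dists": [SizeDistribution(1.0, 0.1)]}),
        "triaxial_ellipsoid": ({"shape": ShapeSpec("triaxial_ellipsoid", (2.0, 4.0, 6.0)),
                                "dists": [SizeDistribution(1.0, 0.1)]}),
        "cylinder": ({"shape": ShapeSpec("cylinder", (2.0, 16.0)),
                      "dists": [SizeDistribution(2.0, 0.1), SizeDistribution(8.0, 0.1)]}),
        "disk": ({"shape": ShapeSpec("disk_lamella", (2.0, 16.0)),
                  "dists": [SizeDistribution(1.0, 0.1), SizeDistribution(8.0, 0.1)]}),
        "cube": ({"shape": ShapeSpec("cube_parallelepiped", (4.0,)),
                  "dists": [SizeDistribution(2.0, 0.1)]}),
    }
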