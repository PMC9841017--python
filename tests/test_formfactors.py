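"""Assembled form factors: coefficient identities, normalization, Guinier
and Porod limits, regime continuity, and agreement with the
numerical-integration oracle for isotropic and oriented averages."""

import math

import numpy as np
import pytest
from scipy import integrate

import hyperscat as hs
from hyperscat.errors import DomainError
from hyperscat.formfactors import oriented_longitudinal
from hyperscat.oracle import OracleConfig, pq_numeric, pq_oriented_numeric

ALL_SHAPES = {
    "sphere": (hs.ShapeSpec("sphere", (3.0,)), [hs.SizeDistribution(3.0, 0.1)]),
    "cylinder": (
        hs.ShapeSpec("cylinder", (2.0, 16.0)),
        [hs.SizeDistribution(2.0, 0.1), hs.SizeDistribution(8.0, 0.1)],
    ),
    "disk": (
        hs.ShapeSpec("disk_lamella", (2.0, 16.0)),
        [hs.SizeDistribution(1.0, 0.1), hs.SizeDistribution(8.0, 0.1)],
    ),
    "lamella": (
        hs.ShapeSpec("disk_lamella", (4.0,)),
        [hs.SizeDistribution(2.0, 0.1)],
    ),
    "biaxial": (
        hs.ShapeSpec("biaxial_ellipsoid", (2.0, 6.0)),
        [hs.SizeDistribution(1.0, 0.1)],
    ),
    "triaxial": (
        hs.ShapeSpec("triaxial_ellipsoid", (2.0, 4.0, 6.0)),
        [hs.SizeDistribution(1.0, 0.1)],
    ),
    "cube": (
        hs.ShapeSpec("cube_parallelepiped", (4.0,)),
        [hs.SizeDistribution(2.0, 0.1)],
    ),
}


@pytest.fixture(scope="module")
def models():
    return {k: hs.precompute(s, d) for k, (s, d) in ALL_SHAPES.items()}


class TestSeriesCoefficients:
    def test_sphere_c0_is_one(self, sphere_model):
        assert sphere_model.profiles[0].coefficients.c[0] == pytest.approx(1.0)

    def test_monodisperse_guinier_coefficient(self, mono_sphere_model):
        # coefficient of q² is -R²/5 (Guinier: 1 - q²Rg²/3, Rg² = 3R²/5)
        c1 = mono_sphere_model.profiles[0].coefficients.c[1]
        assert c1 == pytest.approx(-9.0 / 5.0, rel=1e-12)

    def test_polydisperse_guinier_coefficient(self):
        dist = hs.SizeDistribution(3.0, 0.2)  # z = 24
        m = hs.precompute(hs.ShapeSpec("sphere", (3.0,)), [dist])
        z = dist.z
        expected = -(3.0**2) * (z + 2.0) / (5.0 * (z + 1.0))
        assert m.profiles[0].coefficients.c[1] == pytest.approx(expected, rel=1e-12)


class TestIsotropicFormFactor:
    def test_normalized_at_zero(self, models):
        for name, m in models.items():
            assert hs.pq_iso(m, 0.0) == pytest.approx(1.0, abs=1e-10), name
            assert hs.fq_mean(m, 0.0) == pytest.approx(1.0, abs=1e-10), name

    def test_monodisperse_sphere_at_qr_pi(self, mono_sphere_model):
        q = math.pi / 3.0
        assert hs.pq_iso(mono_sphere_model, q) == pytest.approx(
            (3.0 / math.pi**2) ** 2, rel=1e-9
        )

    def test_bounded_and_positive(self, models):
        q = np.geomspace(1e-3, 12.0, 400)
        for name, m in models.items():
            v = hs.pq_iso(m, q)
            assert np.all(v <= 1.0 + 1e-12), name
            assert np.all(v > 0.0), name

    def test_mean_amplitude_cauchy_schwarz(self, models):
        q = np.geomspace(1e-3, 10.0, 200)
        for name, m in models.items():
            f = hs.fq_mean(m, q)
            p = hs.pq_iso(m, q)
            assert np.all(f * f <= p * (1.0 + 1e-9)), name

    def test_sphere_vs_oracle_dense_grid(self, sphere_model):
        q = np.geomspace(0.05 / 3.0, 30.0 / 3.0, 200)
        ref = pq_numeric(sphere_model.shape, sphere_model.size_dists, q)
        fast = hs.pq_iso(sphere_model, q)
        assert np.max(np.abs(fast - ref) / ref) < 1e-4

    def test_mean_amplitude_vs_quadrature(self):
        dist = hs.SizeDistribution(3.0, 0.1)
        m = hs.precompute(hs.ShapeSpec("sphere", (3.0,)), [dist])
        for q in (0.3, 1.0, 2.5, 5.0):
            ref, _ = integrate.quad(
                lambda r: hs.f01_closed(3, q * r) * dist.pdf(r),
                1e-6, 3.0 * (1 + 8 * 0.1), limit=400, epsabs=1e-13, epsrel=1e-11,
            )
            assert hs.fq_mean(m, q) == pytest.approx(ref, rel=1e-4, abs=1e-9)

    def test_guinier_radius_matches_oracle(self, sphere_model):
        """-3 d(ln P)/d(q²) at q→0 agrees between the series route and the
        quadrature oracle."""
        q = np.array([0.02, 0.04])
        def rg2(vals):
            return -3.0 * np.diff(np.log(vals)) / np.diff(q**2)
        fast = rg2(hs.pq_iso(sphere_model, q))
        ref = rg2(pq_numeric(sphere_model.shape, sphere_model.size_dists, q))
        assert fast == pytest.approx(ref, rel=1e-4)


class TestRegimeContinuity:
    @pytest.mark.parametrize("name", list(ALL_SHAPES))
    def test_jumps_below_1e3(self, models, name):
        m = models[name]
        for prof in m.profiles:
            b = prof.boundaries
            for q0 in (b.q12, b.q23):
                if not math.isfinite(q0):
                    continue
                below = prof.P(q0 * (1 - 1e-9))
                above = prof.P(q0 * (1 + 1e-9))
                assert abs(above - below) / abs(below) < 1e-3


class TestPorod:
    def test_sphere_closed_form(self):
        dist = hs.SizeDistribution(3.0, 0.08)
        m = hs.precompute(hs.ShapeSpec("sphere", (3.0,)), [dist])
        z = dist.z
        expected = 9 * (z + 1) ** 4 / (2 * z * (z - 1) * (z - 2) * (z - 3))
        pl = hs.porod_limit(m)
        assert not pl.estimated
        assert pl.value == pytest.approx(expected, rel=1e-12)

    def test_monodisperse_limit_is_nine_halves(self, mono_sphere_model):
        assert hs.porod_limit(mono_sphere_model).value == pytest.approx(4.5)

    @pytest.mark.parametrize("sigma", [0.05, 0.1, 0.2])
    def test_tail_converges_to_constant(self, sigma):
        dist = hs.SizeDistribution(3.0, sigma)
        m = hs.precompute(hs.ShapeSpec("sphere", (3.0,)), [dist])
        K = hs.porod_limit(m).value
        q = np.geomspace(m.boundaries.q23 * 3, m.boundaries.q23 * 30, 50)
        tail = q**4 * 3.0**4 * hs.pq_iso(m, q)
        assert np.max(np.abs(tail - K) / K) < 0.01

    def test_wide_polydispersity_rejected(self):
        # z = 3 sits at the Eq-12 pole; the asymptotic regime needs the
        # inverse moments up to order 6, so construction already refuses
        with pytest.raises(DomainError, match="z"):
            hs.precompute(
                hs.ShapeSpec("sphere", (3.0,)), [hs.SizeDistribution(3.0, 0.5)]
            )

    def test_anisometric_estimate_flagged(self, cylinder_model):
        pl = hs.porod_limit(cylinder_model)
        assert pl.estimated
        assert pl.value > 0


class TestOriented:
    def test_unity_at_origin(self, cylinder_model):
        od = hs.OrientationDistribution("gaussian_cone", 0.3)
        assert hs.pq_oriented(cylinder_model, 0.0, 0.0, od) == pytest.approx(1.0, abs=1e-9)

    def test_delta_matches_2d_quadrature_oracle(self, cylinder_model):
        od = hs.OrientationDistribution("delta")
        shape, dists = ALL_SHAPES["cylinder"]
        for qx, qy in [(0.3, 0.0), (0.0, 0.6), (0.5, 0.5), (1.5, 0.2)]:
            fast = hs.pq_oriented(cylinder_model, qx, qy, od)
            ref = pq_oriented_numeric(shape, dists, qx, qy, od)
            assert fast == pytest.approx(ref, rel=1e-4)

    def test_cone_matches_quadrature_oracle(self, cylinder_model):
        od = hs.OrientationDistribution("gaussian_cone", 0.25)
        shape, dists = ALL_SHAPES["cylinder"]
        for qx, qy in [(0.3, 0.1), (0.8, 0.4)]:
            fast = hs.pq_oriented(cylinder_model, qx, qy, od)
            ref = pq_oriented_numeric(shape, dists, qx, qy, od)
            assert fast == pytest.approx(ref, rel=1e-4)

    def test_isotropic_odist_reduces_to_powder_average(self, cylinder_model):
        od = hs.OrientationDistribution("uniform_isotropic")
        q = np.array([0.1, 0.4, 0.9, 1.8, 3.0])
        iso = hs.pq_iso(cylinder_model, q)
        ori = np.array(
            [hs.pq_oriented(cylinder_model, v / math.sqrt(2), v / math.sqrt(2), od)
             for v in q]
        )
        assert np.max(np.abs(ori - iso) / iso) < 1e-4

    def test_isotropic_pattern_azimuthally_symmetric(self, cylinder_model):
        od = hs.OrientationDistribution("uniform_isotropic")
        a = hs.pq_oriented(cylinder_model, 0.8, 0.0, od)
        b = hs.pq_oriented(cylinder_model, 0.0, 0.8, od)
        c = hs.pq_oriented(cylinder_model, 0.8 / math.sqrt(2), 0.8 / math.sqrt(2), od)
        assert a == pytest.approx(b, rel=1e-6)
        assert a == pytest.approx(c, rel=1e-6)

    def test_longitudinal_series_matches_node_average(self, cylinder_model):
        """The a_n, b_{l,n} double series reproduces the direct (δ, χ)
        phase average of the longitudinal factor at low q."""
        od = hs.OrientationDistribution("gaussian_cone", 0.25)
        hs.pq_oriented(cylinder_model, 0.1, 0.1, od)  # build tables
        t = cylinder_model.oriented[(od.kind, od.width)]
        lp = cylinder_model.profiles[1]
        for qx, qy in [(0.05, 0.02), (0.1, 0.05), (0.2, 0.1)]:
            ser = oriented_longitudinal(cylinder_model, qx, qy, od)
            qpar = qx * np.cos(t.delta_nodes) - qy * np.sin(t.chi_nodes) * np.sin(t.delta_nodes)
            node = float(lp.P(np.abs(qpar)) @ t.weights)
            assert ser == pytest.approx(node, rel=1e-8)

    def test_unsupported_shape_raises(self, sphere_model):
        with pytest.raises(DomainError):
            hs.pq_oriented(sphere_model, 0.1, 0.1, hs.OrientationDistribution("delta"))


class TestShapeSpecValidation:
    def test_arity_checked(self):
        with pytest.raises(DomainError):
            hs.ShapeSpec("sphere", (3.0, 4.0))
        with pytest.raises(DomainError):
            hs.ShapeSpec("triaxial_ellipsoid", (1.0,))

    def test_positive_sizes(self):
        with pytest.raises(DomainError):
            hs.ShapeSpec("sphere", (-1.0,))

    def test_dimensionality_classes(self):
        assert hs.ShapeSpec("sphere", (3.0,)).d == 3
        assert hs.ShapeSpec("cylinder", (2.0, 16.0)).d == 2
        assert hs.ShapeSpec("disk_lamella", (4.0,)).d == 1
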