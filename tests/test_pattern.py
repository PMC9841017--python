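"""Detector mapping, intensity assembly, PSF convolution, Fresnel optics
and the DWBA grazing-incidence extension."""

import math

import numpy as np
import pytest

import hyperscat as hs
from hyperscat.errors import DomainError
from hyperscat.pattern import azimuthal_average


def small_det(n=64, mode="small_angle"):
    return hs.DetectorGeometry(n, n, 1.0, 0.1, 4000.0, mode=mode)


class TestQMap:
    def test_beam_center_pixel_is_zero(self):
        det = hs.DetectorGeometry(5, 5, 1.0, 0.1, 1000.0, beam_center=(2.5, 2.5))
        qm = hs.q_map(det)
        assert np.allclose(qm[2, 2], 0.0)

    def test_small_angle_arithmetic(self):
        # x = 10 mm, lambda = 0.1 nm, d = 1000 mm -> qx = 2*pi*10/(0.1*1000)
        det = hs.DetectorGeometry(21, 1, 1.0, 0.1, 1000.0, beam_center=(0.5, 0.5))
        qm = hs.q_map(det)
        assert qm[0, 10, 0] == pytest.approx(2 * math.pi * 10.0 / (0.1 * 1000.0), rel=1e-12)

    def test_exact_vs_small_angle_below_two_degrees(self):
        # 2 degrees at 1000 mm is ~35 mm off-center
        det_sa = hs.DetectorGeometry(70, 70, 1.0, 0.1, 1000.0)
        det_ex = hs.DetectorGeometry(70, 70, 1.0, 0.1, 1000.0, mode="exact")
        qa = hs.q_map(det_sa)
        qe = hs.q_map(det_ex)
        qta = np.hypot(qa[..., 0], qa[..., 1])
        qte = np.hypot(qe[..., 0], qe[..., 1])
        x = (np.arange(70) + 0.5 - 35.0) * 1.0
        r = np.hypot(*np.meshgrid(x, x))
        mask = (r < 1000.0 * math.tan(math.radians(2.0))) & (r > 0.1)
        assert np.max(np.abs(qta - qte)[mask] / qta[mask]) < 1e-3

    def test_exact_qz_positive(self):
        qm = hs.q_map(small_det(32, "exact"))
        assert np.all(qm[..., 2] >= 0)


class TestIntensity:
    def test_without_lattice_is_scaled_form_factor(self, sphere_model):
        det = small_det()
        params = hs.IntensityParams(contrast=2.0, number_density=0.5,
                                    include_lattice=False)
        pat = hs.intensity(sphere_model, None, params, det)
        qabs = np.sqrt((pat.qmap**2).sum(-1))
        expected = 4.0 * 0.5 * hs.pq_iso(sphere_model, qabs.ravel()).reshape(qabs.shape)
        assert np.max(np.abs(pat.I - expected) / expected) < 1e-6

    def test_friedel_symmetry(self, sphere_model, fcc_cell):
        lat = hs.LatticeModel(fcc_cell, hs.PeakShape("gaussian", 0.012))
        pat = hs.intensity(sphere_model, lat, hs.IntensityParams(), small_det())
        assert np.allclose(pat.I, pat.I[::-1, ::-1], rtol=1e-9)

    def test_nonnegative_with_lattice(self, sphere_model, fcc_cell):
        lat = hs.LatticeModel(
            fcc_cell, hs.PeakShape("gaussian", 0.012, debye_waller_sigma=1.0)
        )
        pat = hs.intensity(sphere_model, lat, hs.IntensityParams(), small_det())
        assert np.all(pat.I >= 0)

    def test_azimuthal_average_matches_direct_1d(self, sphere_model):
        """Radially averaging an isotropic 2D pattern reproduces the direct
        1D computation within the pixel-binning discretization (0.5%)."""
        det = hs.DetectorGeometry(128, 128, 1.0, 0.1, 4000.0)
        pat = hs.intensity(sphere_model, None,
                           hs.IntensityParams(include_lattice=False), det)
        qc, Ic = azimuthal_average(pat, n_bins=150)
        m = (qc > 0.1) & (qc < np.sqrt((pat.qmap**2).sum(-1)).max() * 0.7)
        direct = hs.curve1d(sphere_model, None,
                            hs.IntensityParams(include_lattice=False), qc[m]).I
        assert np.max(np.abs(Ic[m] - direct) / direct) < 5e-3

    def test_powder_lattice_rings_in_pattern(self, fcc_cell):
        model = hs.precompute(hs.ShapeSpec("sphere", (14.0,)),
                              [hs.SizeDistribution(14.0, 0.08)])
        lat = hs.LatticeModel(fcc_cell, hs.PeakShape("gaussian", 0.012),
                              orientation="powder")
        pat = hs.intensity(model, lat, hs.IntensityParams(), small_det(128))
        qc, Ic = azimuthal_average(pat, n_bins=200)
        q111 = 2 * math.pi * math.sqrt(3) / 35.0
        band = (qc > q111 - 0.03) & (qc < q111 + 0.03)
        flank = (qc > q111 + 0.03) & (qc < q111 + 0.08)
        assert Ic[band].max() > 2.0 * Ic[flank].mean()


class TestPSF:
    def test_delta_kernel_is_identity(self, sphere_model):
        pat = hs.intensity(sphere_model, None,
                           hs.IntensityParams(include_lattice=False), small_det(32))
        kern = np.zeros((3, 3))
        kern[1, 1] = 1.0
        out = hs.convolve_psf(pat, kern)
        assert np.array_equal(out.I, pat.I)

    def test_gaussian_kernel_conserves_and_smooths(self, sphere_model, fcc_cell):
        lat = hs.LatticeModel(fcc_cell, hs.PeakShape("gaussian", 0.012))
        pat = hs.intensity(sphere_model, lat, hs.IntensityParams(), small_det(32))
        x = np.arange(7) - 3.0
        g = np.exp(-0.5 * (x / 1.1) ** 2)
        kern = np.outer(g, g)
        kern /= kern.sum()
        out = hs.convolve_psf(pat, kern)
        assert out.I.max() < pat.I.max()
        inner = slice(4, -4)
        assert out.I[inner, inner].sum() == pytest.approx(
            pat.I[inner, inner].sum(), rel=1e-2
        )

    def test_linearity(self, sphere_model):
        pat = hs.intensity(sphere_model, None,
                           hs.IntensityParams(include_lattice=False), small_det(16))
        kern = np.full((3, 3), 1.0 / 9.0)
        doubled = hs.Pattern2D(pat.qmap, 2.0 * pat.I, pat.meta)
        assert np.allclose(
            hs.convolve_psf(doubled, kern).I, 2.0 * hs.convolve_psf(pat, kern).I
        )

    def test_unnormalized_kernel_rejected(self, sphere_model):
        pat = hs.intensity(sphere_model, None,
                           hs.IntensityParams(include_lattice=False), small_det(16))
        with pytest.raises(DomainError):
            hs.convolve_psf(pat, np.ones((3, 3)))


class TestFresnel:
    DELTA = 1.67e-5

    def alpha_c(self):
        return math.degrees(math.asin(math.sqrt(2 * self.DELTA)))

    def test_transmission_peak_at_critical_angle(self):
        t, _ = hs.fresnel(self.alpha_c(), self.DELTA, 0.0)
        assert abs(t) ** 2 == pytest.approx(4.0, rel=1e-4)

    def test_far_above_critical(self):
        t, r = hs.fresnel(20 * self.alpha_c(), self.DELTA, 0.0)
        assert abs(r) ** 2 < 1e-4
        assert abs(t) ** 2 == pytest.approx(1.0, abs=5e-3)

    def test_total_external_reflection(self):
        _, r = hs.fresnel(1e-4, self.DELTA, 0.0)
        assert abs(r) ** 2 == pytest.approx(1.0, abs=1e-6)


class TestGISAS:
    def film(self):
        return hs.GISASFilm(alpha_i=0.25, delta=1.67e-5, beta=2e-7)

    def det(self):
        return hs.DetectorGeometry(64, 64, 1.0, 0.1, 4000.0, beam_center=(32.0, 8.0))

    def test_no_film_equals_transmission_bitwise(self, sphere_model, fcc_cell):
        lat = hs.LatticeModel(fcc_cell, hs.PeakShape("gaussian", 0.012))
        params = hs.IntensityParams()
        g = hs.gisas_intensity(sphere_model, lat, None, self.det(), params)
        p = hs.intensity(sphere_model, lat, params, self.det())
        assert np.array_equal(g.I, p.I)

    def test_zero_reflectivity_reduces_to_single_channel(self, sphere_model):
        """With δ = β = 0 all Fresnel factors are T=1, R=0 and the DWBA sum
        collapses to I(q₁) with q_z = k(sin α_f + sin α_i)."""
        film0 = hs.GISASFilm(alpha_i=0.25, delta=0.0, beta=0.0)
        det = self.det()
        params = hs.IntensityParams(include_lattice=False)
        g = hs.gisas_intensity(sphere_model, None, film0, det, params)
        k = 2 * math.pi / det.wavelength
        y = (np.arange(det.ny) + 0.5 - det.beam_center[1]) * det.pixel_size
        alpha_f = np.arctan2(y, det.distance)
        qz = k * (np.sin(np.maximum(alpha_f, 0)) + math.sin(math.radians(0.25)))
        qx = hs.q_map(det)[..., 0]
        qabs = np.sqrt(qx**2 + qz[:, None] ** 2)
        expected = hs.pq_iso(sphere_model, qabs.ravel()).reshape(qabs.shape)
        expected[alpha_f < 0, :] = 0.0
        m = expected > 0
        assert np.max(np.abs(g.I[m] - expected[m]) / expected[m]) < 1e-3

    def test_channels_nonnegative_and_sum_dominates(self, sphere_model):
        g = hs.gisas_intensity(sphere_model, None, self.film(), self.det(),
                               hs.IntensityParams(include_lattice=False))
        assert np.all(g.I >= 0)

    def test_yoneda_band_at_critical_exit_angle(self):
        """Dividing out the film-free DWBA intensity isolates the |T_f|²
        row profile, which peaks at α_f = α_c."""
        model = hs.precompute(hs.ShapeSpec("sphere", (10.0,)),
                              [hs.SizeDistribution(10.0, 0.08)])
        film = self.film()
        det = hs.DetectorGeometry(64, 128, 1.0, 0.1, 4000.0, beam_center=(32.0, 16.0))
        params = hs.IntensityParams(include_lattice=False)
        g = hs.gisas_intensity(model, None, film, det, params)
        film0 = hs.GISASFilm(alpha_i=film.alpha_i, delta=1e-12, beta=0.0)
        g0 = hs.gisas_intensity(model, None, film0, det, params)
        y = (np.arange(det.ny) + 0.5 - det.beam_center[1]) * det.pixel_size
        alpha_f = np.degrees(np.arctan2(y, det.distance))
        rows = alpha_f > 0.05  # stay clear of the horizon
        ratio = g.I[rows].mean(axis=1) / np.maximum(g0.I[rows].mean(axis=1), 1e-300)
        peak_alpha = alpha_f[rows][np.argmax(ratio)]
        assert abs(peak_alpha - film.alpha_c_deg) < 0.05
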