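"""Radial PSD, peak detection, model-eye scaling, and Voronoi statistics."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from aorpe.metrics import (
    HEX_LATTICE_FACTOR,
    CellMetrics,
    EyeBiometry,
    PeakResult,
    RadialPSD,
    cell_spacing_from_psd,
    compare_batches,
    compare_to_reference,
    default_band_cyc_per_px,
    detect_peak,
    radial_psd,
    retinal_microns_per_degree,
    retinal_scale,
    voronoi_stats,
)
from aorpe.sim import MosaicSpec, generate_mosaic, simulate_speckle_frame


class TestRadialPSD:
    def test_single_tone_peaks_at_its_frequency(self):
        yy, xx = np.mgrid[0:200, 0:200]
        img = np.cos(2 * np.pi * 0.1 * xx)
        rpsd = radial_psd(img, roi_px=200)
        peak_bin = np.nanargmax(rpsd.log_psd[1:]) + 1
        assert rpsd.freq[peak_bin] == pytest.approx(0.1, abs=1.0 / 200)

    def test_white_noise_spectrum_is_flat(self):
        """Averaged over seeds, log PSD of white noise varies by < 0.3 across
        the passband (Monte-Carlo flatness band)."""
        curves = []
        for seed in range(10):
            img = np.random.default_rng(seed).standard_normal((200, 200))
            curves.append(radial_psd(img, roi_px=200).log_psd)
        mean_curve = np.mean(curves, axis=0)
        f = radial_psd(np.zeros((200, 200)) + np.arange(200), roi_px=200).freq
        band = (f > 0.05) & (f < 0.45)
        assert mean_curve[band].max() - mean_curve[band].min() < 0.3

    def test_circular_shift_invariance(self, jittered_mosaic):
        img = jittered_mosaic.reflectance
        shifted = np.roll(img, (17, 31), axis=(0, 1))
        a = radial_psd(img, roi_px=200, window="none").log_psd
        b = radial_psd(shifted, roi_px=200, window="none").log_psd
        np.testing.assert_allclose(a[1:], b[1:], atol=1e-10)

    def test_parseval_bookkeeping(self, jittered_mosaic):
        """Summed annulus power equals total spectral power minus DC."""
        rpsd = radial_psd(jittered_mosaic.reflectance, roi_px=200)
        assert rpsd.annulus_power[1:].sum() == pytest.approx(
            rpsd.total_ac_power, rel=1e-6)

    def test_constant_image_flagged(self):
        rpsd = radial_psd(np.full((220, 220), 0.7), roi_px=200)
        assert rpsd.is_flat

    def test_roi_must_fit(self):
        with pytest.raises(ValueError):
            radial_psd(np.zeros((100, 100)), roi_px=200)


class TestDetectPeak:
    def test_mosaic_fundamental_frequency(self, jittered_mosaic):
        """The spectral ring of a 14 px mosaic sits within one bin of the
        row-spacing reciprocal."""
        rpsd = radial_psd(jittered_mosaic.reflectance, roi_px=200)
        res = detect_peak(rpsd, default_band_cyc_per_px(1.0))
        assert res.found
        f_ring = HEX_LATTICE_FACTOR / 14.0
        assert abs(res.f_peak_bin - f_ring) <= 1.0 / 200

    def test_averaging_raises_peak_distinctiveness(self, stack120):
        """PD of the 120-frame average exceeds PD of one speckled frame —
        the direction of the measured cellular-contrast gain."""
        band = default_band_cyc_per_px(1.0)
        frames = stack120.as_array()
        one = cell_spacing_from_psd(frames[0], 1.0, band, roi_px=128)
        avg = cell_spacing_from_psd(frames.mean(axis=0), 1.0, band, roi_px=128)
        assert avg.found
        pd_one = one.peak_distinctiveness if one.found else 0.0
        assert avg.peak_distinctiveness > pd_one

    def test_monotone_spectrum_gives_no_peak(self):
        freq = np.arange(101) / 200.0
        rpsd = RadialPSD(freq=freq, log_psd=-10.0 * freq, window="hann", roi_px=200)
        res = detect_peak(rpsd, (0.05, 0.4))
        assert not res.found
        assert np.isnan(res.peak_distinctiveness)

    def test_band_validation(self):
        rpsd = RadialPSD(freq=np.arange(101) / 200.0,
                         log_psd=np.zeros(101), window="hann", roi_px=200)
        with pytest.raises(ValueError):
            detect_peak(rpsd, (0.3, 0.6))


class TestCellSpacing:
    def test_known_spacing_recovered(self, jittered_mosaic):
        res = cell_spacing_from_psd(jittered_mosaic.reflectance, 1.0, roi_px=200)
        assert res.spacing_um == pytest.approx(14.0, abs=0.5)

    def test_scale_linearity(self, jittered_mosaic):
        band = default_band_cyc_per_px(1.0)
        r1 = cell_spacing_from_psd(jittered_mosaic.reflectance, 1.0, band, roi_px=200)
        r2 = cell_spacing_from_psd(jittered_mosaic.reflectance, 2.0, band, roi_px=200)
        assert r2.spacing_um == pytest.approx(2.0 * r1.spacing_um, rel=1e-12)

    def test_spacing_error_band_10_to_20_um(self):
        """Across 20 seeded mosaics spanning 10-20 um, the mean absolute
        spacing error stays within the error magnitude reported for
        recovered-image spacing on real data (1.3 um)."""
        errors = []
        for i, s_um in enumerate(np.linspace(10, 20, 20)):
            mosaic = generate_mosaic(MosaicSpec(260, 260, 1.0, s_um, 0.08, 0.8, 300 + i))
            res = cell_spacing_from_psd(mosaic.reflectance, 1.0, roi_px=200)
            assert res.found
            errors.append(res.spacing_um - s_um)
        assert np.mean(np.abs(errors)) <= 1.3


class TestRetinalScale:
    @staticmethod
    def ray_march_um_per_degree(b: EyeBiometry) -> float:
        """Independent oracle: march the chief ray surface by surface using
        the small-angle refraction update, no transfer matrices."""
        u = np.deg2rad(1.0)  # ray angle in medium n=1
        y = 0.0
        surfaces = [
            (b.corneal_radius_mm, 1.0, b.n_aqueous, b.anterior_chamber_depth_mm),
            (b.lens_front_radius_mm, b.n_aqueous, b.n_lens, b.lens_thickness_mm),
            (b.lens_back_radius_mm, b.n_lens, b.n_vitreous,
             b.axial_length_mm - b.anterior_chamber_depth_mm - b.lens_thickness_mm),
        ]
        for radius, n0, n1, gap in surfaces:
            u = (n0 * u - y * (n1 - n0) / radius) / n1  # paraxial Snell
            y = y + gap * u
        return y * 1000.0

    def test_matrix_trace_matches_ray_marching_oracle(self):
        grid = [
            EyeBiometry(),
            EyeBiometry(axial_length_mm=22.0),
            EyeBiometry(axial_length_mm=26.5, corneal_radius_mm=8.2),
            EyeBiometry(corneal_radius_mm=7.2, anterior_chamber_depth_mm=3.0),
        ]
        for b in grid:
            ours = retinal_microns_per_degree(b)
            oracle = self.ray_march_um_per_degree(b)
            assert ours == pytest.approx(oracle, rel=5e-5)  # 4 significant figures

    def test_pixel_count_halves_scale(self):
        assert retinal_scale(n_px=600) == pytest.approx(retinal_scale(n_px=300) / 2)

    def test_paraxial_homogeneity(self):
        b = EyeBiometry()
        k = 2.0
        scaled = EyeBiometry(
            axial_length_mm=k * b.axial_length_mm,
            corneal_radius_mm=k * b.corneal_radius_mm,
            anterior_chamber_depth_mm=k * b.anterior_chamber_depth_mm,
            lens_thickness_mm=k * b.lens_thickness_mm,
            lens_front_radius_mm=k * b.lens_front_radius_mm,
            lens_back_radius_mm=k * b.lens_back_radius_mm,
        )
        assert retinal_microns_per_degree(scaled) == pytest.approx(
            k * retinal_microns_per_degree(b), rel=1e-12)

    def test_nonphysical_biometry_rejected(self):
        with pytest.raises(ValueError):
            EyeBiometry(axial_length_mm=5.0)


class TestVoronoi:
    def test_perfect_lattice_statistics(self, small_mosaic):
        vs = voronoi_stats(small_mosaic.centers, (200, 200))
        assert vs.fraction_hexagonal == 1.0
        assert vs.mean_neighbor_distance_px == pytest.approx(14.0, abs=1e-9)
        assert vs.sd_neighbor_distance_px == pytest.approx(0.0, abs=1e-9)
        assert set(vs.neighbor_count_hist) == {6}

    def test_adjacency_matches_delaunay_duality(self, jittered_mosaic):
        """Voronoi ridge adjacency equals the Delaunay edge set, edge for edge."""
        pts = jittered_mosaic.centers
        vs = voronoi_stats(pts, (200, 200))
        tri = Delaunay(pts)
        edges = set()
        for simplex in tri.simplices:
            for i in range(3):
                a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
                edges.add((a, b))
        assert vs.adjacency == edges

    def test_deleted_center_enlarges_neighborhoods(self, jittered_mosaic):
        """Removing a cell hands its neighbors the far side of the hole, so
        new long adjacencies appear and the mean neighbor distance rises.
        (Jittered points: on a perfect lattice the hole ring is cocircular
        and the tessellation is degenerate.)"""
        pts = jittered_mosaic.centers
        mid = np.argmin(np.linalg.norm(pts - np.array([100, 100]), axis=1))
        reduced = np.delete(pts, mid, axis=0)
        vs_full = voronoi_stats(pts, (200, 200))
        vs_holed = voronoi_stats(reduced, (200, 200))
        assert vs_holed.mean_neighbor_distance_px > vs_full.mean_neighbor_distance_px
        assert vs_holed.fraction_hexagonal < vs_full.fraction_hexagonal

    def test_interior_count_matches_containment_check(self, rng):
        """Interior classification agrees with a direct vertex-containment
        check of every finite region."""
        from scipy.spatial import Voronoi

        pts = rng.uniform(0, 100, size=(80, 2))
        vs = voronoi_stats(pts, (100, 100))
        vor = Voronoi(pts)
        brute = 0
        for i in range(len(pts)):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or not region:
                continue
            verts = vor.vertices[region]
            if (verts >= 0).all() and (verts <= 100).all():
                brute += 1
        assert vs.n_cells_interior == brute

    def test_collinear_centers_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError):
            voronoi_stats(pts, (10, 10))

    def test_psd_and_voronoi_spacing_agree(self, jittered_mosaic):
        """Dual-method agreement: spectral and packing-based spacing estimates
        stay within 10% on a moderately jittered mosaic."""
        psd_spacing = cell_spacing_from_psd(
            jittered_mosaic.reflectance, 1.0, roi_px=200).spacing_px
        vor_spacing = voronoi_stats(
            jittered_mosaic.centers, (200, 200)).mean_neighbor_distance_px
        assert abs(psd_spacing - vor_spacing) / vor_spacing < 0.10


class TestComparison:
    @staticmethod
    def _metrics(spacing_px, spacing_um, pd_value):
        return CellMetrics(peak=PeakResult(
            found=True, f_peak=1.0 / spacing_px, f_peak_bin=1.0 / spacing_px,
            spacing_px=spacing_px, spacing_um=spacing_um,
            peak_distinctiveness=pd_value, left_min_freq=0.02))

    def test_identical_inputs_zero_error(self):
        m = self._metrics(10.0, 14.0, 0.5)
        report = compare_to_reference(m, m)
        assert all(v == 0.0 for v in report.values())

    def test_signed_spacing_error(self):
        a = self._metrics(9.0, 13.0, 0.4)
        b = self._metrics(10.0, 14.0, 0.5)
        report = compare_to_reference(a, b)
        assert report["spacing_error_um"] == pytest.approx(-1.0)

    def test_batch_mean_sd_convention(self):
        list_a = [self._metrics(10, 13.0, 0.4), self._metrics(10, 15.0, 0.6)]
        list_b = [self._metrics(10, 14.0, 0.5), self._metrics(10, 14.0, 0.5)]
        out = compare_batches(list_a, list_b)
        assert out["spacing_error_um"]["mean"] == pytest.approx(0.0)
        assert out["spacing_error_um"]["sd"] == pytest.approx(np.sqrt(2.0))
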