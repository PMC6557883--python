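"""Geometric QA: BB detection, magnification, flexmaps, Winston-Lutz."""
import numpy as np
import pytest

from kvqa.core import BBProjectionSet
from kvqa.geometry import (
    build_flexmap,
    compute_magnification,
    detect_bb_centroid,
    fit_sinusoid,
    winston_lutz,
)
from kvqa.synthetic import GeometryGroundTruth, _soft_disc, generate_bb_projections

ANGLES = np.arange(0.0, 360.0, 10.0)
HALF_PANEL_PX_ISO = 0.5 * 0.2 / 2.04  # half a panel pixel at isocentre scale, mm


def _bb_image(centre, shape=(120, 160), radius=6.0, noise_sd=0.0, seed=0):
    img = 3000.0 - 2700.0 * _soft_disc(shape, centre, radius)
    if noise_sd:
        img = img + np.random.default_rng(seed).normal(0, noise_sd, shape)
    return img


class TestDetectBBCentroid:
    def test_subpixel_accuracy(self):
        u, v = detect_bb_centroid(_bb_image((100.0, 60.0)))
        assert u == pytest.approx(100.0, abs=0.1)
        assert v == pytest.approx(60.0, abs=0.1)

    def test_exact_centre_of_symmetric_image(self):
        img = _bb_image(((161 - 1) / 2, (121 - 1) / 2), shape=(121, 161))
        u, v = detect_bb_centroid(img)
        assert u == pytest.approx(80.0, abs=1e-6)
        assert v == pytest.approx(60.0, abs=1e-6)

    def test_robust_to_noise(self):
        u, v = detect_bb_centroid(_bb_image((100.25, 59.75), noise_sd=10.0, seed=4))
        assert u == pytest.approx(100.25, abs=0.1)
        assert v == pytest.approx(59.75, abs=0.1)

    def test_two_discs_rejected_with_count(self):
        img = 3000.0 - 2700.0 * (
            _soft_disc((120, 160), (40.0, 60.0), 6.0)
            + _soft_disc((120, 160), (120.0, 60.0), 6.0)
        )
        with pytest.raises(ValueError, match="found 2"):
            detect_bb_centroid(img)

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError, match="found 0"):
            detect_bb_centroid(np.full((50, 50), 3000.0))


class TestMagnification:
    def _shots(self, geom, shifts, z, seed=0, noise_sd=0.0):
        out = []
        for s in shifts:
            proj = generate_bb_projections(geom, [0.0], [(s, 0.0, z)], seed=seed,
                                           noise_sd=noise_sd)
            u, _ = detect_bb_centroid(proj.images[0])
            out.append((s, u))
        return out

    def test_known_geometry_recovered(self):
        geom = GeometryGroundTruth(sad=306.4, sdd=625.0)
        iso = self._shots(geom, (-5.0, -3.0, 3.0, 5.0), 0.0)
        axial = self._shots(geom, (-5.0, -3.0, 3.0, 5.0), 50.0)
        sad, sdd, mag = compute_magnification(iso, axial, 50.0, geom.panel_pixel_pitch)
        assert sad == pytest.approx(306.4, rel=5e-4)
        assert sdd == pytest.approx(625.0, rel=5e-4)
        assert mag == pytest.approx(625.0 / 306.4, rel=5e-4)

    def test_double_distance_gives_magnification_two(self):
        geom = GeometryGroundTruth(sad=300.0, sdd=600.0)
        iso = self._shots(geom, (-5.0, 5.0), 0.0)
        axial = self._shots(geom, (-5.0, 5.0), 50.0)
        _, _, mag = compute_magnification(iso, axial, 50.0, geom.panel_pixel_pitch)
        assert round(mag, 2) == 2.00

    def test_invariant_to_lateral_pair_choice(self):
        geom = GeometryGroundTruth()
        iso = self._shots(geom, (-5.0, -3.0, 3.0, 5.0), 0.0)
        axial = self._shots(geom, (-5.0, -3.0, 3.0, 5.0), 50.0)
        full = compute_magnification(iso, axial, 50.0, geom.panel_pixel_pitch)
        pair = compute_magnification([iso[0], iso[3]], [axial[0], axial[3]], 50.0,
                                     geom.panel_pixel_pitch)
        assert full == pytest.approx(pair, rel=1e-3)

    def test_degenerate_shifts_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_magnification([(1.0, 10.0), (1.0, 10.0)], [(1.0, 12.0), (1.0, 12.0)],
                                  50.0, 0.2)


class TestFlexmap:
    def test_zero_flex_gives_zero_map(self):
        proj = generate_bb_projections(GeometryGroundTruth(), ANGLES, [(0, 0, 0)],
                                       seed=0, noise_sd=0.0)
        fm = build_flexmap(proj)
        assert np.all(np.abs(fm.u) < 0.02)
        assert np.all(np.abs(fm.v) < 0.02)

    def test_sinusoid_amplitude_recovered(self):
        geom = GeometryGroundTruth(flex_u_amp=2.0, flex_u_phase=0.0,
                                   flex_v_amp=0.8, flex_v_phase=0.7)
        proj = generate_bb_projections(geom, ANGLES, [(0, 0, 0)], seed=1, noise_sd=0.0)
        fm = build_flexmap(proj)
        amp_u, _, _ = fit_sinusoid(fm.angles, fm.u)
        amp_v, _, _ = fit_sinusoid(fm.angles, fm.v)
        assert amp_u == pytest.approx(2.0, abs=0.5 * geom.panel_pixel_pitch)
        assert amp_v == pytest.approx(0.8, abs=0.5 * geom.panel_pixel_pitch)

    def test_translation_equivariance(self):
        geom = GeometryGroundTruth(flex_u_amp=1.0, flex_u_phase=0.3)
        proj = generate_bb_projections(geom, ANGLES, [(0, 0, 0)], seed=2, noise_sd=0.0)
        shifted = BBProjectionSet(
            [np.roll(img, (3, 5), axis=(0, 1)) for img in proj.images],
            proj.angles, proj.stage_offsets, proj.panel_pixel_pitch,
        )
        fm = build_flexmap(proj)
        fm_shifted = build_flexmap(shifted)
        assert np.allclose(fm.u, fm_shifted.u, atol=0.02)
        assert np.allclose(fm.v, fm_shifted.v, atol=0.02)

    def test_self_consistency_correction(self):
        geom = GeometryGroundTruth(flex_u_amp=1.5, flex_u_phase=0.2, flex_v_amp=0.5)
        proj = generate_bb_projections(geom, ANGLES, [(0, 0, 0)], seed=3, noise_sd=0.0)
        fm = build_flexmap(proj)
        from kvqa.geometry import detect_bb_centroid as centroid

        pitch = proj.panel_pixel_pitch
        corrected = []
        for img, angle in zip(proj.images, proj.angles):
            u, v = centroid(img)
            fu, fv = fm.at(angle)
            corrected.append((u - fu / pitch, v - fv / pitch))
        corrected = np.asarray(corrected)
        assert np.ptp(corrected[:, 0]) <= 0.2
        assert np.ptp(corrected[:, 1]) <= 0.2

    def test_moving_bb_rejected(self):
        geom = GeometryGroundTruth()
        offs = [(0.0, 0.0, 0.0)] * (len(ANGLES) - 1) + [(1.0, 0.0, 0.0)]
        proj = generate_bb_projections(geom, ANGLES, offs, seed=0, noise_sd=0.0)
        with pytest.raises(ValueError, match="stationary"):
            build_flexmap(proj)

    def test_large_angular_gap_warns(self):
        geom = GeometryGroundTruth()
        angles = [0.0, 40.0, 80.0, 120.0]
        proj = generate_bb_projections(geom, angles, [(0, 0, 0)], seed=0, noise_sd=0.0)
        with pytest.warns(UserWarning, match="gap"):
            build_flexmap(proj)


class TestWinstonLutz:
    def test_perfect_geometry_zero_displacement(self):
        proj = generate_bb_projections(GeometryGroundTruth(), ANGLES, [(0, 0, 0)],
                                       seed=0, aperture_radius_mm=6.0, noise_sd=0.0)
        res = winston_lutz(proj, 2.04)
        assert res.max_magnitude < 0.05

    def test_wobble_amplitude_recovered(self):
        geom = GeometryGroundTruth(iso_wobble_amp=1.0)
        proj = generate_bb_projections(geom, ANGLES, [(0, 0, 0)], seed=1,
                                       aperture_radius_mm=6.0, noise_sd=0.0)
        res = winston_lutz(proj, geom.magnification)
        assert res.max_magnitude == pytest.approx(1.0, abs=0.05)

    def test_flexmap_correction_isolates_wobble(self):
        geom = GeometryGroundTruth(flex_u_amp=1.2, flex_u_phase=0.4,
                                   flex_v_amp=0.6, flex_v_phase=1.1,
                                   iso_wobble_amp=1.0)
        wl = generate_bb_projections(geom, ANGLES, [(0, 0, 0)], seed=2,
                                     aperture_radius_mm=6.0, noise_sd=0.0)
        flex_only = generate_bb_projections(geom, ANGLES, [(0, 0, 0)], seed=3,
                                            noise_sd=0.0)
        fm = build_flexmap(flex_only, magnification=geom.magnification)
        res = winston_lutz(wl, geom.magnification, flexmap=fm)
        amp, _, _ = fit_sinusoid(res.angles, res.u)
        assert amp == pytest.approx(1.0, abs=HALF_PANEL_PX_ISO)
        assert np.max(np.abs(res.v)) <= HALF_PANEL_PX_ISO

    def test_self_correction_residual_below_one_pixel(self):
        geom = GeometryGroundTruth(flex_u_amp=1.2, iso_wobble_amp=1.0)
        proj = generate_bb_projections(geom, ANGLES, [(0, 0, 0)], seed=4,
                                       aperture_radius_mm=6.0, noise_sd=8.0)
        first = winston_lutz(proj, geom.magnification)
        second = winston_lutz(proj, geom.magnification,
                              correction=list(zip(first.u, first.v)))
        pixel_iso = geom.panel_pixel_pitch / geom.magnification
        assert second.residual_max is not None
        assert max(second.residual_max) <= pixel_iso

    def test_translation_equivariance(self):
        geom = GeometryGroundTruth(iso_wobble_amp=0.5)
        proj = generate_bb_projections(geom, ANGLES, [(0, 0, 0)], seed=5,
                                       aperture_radius_mm=6.0, noise_sd=0.0)
        shifted = BBProjectionSet(
            [np.roll(img, (2, 4), axis=(0, 1)) for img in proj.images],
            proj.angles, proj.stage_offsets, proj.panel_pixel_pitch,
        )
        a = winston_lutz(proj, geom.magnification)
        b = winston_lutz(shifted, geom.magnification)
        assert np.allclose(a.u, b.u, atol=0.02)
        assert np.allclose(a.v, b.v, atol=0.02)

    def test_field_required(self):
        # flat bright image: no aperture edge to detect
        imgs = [np.full((100, 120), 3000.0)]
        proj = BBProjectionSet(imgs, np.array([0.0]), np.array([[0.0, 0.0, 0.0]]), 0.2)
        with pytest.raises(ValueError):
            winston_lutz(proj, 2.04)
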