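"""Profile metrics against closed forms and dense brute-force oracles."""
import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import ndtr

from kvqa.core import DoseMap, DoseProfile, ProfileMetrics
from kvqa.metrics import (
    compare_dose_grids,
    compute_flatness,
    compute_fwhm,
    compute_pdd,
    compute_penumbra,
    compute_rof,
    compute_symmetry,
    effective_offset,
    extract_profile,
    percent_difference,
    profile_metrics,
    round_half_up,
)
from kvqa.synthetic import BeamGroundTruth, generate_depth_series, generate_dose_map

from conftest import FILM_PITCH
from oracles import analytic_dose, oracle_metrics


def rect_profile(width=10.0, step=0.1, tail=5.0):
    x = np.arange(-width / 2 - tail, width / 2 + tail + step, step)
    # crossings interpolate to exactly +-width/2
    v = np.clip((width / 2 + step / 2 - np.abs(x)) / step, 0.0, 1.0)
    return DoseProfile(x, v)


class TestProfileExtraction:
    def test_identical_rows_give_single_row(self):
        row = np.concatenate([np.zeros(10), np.ones(21), np.zeros(10)])
        m = DoseMap(np.tile(row, (15, 1)), FILM_PITCH)
        p = extract_profile(m, "crossplane")
        assert np.allclose(p.values * p.values.max() ** -1, row / row.max())

    def test_n_average_irrelevant_on_symmetric_noiseless_field(self):
        # separable square field: adjacent rows are proportional, so the
        # averaged profile has exactly the single-row shape
        t = BeamGroundTruth(shape="square", nominal_size=10.0, edge_sigma=0.4)
        m = generate_dose_map(t, 18.0, FILM_PITCH)
        p1 = extract_profile(m, "crossplane", n_average=1)
        p5 = extract_profile(m, "crossplane", n_average=5)
        c = (len(p1.values) - 1) // 2
        assert np.allclose(p1.values / p1.values[c], p5.values / p5.values[c], atol=1e-12)

    def test_even_n_average_rejected(self, map_10mm):
        with pytest.raises(ValueError, match="odd"):
            extract_profile(map_10mm, "crossplane", n_average=4)

    def test_line_averaging_reduces_noise_variance(self, beam_10mm):
        # restrict to the flat top and remove the common CAX-normalisation
        # error so only the per-line noise remains
        diffs1, diffs5 = [], []
        clean = extract_profile(generate_dose_map(beam_10mm, 20.0, FILM_PITCH),
                                "crossplane", 1)
        plateau = np.abs(clean.positions) < 3.0
        for seed in range(8):
            m = generate_dose_map(beam_10mm, 20.0, FILM_PITCH, seed=seed, noise_sd=0.02)
            for n, sink in ((1, diffs1), (5, diffs5)):
                d = (extract_profile(m, "crossplane", n).values - clean.values)[plateau]
                sink.append(np.var(d - d.mean()))
        ratio = np.mean(diffs5) / np.mean(diffs1)
        assert ratio == pytest.approx(1 / 5, rel=0.5)


class TestFWHM:
    def test_rectangular_profile(self):
        assert compute_fwhm(rect_profile(10.0)) == pytest.approx(10.0, abs=1e-9)

    def test_triangle(self):
        x = np.linspace(-12, 12, 481)
        v = np.clip(1 - np.abs(x) / 10.0, 0, None)
        assert compute_fwhm(DoseProfile(x, v)) == pytest.approx(10.0, abs=1e-9)

    def test_generated_5mm_field(self):
        t = BeamGroundTruth(nominal_size=5.0, edge_sigma=0.3)
        p = extract_profile(generate_dose_map(t, 10.0, FILM_PITCH), "crossplane")
        assert compute_fwhm(p) == pytest.approx(5.0, abs=FILM_PITCH)

    def test_bad_crossing_count_rejected(self):
        x = np.linspace(-5, 5, 101)
        with pytest.raises(ValueError, match="crossings"):
            compute_fwhm(DoseProfile(x, np.full_like(x, 0.9)))
        w = 0.6 + 0.5 * np.cos(x)  # four crossings
        with pytest.raises(ValueError, match="found 4"):
            compute_fwhm(DoseProfile(x, w))

    def test_interpolated_crossings_match_analytic_to_1e6mm(self):
        # dense, noiseless error-function edge: interpolation error at
        # 0.5 um sampling must be below 1e-6 mm
        sigma, half = 0.5, 5.0
        x = np.arange(-8.0, 8.0, 5e-4)
        v = ndtr((half - np.abs(x)) / sigma)
        fwhm = compute_fwhm(DoseProfile(x, v))
        exact = 2 * brentq(lambda t: ndtr((half - t) / sigma) - 0.5, 4.0, 6.0)
        assert fwhm == pytest.approx(exact, abs=1e-6)


class TestPenumbra:
    def test_linear_ramp(self):
        x = np.arange(-8, 8, 0.05)
        v = np.clip((5.0 + 0.5 - np.abs(x)) / 1.0, 0.0, 1.0)  # 1 mm ramp each side
        left, right = compute_penumbra(DoseProfile(x, v))
        assert left == pytest.approx(0.6, abs=1e-9)
        assert right == pytest.approx(0.6, abs=1e-9)

    def test_gaussian_integral_edge_closed_form(self):
        sigma = 0.5
        x = np.arange(-6, 6, 0.002)
        v = ndtr((2.5 - np.abs(x)) / sigma)
        left, right = compute_penumbra(DoseProfile(x, v))
        assert left == pytest.approx(1.6832 * sigma, abs=1e-3)
        assert right == pytest.approx(1.6832 * sigma, abs=1e-3)

    def test_symmetric_field_left_equals_right(self, map_10mm):
        p = extract_profile(map_10mm, "crossplane")
        left, right = compute_penumbra(p)
        assert left == pytest.approx(right, abs=FILM_PITCH)

    def test_non_monotone_edge_rejected(self):
        x = np.arange(-8, 8, 0.1)
        v = ndtr((5.0 - np.abs(x)) / 0.5)
        v[np.argmin(np.abs(x + 5.0))] += 0.3  # spike inside the left edge window
        with pytest.raises(ValueError, match="non-monotone"):
            compute_penumbra(DoseProfile(x, v))


class TestSymmetryFlatness:
    def test_even_profile_symmetry_zero(self, map_10mm):
        p = extract_profile(map_10mm, "crossplane")
        assert compute_symmetry(p) == pytest.approx(0.0, abs=1e-9)

    def test_constant_top_flatness_zero(self):
        assert compute_flatness(rect_profile(10.0, step=0.05)) == pytest.approx(0.0, abs=1e-9)

    def test_known_pair_gap_gives_five_percent(self):
        # one mirrored pair differs by 0.05 on the normalised profile
        x = np.arange(-8.0, 8.0001, 0.25)
        v = np.where(np.abs(x) <= 5.0, 1.0, 0.0)
        v[np.isclose(x, -3.0)] = 0.95
        v[np.isclose(x, 5.0)] = 0.5
        v[np.isclose(x, -5.0)] = 0.5
        p = DoseProfile(x, v)
        assert compute_symmetry(p) == pytest.approx(5.0, abs=1e-6)

    def test_flatness_closed_form(self):
        x = np.arange(-8.0, 8.0001, 0.25)
        v = np.where(np.abs(x) <= 5.0, 1.1, 0.0)
        v[np.isclose(x, 1.0)] = 0.9
        v[np.isclose(x, 5.0)] = 0.55
        v[np.isclose(x, -5.0)] = 0.55
        assert compute_flatness(DoseProfile(x, v)) == pytest.approx(10.0, abs=1e-6)

    def test_tilted_field_matches_brute_force(self):
        t = BeamGroundTruth(nominal_size=10.0, edge_sigma=0.4, tilt=0.01)
        p = extract_profile(generate_dose_map(t, 20.0, FILM_PITCH), "crossplane")
        ref = oracle_metrics(t, FILM_PITCH)
        assert compute_symmetry(p) == pytest.approx(ref["symmetry"], abs=0.5)
        assert compute_flatness(p) == pytest.approx(ref["flatness"], abs=0.5)


@pytest.mark.parametrize("size,sigma", [(5.0, 0.2), (5.0, 0.5), (10.0, 0.5), (25.0, 1.0), (40.0, 1.0)])
@pytest.mark.parametrize("tilt", [0.0, 0.02])
def test_parameter_recovery_against_dense_oracle(size, sigma, tilt):
    """Sampled-profile metrics agree with the dense analytic oracle."""
    truth = BeamGroundTruth(shape="circular", nominal_size=size, edge_sigma=sigma,
                            tilt=tilt, flatness_dome=0.01)
    extent = size + 8 * sigma + 2.0
    m = generate_dose_map(truth, extent, FILM_PITCH)
    p = extract_profile(m, "crossplane")
    got = profile_metrics(p)
    ref = oracle_metrics(truth, FILM_PITCH)
    assert got.fwhm == pytest.approx(ref["fwhm"], abs=FILM_PITCH)
    assert got.penumbra_left == pytest.approx(ref["penumbra_left"], abs=1.5 * FILM_PITCH)
    assert got.penumbra_right == pytest.approx(ref["penumbra_right"], abs=1.5 * FILM_PITCH)
    assert got.symmetry == pytest.approx(ref["symmetry"], abs=0.5)
    assert got.flatness == pytest.approx(ref["flatness"], abs=0.5)


def test_smallest_field_recovery_at_scan_resolution(self=None):
    """On a 2.5 mm field at 75 dpi, size/penumbra/symmetry still track the
    oracle; flatness carries several pp of discretisation error because
    the central-80% boundary falls on the penumbral cliff."""
    truth = BeamGroundTruth(shape="circular", nominal_size=2.5, edge_sigma=0.2,
                            tilt=0.02, flatness_dome=0.01)
    m = generate_dose_map(truth, 6.0, FILM_PITCH)
    got = profile_metrics(extract_profile(m, "crossplane"))
    ref = oracle_metrics(truth, FILM_PITCH)
    assert got.fwhm == pytest.approx(ref["fwhm"], abs=FILM_PITCH)
    assert got.penumbra_left == pytest.approx(ref["penumbra_left"], abs=1.5 * FILM_PITCH)
    assert got.symmetry == pytest.approx(ref["symmetry"], abs=0.5)
    assert got.flatness == pytest.approx(ref["flatness"], abs=4.0)


def test_shape_metrics_scale_invariant(map_10mm):
    p1 = profile_metrics(extract_profile(map_10mm, "crossplane"))
    p2 = profile_metrics(extract_profile(map_10mm.scaled(7.3), "crossplane"))
    for key in p1.as_dict():
        assert p1.as_dict()[key] == pytest.approx(p2.as_dict()[key], abs=1e-9)


class TestPDD:
    def test_single_reference_depth(self, map_10mm):
        series = compute_pdd([(0.0, map_10mm)])
        assert series.pdd.tolist() == [100.0]

    def test_exponential_closed_form(self):
        t = BeamGroundTruth(nominal_size=10.0, edge_sigma=0.4, mu_eff=0.3, scatter_growth=0.0)
        maps = generate_depth_series(t, [0.0, 2.0])
        series = compute_pdd(list(zip([0.0, 2.0], maps)), roi_mm=2.0)
        assert series.pdd[1] == pytest.approx(54.88, abs=0.01)

    def test_monotone_generator_gives_monotone_pdd(self):
        t = BeamGroundTruth(nominal_size=10.0, edge_sigma=0.4, mu_eff=0.3)
        depths = [0.0, 1.0, 2.0, 3.0]
        maps = generate_depth_series(t, depths, ssd=302.0)
        series = compute_pdd(list(zip(depths, maps)))
        assert np.all(np.diff(series.pdd) < 0)

    def test_missing_reference_rejected(self, map_10mm):
        with pytest.raises(ValueError, match="reference"):
            compute_pdd([(1.0, map_10mm)])


class TestROF:
    def test_identity_and_scale_invariance(self):
        assert compute_rof(2.0, 2.0) == 1.0
        assert compute_rof(2.0, 4.0) == compute_rof(2.0 * 3, 4.0 * 3)

    def test_generated_maps_with_known_ratio(self):
        t1 = BeamGroundTruth(nominal_size=10.0, edge_sigma=0.4, dose_cax=2.0)
        t2 = BeamGroundTruth(nominal_size=10.0, edge_sigma=0.4, dose_cax=4.0)
        m1 = generate_dose_map(t1, 20.0, FILM_PITCH)
        m2 = generate_dose_map(t2, 20.0, FILM_PITCH)
        assert compute_rof(m1.central_roi_mean(2.0), m2.central_roi_mean(2.0)) == pytest.approx(0.5, rel=1e-9)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            compute_rof(1.0, 0.0)


class TestEffectiveOffset:
    def test_symmetric_fields_at_origin(self):
        m = ProfileMetrics(10.0, 0.8, 0.8, 0.0, 0.0)
        assert effective_offset([(m, m)]) == [(0.0, 0.0)]

    def test_wider_right_crossplane_penumbra(self):
        inplane = ProfileMetrics(10.0, 0.8, 0.8, 0.0, 0.0)
        crossplane = ProfileMetrics(10.0, 0.8, 1.0, 0.0, 0.0)
        (dx, dy), = effective_offset([(inplane, crossplane)])
        assert dx == pytest.approx(0.2)
        assert dy == 0.0

    def test_wider_left_gives_negative_delta(self):
        inplane = ProfileMetrics(10.0, 1.0, 0.8, 0.0, 0.0)
        crossplane = ProfileMetrics(10.0, 0.8, 0.8, 0.0, 0.0)
        (dx, dy), = effective_offset([(inplane, crossplane)])
        assert dy == pytest.approx(-0.2)
        assert dx == 0.0

    def test_missing_axis_skipped_with_warning(self):
        m = ProfileMetrics(10.0, 0.8, 0.8, 0.0, 0.0)
        with pytest.warns(UserWarning, match="missing axis"):
            out = effective_offset([(m, None), (m, m)])
        assert out[0] is None and out[1] == (0.0, 0.0)


class TestPercentDifference:
    @pytest.mark.parametrize(
        "local,ref,denom,printed,digits",
        [
            (75.00, 77.00, "reference", 2.60, 2),
            (2.64, 2.25, "local", 14.8, 1),
            (5.0, 5.0, "reference", 0.0, 2),
        ],
    )
    def test_report_conventions(self, local, ref, denom, printed, digits):
        assert round_half_up(percent_difference(local, ref, denom), digits) == printed

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0, "reference")

    def test_half_up_rounding(self):
        assert round_half_up(2.5951, 2) == 2.60
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(14.77, 1) == 14.8


class TestCompareDoseGrids:
    def _stack(self, dose_map, n=3, dz=5.0):
        return np.repeat(dose_map.values[None, :, :], n, axis=0), (dz, dose_map.pixel_pitch, dose_map.pixel_pitch)

    def test_identical_grids_zero_differences(self, map_10mm):
        grid, spacing = self._stack(map_10mm)
        cmp = compare_dose_grids(map_10mm, grid, spacing, depth=0.5)
        for ax in ("crossplane", "inplane"):
            for val in cmp.diff_pct[ax].values():
                assert val == pytest.approx(0.0, abs=0.2)
        assert cmp.roi_ratio == pytest.approx(1.0, abs=1e-3)

    def test_scaled_grid_shape_metrics_identical(self, map_10mm):
        grid, spacing = self._stack(map_10mm)
        cmp = compare_dose_grids(map_10mm, grid * 2.0, spacing, depth=0.5)
        assert cmp.roi_ratio == pytest.approx(0.5, abs=1e-3)
        assert cmp.film["crossplane"].fwhm == pytest.approx(
            cmp.external["crossplane"].fwhm, abs=1e-6
        )

    def test_field_size_difference_arithmetic(self):
        film_t = BeamGroundTruth(nominal_size=2.64, edge_sigma=0.2, dose_cax=1.0)
        tps_t = BeamGroundTruth(nominal_size=2.25, edge_sigma=0.2, dose_cax=1.0)
        film_map = generate_dose_map(film_t, 8.0, 0.05)
        tps_map = generate_dose_map(tps_t, 8.0, 0.05)
        grid = np.repeat(tps_map.values[None, :, :], 2, axis=0)
        cmp = compare_dose_grids(film_map, grid, (5.0, 0.05, 0.05), depth=0.0)
        diff = cmp.diff_pct["crossplane"]["fwhm_mm"]
        assert round_half_up(diff, 1) == pytest.approx(14.8, abs=0.3)

    def test_depth_outside_grid_rejected(self, map_10mm):
        grid, spacing = self._stack(map_10mm)
        with pytest.raises(ValueError, match="depth"):
            compare_dose_grids(map_10mm, grid, spacing, depth=9.0)
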