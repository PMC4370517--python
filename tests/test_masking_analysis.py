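import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cimasking.errors import (
    AlignmentError,
    DegenerateFunctionError,
    ExtrapolationError,
    NoPeakError,
    WindowError,
)
from cimasking.masking_analysis import (
    NormalizedFunction,
    ShiftFunction,
    align_to_peak_and_average,
    area_difference_measure,
    compute_shift_function,
    fit_gaussian_peak,
    interpolate_function,
    locate_ipsi_masker,
    normalize_shift_function,
    peak_difference_measure,
    windowed_area,
)


def make_shift(places, shifts, kind="contralateral"):
    return ShiftFunction(
        subject="S01",
        masker_kind=kind,
        masker_location="apical",
        probe_places=np.asarray(places, float),
        shifts=np.asarray(shifts, float),
    )


def make_norm(places, values):
    return NormalizedFunction(
        subject="S01",
        masker_kind="contralateral",
        masker_location="apical",
        probe_places=np.asarray(places, float),
        values=np.asarray(values, float),
        normalization_range=(0.0, 1.0),
    )


def riemann_area(fn, lo, hi, n=200_001):
    """Brute-force fine Riemann sum over the piecewise-linear function."""
    xs = np.linspace(lo, hi, n)
    ys = np.interp(xs, fn.probe_places, fn.values)
    return float(np.sum(0.5 * (ys[1:] + ys[:-1]) * np.diff(xs)))


def frame(places, thresholds):
    return pd.DataFrame({"probe_place": places, "threshold": thresholds})


class TestShiftFunction:
    def test_subtraction(self):
        sf = compute_shift_function(
            frame([5, 6, 7], [220.0, 260.0, 220.0]), frame([5, 6, 7], [200.0] * 3)
        )
        assert sf.shifts == pytest.approx([20.0, 60.0, 20.0])

    def test_identical_tables_give_zero_shifts(self):
        sf = compute_shift_function(frame([1, 2], [200, 210]), frame([1, 2], [200, 210]))
        assert sf.shifts == pytest.approx([0.0, 0.0])

    def test_negative_shifts_preserved(self):
        sf = compute_shift_function(frame([1, 2], [190, 230]), frame([1, 2], [200, 210]))
        assert sf.shifts == pytest.approx([-10.0, 20.0])

    def test_mismatched_places_raise_not_interpolate(self):
        with pytest.raises(AlignmentError) as exc:
            compute_shift_function(frame([5, 6], [220, 260]), frame([5, 6, 7], [200] * 3))
        assert 7.0 in exc.value.offending_places


class TestNormalization:
    @pytest.mark.parametrize(
        "shifts, expected",
        [
            ([0.0, 60.0, 20.0], [0.0, 1.0, 1 / 3]),
            ([-10.0, 50.0, 20.0], [0.0, 1.0, 0.5]),
        ],
    )
    def test_minmax(self, shifts, expected):
        norm = normalize_shift_function(make_shift([5, 6, 7], shifts))
        assert norm.values == pytest.approx(expected)
        assert norm.normalization_range == (min(shifts), max(shifts))

    def test_constant_function_is_degenerate(self):
        with pytest.raises(DegenerateFunctionError):
            normalize_shift_function(make_shift([5, 6, 7], [30.0, 30.0, 30.0]))

    def test_peak_mode_divides_by_maximum(self):
        norm = normalize_shift_function(make_shift([5, 6, 7], [10.0, 50.0, 25.0]), "peak")
        assert norm.values == pytest.approx([0.2, 1.0, 0.5])

    def test_idempotence(self):
        norm = normalize_shift_function(make_shift([5, 6, 7], [0.0, 60.0, 20.0]))
        again = normalize_shift_function(
            make_shift([5, 6, 7], norm.values)
        )
        assert again.values == pytest.approx(norm.values)


class TestInterpolation:
    def test_linear_midpoint(self):
        out = interpolate_function(make_norm([5, 6], [0.0, 1.0]), grid_step=0.5)
        assert out.probe_places == pytest.approx([5.0, 5.5, 6.0])
        assert out.values == pytest.approx([0.0, 0.5, 1.0])

    def test_single_point_rejected(self):
        with pytest.raises(ExtrapolationError):
            interpolate_function(make_norm([5], [1.0]), grid_step=0.5)

    def test_grid_spans_exactly_measured_range(self):
        out = interpolate_function(make_norm([4.0, 6.0, 8.1], [0, 1, 0]), grid_step=0.5)
        assert out.probe_places[0] == 4.0 and out.probe_places[-1] == pytest.approx(8.1)

    def test_triangle_area_exact(self):
        tri = make_norm([4, 6, 8], [0.0, 1.0, 0.0])
        fine = interpolate_function(tri, grid_step=0.01)
        area = np.trapezoid(fine.values, fine.probe_places)
        assert area == pytest.approx(2.0, rel=1e-6)
        assert area == pytest.approx(riemann_area(tri, 4, 8), rel=1e-6)


class TestGaussianPeak:
    def test_recovers_noiseless_gaussian(self):
        x = np.arange(4.0, 9.01, 0.5)
        y = 50.0 * np.exp(-((x - 6.3) ** 2) / 2.0)
        fit = fit_gaussian_peak(make_shift(x, y))
        assert fit.fit_kind == "gaussian"
        assert fit.peak_place == pytest.approx(6.3, abs=0.01)
        assert fit.peak_magnitude == pytest.approx(50.0, abs=0.5)

    def test_symmetric_triangle_centres_at_apex(self):
        x = np.arange(3.0, 9.01, 0.5)
        y = np.maximum(0.0, 40.0 - 20.0 * np.abs(x - 6.0))
        fit = fit_gaussian_peak(make_shift(x, y))
        assert fit.peak_place == pytest.approx(6.0, abs=0.05)

    def test_skewed_bimodal_reports_kind_and_discrepancy(self):
        # two unequal bumps: a Gaussian fit cannot describe this shape
        x = np.arange(2.0, 12.01, 0.5)
        y = 60.0 * np.exp(-((x - 4.0) ** 2) / 0.5) + 45.0 * np.exp(-((x - 9.0) ** 2) / 8.0)
        fit = fit_gaussian_peak(make_shift(x, y), max_residual_fraction=0.1)
        assert fit.fit_kind in ("gaussian", "absolute")
        assert fit.absolute_place == pytest.approx(4.0)
        if fit.fit_kind == "absolute":
            assert fit.peak_place == fit.absolute_place
        else:
            assert abs(fit.peak_place - fit.absolute_place) > 0.0

    def test_all_nonpositive_shifts_rejected(self):
        with pytest.raises(NoPeakError):
            fit_gaussian_peak(make_shift([1, 2, 3, 4], [-5.0, -1.0, -2.0, -4.0]))


class TestLocateIpsiMasker:
    def test_absolute_mode_returns_argmax_place(self):
        sf = make_shift([4, 5, 6, 7, 8], [5, 20, 60, 25, 10])
        assert locate_ipsi_masker(sf, "absolute") == 6.0

    def test_contralateral_peak_remote_from_masker(self):
        # a masker on electrode 9 producing the most masking at electrode 6
        places = np.arange(3.0, 10.01, 0.5)
        shifts = 50.0 * np.exp(-((places - 6.0) ** 2) / 2.0)
        assert locate_ipsi_masker(make_shift(places, shifts), "absolute") == pytest.approx(6.0)

    def test_modes_differ_on_skewed_function(self):
        x = np.arange(2.0, 12.01, 0.5)
        y = 50.0 * np.exp(-((x - 5.0) ** 2) / 0.5) + 40.0 * np.exp(-((x - 8.0) ** 2) / 18.0)
        absolute = locate_ipsi_masker(make_shift(x, y), "absolute")
        gaussian = locate_ipsi_masker(make_shift(x, y), "gaussian")
        assert absolute != pytest.approx(gaussian, abs=0.1)

    def test_plateau_resolves_to_centre(self):
        sf = make_shift([4, 5, 6, 7, 8], [0, 30, 30, 30, 0])
        assert locate_ipsi_masker(sf, "absolute") == pytest.approx(6.0)


class TestWindowedArea:
    def test_constant_one_full_window(self):
        norm = make_norm(np.arange(0.0, 12.1, 1.0), np.ones(13))
        wa = windowed_area(norm, center=6.0, halfwidth=3.0)
        assert wa.area == pytest.approx(6.0)
        assert wa.coverage == pytest.approx(1.0)

    def test_constant_zero(self):
        norm = make_norm(np.arange(0.0, 12.1, 1.0), np.zeros(13))
        assert windowed_area(norm, 6.0).area == pytest.approx(0.0)

    def test_triangle(self):
        norm = make_norm([3.0, 6.0, 9.0], [0.0, 1.0, 0.0])
        wa = windowed_area(norm, center=6.0, halfwidth=3.0)
        assert wa.area == pytest.approx(3.0, rel=1e-9)

    def test_truncated_window_reports_coverage(self):
        norm = make_norm([5.0, 6.0, 7.0], [0.0, 1.0, 0.0])
        wa = windowed_area(norm, center=6.0, halfwidth=3.0)
        assert wa.coverage == pytest.approx(2.0 / 6.0)
        assert wa.area == pytest.approx(1.0, rel=1e-9)

    def test_empty_intersection_rejected(self):
        norm = make_norm([5.0, 6.0, 7.0], [0.0, 1.0, 0.0])
        with pytest.raises(WindowError):
            windowed_area(norm, center=20.0, halfwidth=3.0)

    def test_matches_brute_force_riemann(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            places = np.sort(rng.uniform(1.0, 13.0, size=9))
            places[0], places[-1] = 1.0, 13.0
            values = rng.uniform(0.0, 1.0, size=9)
            norm = make_norm(places, values)
            wa = windowed_area(norm, center=rng.uniform(3.0, 11.0), halfwidth=3.0)
            lo, hi = max(wa.window[0], 1.0), min(wa.window[1], 13.0)
            assert wa.area == pytest.approx(riemann_area(norm, lo, hi), rel=1e-3)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_area_bounds_for_normalized_functions(self, seed):
        rng = np.random.default_rng(seed)
        places = np.sort(rng.uniform(1.0, 13.0, size=7))
        places = np.unique(places)
        if places.size < 2:
            return
        values = rng.uniform(0.0, 1.0, size=places.size)
        wa = windowed_area(make_norm(places, values), center=float(places.mean()), halfwidth=3.0)
        assert 0.0 <= wa.area <= 6.0 + 1e-12


class TestDifferenceMeasures:
    def gaussian_pair(self, sigma_c, sigma_i, peak=7.0, span=(1.0, 13.0), step=0.25):
        x = np.arange(span[0], span[1] + 1e-9, step)
        contra = make_shift(x, 60.0 * np.exp(-((x - peak) ** 2) / (2 * sigma_c**2)), "contralateral")
        ipsi = make_shift(x, 60.0 * np.exp(-((x - peak) ** 2) / (2 * sigma_i**2)), "ipsilateral")
        return normalize_shift_function(contra), normalize_shift_function(ipsi)

    def test_identical_functions_give_unity(self):
        contra, ipsi = self.gaussian_pair(2.0, 2.0)
        dm, _, _ = area_difference_measure(contra, ipsi, center=7.0)
        assert dm.value == pytest.approx(1.0, rel=1e-9)

    def test_narrow_contra_against_numerical_oracle(self):
        contra, ipsi = self.gaussian_pair(1.0, 2.0)
        dm, wa_c, wa_i = area_difference_measure(contra, ipsi, center=7.0)
        # independent oracle: fine Riemann sums of the same normalized samples
        oracle = riemann_area(contra, 4.0, 10.0) / riemann_area(ipsi, 4.0, 10.0)
        assert dm.value == pytest.approx(oracle, rel=1e-3)
        assert dm.value < 1.0

    def test_sharpness_ordering_over_sigma_grid(self):
        for sigma_c in (0.5, 1.0, 1.5, 2.5, 3.0):
            contra, ipsi = self.gaussian_pair(sigma_c, 2.0)
            dm, _, _ = area_difference_measure(contra, ipsi, center=7.0)
            assert (dm.value < 1.0) == (sigma_c < 2.0) or sigma_c == 2.0

    def test_translation_invariance(self):
        c1, i1 = self.gaussian_pair(1.0, 2.0, peak=6.0, span=(1.0, 11.0))
        c2, i2 = self.gaussian_pair(1.0, 2.0, peak=8.0, span=(3.0, 13.0))
        dm1, _, _ = area_difference_measure(c1, i1, center=6.0)
        dm2, _, _ = area_difference_measure(c2, i2, center=8.0)
        assert dm1.value == pytest.approx(dm2.value, rel=1e-9)
        p1 = peak_difference_measure(
            make_shift(c1.probe_places, c1.values * 60), make_shift(i1.probe_places, i1.values * 60)
        )
        p2 = peak_difference_measure(
            make_shift(c2.probe_places, c2.values * 60), make_shift(i2.probe_places, i2.values * 60)
        )
        assert p1.ratio.value == pytest.approx(p2.ratio.value, rel=1e-9)

    def test_peak_ratio_and_difference(self):
        contra = make_shift([5, 6, 7], [10.0, 30.0, 10.0], "contralateral")
        ipsi = make_shift([5, 6, 7], [20.0, 60.0, 20.0], "ipsilateral")
        cmp = peak_difference_measure(contra, ipsi)
        assert cmp.ratio.value == pytest.approx(0.5)
        assert cmp.difference_ua == pytest.approx(30.0)

    def test_equal_peaks_unity_zero(self):
        fn = make_shift([5, 6, 7], [10.0, 30.0, 10.0])
        cmp = peak_difference_measure(fn, make_shift([5, 6, 7], [10.0, 30.0, 10.0], "ipsilateral"))
        assert cmp.ratio.value == pytest.approx(1.0)
        assert cmp.difference_ua == pytest.approx(0.0)


class TestAlignToPeakAndAverage:
    def test_single_function_recentred(self):
        sf = make_shift([4, 5, 6, 7], [0.0, 10.0, 40.0, 5.0])
        prof = align_to_peak_and_average([sf], grid_step=0.5)
        at_zero = prof.loc[prof["rel_place"] == 0.0, "mean_shift"]
        assert at_zero.iloc[0] == pytest.approx(40.0)

    def test_translation_invariant_average(self):
        a = make_shift([4, 5, 6, 7], [0.0, 10.0, 40.0, 5.0])
        b = make_shift([7, 8, 9, 10], [0.0, 10.0, 40.0, 5.0])
        prof = align_to_peak_and_average([a, b], grid_step=0.5)
        solo = align_to_peak_and_average([a], grid_step=0.5)
        merged = prof.merge(solo, on="rel_place", suffixes=("_pair", "_solo"))
        assert merged["mean_shift_pair"].to_numpy() == pytest.approx(
            merged["mean_shift_solo"].to_numpy()
        )
        assert (prof["n"] == 2).all()

    def test_mirrored_asymmetry_cancels(self):
        x = np.arange(3.0, 9.01, 0.5)
        left_skew = np.interp(x, [3, 6, 9], [0, 40, 20])
        right_skew = np.interp(x, [3, 6, 9], [20, 40, 0])
        prof = align_to_peak_and_average(
            [make_shift(x, left_skew), make_shift(x, right_skew)], grid_step=0.5
        )
        sym = prof.set_index("rel_place")["mean_shift"]
        for r in sym.index:
            if -r in sym.index:
                assert sym[r] == pytest.approx(sym[-r], abs=1e-9)
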