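import dataclasses
import math

import numpy as np
import pytest

from cimasking import masking_analysis as ma
from cimasking import virtual_listener as vl
from cimasking.stimulus_space import (
    PulseTrainSpec,
    amplitude_after_db_step,
    resolve_place,
    ua_to_db,
)


def masker(place=6.0, ear="right", level=None, params=None):
    if level is None:
        level = vl.mcl(params, place, ear) if params else 632.455
    return PulseTrainSpec(500.0, level, resolve_place(place), ear)


@pytest.fixture
def flat_listener():
    ear = vl.EarParams(threshold_baseline_ua=200.0)
    return vl.ListenerParams(
        left=ear,
        right=ear,
        masking=vl.MaskingParams(
            ipsi_gain_ua=80.0,
            ipsi_sigma_apical=2.0,
            ipsi_sigma_basal=2.0,
            contra_gain_ua=48.0,
            contra_sigma_apical=1.0,
            contra_sigma_basal=1.0,
            interaural_offset=0.5,
        ),
    )


class TestTrueMaskedThreshold:
    def test_no_masker_returns_flat_profile(self, flat_listener):
        for place in (1.0, 6.3, 12.0):
            assert vl.true_masked_threshold(flat_listener, place, "left") == 200.0

    def test_zero_contra_gain_gives_no_contralateral_masking(self, flat_listener):
        params = dataclasses.replace(
            flat_listener, masking=dataclasses.replace(flat_listener.masking, contra_gain_ua=0.0)
        )
        m = masker(6.0, "right", params=params)
        for place in (4.0, 6.0, 8.0):
            assert vl.true_masked_threshold(params, place, "left", m) == 200.0

    def test_ipsilateral_gaussian_closed_form(self, flat_listener):
        # probe 2 electrodes basal of an MCL masker, sigma 2: 200 + 80*exp(-0.5)
        m = masker(6.0, "left", params=flat_listener)
        got = vl.true_masked_threshold(flat_listener, 8.0, "left", m)
        assert got == pytest.approx(200.0 + 80.0 * math.exp(-0.5), rel=1e-9)

    def test_contralateral_peak_is_offset_from_masker(self, flat_listener):
        m = masker(6.0, "right", params=flat_listener)
        places = np.arange(4.0, 8.01, 0.1)
        thr = [vl.true_masked_threshold(flat_listener, p, "left", m) for p in places]
        assert places[int(np.argmax(thr))] == pytest.approx(6.5)  # masker + offset

    def test_split_sigma_asymmetry(self, flat_listener):
        params = dataclasses.replace(
            flat_listener,
            masking=dataclasses.replace(
                flat_listener.masking, ipsi_sigma_apical=1.0, ipsi_sigma_basal=3.0
            ),
        )
        m = masker(6.0, "left", params=params)
        apical = vl.true_masked_threshold(params, 4.0, "left", m)
        basal = vl.true_masked_threshold(params, 8.0, "left", m)
        assert basal > apical  # broader spread on the basal side

    def test_masker_below_threshold_scales_to_zero(self, flat_listener):
        quiet = masker(6.0, "left", level=100.0)  # below the 200 μA threshold
        assert vl.true_masked_threshold(flat_listener, 6.0, "left", quiet) == 200.0

    def test_masker_level_scales_linearly_to_mcl(self, flat_listener):
        half = masker(6.0, "left", level=amplitude_after_db_step(200.0, 5.0))  # half headroom
        got = vl.true_masked_threshold(flat_listener, 6.0, "left", half)
        assert got == pytest.approx(200.0 + 0.5 * 80.0, rel=1e-9)


class TestPsychometrics:
    def test_saturation_well_above_threshold(self, flat_listener):
        level = amplitude_after_db_step(200.0, 20.0)
        assert vl.audibility_probability(flat_listener, level, 6.0, "left") > 0.999

    def test_midpoint_at_threshold(self, flat_listener):
        assert vl.audibility_probability(flat_listener, 200.0, 6.0, "left") == pytest.approx(0.5)

    def test_quarter_db_above_threshold_closed_form(self, flat_listener):
        level = amplitude_after_db_step(200.0, 0.25)
        p = vl.audibility_probability(flat_listener, level, 6.0, "left")
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-2.0)), rel=1e-6)

    def test_lapse_and_guess_bound_probability(self):
        ear = vl.EarParams(lapse_rate=0.05, guess_rate=0.1)
        params = vl.ListenerParams(left=ear, right=ear)
        high = vl.audibility_probability(params, amplitude_after_db_step(200.0, 30.0), 6.0, "left")
        low = vl.audibility_probability(params, amplitude_after_db_step(200.0, -30.0), 6.0, "left")
        assert high == pytest.approx(0.95, abs=1e-6)
        assert low == pytest.approx(0.10, abs=1e-6)

    def test_compare_loudness_symmetric_and_deterministic(self, flat_listener):
        a = PulseTrainSpec(500.0, 300.0, resolve_place(6.0), "left")
        b = PulseTrainSpec(500.0, 300.0, resolve_place(6.0), "right")
        rng = np.random.default_rng(0)
        picks = [vl.compare_loudness(flat_listener, a, b, rng) for _ in range(2000)]
        assert 0.45 < np.mean([p == "a" for p in picks]) < 0.55

        loud = a.with_amplitude(amplitude_after_db_step(300.0, 10.0))
        det = dataclasses.replace(flat_listener, choice_slope=math.inf)
        assert vl.compare_loudness(det, loud, b, rng) == "a"

    def test_loudness_offset_cancellation(self, flat_listener):
        params = dataclasses.replace(
            flat_listener, right=dataclasses.replace(flat_listener.right, loudness_offset_db=2.0)
        )
        a = PulseTrainSpec(500.0, 300.0, resolve_place(6.0), "left")
        b = PulseTrainSpec(500.0, amplitude_after_db_step(300.0, -2.0), resolve_place(6.0), "right")
        rng = np.random.default_rng(1)
        picks = [vl.compare_loudness(params, a, b, rng) for _ in range(2000)]
        assert 0.45 < np.mean([p == "a" for p in picks]) < 0.55


class TestGenerateExperimentDataset:
    def test_row_bookkeeping(self):
        cohort = vl.null_cohort_params(1)
        design = vl.ExperimentDesign(
            probe_places=(4.0, 5.0, 6.0, 7.0, 8.0),
            masker_places=(("apical", 5.0), ("middle", 7.0)),
            seed=1,
        )
        table = vl.generate_experiment_dataset(cohort, design)
        # 5 unmasked + 5 contra x 2 locations + 5 ipsi x 2 locations
        assert len(table) == 25
        counts = table.groupby("condition").size()
        assert counts["unmasked"] == 5
        assert counts["contra_masked"] == counts["ipsi_masked"] == 10

    def test_reproducible_from_seed(self, small_design):
        cohort = vl.default_cohort_params(2, seed=5)
        t1 = vl.generate_experiment_dataset(cohort, small_design)
        t2 = vl.generate_experiment_dataset(cohort, small_design)
        assert t1.equals(t2)

    def test_different_seed_changes_stochastic_data(self, small_design):
        cohort = vl.default_cohort_params(2, seed=5)
        other = dataclasses.replace(small_design, seed=small_design.seed + 1)
        t1 = vl.generate_experiment_dataset(cohort, small_design)
        t2 = vl.generate_experiment_dataset(cohort, other)
        assert not t1["threshold"].equals(t2["threshold"])

    def test_ipsi_masker_placed_at_contralateral_peak(self):
        cohort = vl.null_cohort_params(1)
        design = vl.ExperimentDesign(seed=2)
        table = vl.generate_experiment_dataset(cohort, design)
        ipsi = table[table["condition"] == "ipsi_masked"]
        # null listener: contra peak sits at the masker place (offset 0)
        for location, masker_place in design.masker_places:
            got = ipsi[ipsi["masker_location"] == location]["masker_place"].iloc[0]
            assert got == pytest.approx(masker_place, abs=0.25)


class TestGenerativeProperties:
    def true_contra_function(self, params, places, masker_place=6.0):
        m = masker(masker_place, "right", params=params)
        return np.array(
            [vl.true_masked_threshold(params, p, "left", m) - 200.0 for p in places]
        )

    def test_wider_contra_sigma_never_decreases_area(self, flat_listener):
        places = np.arange(1.0, 13.01, 0.25)
        areas = []
        for sigma in (0.5, 1.0, 1.5, 2.0, 3.0):
            params = dataclasses.replace(
                flat_listener,
                masking=dataclasses.replace(
                    flat_listener.masking,
                    contra_sigma_apical=sigma,
                    contra_sigma_basal=sigma,
                    interaural_offset=0.0,
                ),
            )
            shifts = self.true_contra_function(params, places)
            norm = ma.normalize_shift_function(
                ma.ShiftFunction("S", "contralateral", "apical", places, shifts)
            )
            areas.append(ma.windowed_area(norm, 6.0).area)
        assert np.all(np.diff(areas) >= -1e-9)

    def test_larger_contra_gain_never_decreases_peak(self, flat_listener):
        places = np.arange(1.0, 13.01, 0.25)
        peaks = []
        for gain in (10.0, 40.0, 80.0):
            params = dataclasses.replace(
                flat_listener,
                masking=dataclasses.replace(flat_listener.masking, contra_gain_ua=gain),
            )
            peaks.append(self.true_contra_function(params, places).max())
        assert np.all(np.diff(peaks) >= -1e-9)

    def test_gaussian_fit_recovers_masker_place_plus_offset(self, flat_listener):
        places = np.arange(1.0, 13.01, 0.5)
        shifts = self.true_contra_function(flat_listener, places, masker_place=6.0)
        sf = ma.ShiftFunction("S", "contralateral", "apical", places, shifts)
        fit = ma.fit_gaussian_peak(sf)
        assert fit.fit_kind == "gaussian"
        # peak = masker place + interaural offset, within the probe grid step
        assert fit.peak_place == pytest.approx(6.5, abs=0.5)
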