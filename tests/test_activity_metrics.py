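"""Population profiles, peak morphometrics and count distributions."""

from dataclasses import replace

import numpy as np
import pytest

from flyburst.activity_metrics import (PopulationProfile, count_distribution,
                                       find_peaks, half_width,
                                       midday_activity, peak_area,
                                       population_average)
from flyburst.dam_io import ActivitySeries, rebin
from flyburst.light_model import make_program
from flyburst.synthetic_cohort import cohort_to_series, get_preset, simulate_cohort

BINS = 48  # 30-min bins per 24 h


def _fly(counts30, n_days=1, fly_id="f"):
    # expand a 30-min/day pattern into a 20-s series over n_days,
    # placing each 30-min total in the first 20-s bin of its half hour
    totals = np.tile(np.asarray(counts30, dtype=int), n_days)
    base = np.zeros(len(totals) * 90, dtype=int)
    base[::90] = totals
    return ActivitySeries(fly_id, 0.0, 20, base)


def _profile(values):
    values = np.asarray(values, dtype=float)
    return PopulationProfile(zt_grid=np.arange(len(values)) * 0.5,
                             mean_counts=values, n_flies=1, n_days=1)


@pytest.fixture(scope="module")
def ld1():
    return make_program("square", 12, 12, 8000, 1)


class TestPopulationAverage:
    def test_single_fly_single_day_is_own_series(self, ld1):
        counts = np.arange(BINS)
        prof = population_average([_fly(counts)], ld1)
        assert np.array_equal(prof.mean_counts, counts)

    def test_two_identical_flies_average_to_either(self, ld1):
        counts = np.arange(BINS)
        prof = population_average([_fly(counts, fly_id="a"), _fly(counts, fly_id="b")], ld1)
        assert np.array_equal(prof.mean_counts, counts)

    def test_constant_cohort_gives_constant_profile(self, ld1):
        prof = population_average([_fly(np.full(BINS, 4))], ld1)
        assert np.all(prof.mean_counts == 4)

    def test_folding_conserves_mass(self, ld1):
        rng = np.random.default_rng(0)
        flies = [ActivitySeries(f"f{i}", 0.0, 20, rng.poisson(0.3, 3 * 4320))
                 for i in range(4)]
        prof = population_average(flies, ld1)
        daily_totals = [s.counts.sum() / 3 for s in flies]
        assert prof.mean_counts.sum() == pytest.approx(np.mean(daily_totals))

    def test_ragged_cohort_rejected(self, ld1):
        a = ActivitySeries("a", 0.0, 20, np.zeros(4320, dtype=int))
        b = ActivitySeries("b", 0.0, 20, np.zeros(8640, dtype=int))
        with pytest.raises(ValueError):
            population_average([a, b], ld1)

    def test_aperiodic_program_rejected(self):
        from flyburst.light_model import make_pulse_train
        prog = make_pulse_train([(1, 5), (8, 5)], 8000)
        with pytest.raises(ValueError):
            population_average([_fly(np.ones(BINS, dtype=int))], prog)


class TestFindPeaks:
    def test_morning_and_evening_bumps_located(self, ld1):
        zt = np.arange(BINS) * 0.5 + 0.25
        prof = _profile(10 * np.exp(-0.5 * ((zt - 0.25) / 0.5) ** 2)
                        + 8 * np.exp(-0.5 * ((zt - 11.0) / 0.5) ** 2))
        peaks = {p.peak_kind: p for p in find_peaks(prof, ld1)}
        assert peaks["M"].peak_time == pytest.approx(0.25, abs=0.5)
        assert peaks["E"].peak_time == pytest.approx(11.0, abs=0.5)
        assert "A" not in peaks

    def test_flat_profile_has_no_peaks(self, ld1):
        assert find_peaks(_profile(np.full(BINS, 3.0)), ld1) == []

    def test_midday_bump_reported_as_a_peak(self, ld1):
        zt = np.arange(BINS) * 0.5 + 0.25
        prof = _profile(10 * np.exp(-0.5 * ((zt - 0.25) / 0.5) ** 2)
                        + 8 * np.exp(-0.5 * ((zt - 11.0) / 0.5) ** 2)
                        + 6 * np.exp(-0.5 * ((zt - 6.0) / 1.0) ** 2))
        peaks = {p.peak_kind: p for p in find_peaks(prof, ld1)}
        assert "A" in peaks
        assert peaks["A"].peak_time == pytest.approx(6.0, abs=0.5)

    def test_m_peak_offset_sign(self, ld1):
        zt = np.arange(BINS) * 0.5 + 0.25
        prof = _profile(10 * np.exp(-0.5 * ((zt - 23.25) / 0.4) ** 2)
                        + 8 * np.exp(-0.5 * ((zt - 11.0) / 0.5) ** 2))
        peaks = {p.peak_kind: p for p in find_peaks(prof, ld1)}
        assert peaks["M"].offset == pytest.approx(-0.75)  # anticipation before dawn


class TestWidthAndArea:
    def test_triangular_peak_fwhm_is_half_base(self, ld1):
        vals = np.zeros(BINS)
        apex = 12
        w_bins = 6  # base half-width in bins -> base = 2*3 h, FWHM = 3 h
        for k in range(-w_bins, w_bins + 1):
            vals[apex + k] = max(0.0, 10 * (1 - abs(k) / w_bins))
        prof = _profile(vals)
        (peak,) = [p for p in find_peaks(prof, ld1) if p.peak_kind == "A"]
        assert half_width(prof, peak) == pytest.approx(3.0, abs=0.3)

    def test_gaussian_peak_fwhm(self, ld1):
        zt = np.arange(BINS) * 0.5 + 0.25
        sigma = 1.0
        prof = _profile(10 * np.exp(-0.5 * ((zt - 6.0) / sigma) ** 2))
        (peak,) = [p for p in find_peaks(prof, ld1) if p.peak_kind == "A"]
        assert half_width(prof, peak) == pytest.approx(2.355 * sigma, abs=0.5)

    def test_flat_peak_has_no_width(self, ld1):
        prof = _profile(np.full(BINS, 5.0))
        from flyburst.activity_metrics import PeakMetrics
        with pytest.raises(ValueError):
            half_width(prof, PeakMetrics("M", 0.25, 5.0))

    def test_constant_profile_area_is_twelve_bins(self):
        prof = _profile(np.full(BINS, 2.0))
        from flyburst.activity_metrics import PeakMetrics
        assert peak_area(prof, PeakMetrics("M", 6.25, 2.0)) == pytest.approx(24.0)

    def test_delta_peak_area_equals_height(self):
        vals = np.zeros(BINS)
        vals[12] = 7.0
        from flyburst.activity_metrics import PeakMetrics
        assert peak_area(_profile(vals), PeakMetrics("A", 6.25, 7.0)) == 7.0

    def test_gaussian_area_matches_quadrature(self, ld1):
        zt = np.arange(BINS) * 0.5 + 0.25
        sigma = 0.8
        vals = 10 * np.exp(-0.5 * ((zt - 6.0) / sigma) ** 2)
        prof = _profile(vals)
        (peak,) = [p for p in find_peaks(prof, ld1) if p.peak_kind == "A"]
        area = peak_area(prof, peak)
        fine = np.linspace(3.0, 9.0, 20001)
        quad = np.trapezoid(10 * np.exp(-0.5 * ((fine - 6.0) / sigma) ** 2), fine) / 0.5
        assert area == pytest.approx(quad, rel=0.02)

    def test_area_at_least_height(self, small_cohort, ld_program):
        prof = population_average(cohort_to_series(small_cohort), ld_program)
        for p in find_peaks(prof, ld_program):
            assert peak_area(prof, p) >= p.height


class TestMidday:
    def test_constant_profile(self, ld1):
        assert midday_activity(_profile(np.full(BINS, 3.0)), ld1) == 3.0

    def test_zero_midday(self, ld1):
        vals = np.zeros(BINS)
        vals[0] = 10
        assert midday_activity(_profile(vals), ld1) == 0.0

    def test_short_day_rejected(self):
        prog = make_program("square", 6, 18, 8000, 1)
        with pytest.raises(ValueError):
            midday_activity(_profile(np.ones(BINS)), prog)

    def test_midday_bump_mean(self, ld1):
        vals = np.zeros(BINS)
        vals[8:16] = 5.0  # exactly ZT 4-8
        assert midday_activity(_profile(vals), ld1) == 5.0

    def test_midday_increases_with_daytime_drive(self, ld_program):
        """Mirrors the light-level dose response of midday activity."""
        mids = []
        for elev in (0.5, 2.0, 6.0):
            params = replace(get_preset("yw"), day_elevation=elev,
                             incidence_scale=0.0)
            cohort = simulate_cohort(6, params, ld_program, seed=33)
            prof = population_average(cohort_to_series(cohort), ld_program)
            mids.append(midday_activity(prof, ld_program))
        assert mids[0] < mids[1] < mids[2]


class TestCountDistribution:
    def test_all_zeros_is_point_mass(self):
        s = ActivitySeries("f", 0, 180, np.zeros(100, dtype=int))
        dist = count_distribution([s])
        assert dist.probs[0] == 1.0 and dist.probs.sum() == 1.0

    def test_matches_direct_tabulation(self):
        a = ActivitySeries("a", 0, 180, np.array([0, 0, 1, 2, 2, 2]))
        b = ActivitySeries("b", 0, 180, np.array([1, 1, 4, 0, 0, 0]))
        dist = count_distribution([a, b])
        assert np.allclose(dist.probs, np.array([5, 3, 3, 0, 1]) / 12)
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_normalised_on_cohort(self, small_cohort_3min):
        dist = count_distribution(small_cohort_3min)
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_hyperactive_preset_right_shifts_distribution(self, ld_program):
        ctrl = simulate_cohort(6, get_preset("iso31"), ld_program, seed=44)
        hdc = simulate_cohort(6, get_preset("hdc"), ld_program, seed=44)
        d_ctrl = count_distribution([rebin(s, 180) for s in cohort_to_series(ctrl)])
        d_hdc = count_distribution([rebin(s, 180) for s in cohort_to_series(hdc)])
        assert d_hdc.mean() > d_ctrl.mean()
        assert d_hdc.mode() >= d_ctrl.mode()

    def test_burst_marker_reports_mean_event_count(self, small_cohort_3min,
                                                   ld_program):
        from flyburst.burst_detector import detect_bursts
        events = [e for s in small_cohort_3min for e in detect_bursts(s, ld_program)]
        dist = count_distribution(small_cohort_3min, events)
        assert dist.burst_marker == pytest.approx(np.mean([e.count for e in events]))
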