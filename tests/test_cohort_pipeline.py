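"""Cohort statistics: incidence, delay clustering, ratios, group tests."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from flyburst.burst_detector import BurstEvent, detect_bursts
from flyburst.cohort_pipeline import (compare_incidence, delay_clusters,
                                      incidence, is_light_associated,
                                      ratio_summary, run_report)
from flyburst.dam_io import rebin
from flyburst.light_model import make_program, make_pulse_train
from flyburst.synthetic_cohort import (cohort_to_series, cohort_truths,
                                       get_preset, sample_delay_mixture,
                                       simulate_cohort, write_cohort)


def _event(fly="f0", cycle=0, dt=2.0, count=50.0, ratio=5.0):
    return BurstEvent(fly_id=fly, cycle_index=cycle, bin_time=cycle * 86400 + dt * 3600,
                      count=count, zscore=15.0, delta_t=dt, ratio_to_m=ratio)


class TestIncidence:
    def test_no_events_is_zero(self, ld_program):
        res = incidence([], 10, ld_program)
        assert res.mean_percent == 0.0
        assert res.n_cycles == 5

    def test_every_fly_every_cycle_is_hundred(self, ld_program):
        events = [_event(f"f{i}", c) for i in range(10) for c in range(5)]
        res = incidence(events, 10, ld_program)
        assert res.mean_percent == 100.0
        assert np.all(res.per_cycle_percent == 100.0)

    def test_zero_flies_rejected(self, ld_program):
        with pytest.raises(ValueError):
            incidence([], 0, ld_program)

    def test_late_cluster_events_count_under_long_days(self, ld_program):
        # delta_t = 10 h is within a 12 h day: attributed to the pulse
        assert is_light_associated(_event(dt=10.0), ld_program)
        # delta_t = 14 h is night-time under 12:12: not attributed
        assert not is_light_associated(_event(dt=14.0), ld_program)

    def test_dark_bursts_after_short_pulse_still_count(self):
        prog = make_pulse_train([(1, 11)] * 3, 8000)
        assert is_light_associated(_event(dt=3.0), prog)  # dark, but in window
        assert not is_light_associated(_event(dt=6.0), prog)

    def test_per_experiment_aggregation(self, ld_program):
        events = [_event("f0", 0), _event("f0", 3), _event("f1", 2)]
        res = incidence(events, 4, ld_program, per="experiment")
        assert res.mean_percent == 50.0


class TestDelayClusters:
    def test_recovers_simulated_mixture(self):
        rng = np.random.default_rng(12)
        delays = sample_delay_mixture(500, (2, 10), (1.3, 2.7), (0.85, 0.15), rng)
        fit = delay_clusters(delays, seed=0)
        assert fit.means[0] == pytest.approx(2.0, abs=0.3)
        assert fit.means[1] == pytest.approx(10.0, abs=0.8)
        assert fit.sds[0] == pytest.approx(1.3, abs=0.2)
        assert fit.sds[1] == pytest.approx(2.7, abs=0.8)
        assert fit.weights[0] == pytest.approx(0.85, abs=0.08)

    def test_matches_sklearn_mixture(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(13)
        delays = sample_delay_mixture(400, (2, 10), (1.3, 2.7), (0.85, 0.15), rng)
        ours = delay_clusters(delays, seed=1)
        gm = sklearn.GaussianMixture(2, n_init=10, random_state=0, tol=1e-8)
        gm.fit(delays[:, None])
        order = np.argsort(gm.means_.ravel())
        assert np.allclose(ours.means, gm.means_.ravel()[order], atol=0.05)
        assert np.allclose(ours.sds, np.sqrt(gm.covariances_.ravel()[order]),
                           atol=0.05)

    def test_identical_delays_degenerate_with_sd_floor(self):
        fit = delay_clusters(np.full(20, 3.0))
        assert fit.degenerate
        assert np.all(fit.sds >= 1e-2)

    def test_fewer_delays_than_components_rejected(self):
        with pytest.raises(ValueError):
            delay_clusters([1.0], k=2)

    def test_well_separated_two_point_sample_exact_means(self):
        delays = np.array([1.0] * 10 + [20.0] * 10)
        fit = delay_clusters(delays, seed=0)
        assert fit.means[0] == pytest.approx(1.0, abs=1e-6)
        assert fit.means[1] == pytest.approx(20.0, abs=1e-6)
        assert fit.weights[0] == pytest.approx(0.5, abs=1e-6)


class TestRatioSummary:
    def test_single_event(self):
        res = ratio_summary([_event(ratio=5.0)])
        assert (res.mean, res.sd, res.n) == (5.0, 0.0, 1)

    def test_two_events_closed_form(self):
        res = ratio_summary([_event(ratio=4.0), _event(ratio=6.0)])
        assert res.mean == pytest.approx(5.0)
        assert res.sd == pytest.approx(np.sqrt(2.0))

    def test_missing_ratios_excluded_and_counted(self):
        res = ratio_summary([_event(ratio=5.0), _event(ratio=None)])
        assert res.n == 1 and res.n_missing == 1

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            ratio_summary([_event(ratio=None)])


def _mwu_enumeration_oracle(a, b):
    """Exact two-sided p by enumerating all rank assignments (tie-free)."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(1 for x in ga for y in gb if x > y))
    us = np.array(us)
    cdf = np.mean(us <= u_obs)
    sf = np.mean(us >= u_obs)
    return min(1.0, 2 * min(cdf, sf))


class TestCompareIncidence:
    def test_identical_groups_p_one(self):
        assert compare_incidence([10, 20, 30], [10, 20, 30]) == pytest.approx(1.0)

    def test_fully_separated_triples(self):
        p = compare_incidence([1, 2, 3], [10, 20, 30])
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (4, 3), (5, 4), (6, 6)])
    def test_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            pooled = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            a, b = pooled[:n1], pooled[n1:]
            assert compare_incidence(a, b) == pytest.approx(
                _mwu_enumeration_oracle(a, b), abs=1e-12)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_incidence([1.0], [2.0, 3.0])

    def test_blind_mutant_vs_control_significant(self, ld_program):
        ctrl = simulate_cohort(24, get_preset("yw"), ld_program, seed=61)
        blind = simulate_cohort(24, get_preset("norpa"), ld_program, seed=62)
        def perc(cohort):
            events = [e for s in cohort_to_series(cohort)
                      for e in detect_bursts(rebin(s, 180), ld_program)]
            return incidence(events, 24, ld_program).per_cycle_percent
        p = compare_incidence(perc(ctrl), perc(blind))
        assert p < 0.05


class TestConsistencyAndReport:
    def test_truth_and_detected_incidence_agree(self, small_cohort,
                                                small_cohort_3min, ld_program):
        """Consistency triangle: detector incidence matches ground truth
        within the measured recall/false-positive bounds."""
        events = [e for s in small_cohort_3min for e in detect_bursts(s, ld_program)]
        det = incidence(events, 16, ld_program).mean_percent
        n_cycles = len(ld_program.cycles())
        per_cycle = []
        for ci in range(n_cycles):
            flies = {t.fly_id for t in cohort_truths(small_cohort)
                     if t.cycle_index == ci and t.component == 0}
            per_cycle.append(100 * len(flies) / 16)
        truth = np.mean(per_cycle)
        assert abs(det - truth) <= 8.0  # late-cluster daytime events + rare misses

    def test_empty_monitor_errors_at_intake(self, tmp_path, ld_program):
        from flyburst.dam_io import write_dam
        mon = tmp_path / "empty.txt"
        write_dam([], mon)
        with pytest.raises(RuntimeError, match="intake"):
            run_report(mon, ld_program, tmp_path / "out")

    def test_report_outputs_are_deterministic(self, tmp_path, ld_program, yw_params):
        cohort = simulate_cohort(6, yw_params, ld_program, seed=77)
        mon = tmp_path / "mon.txt"
        write_cohort(cohort, mon)
        run_report(mon, ld_program, tmp_path / "a", seed=1)
        run_report(mon, ld_program, tmp_path / "b", seed=1)
        for name in ["bursts.csv", "incidence.csv", "delays.csv", "peaks.csv",
                     "summary.txt"]:
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_full_bundle_contents(self, tmp_path, ld_program, yw_params):
        cohort = simulate_cohort(6, yw_params, ld_program, seed=78)
        mon = tmp_path / "mon.txt"
        write_cohort(cohort, mon)
        out = run_report(mon, ld_program, tmp_path / "rep", seed=3)
        assert (tmp_path / "rep" / "summary.txt").exists()
        assert out["incidence"].n_flies == 6
        assert out["peaks"] and {p.peak_kind for p in out["peaks"]} >= {"M", "E"}
        assert out["periodogram"] is not None
        text = (tmp_path / "rep" / "summary.txt").read_text()
        assert "seed=3" in text
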