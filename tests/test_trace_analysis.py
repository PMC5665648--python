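"""Trace statistics: lifetimes, mixtures, cohorts, correlation, peaks, FRAP."""

import numpy as np
import pytest

from escrtdyn.calibration import CalibrationCurve
from escrtdyn.detection import SpotFit
from escrtdyn.synthetic import (generate_frap_trace, sample_lifetime,
                                simulate_trace, snf7_params, vps4_params)
from escrtdyn.trace_analysis import (MoleculeTrace, accumulation_stats,
                                     classify_productive, cohort_curves,
                                     cross_correlate, extract_trace,
                                     fit_biexponential, fit_frap,
                                     fit_max_mixture, fluctuation_peaks,
                                     lifetime, summarize_event)
from escrtdyn.tracking import Track

CAL = CalibrationCurve(unit_intensity=100.0, unit_intensity_sd=2.0,
                       exposure_reference=21.0, n_samples=1000)


def make_trace(n, dt=0.85, channel="eGFP", censored=False, track_id=0):
    n = np.asarray(n, dtype=float)
    return MoleculeTrace(track_id=track_id, channel=channel,
                         times=np.arange(len(n)) * dt, n=n,
                         n_sd=np.full(len(n), 0.5),
                         local_background_n=np.full(len(n), 0.3),
                         interpolated=np.zeros(len(n), dtype=bool),
                         censored=censored)


def make_track(amplitudes, start=3, gaps=()):
    spots = []
    frames = []
    t = start
    for a in amplitudes:
        while t in gaps:
            t += 1
        spots.append(SpotFit(frame=t, position=np.array([5e3, 5e3, 2e3]),
                             position_sd=np.full(3, 20.0), amplitude=a,
                             amplitude_sd=30.0, local_background=10.0,
                             local_background_sd=2.0, residual_sd=90.0,
                             fitted_sigmas=np.array([110.0, 110.0, 380.0]),
                             p_value=1e-6, accepted=True, converged=True,
                             dof=100))
        frames.append(t)
        t += 1
    tr = Track(0, spots)
    tr.gap_frames = sorted(set(gaps) & set(range(start, t)))
    return tr


class TestExtractTrace:
    def test_constant_amplitude_constant_n(self):
        tr = make_track([300.0] * 8)
        mt = extract_trace(tr, CAL, "eGFP", 850.0)
        np.testing.assert_allclose(mt.n, 3.0)
        assert np.all(mt.n_sd > 0)

    def test_gap_frame_interpolated_and_flagged(self):
        tr = make_track([100.0, 100.0, 300.0, 300.0], start=3, gaps={5})
        mt = extract_trace(tr, CAL, "eGFP", 850.0)
        assert len(mt.n) == 5
        assert mt.interpolated[2]
        assert mt.n[2] == pytest.approx(2.0)  # linear between 1 and 3

    def test_missing_calibration_rejected(self):
        with pytest.raises(ValueError):
            extract_trace(make_track([100.0] * 4), None, "eGFP", 850.0)


class TestLifetime:
    def test_frame_count_times_interval(self):
        mt = make_trace(np.ones(12))
        assert lifetime(mt) == pytest.approx(10.2)

    def test_generator_lifetimes_recovered_within_one_frame(self):
        rng = np.random.default_rng(0)
        p = snf7_params()
        err = []
        for _ in range(300):
            counts, life = simulate_trace(p, 850.0, rng)
            mt = make_trace(counts)
            err.append(abs(lifetime(mt) - life))
        assert np.mean(err) <= 0.85

    def test_censored_trace_excluded_from_fit_input(self):
        mt = make_trace(np.ones(60), censored=True)
        s = summarize_event(mt)
        assert s.censored


class TestBiexponentialFit:
    def test_single_exponential_collapse(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(8.0, 2000)
        fit = fit_biexponential(t, n_boot=0)
        eff_mean = fit.w * fit.tau1 + (1 - fit.w) * fit.tau2
        assert eff_mean == pytest.approx(8.0, rel=0.1)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(2)
        n = 2000
        comp = rng.random(n) < 0.7
        t = np.where(comp, rng.exponential(4.0, n), rng.exponential(20.0, n))
        fit = fit_biexponential(t, n_boot=0)
        assert fit.w == pytest.approx(0.7, rel=0.15)
        assert fit.tau1 == pytest.approx(4.0, rel=0.15)
        assert fit.tau2 == pytest.approx(20.0, rel=0.15)

    def test_truncation_handling(self):
        # ignoring left-truncation biases the fit; modeling it removes the bias
        rng = np.random.default_rng(3)
        n = 6000
        comp = rng.random(n) < 0.7
        t = np.where(comp, rng.exponential(4.0, n), rng.exponential(20.0, n))
        t = t[t >= 3.0]
        good = fit_biexponential(t, min_observable=3.0, n_boot=0)
        naive = fit_biexponential(t, min_observable=0.0, n_boot=0)
        # with truncation modeled, the slow component and weight stay honest
        assert good.tau2 == pytest.approx(20.0, rel=0.08)
        assert abs(good.w - 0.7) <= 0.08
        # the naive fit misattributes weight between the components
        assert abs(naive.w - 0.7) > abs(good.w - 0.7)

    def test_requires_enough_events(self):
        with pytest.raises(ValueError):
            fit_biexponential(np.ones(20), n_boot=0)


class TestAccumulation:
    def test_constant_trace(self):
        assert accumulation_stats(make_trace(np.full(6, 24.0))) == (24.0, 24.0)

    def test_triangular_trace(self):
        tri = make_trace([0.0, 10.0, 20.0, 30.0, 20.0, 10.0])
        mx, mn = accumulation_stats(tri)
        assert mx == 30.0
        assert mn == pytest.approx(15.0)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            accumulation_stats(make_trace(np.empty(0)))


class TestMaxMixture:
    def test_unimodal_first_mode(self):
        rng = np.random.default_rng(4)
        x = rng.normal(24.0, 6.0, 3000)
        fit = fit_max_mixture(x, K=2)
        se = 6.0 / np.sqrt(3000)
        assert fit.means[0] == pytest.approx(24.0, abs=max(3 * se, 0.5))
        assert fit.sds[0] == pytest.approx(6.0, abs=1.0)

    def test_bimodal_modes_recovered(self):
        # two populations, as for small endosomes vs clusters of two
        rng = np.random.default_rng(5)
        comp = rng.random(3000) < 0.5
        x = np.where(comp, rng.normal(12.0, 3.0, 3000),
                     rng.normal(24.0, 3.0, 3000))
        fit = fit_max_mixture(x, K=2)
        assert fit.means[0] == pytest.approx(12.0, abs=0.5)
        assert fit.means[1] == pytest.approx(24.0, abs=0.5)

    def test_degenerate_sample_single_component(self):
        fit = fit_max_mixture(np.full(500, 7.0), K=2)
        assert fit.K == 1
        assert fit.sds[0] == 0.0


class TestCohorts:
    def test_identical_traces_mean_equals_trace(self):
        trs = [make_trace(np.full(5, 20.0)) for _ in range(30)]
        cc = cohort_curves(trs, bin_edges=(3.0, 5.0), min_count=10, n_boot=200)
        assert cc.counts == [30]
        np.testing.assert_allclose(cc.means[0], 20.0)
        assert np.all(cc.hi[0] - cc.lo[0] < 1e-9)

    def test_cohort_plateau_ordering(self):
        rng = np.random.default_rng(6)
        trs = []
        for level, n_frames in ((20.0, 4), (40.0, 9), (60.0, 20)):
            for _ in range(15):
                trs.append(make_trace(
                    np.full(n_frames, level) + rng.normal(0, 1, n_frames)))
        cc = cohort_curves(trs, bin_edges=(3.0, 5.0, 10.0, 51.0),
                           min_count=10, n_boot=100)
        plateaus = [m[:3].mean() for m in cc.means]
        assert plateaus[0] < plateaus[1] < plateaus[2]

    def test_small_cohort_dropped(self):
        trs = [make_trace(np.full(5, 20.0))] * 2
        cc = cohort_curves(trs, bin_edges=(3.0, 5.0), min_count=10)
        assert cc.counts == []
        assert cc.dropped == [(3.0, 5.0, 2)]


class TestCrossCorrelation:
    def test_self_pair_unit_peak_at_zero(self):
        rng = np.random.default_rng(7)
        mt = make_trace(60 + np.cumsum(rng.normal(0, 4, 30)))
        cc = cross_correlate([mt], [mt], max_lag=5, min_lifetime=11.0)
        mid = len(cc.lags) // 2
        assert cc.cc_intensity[mid] == pytest.approx(1.0)
        assert np.argmax(cc.cc_intensity) == mid
        assert np.argmax(cc.cc_derivative) == mid

    def test_shifted_pair_peaks_at_lag(self):
        rng = np.random.default_rng(8)
        base = 60 + np.cumsum(rng.normal(0, 5, 60))
        a = make_trace(base[:-3])
        b = make_trace(base[3:] * 0 + np.roll(base, 3)[3:])  # b[t] = a[t-3]
        b = make_trace(np.concatenate([base[:3], base[:-3]]))
        cc = cross_correlate([a], [b], max_lag=6, min_lifetime=11.0)
        assert cc.lags[np.argmax(cc.cc_derivative)] == 3

    def test_independent_noise_stays_small(self):
        rng = np.random.default_rng(9)
        n_pairs, n_frames = 40, 40
        ccs = []
        for _ in range(n_pairs):
            a = make_trace(rng.normal(0, 1, n_frames))
            b = make_trace(rng.normal(0, 1, n_frames))
            ccs.append(cross_correlate([a], [b], max_lag=4,
                                       min_lifetime=11.0).cc_intensity)
        mean_cc = np.abs(np.mean(ccs, axis=0))
        assert np.all(mean_cc <= 2.0 / np.sqrt(n_frames) + 3 / np.sqrt(
            n_pairs * n_frames))

    def test_short_pairs_excluded(self):
        mt = make_trace(np.ones(5))
        with pytest.raises(ValueError):
            cross_correlate([mt], [mt], min_lifetime=11.0)


class TestFluctuationPeaks:
    def test_single_bump(self):
        mt = make_trace([10, 10, 10, 25, 10, 10, 10])
        t, h, prom = fluctuation_peaks(mt, min_prominence=6.0)
        assert len(t) == 1
        assert prom[0] == pytest.approx(15.0)

    def test_subthreshold_bump_ignored(self):
        mt = make_trace([10, 10, 25, 10, 13, 10, 10])
        t, h, prom = fluctuation_peaks(mt, min_prominence=6.0)
        assert len(t) == 1

    def test_class_ii_peak_heights_match_single_events(self):
        # summed asynchronous events fluctuate by single-event magnitudes
        rng = np.random.default_rng(10)
        p = vps4_params()
        series = np.zeros(300)
        cursor = 0
        while cursor < 300:
            for _ in range(4):
                c, _ = simulate_trace(p, 850.0, rng)
                s = int(rng.integers(max(0, cursor - 5), cursor + 5))
                e = min(300, s + len(c))
                series[s:e] += c[:e - s]
            cursor += 10
        mt = make_trace(series)
        _, _, prom = fluctuation_peaks(mt, min_prominence=6.0)
        assert len(prom) > 3
        assert np.median(prom) < 3 * p.burst_mean


class TestProductive:
    @pytest.mark.parametrize("maxn,expected", [(24.0, True), (18.0, False),
                                               (0.0, False)])
    def test_hexamer_threshold(self, maxn, expected):
        mt = make_trace(np.array([0.0, maxn / 2, maxn, maxn / 2, 0.0]))
        assert classify_productive(mt) is expected

    def test_agrees_with_direct_ground_truth_threshold(self):
        rng = np.random.default_rng(11)
        p = vps4_params()
        agree = 0
        for _ in range(200):
            counts, _ = simulate_trace(p, 850.0, rng)
            mt = make_trace(counts)
            # direct rule: >= 4 hexamers <=> max count >= 21 molecules
            agree += classify_productive(mt) == (counts.max() >= 21)
        assert agree == 200


class TestFrapFit:
    def test_noiseless_rate_recovery(self):
        rng = np.random.default_rng(12)
        t, y = generate_frap_trace(0.5, 0.8, 0.9, 0.0, 120, rng,
                                   frame_interval=0.1)
        fit = fit_frap(t, y)
        assert not fit.no_recovery
        assert fit.rate == pytest.approx(0.5, rel=0.01)
        assert fit.mobile_fraction == pytest.approx(0.9, abs=0.02)

    def test_immobile_flagged_no_recovery(self):
        rng = np.random.default_rng(13)
        t, y = generate_frap_trace(0.5, 0.8, 0.0, 0.002, 80, rng)
        fit = fit_frap(t, y)
        assert fit.no_recovery

    def test_noisy_rate_within_fifteen_percent(self):
        rng = np.random.default_rng(14)
        rates = []
        for _ in range(100):
            t, y = generate_frap_trace(0.5, 0.8, 0.9, 0.01, 120, rng,
                                       frame_interval=0.1)
            rates.append(fit_frap(t, y).rate)
        assert np.mean(rates) == pytest.approx(0.5, rel=0.15)
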