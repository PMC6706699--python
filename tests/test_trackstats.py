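"""Tracking, classification, lifetimes, cohorts, recruitment timing."""

import numpy as np
import pandas as pd
import pytest

from ccpquant import synthgen
from ccpquant.trackstats import (Track, classify, cohort_traces, link,
                                 lifetime_stats, max_intensity_time,
                                 max_rate_time, persistent_density,
                                 slave_positivity,
                                 slave_significance_from_traces)


def _det_table(rows):
    return pd.DataFrame(rows, columns=["frame", "x", "y", "amplitude"])


def _track(frames, amp, frame_interval=2.0, slave_sig=None, category=None):
    frames = np.asarray(frames)
    t = Track(0, frames, np.zeros(len(frames)), np.zeros(len(frames)),
              {"master": np.asarray(amp, float)}, {},
              frame_interval, category=category)
    if slave_sig is not None:
        t.significant["slave"] = np.asarray(slave_sig, bool)
        t.amplitude["slave"] = np.zeros(len(frames))
    return t


class TestLink:
    def test_single_stationary_spot_one_track(self):
        det = _det_table([(f, 10.0, 12.0, 50.0) for f in range(50)])
        tracks = link(det)
        assert len(tracks) == 1 and len(tracks[0]) == 50

    def test_two_distant_spots_no_switches(self):
        rows = [(f, 5.0, 5.0, 50.0) for f in range(30)]
        rows += [(f, 25.0, 5.0, 80.0) for f in range(30)]
        tracks = link(_det_table(rows))
        assert len(tracks) == 2
        for t in tracks:
            assert np.ptp(t.x) == 0 and np.ptp(t.y) == 0  # no identity switch

    def test_gap_closing_bridges_dropout(self):
        frames = [f for f in range(20) if f != 9]  # one-frame dropout
        det = _det_table([(f, 10.0, 10.0, 50.0) for f in frames])
        tracks = link(det, max_gap=2)
        assert len(tracks) == 1
        assert tracks[0].first == 0 and tracks[0].last == 19

    def test_gap_beyond_limit_splits(self):
        frames = [f for f in range(20) if f not in (8, 9, 10)]
        tracks = link(_det_table([(f, 10.0, 10.0, 50.0) for f in frames]),
                      max_gap=2)
        assert len(tracks) == 2

    def test_each_detection_used_once(self):
        det = _det_table([(f, x, 10.0, 50.0) for f in range(10)
                          for x in (5.0, 9.0)])
        tracks = link(det, max_displacement=3.0)
        assert sum(len(t) for t in tracks) == len(det)

    def test_empty_input(self):
        assert link(_det_table([])) == []


class TestClassify:
    def test_full_span_is_persistent_regardless_of_amplitude(self):
        t = _track(range(30), np.full(30, 0.1))
        classify([t], n_frames=30, intensity_threshold=100.0)
        assert t.category == "persistent"

    def test_low_amplitude_short_track_transient(self):
        t = _track(range(4), np.full(4, 1.0))
        classify([t], n_frames=100, intensity_threshold=10.0)
        assert t.category == "transient"

    def test_partition_is_total(self):
        tracks = [_track(range(a, b), np.full(b - a, amp))
                  for a, b, amp in [(0, 50, 5), (3, 9, 50), (10, 13, 1),
                                    (0, 20, 80), (25, 45, 60)]]
        classify(tracks, n_frames=50, intensity_threshold=20.0)
        cats = [t.category for t in tracks]
        assert all(c in {"transient", "bona_fide", "persistent"} for c in cats)
        assert len(cats) == len(tracks)  # every track labelled exactly once

    def test_planted_population_categorized(self):
        """>=95% category recovery at the generator's amplitude separation."""
        table, gt = synthgen.generate_track_table(
            400, noise_sd=1.0, peak_amplitude=10.0, seed=8)
        correct = 0
        for tid, grp in table.groupby("track_id"):
            m = grp[grp.channel == "master"].sort_values("frame")
            t = _track(m["frame"].to_numpy(), m["amplitude"].to_numpy())
            # threshold between transient plateau (5) and bona fide peak (10)
            classify([t], n_frames=10**9, intensity_threshold=7.5,
                     min_frames=2)
            correct += t.category == gt.loc[gt.track_id == tid,
                                            "category"].iloc[0]
        assert correct / 400 >= 0.95


class TestSlavePositivity:
    def test_all_significant_positive(self):
        t = _track(range(10), np.ones(10), slave_sig=np.ones(10, bool))
        assert slave_positivity(t) is True

    def test_none_significant_negative(self):
        t = _track(range(10), np.ones(10), slave_sig=np.zeros(10, bool))
        assert slave_positivity(t) is False

    def test_planted_fraction_recovered_within_ci(self):
        table, gt = synthgen.generate_track_table(
            1000, slave_positive_fraction=0.65, noise_sd=1.0, seed=21)
        pos = []
        for _, grp in table.groupby("track_id"):
            sl = grp[grp.channel == "slave"].sort_values("frame")
            sig = slave_significance_from_traces(sl["amplitude"], 1.0)
            pos.append(sig.mean() >= 0.3)
        measured = np.mean(pos)
        assert abs(measured - 0.65) < 4 * np.sqrt(0.65 * 0.35 / 1000)

    def test_missing_slave_channel_rejected(self):
        with pytest.raises(ValueError):
            slave_positivity(_track(range(5), np.ones(5)))


class TestLifetimeStats:
    def test_uniform_1_to_100(self):
        """Lifetimes 1..100 s: 95th percentile 95.05, top-5% mean = 98."""
        tracks = [_track(range(1), [50.0], frame_interval=float(s),
                         category="bona_fide") for s in range(1, 101)]
        ls = lifetime_stats(tracks)
        assert ls.p95_value_s == pytest.approx(95.05)
        assert ls.p95_mean_s == pytest.approx(98.0)  # mean of {96..100}
        assert ls.mean_s == pytest.approx(50.5)

    def test_all_equal_lifetimes(self):
        tracks = [_track(range(5), np.ones(5), category="bona_fide")
                  for _ in range(25)]
        assert lifetime_stats(tracks).p95_mean_s == pytest.approx(10.0)

    def test_mixture_is_bimodal(self):
        """Two planted lifetime populations separate under a 2-vs-1
        Gaussian-mixture comparison (BIC)."""
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(3)
        life = np.concatenate([rng.normal(8, 1.5, 300),
                               rng.normal(60, 8, 300)])
        X = life.reshape(-1, 1)
        bic1 = GaussianMixture(1, random_state=0).fit(X).bic(X)
        bic2 = GaussianMixture(2, random_state=0).fit(X).bic(X)
        assert bic2 < bic1

    def test_insufficient_tracks(self):
        tracks = [_track(range(3), np.ones(3), category="bona_fide")] * 5
        with pytest.raises(ValueError):
            lifetime_stats(tracks)


class TestPersistentDensity:
    def test_zero_and_simple_counts(self):
        t1 = _track(range(10), np.ones(10), category="transient")
        assert persistent_density([t1], 100.0) == 0.0
        t2 = _track(range(10), np.ones(10), category="persistent")
        assert persistent_density([t2] * 10 + [t1], 100.0) == pytest.approx(0.1)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            persistent_density([], 0.0)


class TestCohortTraces:
    def test_identical_tracks_zero_se(self):
        tracks = [_track(range(10), np.linspace(0, 9, 10),
                         category="bona_fide") for _ in range(5)]
        (cs,) = cohort_traces(tracks, [(10.0, 30.0)])
        assert cs.n_tracks == 5
        assert np.allclose(cs.se["master"], 0.0)

    def test_single_track_cohort_se_zero_by_convention(self):
        t = _track(range(10), np.arange(10.0), category="bona_fide")
        (cs,) = cohort_traces([t], [(10.0, 30.0)])
        assert cs.n_tracks == 1
        assert np.all(cs.se["master"] == 0.0)
        assert np.allclose(cs.mean["master"],
                           np.interp(np.linspace(0, 1, 50),
                                     np.linspace(0, 1, 10), np.arange(10.0)))

    def test_planted_profile_recovered(self, rng):
        truth = synthgen.amplitude_profile("bona_fide", 100.0, 50)
        tracks = []
        for i in range(200):
            noisy = truth + rng.normal(0, 10.0, 50)
            tracks.append(_track(range(50), noisy, category="bona_fide"))
        (cs,) = cohort_traces(tracks, [(50.0, 150.0)])
        assert np.max(np.abs(cs.mean["master"] - truth)) < 5 * 10.0 / np.sqrt(200)

    def test_empty_cohort_empty_summary(self):
        (cs,) = cohort_traces([], [(10.0, 20.0)])
        assert cs.n_tracks == 0 and cs.mean == {}

    def test_overlapping_bounds_rejected(self):
        with pytest.raises(ValueError):
            cohort_traces([], [(10.0, 30.0), (20.0, 40.0)])

    def test_lifetime_conservation_across_cohorts(self):
        rng = np.random.default_rng(6)
        tracks = []
        for i in range(100):
            n = int(rng.integers(5, 60))
            tracks.append(_track(range(n), np.ones(n), category="bona_fide"))
        bounds = [(0.0, 40.0), (40.0, 80.0), (80.0, 200.0)]
        summaries = cohort_traces(tracks, bounds)
        assert sum(cs.n_tracks for cs in summaries) == len(tracks)


class TestRecruitmentTiming:
    def test_single_sample_peak(self):
        trace = np.zeros(21)
        trace[10] = 5.0
        est = max_intensity_time(trace, frame_interval=2.0)
        assert est.time_s == pytest.approx(20.0, abs=0.5)

    def test_parabola_subsample_precision(self):
        """Noiseless sampled parabola: recovered within 0.1 sample."""
        t = np.arange(30, dtype=float)
        for peak in (14.37, 9.5, 20.81):
            trace = 100.0 - 0.5 * (t - peak) ** 2
            est = max_intensity_time(trace, frame_interval=1.0)
            assert abs(est.time_s - peak) < 0.1
            assert est.reliable

    def test_flat_trace_degenerate(self):
        est = max_intensity_time(np.full(10, 3.0), 2.0)
        assert est.degenerate and est.time_s == 0.0

    def test_white_noise_flagged_unreliable(self, rng):
        flagged = sum(
            not max_intensity_time(rng.normal(0, 1, 40), 2.0).reliable
            for _ in range(50))
        assert flagged >= 45

    def test_ramp_rate_peak_precedes_intensity_peak(self):
        trace = np.concatenate([np.linspace(0, 100, 20), np.full(20, 100.0)])
        rate = max_rate_time(trace, frame_interval=1.0)
        intensity = max_intensity_time(trace, frame_interval=1.0)
        assert rate.time_s < 20.0          # within the ramp
        assert rate.time_s < intensity.time_s

    def test_triangle_rate_extremes(self):
        tri = np.concatenate([np.linspace(0, 100, 21),
                              np.linspace(100, 0, 21)[1:]])
        sm_rate_time = max_rate_time(tri, frame_interval=1.0)
        assert sm_rate_time.time_s < 20.0  # maximum slope on the rising flank

    def test_late_slave_ordering(self):
        """A slave rising late relative to the master reproduces the ordering:
        slave max-rate time >= master max-intensity time."""
        n = 60
        t = np.arange(n, dtype=float)
        master = synthgen.amplitude_profile("bona_fide", 100.0, n)
        slave = 100.0 / (1.0 + np.exp(-(t - 45.0) / 3.0))  # late sigmoid
        m_peak = max_intensity_time(master, frame_interval=2.0)
        s_rate = max_rate_time(slave, frame_interval=2.0)
        assert s_rate.time_s >= m_peak.time_s

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            max_intensity_time(np.ones(4), 2.0)
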