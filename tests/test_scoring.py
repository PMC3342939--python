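"""Bout classification, architecture metrics, profiles and death calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flysleep import scoring
from flysleep.scoring import Bout, bout_length_distribution, call_death, find_runs, score_sleep

import oracles
from conftest import make_series


def _kinds(bouts, kind):
    return [b for b in bouts if b.kind == kind]


class TestFindRuns:
    def test_five_minute_zero_run_is_sleep(self):
        counts = [1] * 10 + [0] * 5 + [1] * 10
        bouts = find_runs(make_series(counts))
        sleeps = _kinds(bouts, "sleep")
        assert len(sleeps) == 1
        assert (sleeps[0].start, sleeps[0].end) == (10, 15)
        assert not sleeps[0].censored

    def test_four_minute_zero_run_is_rest_not_sleep(self):
        counts = [1] * 10 + [0] * 4 + [1] * 10
        bouts = find_runs(make_series(counts))
        assert len(_kinds(bouts, "sleep")) == 0
        rests = _kinds(bouts, "rest")
        assert len(rests) == 1 and rests[0].length == 4

    def test_all_inactive_day_is_one_censored_bout(self):
        bouts = find_runs(make_series([0] * 1440))
        assert len(bouts) == 1
        b = bouts[0]
        assert (b.start, b.end, b.kind, b.censored) == (0, 1440, "sleep", True)

    def test_bouts_tile_series(self, rng):
        counts = rng.integers(0, 2, 500)
        bouts = find_runs(make_series(counts))
        assert sum(b.length for b in bouts) == 500
        assert bouts[0].start == 0 and bouts[-1].end == 500
        for a, b in zip(bouts, bouts[1:]):
            assert a.end == b.start

    def test_missing_minutes_censor_neighbours(self):
        counts = [1] * 10 + [float("nan")] * 3 + [0] * 7 + [1] * 10
        bouts = find_runs(make_series(counts))
        sleeps = _kinds(bouts, "sleep")
        assert len(sleeps) == 1 and sleeps[0].censored
        assert sum(b.length for b in bouts) == 27  # gap is not a bout

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=200))
    def test_matches_brute_force_scanner(self, counts):
        bouts = find_runs(make_series(counts))
        expected = oracles.brute_runs(counts)
        got = [(b.start, b.end, b.kind, b.censored) for b in bouts]
        assert got == expected


class TestScoreSleep:
    def test_alternating_counts_give_no_sleep(self):
        counts = [1, 0] * 360
        rec = score_sleep(make_series(counts), latencies=False)
        assert rec.whole.total_sleep_min == 0
        assert rec.whole.sleep_bout_count == 0
        assert rec.whole.rest_count == 360

    def test_forced_arithmetic_half_active_half_asleep(self):
        counts = [2] * 720 + [0] * 720
        rec = score_sleep(make_series(counts), latencies=False)
        assert rec.whole.total_sleep_min == 720
        assert rec.whole.sleep_bout_count == 1
        assert rec.whole.waking_activity == pytest.approx(2.0)

    def test_day_night_totals_are_additive(self, rng):
        counts = rng.integers(0, 2, 2 * 1440)
        rec = score_sleep(make_series(counts), latencies=False)
        assert rec.whole.total_sleep_min == (
            rec.day.total_sleep_min + rec.night.total_sleep_min
        )
        assert rec.whole.minutes == rec.day.minutes + rec.night.minutes

    def test_brief_awakenings_are_interior_one_minute_wake_runs(self):
        counts = [0] * 10 + [3] + [0] * 10 + [1, 1] + [0] * 10
        rec = score_sleep(make_series(counts), latencies=False)
        assert rec.whole.brief_awakening_count == 1

    def test_scored_totals_match_simulator_truth(self):
        from flysleep.simulate import SimParams, simulate_activity

        res = simulate_activity(SimParams(n_flies=4, days=2, seed=7))
        for i, s in enumerate(res.series):
            rec = score_sleep(s, latencies=False)
            truth_ge5 = sum(
                e - b >= 5 for b, e in res.true_bouts(i)
            )
            truth_min_ge5 = sum(
                e - b for b, e in res.true_bouts(i) if e - b >= 5
            )
            assert rec.whole.sleep_bout_count == truth_ge5
            assert rec.whole.total_sleep_min == truth_min_ge5

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            score_sleep(make_series([float("nan")] * 10))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_whole_metrics_match_oracle_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 3, rng.integers(50, 400)).tolist()
        rec = score_sleep(make_series(counts), latencies=False)
        assert rec.whole.total_sleep_min == oracles.brute_total_sleep(counts)
        assert rec.whole.sleep_bout_count == oracles.brute_sleep_bout_count(counts)
        assert rec.whole.waking_activity == pytest.approx(
            oracles.brute_waking_activity(counts), nan_ok=True
        )


class TestSleepLatency:
    def test_sleep_starting_at_lights_off_gives_zero(self):
        counts = [1] * 720 + [0] * 720
        assert scoring.sleep_latency(make_series(counts), "lights_off", 0) == 0

    def test_constructed_37_minute_latency(self):
        counts = [1] * 720 + [1] * 37 + [0] * 10 + [1] * (720 - 47)
        assert scoring.sleep_latency(make_series(counts), "lights_off", 0) == 37

    def test_fully_active_night_gives_missing(self):
        counts = [1] * 1440
        assert scoring.sleep_latency(make_series(counts), "lights_off", 0) is None

    def test_constant_regimes_have_no_transitions(self):
        with pytest.raises(ValueError):
            scoring.sleep_latency(make_series([0] * 1440, regime="DD"), "lights_on", 0)


class TestSleepProfile:
    def test_always_asleep_gives_ones(self):
        prof = scoring.sleep_profile(make_series([0] * 2880))
        np.testing.assert_allclose(prof, 1.0)

    def test_always_awake_gives_zeros(self):
        prof = scoring.sleep_profile(make_series([1] * 2880))
        np.testing.assert_allclose(prof, 0.0)

    def test_square_wave_crosses_half_at_boundaries(self):
        # asleep all night, awake all day for 4 days; profile is indexed by
        # clock minute-of-day and the series starts at lights-on (08:00)
        counts = ([1] * 720 + [0] * 720) * 4
        series = make_series(counts)
        prof = scoring.sleep_profile(series, window_min=30)
        indicator = np.zeros(1440)
        start = 8 * 60
        for i in range(1440):
            indicator[(start + i) % 1440] = 0.0 if i < 720 else 1.0
        kernel_idx = np.arange(-15, 15)
        expected = np.array(
            [indicator[(i + kernel_idx) % 1440].mean() for i in range(1440)]
        )
        np.testing.assert_allclose(prof, expected)
        # the smoothed profile crosses 0.5 within +/-15 min of lights-off (20:00)
        off = 20 * 60
        assert prof[off - 15: off + 15].min() < 0.5 < prof[off - 15: off + 15].max()

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            scoring.sleep_profile(make_series([0] * 1440), window_min=2000)


class TestBoutLengthDistribution:
    def test_masses_from_known_lengths(self):
        bouts = [
            Bout(0, 5, "sleep", "day"),
            Bout(10, 15, "sleep", "day"),
            Bout(20, 30, "sleep", "day"),
        ]
        dist = bout_length_distribution(bouts)
        assert dist[5] == pytest.approx(2 / 3)
        assert dist[10] == pytest.approx(1 / 3)

    def test_censored_bouts_excluded(self):
        bouts = [Bout(0, 5, "sleep", "day", censored=True), Bout(10, 17, "sleep", "day")]
        dist = bout_length_distribution(bouts)
        assert list(dist.index) == [7]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            bout_length_distribution([])

    def test_truncated_geometric_mean_matches_analytic(self, rng):
        # run lengths geometric(p) conditioned on >= 5 have mean 4 + 1/p
        p = 0.1
        lengths = rng.geometric(p, size=4000)
        kept = lengths[lengths >= 5][:500]
        bouts = [Bout(0, int(l), "sleep", "day") for l in kept]
        dist = bout_length_distribution(bouts)
        mean = float((dist.index.to_numpy() * dist.to_numpy()).sum())
        analytic = 4 + 1 / p
        se = kept.std(ddof=1) / np.sqrt(kept.size)
        assert abs(mean - analytic) < 3 * se


class TestCallDeath:
    def test_terminal_quiescence_yields_death_call(self):
        counts = [1] * 5001 + [0] * 800
        assert call_death(make_series(counts)) == 5001

    def test_active_final_hour_gives_none(self):
        counts = [0] * 2000 + [1] * 60
        assert call_death(make_series(counts)) is None

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 2, 1500).tolist()
        if rng.random() < 0.5:
            cut = int(rng.integers(0, 1500))
            counts[cut:] = [0] * (1500 - cut)
        assert call_death(make_series(counts)) == oracles.brute_death(counts)


class TestPhenotypeRecovery:
    def test_fragmentation_raises_bout_count_not_total_sleep(self):
        """Joint hazard scaling fragments sleep while conserving its total."""
        from flysleep import dam
        from flysleep.simulate import SimParams, simulate_activity

        means = {}
        totals = {}
        latent = {}
        for k in (1.0, 2.0, 4.0):
            res = simulate_activity(SimParams(n_flies=32, days=6, seed=5, fragmentation_k=k))
            recs = [
                score_sleep(dam.trim_acclimation(s, 1), latencies=False)
                for s in res.series
            ]
            means[k] = np.mean([r.whole.sleep_bout_count for r in recs])
            totals[k] = np.mean([r.whole.total_sleep_min for r in recs])
            latent[k] = np.mean(
                [(res.states[i, 1440:] == 1).sum() for i in range(len(res.series))]
            )
        assert means[1.0] < means[2.0] < means[4.0]
        # latent sleep is exactly k-invariant in expectation
        for k in (2.0, 4.0):
            assert abs(latent[k] - latent[1.0]) / latent[1.0] < 0.02
        # scored sleep additionally drops runs shorter than 5 min, so it is
        # conserved to <2% only at moderate fragmentation
        assert abs(totals[2.0] - totals[1.0]) / totals[1.0] < 0.02
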