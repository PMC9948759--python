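"""Event classification, transition frequencies, and dynamics summaries."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtlk.dynamics import (
    SurvivalResult,
    Thresholds,
    analyze_trajectory,
    classify_and_filter,
    merge_excluded,
    seed_survival,
    summarize_dynamics,
    transition_frequencies,
)
from mtlk.simulate import DynamicsConfig, simulate_dynamics, simulate_many

from conftest import make_trace


class TestClassification:
    def test_velocity_cutoff_classes(self):
        # +0.50 growth, -0.50 shrinkage, +0.10 pause (cutoff 0.24 µm/min)
        t, x = make_trace([(0.50, 60), (-0.50, 30), (0.10, 60)])
        ev = classify_and_filter(t, x)
        assert ev.state.tolist() == ["growth", "shrinkage", "pause"]

    def test_exact_cutoff_velocity_is_pause(self):
        t, x = make_trace([(0.24, 100)])
        ev = classify_and_filter(t, x)
        assert ev.state.tolist() == ["pause"]

    def test_short_pause_absorbed_into_single_growth_event(self):
        # 15 s pause flanked by growth: below the 20 s cutoff, so the merged
        # timeline is one growth event spanning the whole interval
        t, x = make_trace([(1.0, 60), (0.0, 15), (1.0, 60)])
        ev = classify_and_filter(t, x)
        assert not ev.loc[ev.state == "pause", "included"].any()
        merged = merge_excluded(ev)
        assert len(merged) == 1
        assert merged.state.iloc[0] == "growth"
        assert merged.t_start.iloc[0] == 0.0 and merged.t_end.iloc[0] == 135.0

    def test_pause_longer_than_cutoff_is_kept(self):
        t, x = make_trace([(1.0, 60), (0.0, 25), (1.0, 60)])
        ev = classify_and_filter(t, x)
        assert ev.loc[ev.state == "pause", "included"].all()
        assert len(merge_excluded(ev)) == 3

    def test_short_growth_excursion_excluded(self):
        # 0.30 µm growth excursion: below the 0.40 µm inclusion length
        t, x = make_trace([(0.0, 30), (0.9, 20), (0.0, 30)])
        ev = classify_and_filter(t, x)
        g = ev[ev.state == "growth"]
        assert len(g) == 1
        assert g.length_um.iloc[0] == pytest.approx(0.30)
        assert not g.included.iloc[0]

    def test_single_zero_velocity_segment_is_one_pause(self):
        ev = classify_and_filter([0.0, 10.0], [1.0, 1.0])
        assert len(ev) == 1
        assert ev.state.iloc[0] == "pause"

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError):
            classify_and_filter([0.0, 1.0, 1.0], [0.0, 0.1, 0.2])
        with pytest.raises(ValueError):
            classify_and_filter([0.0], [0.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_collinear_refinement_does_not_change_events(self, seed):
        rng = np.random.default_rng(seed)
        t, x = make_trace([(1.0, 60), (-2.0, 12), (0.0, 30), (2.0, 45)])
        # insert a collinear vertex inside a random segment
        i = int(rng.integers(0, len(t) - 1))
        frac = rng.uniform(0.2, 0.8)
        tm = t[i] + frac * (t[i + 1] - t[i])
        xm = np.interp(tm, t, x)
        t2, x2 = np.insert(t, i + 1, tm), np.insert(x, i + 1, xm)
        a, b = classify_and_filter(t, x), classify_and_filter(t2, x2)
        pd.testing.assert_frame_equal(a, b, check_exact=False, atol=1e-9)


class TestTransitions:
    def test_catastrophe_frequency_arithmetic(self):
        # 2 growth->shrinkage transitions over 400 s total growth time
        t, x = make_trace([
            (1.5, 200), (-15.0, 10), (1.5, 200), (-15.0, 10), (0.0, 30),
        ])
        thr = Thresholds(min_pause_duration=20.0)
        tf = transition_frequencies(classify_and_filter(t, x, thr),
                                    boundary_position=None)
        row = tf[(tf["from"] == "growth") & (tf["to"] == "shrinkage")].iloc[0]
        assert row["count"] == 2
        assert row.frequency_per_s == pytest.approx(2 / 400)

    def test_states_without_time_flagged_undefined(self):
        t, x = make_trace([(1.0, 100), (0.0, 50)])
        tf = transition_frequencies(classify_and_filter(t, x))
        shrink_rows = tf[tf["from"] == "shrinkage"]
        assert not shrink_rows.defined.any()
        assert shrink_rows.frequency_per_s.isna().all()

    def test_simulator_round_trip_recovers_rates(self):
        cfg = DynamicsConfig(v_growth=2.0, v_shrink=30.0,
                             growth_to_shrinkage=0.004, shrinkage_to_growth=0.02,
                             duration=1e5, dt=0.25, rng_seed=21)
        traj = simulate_dynamics(cfg)
        thr = Thresholds(min_growth_length=1e-6, min_pause_duration=1e-6)
        tf = transition_frequencies(analyze_trajectory(traj, thr))
        for src, dst, rate in [("growth", "shrinkage", 0.004),
                               ("shrinkage", "growth", 0.02)]:
            row = tf[(tf["from"] == src) & (tf["to"] == dst)].iloc[0]
            se = rate / np.sqrt(max(row["count"], 1))
            assert row.frequency_per_s == pytest.approx(rate, abs=3 * se)


class TestSummary:
    def test_single_growth_event_sem_undefined(self):
        t, x = make_trace([(1.2, 60)])
        s = summarize_dynamics([classify_and_filter(t, x)])
        assert s.growth_rate_mean == pytest.approx(1.2)
        assert np.isnan(s.growth_rate_sem)
        assert s.n_growth_events == 1

    def test_state_fractions_hand_computed_and_sum_to_one(self):
        t, x = make_trace([(1.5, 60), (0.0, 30), (-9.0, 10)])
        s = summarize_dynamics([classify_and_filter(t, x)],
                               boundary_position=None)
        assert s.state_fractions["growth"] == pytest.approx(0.6)
        assert s.state_fractions["pause"] == pytest.approx(0.3)
        assert s.state_fractions["shrinkage"] == pytest.approx(0.1)
        assert sum(s.state_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_growth_rate_recovery_within_5pct_on_simulated_mts(self):
        cfg = DynamicsConfig(v_growth=2.0, v_shrink=30.0,
                             growth_to_shrinkage=0.004, shrinkage_to_growth=0.02,
                             growth_to_pause=0.01, pause_to_growth=0.01,
                             duration=600.0, dt=0.25, rng_seed=22)
        tables = [analyze_trajectory(tr, Thresholds(min_growth_length=1e-6,
                                                    min_pause_duration=1e-6))
                  for tr in simulate_many(cfg, 60)]
        s = summarize_dynamics(tables)
        assert s.n_growth_events >= 100
        assert s.growth_rate_mean == pytest.approx(2.0, rel=0.05)

    def test_noiseless_segmentation_matches_simulator_states(self):
        cfg = DynamicsConfig(v_growth=2.0, v_shrink=30.0,
                             growth_to_pause=0.01, pause_to_growth=0.01,
                             growth_to_shrinkage=0.005, shrinkage_to_growth=0.05,
                             duration=2000.0, dt=0.25, rng_seed=23)
        traj = simulate_dynamics(cfg)
        ev = analyze_trajectory(traj, Thresholds(min_growth_length=1e-9,
                                                 min_pause_duration=1e-9))
        seg = traj.segments
        true_boundaries = seg.t1.to_numpy()[:-1]
        found_boundaries = ev.t_end.to_numpy()[:-1]
        # every true dwell boundary longer than one sample matched within dt
        for tb in true_boundaries:
            assert np.min(np.abs(found_boundaries - tb)) <= cfg.dt + 1e-9


class TestSeedSurvival:
    def _make(self, die_at, horizon_len=400.0):
        times = np.arange(0.0, horizon_len, 1.0)
        pos = np.ones_like(times)
        if die_at is not None:
            pos = np.where(times >= die_at, 0.0, 1.0)
        from mtlk.simulate import TipTrajectory
        return TipTrajectory(times=times, positions=pos)

    def test_all_die_is_zero_percent(self):
        res = seed_survival([self._make(50.0) for _ in range(5)])
        assert res.percent_surviving == 0.0

    def test_none_die_is_hundred_percent(self):
        res = seed_survival([self._make(None) for _ in range(5)])
        assert res.percent_surviving == 100.0

    def test_half_die_is_fifty_percent(self):
        trajs = [self._make(100.0)] * 5 + [self._make(None)] * 5
        assert seed_survival(trajs).percent_surviving == 50.0

    def test_short_record_flagged_partial(self):
        res = seed_survival([self._make(None, horizon_len=100.0)], horizon=300.0)
        assert res.partial
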