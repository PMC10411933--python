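"""Synthetic performer: minimum-jerk kernel, trial anatomy, and the
statistical structure of generated sessions."""

import numpy as np
import pytest

from aimkin.performer import (
    PerformerParams,
    learning_multipliers,
    min_jerk_profile,
    simulate_experiment1,
    simulate_experiment2,
    simulate_trial,
)
from conftest import make_spec


class TestMinJerkProfile:
    def test_displacement_reaches_target_at_end(self):
        t, s, v = min_jerk_profile(D=0.8, T_ms=400.0, dt_ms=1.0)
        assert s[-1] == pytest.approx(0.8, abs=1e-9)

    def test_starts_and_ends_at_rest(self):
        t, s, v = min_jerk_profile(D=1.0, T_ms=500.0, dt_ms=1.0)
        assert v[0] == 0.0
        assert v[-1] == pytest.approx(0.0, abs=1e-9)

    def test_peak_speed_is_1875_D_over_T(self):
        # numeric maximum of the quintic derivative vs the closed form
        D, T = 1.0, 400.0
        t, s, v = min_jerk_profile(D, T, dt_ms=0.01)
        assert v.max() == pytest.approx(1.875 * D / (T / 1000.0), rel=1e-6)
        assert t[np.argmax(v)] == pytest.approx(T / 2, abs=0.02)

    def test_rejects_nonpositive_arguments(self):
        with pytest.raises(ValueError):
            min_jerk_profile(0.0, 400.0, 1.0)


class TestSimulateTrial:
    def test_noiseless_generous_limit_single_submovement(self, rng):
        """Zero noise with aim at 0.95 D lands inside the 0.1-au target:
        success with exactly one submovement at the aimpoint."""
        params = PerformerParams().noiseless(undershoot_frac=0.95)
        rec = simulate_trial(params, make_spec(), 10_000.0, rng)
        assert rec.success
        assert rec.n_submovements == 1
        endpoint = np.array([rec.x[-1], rec.y[-1]])
        np.testing.assert_allclose(endpoint, (0.95, 0.0), atol=1e-9)

    def test_impossible_time_limit_fails(self, rng):
        params = PerformerParams().noiseless()
        rec = simulate_trial(params, make_spec(), 50.0, rng)
        assert not rec.success

    def test_trace_deltas_consistent_with_positions(self, rng, params):
        """Cumulative gain-scaled deltas reproduce the logged cursor path."""
        rec = simulate_trial(params, make_spec(distance=0.6, angle=135.0), None, rng)
        x = rec.x[0] + np.cumsum(rec.dx) - rec.dx[0]
        y = rec.y[0] + np.cumsum(rec.dy) - rec.dy[0]
        np.testing.assert_allclose(x, rec.x, atol=1e-9)
        np.testing.assert_allclose(y, rec.y, atol=1e-9)

    def test_events_are_time_sorted_and_click_matches_outcome(self, rng, params):
        rec = simulate_trial(params, make_spec(), None, rng)
        times = [t for t, _ in rec.events]
        assert times == sorted(times)
        names = [n for _, n in rec.events]
        assert names[0] == "target_shown"
        assert "click" in names
        assert ("success" in names) == rec.success

    def test_look_context_has_longer_reaction(self, params):
        """The Look penalty shifts reaction time by exactly its value under
        matched random draws."""
        rec_p = simulate_trial(params, make_spec(context="point"), None, np.random.default_rng(9))
        rec_l = simulate_trial(params, make_spec(context="look"), None, np.random.default_rng(9))
        on_p = rec_p.ground_truth.true_onset if rec_p.ground_truth else None
        on_l = rec_l.ground_truth.true_onset if rec_l.ground_truth else None
        if on_p is not None and on_l is not None:
            assert on_l - on_p == pytest.approx(params.look_rt_penalty, abs=1e-9)

    def test_correction_loop_bounded(self, rng):
        params = PerformerParams(corr_gain=0.05, max_submovements=4)
        rec = simulate_trial(params.noiseless(undershoot_frac=0.5), make_spec(), None, rng)
        assert rec.n_submovements <= 4
        assert not rec.success


class TestLearningMultipliers:
    def test_round_zero_is_unity(self, params):
        m = learning_multipliers(0, params)
        assert m["latency"] == pytest.approx(1.0)
        assert m["mt"] == pytest.approx(1.0)

    def test_monotone_decreasing(self, params):
        lat = [learning_multipliers(k, params)["latency"] for k in range(20)]
        assert np.all(np.diff(lat) < 0)

    def test_fast_then_slow_shape(self, params):
        lat = [learning_multipliers(k, params)["latency"] for k in range(20)]
        early = lat[0] - lat[4]
        late = lat[4] - lat[19]
        assert early > late  # most of the improvement in the first rounds


class TestExperiment1Session:
    def test_640_trials_with_staircase_bookkeeping(self, params):
        sess = simulate_experiment1(params, np.random.default_rng(2))
        assert len(sess) == 640
        assert sum(tr.context == "point" for tr in sess.trials) == 320
        for tr in sess.trials:
            assert tr.staircase_id in ("low", "high")
            assert tr.time_limit is not None

    def test_staircase_limits_walk_by_single_steps(self, params):
        sess = simulate_experiment1(params, np.random.default_rng(2))
        for context in ("point", "look"):
            for sid in ("low", "high"):
                limits = [
                    tr.time_limit
                    for tr in sess.by_context(context)
                    if tr.staircase_id == sid
                ]
                assert len(limits) == 160
                assert np.all(np.abs(np.diff(limits)) == 30.0)

    def test_look_asymptote_exceeds_point_in_expectation(self, params):
        """Positive Look penalties raise the Look-context skill limit."""
        from aimkin.task import asymptotic_time_limit

        diffs = []
        for s in range(6):
            sess = simulate_experiment1(params, np.random.default_rng(300 + s))
            asym = {}
            for context in ("point", "look"):
                trs = sess.by_context(context)
                asym[context] = asymptotic_time_limit(
                    [tr.time_limit for tr in trs], [tr.staircase_id for tr in trs]
                )
            diffs.append(asym["look"] - asym["point"])
        assert np.mean(diffs) > 0


class TestExperiment2Session:
    @pytest.fixture(scope="class")
    def session(self):
        return simulate_experiment2(PerformerParams(), np.random.default_rng(8))

    def test_960_movements_in_20_rounds(self, session):
        assert len(session) == 960
        assert {tr.round_index for tr in session.trials} == set(range(20))

    def test_movements_chain_between_targets(self, session):
        prev_target = None
        for tr in session.trials:
            if tr.trial_id % 48 == 0:
                assert tr.start_pos == (0.0, 0.0)
            else:
                assert tr.start_pos == prev_target
            prev_target = tr.target_pos

    def test_peak_speed_mean_and_sd_increase_with_distance(self, session):
        """Speed scaling and signal-dependent noise across 0.4/0.6/0.8 au
        (SDs pooled over extra sessions: the per-session SD estimate carries
        sampling error comparable to the between-distance gaps)."""
        from aimkin.kinematics import segment_trial
        from aimkin.metrics import trial_metrics

        by_dist = {d: [] for d in (0.4, 0.6, 0.8)}
        sessions = [session] + [
            simulate_experiment2(PerformerParams(), np.random.default_rng(80 + s), n_rounds=7)
            for s in range(3)
        ]
        for sess in sessions:
            for tr in sess.trials:
                m = trial_metrics(tr, segment_trial(tr))
                if np.isfinite(m.peak_speed):
                    by_dist[tr.target_distance].append(m.peak_speed)
        means = [np.mean(by_dist[d]) for d in (0.4, 0.6, 0.8)]
        sds = [np.std(by_dist[d]) for d in (0.4, 0.6, 0.8)]
        assert means[0] < means[1] < means[2]
        assert sds[0] < sds[1] < sds[2]

    def test_acquire_time_improves_with_practice(self):
        """Round-median acquire time decreases from early to late rounds
        in expectation over seeds."""
        from aimkin.metrics import round_summary, trials_table

        drops = []
        for s in range(5):
            sess = simulate_experiment2(
                PerformerParams(), np.random.default_rng(900 + s), n_rounds=10
            )
            rs = round_summary(trials_table(sess))
            drops.append(rs["median_acquire"].iloc[0] - rs["median_acquire"].iloc[-1])
        assert np.mean(drops) > 0
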