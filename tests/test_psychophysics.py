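"""Adaptive staircases, simulated observers, scoring and stability screening."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afgkit import psychophysics as psy


def run_scripted(cfg, responses):
    """Drive a track with a scripted correct/error sequence."""
    state = psy.StaircaseState.fresh(cfg)
    for r in responses:
        if state.finished:
            break
        psy.staircase_step(state, cfg, r)
    return state


def reference_staircase(cfg, responses):
    """Independent re-implementation of the transformed up-down rule used as
    an oracle for random response sequences (kept deliberately separate from
    the library's bookkeeping)."""
    snr, direction, streak = cfg.start_snr, 0, 0
    reversals = []
    for correct in responses:
        if len(reversals) >= cfg.stop_after:
            break
        if cfg.rule == "1up1down":
            move = -1 if correct else 1
        else:
            if correct:
                streak += 1
                move = -1 if streak == 2 else 0
                if move:
                    streak = 0
            else:
                streak = 0
                move = 1
        if move == 0:
            continue
        if direction and move != direction:
            reversals.append(snr)
            if len(reversals) >= cfg.stop_after:
                break
        step = cfg.step_final if len(reversals) >= cfg.step_change_after else cfg.step_initial
        snr = min(max(snr + move * step, cfg.snr_floor), cfg.snr_ceiling)
        direction = move
    return reversals


class TestObserver:
    def test_formula_on_grid(self):
        obs = psy.Observer(threshold_db=3.0, slope_db=1.5, guess=0.5, lapse=0.02)
        for snr in np.linspace(-20, 20, 41):
            expected = 0.5 + (1 - 0.5 - 0.02) / (1 + math.exp(-(snr - 3.0) / 1.5))
            assert psy.observer_p_correct(obs, snr) == pytest.approx(expected)

    def test_midpoint_is_three_quarters_for_2afc(self):
        obs = psy.Observer(threshold_db=-5.0, slope_db=2.0, guess=0.5, lapse=0.0)
        assert psy.observer_p_correct(obs, -5.0) == pytest.approx(0.75)

    def test_upper_asymptote(self):
        obs = psy.Observer(threshold_db=0.0, slope_db=2.0, guess=0.5, lapse=0.03)
        assert psy.observer_p_correct(obs, 1e6) == pytest.approx(0.97)

    def test_monotone_in_snr(self):
        obs = psy.Observer(threshold_db=0.0, slope_db=1.0)
        p = [psy.observer_p_correct(obs, s) for s in np.linspace(-30, 30, 201)]
        assert np.all(np.diff(p) >= 0)

    def test_snr_at_p_inverts(self):
        obs = psy.Observer(threshold_db=2.0, slope_db=3.0, guess=0.5, lapse=0.01)
        snr = obs.snr_at_p(1 / math.sqrt(2))
        assert psy.observer_p_correct(obs, snr) == pytest.approx(1 / math.sqrt(2))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            psy.Observer(threshold_db=0.0, slope_db=-1.0)
        with pytest.raises(ValueError):
            psy.Observer(threshold_db=0.0, slope_db=1.0, guess=0.99, lapse=0.05)


class TestStaircaseStep:
    def test_two_down_needs_two_corrects(self):
        cfg = psy.dynamic_pattern_staircase()
        state = run_scripted(cfg, [True])
        assert state.current_snr == 12.0  # one correct: no movement yet
        state = run_scripted(cfg, [True, True])
        assert state.current_snr == 10.0

    def test_one_up_one_down_moves_every_trial(self):
        cfg = psy.fixed_gap_staircase()
        assert run_scripted(cfg, [True]).current_snr == 4.0
        assert run_scripted(cfg, [False]).current_snr == 8.0

    def test_hand_traced_sequence(self):
        """18 scripted responses on the gap task's track, traced by hand."""
        cfg = psy.fixed_gap_staircase()
        responses = [True, True, True, False, False, True, False, True, True,
                     False, False, True, True, False, True, False, False, True]
        state = run_scripted(cfg, responses)
        assert state.finished
        assert state.reversal_snrs == [0.0, 4.0, 2.0, 2.5, 1.5, 2.5, 1.5, 2.0, 1.5, 2.5]
        assert psy.score_run(state.reversal_snrs) == pytest.approx(1.75)
        assert psy.stability_check(state.reversal_snrs)

    def test_alternating_responses_oscillate_one_step(self):
        cfg = psy.StaircaseConfig(rule="1up1down", start_snr=6.0, step_initial=2.0,
                                  step_final=2.0, step_change_after=3, stop_after=50)
        state = psy.StaircaseState.fresh(cfg)
        for i in range(60):
            if state.finished:
                break
            psy.staircase_step(state, cfg, i % 2 == 0)
        snrs = [t["snr"] for t in state.trial_log[2:]]
        assert max(snrs) - min(snrs) <= 2.0  # one-step band
        # every trial after the first movement flips direction
        assert len(state.reversal_snrs) == 50

    def test_stepping_finished_track_raises(self):
        cfg = psy.fixed_gap_staircase()
        state = psy.StaircaseState.fresh(cfg)
        state.finished = True
        with pytest.raises(RuntimeError):
            psy.staircase_step(state, cfg, True)

    def test_clamping_no_spurious_reversal(self):
        cfg = psy.StaircaseConfig(rule="1up1down", start_snr=-38.0, step_initial=2.0,
                                  step_final=0.5, step_change_after=3, stop_after=10,
                                  snr_floor=-40.0)
        state = run_scripted(cfg, [True] * 10)  # descend into the floor
        assert state.current_snr == -40.0
        assert state.reversal_snrs == []

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.booleans(), min_size=5, max_size=200),
           st.sampled_from(["1up1down", "2down1up"]))
    def test_matches_reference_implementation(self, responses, rule):
        cfg = psy.StaircaseConfig(rule=rule, start_snr=10.0, step_initial=2.0,
                                  step_final=0.5, step_change_after=3, stop_after=8)
        state = run_scripted(cfg, responses)
        assert state.reversal_snrs == reference_staircase(cfg, responses)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_reversals_alternate_direction(self, seed):
        rng = np.random.default_rng(seed)
        cfg = psy.dynamic_pattern_staircase()
        state = psy.StaircaseState.fresh(cfg)
        while not state.finished:
            psy.staircase_step(state, cfg, bool(rng.random() < 0.6))
        moves = np.sign(np.diff([t["snr"] for t in state.trial_log if True]))
        assert len(state.reversal_snrs) == cfg.stop_after


class TestScoring:
    def test_median_of_last_six(self):
        assert psy.score_run([9, 9, 9, 4, 3, 5, 3, 4, 3]) == pytest.approx(3.5)

    def test_constant_reversals(self):
        assert psy.score_run([2.0] * 8) == 2.0

    def test_combine_is_mean(self):
        assert psy.combine_runs([2.0, 4.0]) == 3.0

    def test_too_few_reversals_raise(self):
        with pytest.raises(ValueError):
            psy.score_run([1, 2, 3])
        with pytest.raises(ValueError):
            psy.stability_check([1, 2, 3])

    def test_score_ignores_early_history(self):
        early_a = [20.0, -20.0, 15.0]
        early_b = [0.0, 0.0, 0.0]
        last6 = [3.0, 3.5, 4.0, 3.0, 3.5, 4.0]
        assert psy.score_run(early_a + last6) == psy.score_run(early_b + last6)


class TestStability:
    def test_tight_run_is_stable(self):
        assert psy.stability_check([3, 3.5, 4, 3, 3.5, 4])

    def test_six_db_swing_unstable(self):
        assert not psy.stability_check([0, 6, 0, 6, 0, 6])

    def test_constant_is_stable(self):
        assert psy.stability_check([1.0] * 6)

    def test_boundary_band_is_exclusive(self):
        assert not psy.stability_check([0, 0, 0, 0, 0, 5.0])
        assert psy.stability_check([0, 0, 0, 0, 0, 4.999])


class TestRunTrack:
    def test_terminates_with_configured_reversals(self):
        obs = psy.Observer(threshold_db=10.0, slope_db=2.0, guess=0.5)
        res = psy.run_track(obs, psy.dynamic_pattern_staircase(),
                            rng=np.random.default_rng(0), task="pattern")
        assert len(res.reversal_snrs) == 22

    def test_perfect_observer_descends_to_floor(self):
        obs = psy.Observer(threshold_db=-100.0, slope_db=0.5, guess=0.0)
        cfg = psy.fixed_gap_staircase()
        state = psy.StaircaseState.fresh(cfg)
        for _ in range(40):
            if state.finished:
                break
            psy.staircase_step(state, cfg, True)
        snrs = [t["snr"] for t in state.trial_log]
        assert all(np.diff(snrs) < 0) or state.current_snr == cfg.snr_floor
        assert state.current_snr == cfg.snr_floor

    def test_two_down_one_up_converges_to_70_7_percent_point(self):
        obs = psy.Observer(threshold_db=8.0, slope_db=2.0, guess=0.5, lapse=0.0)
        target = obs.snr_at_p(1 / math.sqrt(2))  # = threshold - slope*ln2/2
        assert target == pytest.approx(8.0 - 2.0 * math.log(2) / 2)
        rng = np.random.default_rng(202)
        scores = [psy.run_track(obs, psy.dynamic_pattern_staircase(), rng=rng).score_db
                  for _ in range(200)]
        assert abs(np.mean(scores) - target) < 1.0

    def test_one_up_one_down_converges_to_50_percent_point(self):
        obs = psy.Observer(threshold_db=-12.0, slope_db=2.0, guess=0.0, lapse=0.0)
        rng = np.random.default_rng(203)
        scores = [psy.run_track(obs, psy.fixed_gap_staircase(), rng=rng).score_db
                  for _ in range(200)]
        assert abs(np.mean(scores) - (-12.0)) < 1.0

    def test_deterministic_under_seed(self):
        obs = psy.Observer(threshold_db=5.0, slope_db=2.0, guess=0.5)
        factory = psy.pattern_trial_factory("dynamic_low")
        a = psy.run_track(obs, psy.dynamic_pattern_staircase(), factory,
                          np.random.default_rng(77), task="pattern")
        b = psy.run_track(obs, psy.dynamic_pattern_staircase(), factory,
                          np.random.default_rng(77), task="pattern")
        assert a.reversal_snrs == b.reversal_snrs
        assert a.trial_log == b.trial_log

    def test_gap_factory_logs_interval_and_isi(self):
        obs = psy.Observer(threshold_db=0.0, slope_db=2.0, guess=0.0)
        res = psy.run_track(obs, psy.fixed_gap_staircase(), psy.gap_trial_factory(),
                            np.random.default_rng(5), task="gap")
        for entry in res.trial_log:
            assert entry["isi_ms"] == 400.0
            assert entry["gap_interval"] in (0, 1)
            assert entry["response_interval"] in (0, 1)
            hit = entry["response_interval"] == entry["gap_interval"]
            assert hit == entry["correct"]
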