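"""Adaptive staircase tasks with simulated observers.

The gap-discrimination task runs a 1-up 1-down track (start 6 dB SNR, 2 dB
steps falling to 0.5 dB after three reversals, stopping after 10); the
pattern-discrimination task runs a 2-down 1-up track (start 12 dB, step
2 -> 0.5 dB after seven reversals, stopping after 22).  A transformed
up-down track converges on the SNR where the response probability equals
0.5 (1-up 1-down) or sqrt(0.5) ~ 70.7% (2-down 1-up).  Scores are the
median of the last six reversal SNRs; runs whose last six reversals span
5 dB or more are flagged unstable and excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "Observer",
    "RunResult",
    "fixed_gap_staircase",
    "dynamic_pattern_staircase",
    "observer_p_correct",
    "staircase_step",
    "run_track",
    "score_run",
    "combine_runs",
    "stability_check",
    "gap_trial_factory",
    "pattern_trial_factory",
]

RULES = ("1up1down", "2down1up")


@dataclass(frozen=True)
class StaircaseConfig:
    rule: str
    start_snr: float
    step_initial: float = 2.0
    step_final: float = 0.5
    step_change_after: int = 3   # reversals before the step size shrinks
    stop_after: int = 10         # total reversals to terminate
    snr_ceiling: float = 20.0
    snr_floor: float = -40.0

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown staircase rule {self.rule!r}")
        if self.step_final > self.step_initial:
            raise ValueError("step_final must be <= step_initial")
        if self.stop_after <= self.step_change_after:
            raise ValueError("stop_after must exceed step_change_after")
        if self.snr_floor >= self.snr_ceiling:
            raise ValueError("snr_floor must be below snr_ceiling")


def fixed_gap_staircase() -> StaircaseConfig:
    """The gap task's 1-up 1-down track: 6 dB start, 10 reversals."""
    return StaircaseConfig(
        rule="1up1down", start_snr=6.0, step_initial=2.0, step_final=0.5,
        step_change_after=3, stop_after=10,
    )


def dynamic_pattern_staircase() -> StaircaseConfig:
    """The pattern task's 2-down 1-up track: 12 dB start, 22 reversals."""
    return StaircaseConfig(
        rule="2down1up", start_snr=12.0, step_initial=2.0, step_final=0.5,
        step_change_after=7, stop_after=22,
    )


@dataclass
class StaircaseState:
    current_snr: float
    direction: int = 0            # +1 rising, -1 falling, 0 before first move
    consecutive_correct: int = 0
    reversal_snrs: list[float] = field(default_factory=list)
    trial_log: list[dict] = field(default_factory=list)
    finished: bool = False

    @classmethod
    def fresh(cls, cfg: StaircaseConfig) -> "StaircaseState":
        return cls(current_snr=cfg.start_snr)


@dataclass(frozen=True)
class Observer:
    """Logistic psychometric observer.

    p(correct | snr) = guess + (1 - guess - lapse) * logistic((snr - threshold_db) / slope_db)

    ``threshold_db`` is the psychometric midpoint; for a 2-down 1-up track
    the converged SNR is ``threshold_db - slope_db * ln(2)/2`` (where
    p = sqrt(0.5)) when guess = 0.5 and lapse = 0.
    """

    threshold_db: float
    slope_db: float = 2.0
    guess: float = 0.5
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.guess < 1 - self.lapse <= 1):
            raise ValueError("require 0 <= guess < 1 - lapse <= 1")
        if self.slope_db <= 0:
            raise ValueError("slope_db must be positive")

    def snr_at_p(self, p: float) -> float:
        """SNR where the psychometric function reaches probability ``p``."""
        core = (p - self.guess) / (1 - self.guess - self.lapse)
        if not 0 < core < 1:
            raise ValueError("p outside the attainable range of this observer")
        return self.threshold_db + self.slope_db * math.log(core / (1 - core))


def observer_p_correct(obs: Observer, snr: float) -> float:
    """Probability of a correct response at the given SNR."""
    x = (snr - obs.threshold_db) / obs.slope_db
    return obs.guess + (1 - obs.guess - obs.lapse) / (1 + math.exp(-x))


def staircase_step(state: StaircaseState, cfg: StaircaseConfig, correct: bool) -> StaircaseState:
    """Advance the track by one response; mutates and returns ``state``.

    1-up 1-down moves down on every correct response and up on every error;
    2-down 1-up moves down only after two consecutive corrects (the counter
    resets on the move) and up on any error.  A reversal is logged at the
    SNR where the movement direction flips; the step size drops to
    ``step_final`` once ``step_change_after`` reversals have occurred, and
    the track finishes at ``stop_after`` reversals.  SNR is clamped to
    [floor, ceiling] without logging a spurious reversal.
    """
    if state.finished:
        raise RuntimeError("cannot step a finished track")

    state.trial_log.append({"snr": state.current_snr, "correct": bool(correct)})

    if cfg.rule == "1up1down":
        move = -1 if correct else +1
        state.consecutive_correct = state.consecutive_correct + 1 if correct else 0
    else:  # 2down1up
        if correct:
            state.consecutive_correct += 1
            if state.consecutive_correct >= 2:
                move = -1
                state.consecutive_correct = 0
            else:
                move = 0
        else:
            move = +1
            state.consecutive_correct = 0

    if move == 0:
        return state

    if state.direction != 0 and move != state.direction:
        state.reversal_snrs.append(state.current_snr)
        state.trial_log[-1]["reversal"] = True
        if len(state.reversal_snrs) >= cfg.stop_after:
            state.finished = True
            state.direction = move
            return state

    step = cfg.step_final if len(state.reversal_snrs) >= cfg.step_change_after else cfg.step_initial
    state.current_snr = float(np.clip(state.current_snr + move * step, cfg.snr_floor, cfg.snr_ceiling))
    state.direction = move
    return state


@dataclass(frozen=True)
class RunResult:
    score_db: float
    reversal_snrs: tuple[float, ...]
    stable: bool
    task: str
    n_trials: int
    trial_log: tuple[dict, ...] = ()


def score_run(reversal_snrs) -> float:
    """Median SNR of the last six reversals."""
    revs = list(reversal_snrs)
    if len(revs) < 6:
        raise ValueError("need at least 6 reversals to score a run")
    return float(np.median(revs[-6:]))


def combine_runs(scores) -> float:
    """Average of run scores (the two-run fixed-task outcome measure)."""
    scores = list(scores)
    if not scores:
        raise ValueError("no run scores to combine")
    return float(np.mean(scores))


def stability_check(reversal_snrs, band_db: float = 5.0) -> bool:
    """True iff the last six reversal SNRs span less than ``band_db``.

    Implements the +/-5 dB screening rule as a range criterion
    (max - min < 5 dB), the only symmetric reading using all six values.
    """
    revs = list(reversal_snrs)
    if len(revs) < 6:
        raise ValueError("need at least 6 reversals for the stability check")
    last6 = np.asarray(revs[-6:])
    return bool(last6.max() - last6.min() < band_db)


def run_track(
    obs: Observer,
    cfg: StaircaseConfig,
    trial_factory: Callable | None = None,
    rng: np.random.Generator | None = None,
    task: str = "gap",
    max_trials: int = 2000,
) -> RunResult:
    """Run one adaptive track to completion with a simulated observer.

    Per trial: (i) the optional ``trial_factory(snr_db, rng)`` constructs the
    stimulus pair (its metadata is logged); (ii) the observer's response is
    drawn Bernoulli(p_correct(snr)) and scored by the task rule (gap-interval
    choice or same/different judgment); (iii) the staircase advances.
    Deterministic for a fixed generator.
    """
    rng = rng or np.random.default_rng()
    state = StaircaseState.fresh(cfg)
    n_trials = 0
    while not state.finished:
        if n_trials >= max_trials:
            raise RuntimeError("staircase failed to terminate within max_trials")
        snr = state.current_snr
        trial_meta = trial_factory(snr, rng) if trial_factory is not None else None
        correct = bool(rng.random() < observer_p_correct(obs, snr))
        staircase_step(state, cfg, correct)
        if trial_meta is not None:
            state.trial_log[-1].update(trial_meta)
        _log_judgment(state.trial_log[-1], task, correct, rng)
        n_trials += 1
    return RunResult(
        score_db=score_run(state.reversal_snrs),
        reversal_snrs=tuple(state.reversal_snrs),
        stable=stability_check(state.reversal_snrs),
        task=task,
        n_trials=n_trials,
        trial_log=tuple(state.trial_log),
    )


def _log_judgment(entry: dict, task: str, correct: bool, rng: np.random.Generator) -> None:
    """Record the overt response implied by correctness and the task rule."""
    if task == "gap":
        target = entry.get("gap_interval", int(rng.integers(2)))
        entry.setdefault("gap_interval", target)
        entry["response_interval"] = target if correct else 1 - target
    else:
        same = entry.get("same_pattern", bool(rng.integers(2)))
        entry.setdefault("same_pattern", same)
        entry["response_same"] = same if correct else not same


# --------------------------------------------------------------------------
# Trial factories wiring the staircase to the stimulus generator.  Symbolic
# (unrendered) construction is the default: track simulation then exercises
# figure/ground/gap construction without paying audio-rendering cost.


def gap_trial_factory(cfg_stim=None, render: bool = False):
    """Factory for gap-task trials: two fixed-figure intervals, one gapped."""
    from . import stimgen

    cfg_stim = cfg_stim or stimgen.StimulusConfig()

    def factory(snr_db: float, rng: np.random.Generator) -> dict:
        gap_interval = int(rng.integers(2))
        meta = {"gap_interval": gap_interval, "isi_ms": cfg_stim.isi_fixed_ms}
        figures = []
        for i in range(2):
            fig = stimgen.build_fixed_figure(rng, cfg_stim)
            if i == gap_interval:
                fig = stimgen.insert_gap(fig, cfg_stim.gap_chords, rng, cfg_stim.gap_margin_chords)
            figures.append(fig)
        if render:
            for fig in figures:
                ground = stimgen.build_ground(rng, fig.n_chords, cfg_stim, cfg_stim.ground_range_high)
                stimgen.render_stimulus(fig, ground, snr_db, cfg_stim)
        meta["gap"] = figures[gap_interval].gap
        return meta

    return factory


def pattern_trial_factory(variant: str = "dynamic_low", cfg_stim=None, render: bool = False):
    """Factory for pattern-task trials: a same/different dynamic pair."""
    from . import stimgen

    cfg_stim = cfg_stim or stimgen.StimulusConfig()

    def factory(snr_db: float, rng: np.random.Generator) -> dict:
        same = bool(rng.integers(2))
        meta = {"same_pattern": same, "isi_ms": cfg_stim.isi_dynamic_ms}
        if render:
            stimgen.make_pattern_pair(rng, None, same, cfg_stim, variant, snr_db)
        else:
            n_chords = int(rng.integers(cfg_stim.dynamic_chord_range[0],
                                        cfg_stim.dynamic_chord_range[1] + 1))
            series_a = stimgen.draw_dynamic_series(rng, cfg_stim, variant, n_chords=n_chords)
            series_b = series_a if same else stimgen.draw_dynamic_series(
                rng, cfg_stim, variant, n_chords=n_chords)
            meta["n_chords"] = series_a.n_chords
            assert series_b.n_chords == series_a.n_chords
        return meta

    return factory
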