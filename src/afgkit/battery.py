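"""Session-level configuration and the simulated test battery.

``run_battery`` pushes one synthetic participant through the figure-ground
battery: two fixed-task gap runs (scores averaged), then the low- and
high-frequency dynamic pattern tasks in an order counterbalanced by seed
parity.  Speech-score fields come from the cohort generator.  Every
stochastic branch derives from the master seed through the named fan-out in
:mod:`afgkit._seeds`, so reports are byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cohort, psychophysics as psy, stimgen
from ._seeds import spawn_rng

__all__ = ["RunConfig", "ConfigError", "load_config", "run_battery", "TASK_VARIANTS"]

TASK_VARIANTS = {"afg_fixed": "fixed", "afg_low": "dynamic_low", "afg_high": "dynamic_high"}

#: Default simulated-observer settings per task.  Converged track SNRs land
#: near the cohort generator's mean scores.  The gap-task observer uses a
#: zero guess rate so its 1-up 1-down track has a well-defined 50% target.
DEFAULT_OBSERVERS = {
    "afg_fixed": dict(threshold_db=-14.5, slope_db=2.0, guess=0.0, lapse=0.01),
    "afg_low": dict(threshold_db=9.7, slope_db=2.0, guess=0.5, lapse=0.01),
    "afg_high": dict(threshold_db=7.9, slope_db=2.0, guess=0.5, lapse=0.01),
}


class ConfigError(ValueError):
    """Malformed or contradictory run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Validated session configuration with battery defaults filled in."""

    master_seed: int = 0
    output_dir: Path | None = None
    log_level: str = "INFO"
    stimulus: stimgen.StimulusConfig = field(default_factory=stimgen.StimulusConfig)
    staircase_gap: psy.StaircaseConfig = field(default_factory=psy.fixed_gap_staircase)
    staircase_pattern: psy.StaircaseConfig = field(default_factory=psy.dynamic_pattern_staircase)
    observers: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OBSERVERS.items()})


def _build(cls, defaults, overrides: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - known
    if unknown:
        raise ConfigError(f"unknown {context} keys: {sorted(unknown)}")
    merged = {**{f.name: getattr(defaults, f.name) for f in dataclasses.fields(cls)}, **overrides}
    # lists from YAML must become the tuples the dataclasses validate
    merged = {k: tuple(v) if isinstance(v, list) else v for k, v in merged.items()}
    try:
        return cls(**merged)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context} configuration: {exc}") from exc


def load_config(source=None, **flags) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML/JSON file, dict and/or flags.

    Battery defaults fill unset fields.  Unknown keys raise
    :class:`ConfigError` naming them, as do field values violating the
    underlying type invariants.
    """
    raw: dict = {}
    if source is not None:
        if isinstance(source, dict):
            raw = dict(source)
        else:
            text = Path(source).read_text()
            try:
                raw = yaml.safe_load(text) or {}
            except yaml.YAMLError as exc:
                raise ConfigError(f"cannot parse config file {source}: {exc}") from exc
            if not isinstance(raw, dict):
                raise ConfigError("config file must contain a mapping")
    raw.update({k: v for k, v in flags.items() if v is not None})

    known_top = {"master_seed", "output_dir", "log_level", "stimulus",
                 "staircase_gap", "staircase_pattern", "observers"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    stim = _build(stimgen.StimulusConfig, stimgen.StimulusConfig(),
                  raw.get("stimulus", {}), "stimulus")
    sc_gap = _build(psy.StaircaseConfig, psy.fixed_gap_staircase(),
                    raw.get("staircase_gap", {}), "staircase_gap")
    sc_pat = _build(psy.StaircaseConfig, psy.dynamic_pattern_staircase(),
                    raw.get("staircase_pattern", {}), "staircase_pattern")
    observers = {k: dict(v) for k, v in DEFAULT_OBSERVERS.items()}
    for task, ov in (raw.get("observers") or {}).items():
        if task not in observers:
            raise ConfigError(f"unknown observer task {task!r}")
        unknown = set(ov) - {"threshold_db", "slope_db", "guess", "lapse"}
        if unknown:
            raise ConfigError(f"unknown observer keys for {task}: {sorted(unknown)}")
        observers[task].update(ov)
    try:
        seed = int(raw.get("master_seed", 0))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"master_seed must be an integer: {exc}") from exc
    out_dir = raw.get("output_dir")
    return RunConfig(
        master_seed=seed,
        output_dir=Path(out_dir) if out_dir else None,
        log_level=str(raw.get("log_level", "INFO")),
        stimulus=stim, staircase_gap=sc_gap, staircase_pattern=sc_pat,
        observers=observers,
    )


def run_battery(cfg: RunConfig) -> dict:
    """Simulate one participant's session; returns (and optionally writes)
    the JSON-able report of scores, stability flags and sub-seeds."""
    seed = cfg.master_seed
    report: dict = {"master_seed": seed, "tasks": {}, "sub_seeds": {}}

    # fixed task: two runs with different exemplars, scores averaged
    obs_fixed = psy.Observer(**cfg.observers["afg_fixed"])
    factory = psy.gap_trial_factory(cfg.stimulus)
    runs = []
    for run_idx in range(2):
        rng = spawn_rng(seed, "battery", "afg_fixed", run_idx)
        report["sub_seeds"][f"afg_fixed/run{run_idx}"] = ["battery", "afg_fixed", run_idx]
        res = psy.run_track(obs_fixed, cfg.staircase_gap, factory, rng, task="gap")
        runs.append(res)
    score = psy.combine_runs([r.score_db for r in runs])
    report["tasks"]["afg_fixed"] = {
        "runs": [_run_report(r) for r in runs],
        "score_db": score,
        "stable": all(r.stable for r in runs),
        "excluded": not all(r.stable for r in runs),
    }

    # dynamic tasks, order counterbalanced on seed parity
    order = ["afg_low", "afg_high"] if seed % 2 == 0 else ["afg_high", "afg_low"]
    report["dynamic_order"] = order
    for task in order:
        obs = psy.Observer(**cfg.observers[task])
        factory = psy.pattern_trial_factory(TASK_VARIANTS[task], cfg.stimulus)
        rng = spawn_rng(seed, "battery", task, 0)
        report["sub_seeds"][f"{task}/run0"] = ["battery", task, 0]
        res = psy.run_track(obs, cfg.staircase_pattern, factory, rng, task="pattern")
        report["tasks"][task] = {
            "runs": [_run_report(res)],
            "score_db": res.score_db,
            "stable": res.stable,
            "excluded": not res.stable,
        }

    # speech and demographic fields from the cohort generator
    crng = spawn_rng(seed, "battery", "speech_scores")
    row = cohort.simulate_cohort(cohort.cohort_defaults(n=10), crng).iloc[0]
    report["speech"] = {k: float(row[k]) for k in ("WiN", "SiB", "SSQ", "age", "PTA")}

    if cfg.output_dir is not None:
        cfg.output_dir.mkdir(parents=True, exist_ok=True)
        out = cfg.output_dir / f"battery_seed{seed}.json"
        out.write_text(json.dumps(report, indent=1, sort_keys=True))
        report["written_to"] = str(out)
    return report


def _run_report(res: psy.RunResult) -> dict:
    return {
        "score_db": res.score_db,
        "reversal_snrs": list(res.reversal_snrs),
        "stable": res.stable,
        "n_trials": res.n_trials,
    }
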