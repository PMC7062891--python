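"""Timed trial structure of the cued foraging task.

The task consists of a fixed number of trials (default 12). Each trial is a
coloured cue (2 s) announcing the reward level of the upcoming foraging patch
(1 or 20 cents per hit), a fixation interval (3 s), the foraging patch itself
(14.5 s) during which lateralised target dots appear and each correct response
pays the announced amount, and a 10 s inter-trial pause.  With the defaults the
whole run lasts 354 s, i.e. six minutes to the nearest minute.

Three experimental variations are expressed through :class:`TaskConfig`:

* reward levels alternate at random (balanced) or strictly regularly, which
  makes the cue informative or fully predictable;
* target onsets are drawn from a bounded exponential schedule (support
  300-1800 ms, mean calibrated to 1220 ms) or occur at regular 1250 ms
  intervals.

Schedules round-trip through tab-separated events tables (one row per cue,
patch and target, with ``onset``/``duration`` in seconds).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

MS = 1000.0
LOW = "low"
HIGH = "high"
LEVELS = (LOW, HIGH)


class ScheduleError(ValueError):
    """Invalid task configuration or malformed events table."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of one run of the foraging task.

    Durations of the trial phases are in seconds; target-interval parameters
    are in milliseconds (internal convention: milliseconds for within-patch
    timing, seconds in events files).
    """

    n_trials: int = 12
    cue_duration: float = 2.0
    interval_duration: float = 3.0
    patch_duration: float = 14.5
    iti_duration: float = 10.0
    reward_low: float = 1.0
    reward_high: float = 20.0
    target_mode: str = "irregular"            # "irregular" | "regular"
    interval_bounds: tuple[float, float] = (300.0, 1800.0)   # ms
    interval_mean: float = 1220.0             # ms, calibration target
    regular_interval: float = 1250.0          # ms
    alternation: str = "random_balanced"      # "random_balanced" | "regular"
    regular_start: str = LOW                  # first level under regular alternation
    target_onscreen: float = 800.0            # ms
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cue_duration", "interval_duration", "patch_duration",
                     "iti_duration"):
            if getattr(self, name) <= 0:
                raise ScheduleError(f"{name} must be positive")
        if self.n_trials < 0:
            raise ScheduleError("n_trials must be non-negative")
        lo, hi = self.interval_bounds
        if lo <= 0 or hi <= lo:
            raise ScheduleError(
                f"infeasible interval bounds {self.interval_bounds!r}")
        if not (lo < self.interval_mean < hi):
            raise ScheduleError(
                "interval_mean must lie strictly inside interval_bounds")
        if self.regular_interval <= 0:
            raise ScheduleError("regular_interval must be positive")
        if self.target_mode not in ("irregular", "regular"):
            raise ScheduleError(f"unknown target_mode {self.target_mode!r}")
        if self.alternation not in ("random_balanced", "regular"):
            raise ScheduleError(f"unknown alternation {self.alternation!r}")
        if self.regular_start not in LEVELS:
            raise ScheduleError(f"unknown regular_start {self.regular_start!r}")

    @property
    def trial_duration(self) -> float:
        """Length of one trial in seconds (cue + interval + patch + pause)."""
        return (self.cue_duration + self.interval_duration
                + self.patch_duration + self.iti_duration)

    def reward(self, level: str) -> float:
        if level not in LEVELS:
            raise ScheduleError(f"unknown reward level {level!r}")
        return self.reward_high if level == HIGH else self.reward_low


@dataclass(frozen=True)
class TargetEvent:
    """One target presentation: absolute onset (s), screen side, pay-out."""

    onset: float
    side: str
    reward: float


@dataclass(frozen=True)
class Trial:
    index: int
    reward_level: str
    cue_onset: float
    interval_onset: float
    patch_onset: float
    iti_onset: float
    targets: tuple[TargetEvent, ...] = ()

    @property
    def patch_duration(self) -> float:
        return self.iti_onset - self.patch_onset


@dataclass(frozen=True)
class TrialSchedule:
    trials: tuple[Trial, ...]
    total_duration: float
    config: TaskConfig

    def targets(self, level: str | None = None) -> list[TargetEvent]:
        out: list[TargetEvent] = []
        for tr in self.trials:
            if level is None or tr.reward_level == level:
                out.extend(tr.targets)
        return out

    def total_payout(self) -> float:
        """Pay-out if every target is hit (cents)."""
        return sum(t.reward for t in self.targets())


# ---------------------------------------------------------------------------
# reward-level alternation


def alternation_sequence(mode: str, n_trials: int,
                         seed: int | None = None,
                         start: str = LOW,
                         rng: np.random.Generator | None = None) -> list[str]:
    """Sequence of per-trial reward levels.

    ``regular`` strictly alternates starting from ``start``; the starting
    level is a design choice, the defaults begin with a low trial.
    ``random_balanced`` is a seeded permutation with exactly equal counts of
    low and high, so ``n_trials`` must be even.
    """
    if n_trials < 0:
        raise ScheduleError("n_trials must be non-negative")
    if mode == "regular":
        other = HIGH if start == LOW else LOW
        return [start if i % 2 == 0 else other for i in range(n_trials)]
    if mode == "random_balanced":
        if n_trials % 2:
            raise ScheduleError(
                f"random_balanced alternation needs an even trial count, "
                f"got {n_trials}")
        if rng is None:
            rng = np.random.default_rng(seed)
        levels = np.array([LOW, HIGH] * (n_trials // 2), dtype=object)
        return list(rng.permutation(levels))
    raise ScheduleError(f"unknown alternation mode {mode!r}")


# ---------------------------------------------------------------------------
# target-interval sampling

def _truncexp_mean(rate: float, lo: float, hi: float) -> float:
    """Mean of an exponential density truncated to [lo, hi].

    The density is proportional to exp(-rate*x); negative rates (increasing
    density) are admitted, which is what a bounded schedule whose mean lies
    above the midpoint of its support requires.  rate -> 0 recovers the
    uniform distribution.
    """
    span = hi - lo
    if rate == 0.0:
        return lo + span / 2.0
    x = rate * span
    if x > 700.0:          # mass piles up at lo; the span term vanishes
        return lo + 1.0 / rate
    if x < -700.0:         # mass piles up at hi
        return hi + 1.0 / rate
    return lo + 1.0 / rate - span / math.expm1(x)


def calibrate_interval_rate(lo: float, hi: float, mean: float) -> float:
    """Rate (per ms) whose [lo, hi]-truncated exponential has the given mean.

    Solved by scalar root-finding; only the bounds and the mean of the
    schedule are constrained, the rate is the free parameter.
    """
    if not (lo < mean < hi):
        raise ScheduleError("target mean must lie strictly inside the bounds")
    midpoint = lo + (hi - lo) / 2.0
    if abs(mean - midpoint) < 1e-9:
        return 0.0
    bracket = (1e-10, 0.5) if mean < midpoint else (-0.5, -1e-10)
    return brentq(lambda lam: _truncexp_mean(lam, lo, hi) - mean, *bracket,
                  xtol=1e-14)


def sample_target_intervals(mode: str, n: int,
                            config: TaskConfig | None = None,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None
                            ) -> np.ndarray:
    """Draw ``n`` inter-target intervals in milliseconds.

    ``irregular`` draws from the bounded exponential schedule with the rate
    calibrated so that the truncated mean equals ``config.interval_mean``;
    ``regular`` returns constant ``config.regular_interval`` spacing.
    """
    if n < 0:
        raise ScheduleError("n must be non-negative")
    config = config or TaskConfig()
    if mode == "regular":
        return np.full(n, float(config.regular_interval))
    if mode != "irregular":
        raise ScheduleError(f"unknown target mode {mode!r}")
    lo, hi = config.interval_bounds
    if hi <= lo:
        raise ScheduleError(f"infeasible interval bounds ({lo}, {hi})")
    lam = calibrate_interval_rate(lo, hi, config.interval_mean)
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.random(n)
    span = hi - lo
    if lam == 0.0:
        return lo + u * span
    # inverse CDF of the truncated exponential; valid for either sign of lam
    c = -math.expm1(-lam * span)            # 1 - exp(-lam*span)
    return lo - np.log1p(-u * c) / lam


# ---------------------------------------------------------------------------
# schedule generation


def generate_schedule(config: TaskConfig | None = None) -> TrialSchedule:
    """Generate the timed trial structure for one run.

    Reward levels follow the configured alternation; target onsets are packed
    into each patch, the first one interval after patch onset, until the next
    sampled onset would fall beyond the patch end.  Sides are independent
    fair coin flips.  Identical config (including seed) gives a bit-identical
    schedule.
    """
    config = config or TaskConfig()
    ss = np.random.SeedSequence(config.seed)
    r_alt, r_int, r_side = (np.random.default_rng(s) for s in ss.spawn(3))
    levels = alternation_sequence(config.alternation, config.n_trials,
                                  start=config.regular_start, rng=r_alt)
    patch_ms = config.patch_duration * MS
    min_gap = (config.interval_bounds[0] if config.target_mode == "irregular"
               else config.regular_interval)
    max_n = int(patch_ms // min_gap) + 1

    trials: list[Trial] = []
    for i, level in enumerate(levels):
        base = i * config.trial_duration
        cue_onset = base
        interval_onset = cue_onset + config.cue_duration
        patch_onset = interval_onset + config.interval_duration
        iti_onset = patch_onset + config.patch_duration

        gaps = sample_target_intervals(config.target_mode, max_n, config,
                                       rng=r_int)
        rel = np.cumsum(gaps)
        rel = rel[rel <= patch_ms + 1e-9]
        if rel.size == 0:
            warnings.warn(
                f"trial {i}: foraging patch shorter than one target interval; "
                "no targets placed", stacklevel=2)
        sides = np.where(r_side.random(rel.size) < 0.5, "left", "right")
        reward = config.reward(level)
        targets = tuple(
            TargetEvent(onset=patch_onset + t / MS, side=str(s), reward=reward)
            for t, s in zip(rel, sides))
        trials.append(Trial(index=i, reward_level=level, cue_onset=cue_onset,
                            interval_onset=interval_onset,
                            patch_onset=patch_onset, iti_onset=iti_onset,
                            targets=targets))
    total = config.n_trials * config.trial_duration
    return TrialSchedule(trials=tuple(trials), total_duration=total,
                         config=config)


# ---------------------------------------------------------------------------
# events-table round trip

EVENT_COLUMNS = ("onset", "duration", "trial_type", "reward", "side")


def write_events(schedule: TrialSchedule, path: str | Path) -> Path:
    """Write the schedule as a tab-separated events table.

    One row per cue (``cue_low``/``cue_high``), one per foraging patch
    (``patch_low``/``patch_high``) and one per target, sorted by onset.
    """
    cfg = schedule.config
    rows = []
    for tr in schedule.trials:
        level = tr.reward_level
        rows.append((tr.cue_onset, cfg.cue_duration, f"cue_{level}",
                     cfg.reward(level), "n/a"))
        rows.append((tr.patch_onset, cfg.patch_duration, f"patch_{level}",
                     cfg.reward(level), "n/a"))
        for tg in tr.targets:
            rows.append((tg.onset, cfg.target_onscreen / MS, "target",
                         tg.reward, tg.side))
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS).sort_values(
        "onset", kind="stable").reset_index(drop=True)
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False, float_format="%.9f")
    return path


def read_events(path: str | Path,
                config: TaskConfig | None = None) -> TrialSchedule:
    """Read an events table back into a :class:`TrialSchedule`.

    If no config is supplied, phase durations and reward levels are inferred
    from the table; fields that leave no trace in the table (alternation and
    target modes, seed) keep their defaults.  Onsets survive a write/read
    round trip to within 1e-9 s.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration", "trial_type"):
        if col not in frame.columns:
            raise ScheduleError(f"events table missing the {col!r} column")
    for col in ("onset", "duration"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ScheduleError(
                f"events table row {row}: cannot parse {col}="
                f"{frame[col].iloc[row]!r}")
        frame[col] = vals

    cues = frame[frame.trial_type.str.startswith("cue_")].sort_values("onset")
    patches = frame[frame.trial_type.str.startswith("patch_")] \
        .sort_values("onset")
    targets = frame[frame.trial_type == "target"].sort_values("onset")
    if len(cues) != len(patches):
        raise ScheduleError("cue and patch rows do not pair up")

    if config is None:
        rewards = sorted(pd.to_numeric(cues.reward).unique()) if len(cues) \
            else [1.0, 20.0]
        reward_low = float(rewards[0])
        reward_high = float(rewards[-1])
        cue_dur = float(cues.duration.iloc[0]) if len(cues) else 2.0
        patch_dur = float(patches.duration.iloc[0]) if len(patches) else 14.5
        interval_dur = (float(patches.onset.iloc[0] - cues.onset.iloc[0])
                        - cue_dur) if len(cues) else 3.0
        if len(cues) > 1:
            spacing = float(cues.onset.iloc[1] - cues.onset.iloc[0])
            iti_dur = spacing - cue_dur - interval_dur - patch_dur
        else:
            iti_dur = 10.0
        onscreen = (float(targets.duration.iloc[0]) * MS if len(targets)
                    else 800.0)
        config = TaskConfig(n_trials=len(cues), cue_duration=cue_dur,
                            interval_duration=interval_dur,
                            patch_duration=patch_dur, iti_duration=iti_dur,
                            reward_low=reward_low, reward_high=reward_high,
                            target_onscreen=onscreen)

    trials = []
    cue_rows = cues.reset_index(drop=True)
    patch_rows = patches.reset_index(drop=True)
    for i in range(len(cue_rows)):
        cue_onset = float(cue_rows.onset.iloc[i])
        level = cue_rows.trial_type.iloc[i].removeprefix("cue_")
        if level not in LEVELS:
            raise ScheduleError(
                f"events table: unknown trial_type {cue_rows.trial_type.iloc[i]!r}")
        patch_onset = float(patch_rows.onset.iloc[i])
        patch_end = patch_onset + float(patch_rows.duration.iloc[i])
        sel = targets[(targets.onset >= patch_onset - 1e-9)
                      & (targets.onset <= patch_end + 1e-9)]
        tg = tuple(TargetEvent(onset=float(r.onset), side=str(r.side),
                               reward=float(r.reward))
                   for r in sel.itertuples())
        trials.append(Trial(
            index=i, reward_level=level, cue_onset=cue_onset,
            interval_onset=cue_onset + config.cue_duration,
            patch_onset=patch_onset, iti_onset=patch_end, targets=tg))
    total = config.n_trials * config.trial_duration
    return TrialSchedule(trials=tuple(trials), total_duration=total,
                         config=config)


def experiment_task_config(experiment: int, **overrides) -> TaskConfig:
    """Task configuration preset for one of the three experiment variants.

    1: random balanced reward alternation, irregular targets.
    2: regular (predictable) alternation, irregular targets.
    3: random balanced alternation, regular 1250 ms targets.
    """
    if experiment == 1:
        base = dict(alternation="random_balanced", target_mode="irregular")
    elif experiment == 2:
        base = dict(alternation="regular", target_mode="irregular")
    elif experiment == 3:
        base = dict(alternation="random_balanced", target_mode="regular")
    else:
        raise ScheduleError(f"unknown experiment {experiment!r}")
    base.update(overrides)
    return TaskConfig(**base)
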