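"""Tabular TD(0) simulation of the foraging task's episode chain.

The task is approximated by a finite chain of discrete episodes per trial: a
pre-cue context state, the cue, the fixation interval, one 250 ms slot per
model step of the foraging patch (each slot either a target episode carrying
the trial's reward or a non-target episode carrying nothing), the inter-trial
pause, and a terminal state whose value is pinned to zero.

State values are the undiscounted expected future reward

    V(s_t) = E[r_t + r_{t+1} + r_{t+2} + ...]

learned by incrementing each visited state's value by a fraction ``alpha`` of
the one-step prediction error

    delta(s_t) = V(s_{t+1}) - V(s_t) + r_t,

where ``r_t`` is the reward delivered in state ``s_t``.  When learned values
predict rewards correctly the prediction error vanishes and the consistency
condition ``r_t = V(s_t) - V(s_{t+1})`` holds: during the foraging patch the
reward stream is then carried entirely by the differential valuation of
successive states, which is the quantity this package contrasts against the
phasic prediction-error response at the cue.

Variant 2 (predictable reward alternation) is realised by letting the pre-cue
context state encode the upcoming trial type, the minimal state extension
under which a strictly alternating cue is fully predicted and generates no
prediction error.  Variant 3 (regular target spacing) yields a chain that is
deterministic after the cue, where converged prediction errors vanish
identically within the patch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .task_schedule import (MS, HIGH, LOW, ScheduleError, TargetEvent,
                            TaskConfig, Trial, TrialSchedule,
                            experiment_task_config, sample_target_intervals)

CLICK = "click"
NO_CLICK = "no_click"
TERMINAL = "terminal"
PATCH_KINDS = ("target", "non_target")


@dataclass(frozen=True)
class TDConfig:
    """Learning parameters for the tabular TD(0) simulator.

    gamma is fixed at 1 (undiscounted episodic variant); alpha is the fraction
    of the prediction error applied at each update.  Training stops when the
    largest value update within a trial drops below ``convergence_tol`` or
    after ``n_train`` trials, whichever comes first.  ``step_grain`` is the
    length in milliseconds of one model step within the foraging patch.
    """

    gamma: float = 1.0
    alpha: float = 0.1
    n_train: int = 10_000
    convergence_tol: float = 1e-8
    n_record: int = 200
    hit_prob: float = 1.0
    step_grain: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma != 1.0:
            raise ValueError("this simulator implements the undiscounted "
                             "variant; gamma must be 1.0")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.step_grain <= 0:
            raise ValueError("step_grain must be positive")
        if not 0.0 <= self.hit_prob <= 1.0:
            raise ValueError("hit_prob must lie in [0, 1]")


@dataclass(frozen=True, slots=True)
class Episode:
    state: str
    kind: str
    reward: float
    onset: float        # seconds on the trial clock


@dataclass(frozen=True, slots=True)
class EpisodeChain:
    episodes: tuple[Episode, ...]
    trial_type: str

    def __len__(self) -> int:
        return len(self.episodes)

    def total_reward(self) -> float:
        return sum(e.reward for e in self.episodes)


@dataclass
class ValueTable:
    """Learned state values (cents of expected future reward)."""

    values: dict[str, float]
    converged: bool
    sweeps_used: int

    def __getitem__(self, state: str) -> float:
        return self.values.get(state, 0.0)


@dataclass
class QValueTable:
    """State-action values under the fixed optimal policy (click at targets)."""

    values: dict[tuple[str, str], float]
    converged: bool
    sweeps_used: int

    def value(self, state: str, action: str) -> float:
        return self.values.get((state, action), 0.0)

    def greedy_value(self, state: str) -> float:
        return max(self.value(state, CLICK), self.value(state, NO_CLICK))


@dataclass
class TDTrace:
    """Per-step records from recording trials (no learning).

    ``frame`` has one row per transition s_t -> s_{t+1} with the delivered
    reward r_t (reward of s_t), the stored values of both states and the
    prediction error delta = value_to - value_from + reward.  ``time`` is the
    trial-clock onset of the entered state (where a cue- or target-locked
    response would be plotted); ``time_from`` is the onset of s_t (where the
    delivered reward sits).
    """

    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class ConsistencySummary:
    mean: float
    mean_abs: float
    max_abs: float
    n: int


@dataclass
class ModelCurves:
    """Trial-averaged, response-convolved prediction-error and reward curves."""

    time: np.ndarray
    delta: dict[str, np.ndarray]
    reward_rate: dict[str, np.ndarray]
    n_trials: dict[str, int]


# ---------------------------------------------------------------------------
# chain construction


def build_episode_chain(trial: Trial, experiment_variant: int,
                        step_grain: float = 250.0,
                        trial_end: float | None = None) -> EpisodeChain:
    """Finite-state episode chain for one trial.

    One episode for the pre-cue context, the cue and the interval, one per
    ``step_grain`` slot of the foraging patch (targets land on their nearest
    slot), one for the pause and one terminal episode.  In variant 2 the
    pre-cue state encodes the trial type, so the strictly alternating cue is
    fully predicted.
    """
    if experiment_variant not in (1, 2, 3):
        raise ScheduleError(f"unknown experiment variant {experiment_variant!r}")
    level = trial.reward_level
    grain_s = step_grain / MS
    pre_state = f"pre_cue|{level}" if experiment_variant == 2 else "pre_cue"
    episodes = [
        Episode(pre_state, "pre_cue", 0.0, trial.cue_onset - grain_s),
        Episode(f"cue|{level}", "cue", 0.0, trial.cue_onset),
        Episode(f"interval|{level}", "interval", 0.0, trial.interval_onset),
    ]
    patch_ms = trial.patch_duration * MS
    n_slots = int(patch_ms / step_grain + 1e-9)
    slot_reward: dict[int, float] = {}
    for tg in trial.targets:
        rel_ms = (tg.onset - trial.patch_onset) * MS
        slot = min(max(int(round(rel_ms / step_grain)), 1), n_slots)
        slot_reward[slot] = slot_reward.get(slot, 0.0) + tg.reward
    for s in range(1, n_slots + 1):
        onset = trial.patch_onset + s * grain_s
        if s in slot_reward:
            episodes.append(Episode(f"patch|{level}|{s:02d}|T", "target",
                                    slot_reward[s], onset))
        else:
            episodes.append(Episode(f"patch|{level}|{s:02d}|N", "non_target",
                                    0.0, onset))
    end = trial.iti_onset + 10.0 if trial_end is None else trial_end
    episodes.append(Episode(f"iti|{level}", "iti", 0.0, trial.iti_onset))
    episodes.append(Episode(TERMINAL, TERMINAL, 0.0, end))
    return EpisodeChain(tuple(episodes), level)


class ChainGenerator:
    """Endless stream of i.i.d. trial chains for one experiment variant.

    Trial types are drawn fairly at random (variants 1 and 3) or strictly
    alternate (variant 2); target onsets are sampled from the task's interval
    schedule; targets pay the trial's reward with probability ``hit_prob``.
    All randomness flows from the TD seed, so streams are reproducible.
    """

    def __init__(self, task_config: TaskConfig | None = None,
                 experiment_variant: int = 1,
                 td_config: TDConfig | None = None,
                 seed: int | None = None) -> None:
        if experiment_variant not in (1, 2, 3):
            raise ScheduleError(
                f"unknown experiment variant {experiment_variant!r}")
        self.task = task_config or experiment_task_config(experiment_variant)
        self.variant = experiment_variant
        self.td = td_config or TDConfig()
        self.rng = np.random.default_rng(
            self.td.seed if seed is None else seed)
        self._next_level = (self.task.regular_start if self.variant == 2
                            else None)
        patch_ms = self.task.patch_duration * MS
        min_gap = (self.task.interval_bounds[0]
                   if self.task.target_mode == "irregular"
                   else self.task.regular_interval)
        self._max_n = int(patch_ms // min_gap) + 1

    def _draw_level(self) -> str:
        if self.variant == 2:
            level = self._next_level
            self._next_level = HIGH if level == LOW else LOW
            return level
        return HIGH if self.rng.random() < 0.5 else LOW

    def draw_trial(self) -> Trial:
        cfg = self.task
        level = self._draw_level()
        cue, interval = 0.0, cfg.cue_duration
        patch = interval + cfg.interval_duration
        iti = patch + cfg.patch_duration
        gaps = sample_target_intervals(cfg.target_mode, self._max_n, cfg,
                                       rng=self.rng)
        rel = np.cumsum(gaps)
        rel = rel[rel <= cfg.patch_duration * MS + 1e-9]
        reward = cfg.reward(level)
        if self.td.hit_prob < 1.0:
            hits = self.rng.random(rel.size) < self.td.hit_prob
        else:
            hits = np.ones(rel.size, dtype=bool)
        targets = tuple(
            TargetEvent(onset=patch + t / MS, side="left",
                        reward=reward if h else 0.0)
            for t, h in zip(rel, hits))
        return Trial(index=0, reward_level=level, cue_onset=cue,
                     interval_onset=interval, patch_onset=patch,
                     iti_onset=iti, targets=targets)

    def __iter__(self) -> Iterator[EpisodeChain]:
        while True:
            trial = self.draw_trial()
            yield build_episode_chain(
                trial, self.variant, self.td.step_grain,
                trial_end=trial.iti_onset + self.task.iti_duration)


# ---------------------------------------------------------------------------
# learning


def train_values(chains: Iterable[EpisodeChain],
                 td_config: TDConfig | None = None) -> ValueTable:
    """Learn state values by TD(0): V(s_t) += alpha * delta(s_t).

    Consumes at most ``n_train`` chains; stops early once the largest update
    within a chain falls below ``convergence_tol`` and flags convergence
    accordingly.  The terminal state is pinned at zero.
    """
    cfg = td_config or TDConfig()
    alpha, tol = cfg.alpha, cfg.convergence_tol
    V: dict[str, float] = {TERMINAL: 0.0}
    get = V.get
    converged = False
    sweeps = 0
    for chain in itertools.islice(iter(chains), cfg.n_train):
        sweeps += 1
        eps = chain.episodes
        max_upd = 0.0
        for t in range(len(eps) - 1):
            e = eps[t]
            s = e.state
            delta = get(eps[t + 1].state, 0.0) - get(s, 0.0) + e.reward
            upd = alpha * delta
            V[s] = get(s, 0.0) + upd
            if upd > max_upd:
                max_upd = upd
            elif -upd > max_upd:
                max_upd = -upd
        if max_upd < tol:
            converged = True
            break
    V[TERMINAL] = 0.0
    return ValueTable(V, converged, sweeps)


def train_q_values(chains: Iterable[EpisodeChain],
                   td_config: TDConfig | None = None) -> QValueTable:
    """On-policy state-action values under the optimal policy.

    The policy is fixed: click whenever a target appears, otherwise no click.
    Clicking at a target collects the episode's reward; anything else pays
    nothing.  At convergence the identity
    r_t = Q(s_t, a_t) - Q(s_{t+1}, a_{t+1}) holds along the chain.
    """
    cfg = td_config or TDConfig()
    alpha, tol = cfg.alpha, cfg.convergence_tol
    Q: dict[tuple[str, str], float] = {(TERMINAL, NO_CLICK): 0.0}
    get = Q.get
    converged = False
    sweeps = 0
    for chain in itertools.islice(iter(chains), cfg.n_train):
        sweeps += 1
        eps = chain.episodes
        pairs = [(e.state, CLICK if e.kind == "target" else NO_CLICK)
                 for e in eps]
        max_upd = 0.0
        for t in range(len(eps) - 1):
            sa, sa1 = pairs[t], pairs[t + 1]
            r = eps[t].reward if sa[1] == CLICK else 0.0
            delta = r + get(sa1, 0.0) - get(sa, 0.0)
            upd = alpha * delta
            Q[sa] = get(sa, 0.0) + upd
            if abs(upd) > max_upd:
                max_upd = abs(upd)
        if max_upd < tol:
            converged = True
            break
    Q[(TERMINAL, NO_CLICK)] = 0.0
    return QValueTable(Q, converged, sweeps)


def q_consistency_residual(qtable: QValueTable, chain: EpisodeChain) -> float:
    """Largest |r_t - (Q(s_t,a_t) - Q(s_{t+1},a_{t+1}))| along a chain."""
    eps = chain.episodes
    worst = 0.0
    for t in range(len(eps) - 1):
        a = CLICK if eps[t].kind == "target" else NO_CLICK
        a1 = CLICK if eps[t + 1].kind == "target" else NO_CLICK
        r = eps[t].reward if a == CLICK else 0.0
        resid = r - (qtable.value(eps[t].state, a)
                     - qtable.value(eps[t + 1].state, a1))
        worst = max(worst, abs(resid))
    return worst


def backward_induction(chain: EpisodeChain) -> dict[str, float]:
    """Dynamic-programming values for a fixed (deterministic) chain.

    Independent oracle for the TD learner: V(s_t) = r_t + V(s_{t+1}) with
    V(terminal) = 0, evaluated by one backward pass.
    """
    eps = chain.episodes
    V = {eps[-1].state: 0.0}
    acc = 0.0
    for e in reversed(eps[:-1]):
        V[e.state] = acc + e.reward
        acc = V[e.state]
    return V


# ---------------------------------------------------------------------------
# recording


def record_trace(values: ValueTable, chains: Iterable[EpisodeChain],
                 td_config: TDConfig | None = None) -> TDTrace:
    """Run ``n_record`` trials without learning, recording delta and r.

    Each row stores the transition's endpoints, kinds, stored values, the
    delivered reward and the prediction error, which satisfies
    delta = value_to - value_from + reward exactly by construction.
    """
    cfg = td_config or TDConfig()
    rows = []
    for trial_idx, chain in enumerate(
            itertools.islice(iter(chains), cfg.n_record)):
        eps = chain.episodes
        for t in range(len(eps) - 1):
            e, e1 = eps[t], eps[t + 1]
            v, v1 = values[e.state], values[e1.state]
            rows.append((trial_idx, chain.trial_type, t, e.state, e1.state,
                         e.kind, e1.kind, e.reward, v, v1, v1 - v + e.reward,
                         e.onset, e1.onset))
    frame = pd.DataFrame(rows, columns=[
        "trial", "trial_type", "step", "state_from", "state_to", "kind_from",
        "kind_to", "reward", "value_from", "value_to", "delta", "time_from",
        "time"])
    return TDTrace(frame)


def consistency_residual(trace: TDTrace,
                         phase_filter: Sequence[str] = PATCH_KINDS,
                         on: str = "from") -> ConsistencySummary:
    """Summarise delta over the steps whose episode kind matches the filter.

    ``on`` selects whether the filter applies to the departed state
    (``"from"``, the state in which the reward was delivered) or the entered
    state (``"to"``, where cue- and target-locked responses live).
    """
    if on not in ("from", "to"):
        raise ValueError("on must be 'from' or 'to'")
    col = f"kind_{on}"
    sel = trace.frame[trace.frame[col].isin(tuple(phase_filter))]
    if sel.empty:
        raise ValueError(
            f"no recorded steps match phase filter {tuple(phase_filter)!r}")
    d = sel.delta.to_numpy()
    return ConsistencySummary(mean=float(d.mean()),
                              mean_abs=float(np.abs(d).mean()),
                              max_abs=float(np.abs(d).max()), n=int(d.size))


# ---------------------------------------------------------------------------
# smoothed curves


def smooth_trace_to_curves(trace: TDTrace, task_config: TaskConfig,
                           hrf_kernel: np.ndarray | None = None,
                           dt: float = 0.1) -> ModelCurves:
    """Fig.-style smoothed mean curves of delta and r on the trial clock.

    Step impulses are placed at their trial times (prediction errors at the
    onset of the entered state, rewards at the onset of the state delivering
    them), averaged across the recorded trials of each condition and
    convolved with a haemodynamic-response kernel so that the curves reflect
    what the BOLD signal would carry.
    """
    if hrf_kernel is None:
        from .design_matrix import HRFSpec, canonical_hrf
        hrf_kernel = canonical_hrf(HRFSpec(), tr=dt, oversampling=1)
    duration = task_config.trial_duration
    n = int(np.ceil(duration / dt)) + 1
    times = np.arange(n) * dt
    frame = trace.frame
    if len(frame) and frame.time.max() > duration + dt:
        raise ValueError("trace times extend beyond the configured trial "
                         "duration; trace and schedule are misaligned")
    delta_curves: dict[str, np.ndarray] = {}
    r_curves: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for level, sub in frame.groupby("trial_type"):
        n_tr = int(sub.trial.nunique())
        counts[level] = n_tr
        d_imp = np.zeros(n)
        idx = np.clip(np.round(sub.time.to_numpy() / dt).astype(int), 0, n - 1)
        np.add.at(d_imp, idx, sub.delta.to_numpy() / n_tr)
        r_imp = np.zeros(n)
        rew = sub[sub.reward != 0.0]
        if len(rew):
            ridx = np.clip(np.round(rew.time_from.to_numpy() / dt).astype(int),
                           0, n - 1)
            np.add.at(r_imp, ridx, rew.reward.to_numpy() / n_tr)
        delta_curves[level] = np.convolve(d_imp, hrf_kernel)[:n]
        r_curves[level] = np.convolve(r_imp, hrf_kernel)[:n]
    return ModelCurves(time=times, delta=delta_curves, reward_rate=r_curves,
                       n_trials=counts)


def reward_rate_ratio(curves: ModelCurves, task_config: TaskConfig) -> float:
    """Ratio of time-averaged high/low reward-rate curves over the patch."""
    start = task_config.cue_duration + task_config.interval_duration
    end = start + task_config.patch_duration
    sel = (curves.time >= start) & (curves.time <= end)
    lo = float(curves.reward_rate[LOW][sel].mean())
    hi = float(curves.reward_rate[HIGH][sel].mean())
    if lo == 0.0:
        raise ValueError("low-reward curve averages to zero over the patch")
    return hi / lo


def simulate_experiment(experiment_variant: int,
                        task_config: TaskConfig | None = None,
                        td_config: TDConfig | None = None
                        ) -> tuple[ValueTable, TDTrace, ModelCurves]:
    """Train, record and smooth in one call for a given experiment variant."""
    td = td_config or TDConfig()
    task = task_config or experiment_task_config(experiment_variant)
    ss = np.random.SeedSequence(td.seed)
    s_train, s_rec = (int(c.generate_state(1)[0]) for c in ss.spawn(2))
    values = train_values(
        ChainGenerator(task, experiment_variant, td, seed=s_train), td)
    trace = record_trace(
        values, ChainGenerator(task, experiment_variant, td, seed=s_rec), td)
    curves = smooth_trace_to_curves(trace, task)
    return values, trace, curves
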