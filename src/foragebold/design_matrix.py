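"""First-level regression designs for the foraging task.

Task phases are modelled as boxcars (cues, foraging patches) or event sticks
(one impulse per target) on an oversampled time grid, convolved with a
canonical double-gamma haemodynamic response and decimated at scan times.
Parametric modulators scale each event by a covariate: trial number at the
cues, powers of within-patch time (up to the fourth degree, sequentially
orthogonalised against lower degrees) or first/last-quartile indicators at
the targets.  An intercept and, optionally, a discrete-cosine high-pass drift
basis complete the design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .task_schedule import LEVELS, TaskConfig, TrialSchedule


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma haemodynamic response.

    Defaults are the de-facto standard: response peaking ~5 s after onset
    (gamma with 6 s delay, 1 s dispersion), an undershoot peaking near 15 s
    (16 s delay) at one sixth of the peak amplitude, a 32 s kernel, and a
    16-fold oversampling of the scan grid when building regressors.  The
    kernel is scaled to unit peak so fitted coefficients read in signal units.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    length: float = 32.0
    oversampling: int = 16

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("kernel length must be positive")
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")


def canonical_hrf(spec: HRFSpec | None = None, tr: float = 2.46,
                  oversampling: int | None = None) -> np.ndarray:
    """Sample the canonical response at tr / oversampling resolution."""
    spec = spec or HRFSpec()
    if tr <= 0:
        raise ValueError("tr must be positive")
    os_ = spec.oversampling if oversampling is None else oversampling
    dt = tr / os_
    t = np.arange(0.0, spec.length + dt / 2, dt)
    h = (gamma_dist.pdf(t, spec.peak_delay / spec.peak_dispersion,
                        scale=spec.peak_dispersion)
         - gamma_dist.pdf(t, spec.undershoot_delay / spec.undershoot_dispersion,
                          scale=spec.undershoot_dispersion) / spec.ratio)
    return h / h.max()


@dataclass
class DesignMatrix:
    """Per-scan regressor table with named, kinded columns."""

    frame: pd.DataFrame
    kinds: dict[str, str]
    tr: float

    @property
    def n_scans(self) -> int:
        return len(self.frame)

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def copy(self) -> "DesignMatrix":
        return DesignMatrix(self.frame.copy(), dict(self.kinds), self.tr)

    def add_column(self, name: str, values: np.ndarray, kind: str) -> None:
        if name in self.frame.columns:
            raise ValueError(f"duplicate design column {name!r}")
        self.frame[name] = values
        self.kinds[name] = kind

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.values))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, sep="\t", index=False)
        return path


# ---------------------------------------------------------------------------
# regressor assembly


def _convolve_onsets(onsets: Sequence[float], durations: Sequence[float],
                     amplitudes: Sequence[float], tr: float, n_scans: int,
                     kernel: np.ndarray, oversampling: int) -> np.ndarray:
    """Boxcar/stick train -> convolved regressor sampled at scan times."""
    dt = tr / oversampling
    n_fine = n_scans * oversampling
    x = np.zeros(n_fine)
    t_end = n_scans * tr
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        if onset + dur > t_end + 1e-9:
            warnings.warn(
                f"event at {onset:.2f}s (duration {dur:.2f}s) extends beyond "
                f"the scan window of {t_end:.2f}s; truncating", stacklevel=3)
        i0 = int(round(onset / dt))
        if i0 >= n_fine:
            continue
        if dur <= 0:
            x[i0] += amp
        else:
            i1 = min(int(round((onset + dur) / dt)), n_fine)
            x[i0:i1] += amp
    y = np.convolve(x, kernel)[:n_fine]
    return y[::oversampling][:n_scans]


def _dct_basis(n_scans: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine high-pass basis, periods longer than ``cutoff`` s."""
    order = int(np.floor(2.0 * n_scans * tr / cutoff))
    t = np.arange(n_scans)
    cols = [np.sqrt(2.0 / n_scans)
            * np.cos(np.pi * (2 * t + 1) * k / (2.0 * n_scans))
            for k in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def _orthogonalize(col: np.ndarray, against: np.ndarray) -> np.ndarray:
    """Residual of ``col`` after projection onto the columns of ``against``.

    Projects twice (classical reorthogonalisation) so residual dot products
    sit at the rounding floor rather than at lstsq's conditioning floor.
    """
    if against.size == 0:
        return col
    for _ in range(2):
        coef, *_ = np.linalg.lstsq(against, col, rcond=None)
        col = col - against @ coef
    return col


def _levels_present(schedule: TrialSchedule) -> list[str]:
    present = {t.reward_level for t in schedule.trials}
    return [lv for lv in LEVELS if lv in present]


def build_block_design(schedule: TrialSchedule, tr: float, n_scans: int,
                       hrf: HRFSpec | None = None, drift: bool = False,
                       drift_cutoff: float = 128.0) -> DesignMatrix:
    """Boxcar design: cue and patch blocks per reward level, plus intercept.

    Cue and foraging phases get separate unit-height boxcars of their phase
    durations per condition, convolved with the canonical response of equal
    amplitude.  ``drift=True`` appends a discrete-cosine high-pass basis
    (cutoff ``drift_cutoff`` seconds).
    """
    hrf = hrf or HRFSpec()
    kernel = canonical_hrf(hrf, tr)
    cfg = schedule.config
    frame = pd.DataFrame(index=range(n_scans))
    kinds: dict[str, str] = {}
    for level in _levels_present(schedule):
        trials = [t for t in schedule.trials if t.reward_level == level]
        frame[f"cue_{level}"] = _convolve_onsets(
            [t.cue_onset for t in trials], [cfg.cue_duration] * len(trials),
            [1.0] * len(trials), tr, n_scans, kernel, hrf.oversampling)
        kinds[f"cue_{level}"] = "task"
        frame[f"patch_{level}"] = _convolve_onsets(
            [t.patch_onset for t in trials],
            [cfg.patch_duration] * len(trials),
            [1.0] * len(trials), tr, n_scans, kernel, hrf.oversampling)
        kinds[f"patch_{level}"] = "task"
    if drift:
        basis = _dct_basis(n_scans, tr, drift_cutoff)
        for k in range(basis.shape[1]):
            frame[f"drift_{k + 1}"] = basis[:, k]
            kinds[f"drift_{k + 1}"] = "drift"
    frame["intercept"] = 1.0
    kinds["intercept"] = "intercept"
    return DesignMatrix(frame, kinds, tr)


def build_target_event_design(schedule: TrialSchedule, tr: float,
                              n_scans: int,
                              hrf: HRFSpec | None = None) -> DesignMatrix:
    """Event design: one stick per target presentation, per reward level."""
    hrf = hrf or HRFSpec()
    kernel = canonical_hrf(hrf, tr)
    frame = pd.DataFrame(index=range(n_scans))
    kinds: dict[str, str] = {}
    for level in _levels_present(schedule):
        onsets = [tg.onset for tg in schedule.targets(level)]
        col = _convolve_onsets(onsets, [0.0] * len(onsets),
                               [1.0] * len(onsets), tr, n_scans, kernel,
                               hrf.oversampling)
        if not onsets:
            warnings.warn(f"no targets in condition {level!r}; event "
                          "regressor is all-zero", stacklevel=2)
        frame[f"target_{level}"] = col
        kinds[f"target_{level}"] = "task"
    frame["intercept"] = 1.0
    kinds["intercept"] = "intercept"
    return DesignMatrix(frame, kinds, tr)


def _patch_times(schedule: TrialSchedule, level: str
                 ) -> tuple[list[float], list[float]]:
    """Target onsets (absolute) and within-patch times for one condition."""
    onsets, within = [], []
    for trial in schedule.trials:
        if trial.reward_level != level:
            continue
        for tg in trial.targets:
            onsets.append(tg.onset)
            within.append(tg.onset - trial.patch_onset)
    return onsets, within


def add_polynomial_time_modulators(design: DesignMatrix,
                                   schedule: TrialSchedule, degree: int = 4,
                                   hrf: HRFSpec | None = None
                                   ) -> DesignMatrix:
    """Within-patch time raised to powers 1..degree as target modulators.

    For each condition the modulators are mean-centred powers of within-patch
    time applied to the target sticks, convolved, then sequentially
    orthogonalised against the condition's main event regressor and all
    lower-degree modulators (ascending degree, after convolution).
    Requires the design to contain the ``target_<level>`` event columns.
    """
    if degree < 1:
        raise ValueError("polynomial degree must be >= 1")
    hrf = hrf or HRFSpec()
    kernel = canonical_hrf(hrf, design.tr)
    out = design.copy()
    for level in _levels_present(schedule):
        base = f"target_{level}"
        if base not in out.frame.columns:
            raise ValueError(
                f"design lacks the {base!r} event regressor; build the "
                "target event design first")
        onsets, within = _patch_times(schedule, level)
        tau = np.asarray(within)
        lower = [base]
        for d in range(1, degree + 1):
            vals = tau ** d
            centred = vals - vals.mean()
            if np.allclose(centred, 0.0):
                warnings.warn(
                    f"degree-{d} modulator for {level!r} is constant after "
                    "mean-centering; column rejected (rank deficiency)",
                    stacklevel=2)
                continue
            col = _convolve_onsets(onsets, [0.0] * len(onsets), centred,
                                   design.tr, out.n_scans, kernel,
                                   hrf.oversampling)
            col = _orthogonalize(col, out.frame[lower].to_numpy())
            name = f"target_{level}_t{d}"
            out.add_column(name, col, "modulator")
            lower = lower + [name]
    return out


def add_trial_number_modulator(design: DesignMatrix,
                               schedule: TrialSchedule,
                               hrf: HRFSpec | None = None) -> DesignMatrix:
    """Mean-centred trial-number modulation of the cue regressors.

    Adds one column per cue condition whose events are scaled by the
    (centred) trial number, supporting the reward-level x time interaction
    contrast (+1 on the high modulator, -1 on the low one).
    """
    hrf = hrf or HRFSpec()
    kernel = canonical_hrf(hrf, design.tr)
    cfg = schedule.config
    out = design.copy()
    for level in _levels_present(schedule):
        trials = [t for t in schedule.trials if t.reward_level == level]
        if len(trials) < 2:
            raise ValueError(
                f"condition {level!r} has {len(trials)} cue(s); at least two "
                "are needed for a trial-number modulator")
        ranks = np.array([t.index + 1 for t in trials], dtype=float)
        centred = ranks - ranks.mean()
        col = _convolve_onsets([t.cue_onset for t in trials],
                               [cfg.cue_duration] * len(trials), centred,
                               design.tr, out.n_scans, kernel,
                               hrf.oversampling)
        out.add_column(f"cue_{level}_x_trial", col, "modulator")
    return out


def add_quartile_model(design: DesignMatrix, schedule: TrialSchedule,
                       hrf: HRFSpec | None = None) -> DesignMatrix:
    """First- vs last-quartile target regressors within the foraging patch.

    Adds per-condition event columns for targets falling in the first and
    last quarter of the patch, enabling a last-minus-first contrast on signal
    drift within the patch.
    """
    hrf = hrf or HRFSpec()
    kernel = canonical_hrf(hrf, design.tr)
    cfg = schedule.config
    q = cfg.patch_duration / 4.0
    out = design.copy()
    for level in _levels_present(schedule):
        onsets, within = _patch_times(schedule, level)
        onsets = np.asarray(onsets)
        within = np.asarray(within)
        first = onsets[within < q]
        last = onsets[within >= 3.0 * q]
        if first.size == 0 or last.size == 0:
            raise ValueError(
                f"condition {level!r}: foraging patch holds no targets in "
                "its first or last quartile")
        for tag, sel in (("q1", first), ("q4", last)):
            col = _convolve_onsets(sel, [0.0] * sel.size, [1.0] * sel.size,
                                   design.tr, out.n_scans, kernel,
                                   hrf.oversampling)
            out.add_column(f"target_{level}_{tag}", col, "modulator")
    return out


def quartile_contrast(level: str) -> dict[str, float]:
    """Last-minus-first quartile contrast weights for one condition."""
    return {f"target_{level}_q4": 1.0, f"target_{level}_q1": -1.0}
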