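"""First- and second-level general linear models with AR(1) prewhitening.

First level: ordinary least squares per voxel, a single AR(1) coefficient
pooled over voxels from the lag-1 autocorrelation of the OLS residuals, one
Cochrane-Orcutt-style whitening pass of data and design, and re-estimation on
the whitened system.  Degrees of freedom are n_scans - rank(X); no correction
is applied for the AR estimate (a second-order effect at these series
lengths).

Second level: summary-statistics random effects — one-sample t across
subjects' contrast maps, or two-sample t between two cohorts (the
between-experiments interaction).  Voxels with zero residual variance are
flagged and masked out of t maps rather than producing infinities.

Fitted trial time courses combine the cue fit with the patch main effect and
its polynomial expansion on a fine trial grid; the 90% band is mean
+/- 1.645 standard errors of the between-subject mean, point-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.stats import norm

from .design_matrix import (DesignMatrix, HRFSpec, _convolve_onsets,
                            _orthogonalize, canonical_hrf)
from .synth_bold import VolumeSeries
from .task_schedule import TaskConfig


@dataclass
class FirstLevelFit:
    """Per-voxel coefficients and noise estimates from one subject's series."""

    betas: np.ndarray           # (n_columns, *spatial)
    sigma2: np.ndarray          # residual variance map
    ar1: float                  # pooled AR(1) coefficient used for whitening
    dof: int
    names: list[str]
    cov: np.ndarray             # (X'X)^-1 of the whitened design
    shape: tuple[int, ...]
    whitened_resid_ac1: float   # pooled lag-1 autocorr of whitened residuals

    def beta_map(self, name: str) -> np.ndarray:
        return self.betas[self.names.index(name)]


@dataclass
class ContrastResult:
    weights: np.ndarray
    names: list[str]
    effect: np.ndarray
    t: np.ndarray
    se: np.ndarray
    dof: int
    zero_variance: np.ndarray


@dataclass
class GroupResult:
    t: np.ndarray
    effect: np.ndarray
    analysis_type: str
    dof: int
    n: int
    zero_variance: np.ndarray


@dataclass
class TimeCourseFit:
    time: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    per_subject: np.ndarray     # (n_subjects, n_time)


def _as_matrix(series) -> tuple[np.ndarray, tuple[int, ...]]:
    if isinstance(series, VolumeSeries):
        data = series.data
    else:
        data = np.asarray(series, dtype=float)
    shape = data.shape[:-1]
    return data.reshape(-1, data.shape[-1]).T, shape   # (T, V)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> int:
    rank = int(np.linalg.matrix_rank(X))
    if rank < X.shape[1]:
        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        raise ValueError(
            f"design is rank deficient; collinear column(s): {bad}")
    return rank


def _pooled_ac1(resid: np.ndarray) -> float:
    """Lag-1 autocorrelation pooled over all voxels (resid is T x V)."""
    num = float(np.sum(resid[1:] * resid[:-1]))
    den = float(np.sum(resid * resid))
    return num / den if den > 0 else 0.0


def fit_first_level(series, design: DesignMatrix,
                    ar1: float | str = "pooled") -> FirstLevelFit:
    """Fit the voxelwise GLM with one AR(1) prewhitening pass.

    ``ar1`` is ``"pooled"`` (estimate one global coefficient from the OLS
    residuals), ``"none"`` (plain OLS) or a float to impose a coefficient.
    With a zero coefficient the fit coincides with ordinary least squares.
    """
    Y, shape = _as_matrix(series)
    X = design.values.astype(float)
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"series has {Y.shape[0]} scans but design has {X.shape[0]} rows")
    rank = _check_rank(X, design.names)

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    if ar1 == "pooled":
        phi = _pooled_ac1(Y - X @ beta)
    elif ar1 == "none":
        phi = 0.0
    else:
        phi = float(ar1)

    if phi != 0.0:
        w0 = np.sqrt(1.0 - phi * phi)
        Yw = np.empty_like(Y)
        Yw[0] = w0 * Y[0]
        Yw[1:] = Y[1:] - phi * Y[:-1]
        Xw = np.empty_like(X)
        Xw[0] = w0 * X[0]
        Xw[1:] = X[1:] - phi * X[:-1]
    else:
        Yw, Xw = Y, X

    beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    resid = Yw - Xw @ beta
    dof = Y.shape[0] - rank
    sigma2 = (resid ** 2).sum(axis=0) / dof
    cov = np.linalg.inv(Xw.T @ Xw)
    return FirstLevelFit(
        betas=beta.reshape(X.shape[1], *shape),
        sigma2=sigma2.reshape(shape), ar1=phi, dof=dof,
        names=list(design.names), cov=cov, shape=shape,
        whitened_resid_ac1=_pooled_ac1(resid))


def contrast_map(fit: FirstLevelFit,
                 weights: Mapping[str, float]) -> ContrastResult:
    """Weighted coefficient combination with its t map.

    Columns absent from ``weights`` get weight zero; an unknown column name
    raises.  Zero-variance voxels (and an all-zero contrast) yield NaN t
    values and are flagged in ``zero_variance``.
    """
    c = np.zeros(len(fit.names))
    for name, w in weights.items():
        if name not in fit.names:
            raise ValueError(f"unknown design column {name!r}")
        c[fit.names.index(name)] = w
    flat = fit.betas.reshape(len(fit.names), -1)
    effect = (c @ flat).reshape(fit.shape)
    quad = float(c @ fit.cov @ c)
    var = quad * fit.sigma2
    zero = var <= 0
    se = np.sqrt(np.where(zero, np.nan, var))
    with np.errstate(invalid="ignore"):
        t = effect / se
    return ContrastResult(weights=c, names=list(fit.names), effect=effect,
                          t=t, se=se, dof=fit.dof, zero_variance=zero)


def second_level(maps, analysis_type: str = "one_sample",
                 labels: Sequence[int] | None = None) -> GroupResult:
    """Random-effects group analysis on per-subject contrast maps.

    ``one_sample``: t of the voxelwise mean against zero, dof n - 1.
    ``two_sample``: pooled-variance t between the two groups indicated by
    ``labels`` (0/1), dof n0 + n1 - 2.  Zero-variance voxels are flagged and
    carry NaN t values.
    """
    data = np.asarray(list(maps) if not isinstance(maps, np.ndarray) else maps,
                      dtype=float)
    n = data.shape[0]
    if analysis_type == "one_sample":
        if n < 2:
            raise ValueError("one-sample analysis needs at least 2 maps")
        mean = data.mean(axis=0)
        var = data.var(axis=0, ddof=1)
        dof = n - 1
        zero = var <= 0
        se = np.sqrt(np.where(zero, np.nan, var / n))
        with np.errstate(invalid="ignore"):
            t = mean / se
        return GroupResult(t=t, effect=mean, analysis_type=analysis_type,
                           dof=dof, n=n, zero_variance=zero)
    if analysis_type == "two_sample":
        if labels is None:
            raise ValueError("two-sample analysis needs group labels")
        labels = np.asarray(labels)
        g0, g1 = data[labels == 0], data[labels == 1]
        n0, n1 = g0.shape[0], g1.shape[0]
        if n0 < 1 or n1 < 1 or n0 + n1 < 3:
            raise ValueError("each group needs members and pooled dof > 0")
        dof = n0 + n1 - 2
        diff = g1.mean(axis=0) - g0.mean(axis=0)
        ss = (g0.var(axis=0, ddof=0) * n0 + g1.var(axis=0, ddof=0) * n1)
        sp2 = ss / dof
        zero = sp2 <= 0
        se = np.sqrt(np.where(zero, np.nan, sp2 * (1.0 / n0 + 1.0 / n1)))
        with np.errstate(invalid="ignore"):
            t = diff / se
        return GroupResult(t=t, effect=diff, analysis_type=analysis_type,
                           dof=dof, n=n0 + n1, zero_variance=zero)
    raise ValueError(f"unknown analysis type {analysis_type!r}")


# ---------------------------------------------------------------------------
# fitted trial time courses


def single_trial_bank(task_config: TaskConfig | None = None,
                      hrf: HRFSpec | None = None, dt: float = 0.1,
                      degree: int = 4,
                      target_onsets: Sequence[float] | None = None
                      ) -> pd.DataFrame:
    """Regressor bank for one trial on a fine time grid.

    Columns: ``cue`` (cue boxcar), ``patch`` (target-event main effect) and
    ``t1``..``t<degree>`` (centred within-patch time powers, sequentially
    orthogonalised as in the full design).  ``target_onsets`` are seconds
    within the patch; by default targets sit at regular spacing.
    """
    cfg = task_config or TaskConfig()
    hrf = hrf or HRFSpec()
    kernel = canonical_hrf(hrf, dt, oversampling=1)
    n = int(np.ceil(cfg.trial_duration / dt)) + 1
    patch_onset = cfg.cue_duration + cfg.interval_duration
    if target_onsets is None:
        gap = cfg.regular_interval / 1000.0
        target_onsets = np.arange(gap, cfg.patch_duration + 1e-9, gap)
    tau = np.asarray(target_onsets, dtype=float)
    onsets = patch_onset + tau

    frame = pd.DataFrame({"time": np.arange(n) * dt})
    frame["cue"] = _convolve_onsets([0.0], [cfg.cue_duration], [1.0], dt, n,
                                    kernel, 1)
    frame["patch"] = _convolve_onsets(onsets, [0.0] * tau.size,
                                      [1.0] * tau.size, dt, n, kernel, 1)
    lower = ["patch"]
    for d in range(1, degree + 1):
        vals = tau ** d
        centred = vals - vals.mean()
        col = _convolve_onsets(onsets, [0.0] * tau.size, centred, dt, n,
                               kernel, 1)
        col = _orthogonalize(col, frame[lower].to_numpy())
        frame[f"t{d}"] = col
        lower = lower + [f"t{d}"]
    return frame.set_index("time")


def fitted_time_course(per_subject_betas: Sequence[Mapping[str, float]],
                       bank: pd.DataFrame,
                       columns: Sequence[str] | None = None,
                       ci: float = 0.90) -> TimeCourseFit:
    """Per-condition fitted BOLD curve with a point-wise confidence band.

    Each subject's curve is the bank columns weighted by that subject's
    coefficients; the band is mean +/- z * between-subject standard error at
    each time point (z = 1.645 for the default 90% band).  Missing
    coefficient names raise (e.g. absent polynomial columns).
    """
    columns = list(columns) if columns is not None else list(bank.columns)
    for name in columns:
        if name not in bank.columns:
            raise ValueError(f"bank lacks column {name!r}")
    curves = []
    for betas in per_subject_betas:
        missing = [c for c in columns if c not in betas]
        if missing:
            raise ValueError(f"subject fit lacks coefficient(s) {missing}")
        curves.append(sum(betas[c] * bank[c].to_numpy() for c in columns))
    curves = np.asarray(curves)
    n = curves.shape[0]
    mean = curves.mean(axis=0)
    se = curves.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 \
        else np.zeros_like(mean)
    z = float(norm.ppf(0.5 + ci / 2.0))
    return TimeCourseFit(time=bank.index.to_numpy(), mean=mean,
                         lower=mean - z * se, upper=mean + z * se,
                         per_subject=curves)
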