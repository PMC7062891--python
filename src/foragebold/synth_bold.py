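"""Synthetic multi-subject 4-D BOLD data with planted region effects.

A phantom is a small voxel grid (RAS orientation, centred on the origin so
voxel centres carry MNI-like millimetre coordinates) holding named box
regions: a "VS" box standing in for the ventral striatum, where a cue effect
is planted, and a "VTA_SN" box in the midbrain, where the foraging-patch
effect is planted.  Geometry is schematic, not anatomical.

Each subject's voxel time series is

    baseline + sum_regressor amplitude(region, regressor) * regressor(t)
             + AR(1) Gaussian noise (+ optional slow sinusoidal drift),

the exact generative counterpart of the autoregressive model the estimator
assumes.  With ``baseline = 100`` the amplitude and noise units read as
percent signal change.  Cohorts draw per-subject amplitudes around the group
mean (between-subject Gaussian deviations), realising the random-effects
structure the second-level analysis models; a master seed splits into
per-subject streams so cohorts are reproducible and extensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from .design_matrix import DesignMatrix

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))    # ~2.3548

# group-mean amplitudes: {region: {design column: % signal}}
Amplitudes = Mapping[str, Mapping[str, float]]


@dataclass(frozen=True)
class NoiseSpec:
    """Temporal noise model: white sd (% signal), AR(1) coefficient, drift."""

    sd: float = 1.0
    ar1: float = 0.2
    drift_amplitude: float = 0.0
    drift_period: float = 128.0
    baseline: float = 100.0

    def __post_init__(self) -> None:
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError("ar1 coefficient must lie in (-1, 1)")
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.drift_period <= 0:
            raise ValueError("drift_period must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size and between-subject amplitude variability."""

    n_subjects: int
    between_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("a cohort needs at least one subject")
        if self.between_sd < 0:
            raise ValueError("between-subject sd must be non-negative")


@dataclass
class Phantom:
    """Voxel grid with named region masks."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray
    regions: dict[str, np.ndarray]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def region_volume(self, name: str) -> float:
        """Region volume in cubic millimetres."""
        return float(self.regions[name].sum()) * self.voxel_volume


@dataclass
class VolumeSeries:
    """4-D intensity grid (x, y, z, t) with scan timing and orientation."""

    data: np.ndarray
    tr: float
    affine: np.ndarray
    subject_id: str = "sub-00"

    @property
    def n_scans(self) -> int:
        return self.data.shape[-1]

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        zooms = tuple(img.header.get_zooms()[:3]) + (self.tr,)
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
        return img

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        nib.save(self.to_nifti(), str(path))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path,
                   subject_id: str = "sub-00") -> "VolumeSeries":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        tr = float(img.header.get_zooms()[3]) if len(
            img.header.get_zooms()) > 3 else 0.0
        return cls(data=data, tr=tr, affine=np.asarray(img.affine),
                   subject_id=subject_id)


def centered_affine(shape: Sequence[int],
                    voxel_size: Sequence[float]) -> np.ndarray:
    """RAS affine placing the grid centre at the world origin."""
    shape = np.asarray(shape)
    vox = np.asarray(voxel_size, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vox)
    affine[:3, 3] = -(shape - 1) / 2.0 * vox
    return affine


def build_phantom(shape: Sequence[int], voxel_size: Sequence[float] | float,
                  region_specs: Mapping[str, Sequence[tuple[int, int]]],
                  allow_overlap: bool = False) -> Phantom:
    """Assemble a phantom from per-region voxel-index boxes.

    ``region_specs`` maps a region name to three (start, stop) index pairs.
    Regions must fit inside the grid and, unless declared additive via
    ``allow_overlap``, must not overlap.
    """
    shape = tuple(int(s) for s in shape)
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    voxel_size = tuple(float(v) for v in voxel_size)
    regions: dict[str, np.ndarray] = {}
    occupied = np.zeros(shape, dtype=bool)
    for name, box in region_specs.items():
        mask = np.zeros(shape, dtype=bool)
        slices = []
        for ax, (start, stop) in enumerate(box):
            if start < 0 or stop > shape[ax] or stop <= start:
                raise ValueError(
                    f"region {name!r} exceeds the grid on axis {ax}: "
                    f"({start}, {stop}) vs extent {shape[ax]}")
            slices.append(slice(start, stop))
        mask[tuple(slices)] = True
        if not allow_overlap and (occupied & mask).any():
            raise ValueError(f"region {name!r} overlaps an earlier region")
        occupied |= mask
        regions[name] = mask
    return Phantom(shape=shape, voxel_size=voxel_size,
                   affine=centered_affine(shape, voxel_size), regions=regions)


def default_phantom(voxel_size: float = 3.0) -> Phantom:
    """Two-region default phantom on a 20 x 24 x 18 grid.

    The "VS" box sits inside the ventral-striatum ROI (around y ~ +6 mm),
    the "VTA_SN" box in the midbrain (around y ~ -20, z ~ -14 mm); both are
    4 x 4 x 4 voxels and disjoint.
    """
    return build_phantom((20, 24, 18), voxel_size, {
        "VS": ((8, 12), (12, 16), (5, 9)),
        "VTA_SN": ((10, 14), (3, 7), (2, 6)),
    })


# ---------------------------------------------------------------------------
# simulation


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...], n_scans: int,
               sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) series along the last axis, marginal sd ``sd``."""
    out = np.empty(shape + (n_scans,))
    if sd == 0.0:
        out[:] = 0.0
        return out
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    out[..., 0] = rng.normal(0.0, sd, size=shape)
    eps = rng.normal(0.0, innov_sd, size=shape + (n_scans - 1,))
    for t in range(1, n_scans):
        out[..., t] = phi * out[..., t - 1] + eps[..., t - 1]
    return out


def _expected_signal(phantom: Phantom, design: DesignMatrix,
                     amplitudes: Amplitudes) -> np.ndarray:
    signal = np.zeros(phantom.shape + (design.n_scans,))
    for region, effects in amplitudes.items():
        if region not in phantom.regions:
            raise ValueError(f"unknown phantom region {region!r}")
        mask = phantom.regions[region]
        for column, amp in effects.items():
            if column not in design.frame.columns:
                raise ValueError(
                    f"unknown design column {column!r} for region {region!r}")
            signal[mask] += amp * design.frame[column].to_numpy()
    return signal


def simulate_subject(phantom: Phantom, design: DesignMatrix,
                     noise: NoiseSpec, amplitudes: Amplitudes,
                     seed: int | np.random.SeedSequence = 0,
                     subject_id: str = "sub-00") -> VolumeSeries:
    """Forward-simulate one subject's 4-D series; deterministic given seed."""
    rng = np.random.default_rng(seed)
    data = noise.baseline + _expected_signal(phantom, design, amplitudes)
    data += _ar1_noise(rng, phantom.shape, design.n_scans, noise.sd,
                       noise.ar1)
    if noise.drift_amplitude:
        t = np.arange(design.n_scans) * design.tr
        data += noise.drift_amplitude * np.cos(
            2.0 * np.pi * t / noise.drift_period)
    return VolumeSeries(data=data, tr=design.tr, affine=phantom.affine,
                        subject_id=subject_id)


def draw_subject_amplitudes(group: Amplitudes, between_sd: float,
                            rng: np.random.Generator) -> dict:
    """Group mean + Gaussian between-subject deviation, per region effect."""
    return {region: {col: mean + rng.normal(0.0, between_sd)
                     for col, mean in effects.items()}
            for region, effects in group.items()}


def simulate_cohort(phantom: Phantom, design: DesignMatrix, noise: NoiseSpec,
                    cohort: CohortSpec, group_amplitudes: Amplitudes
                    ) -> list[VolumeSeries]:
    """Simulate a cohort with random per-subject effect amplitudes.

    The master seed is split into independent per-subject streams
    (SeedSequence spawning), one for the amplitude draw and one for the
    noise, so any subject's data can be regenerated in isolation.
    """
    out = []
    children = np.random.SeedSequence(cohort.seed).spawn(cohort.n_subjects)
    for i, child in enumerate(children):
        amp_seed, noise_seed = child.spawn(2)
        amps = draw_subject_amplitudes(
            group_amplitudes, cohort.between_sd,
            np.random.default_rng(amp_seed))
        out.append(simulate_subject(phantom, design, noise, amps,
                                    seed=noise_seed,
                                    subject_id=f"sub-{i:02d}"))
    return out


# ---------------------------------------------------------------------------
# spatial smoothing


def gaussian_smooth(data: np.ndarray | VolumeSeries, fwhm_mm: float,
                    voxel_size: Sequence[float] | float = 3.0):
    """Separable Gaussian spatial smoothing of a 3-D map or 4-D series.

    ``fwhm = 0`` is the identity.  Borders are renormalised by the smoothed
    support (kernel-mass correction), so flat images stay flat: the kernel
    mass seen by every voxel is exactly one and constant volumes keep their
    spatial mean to numerical precision.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if isinstance(data, VolumeSeries):
        vox = np.abs(np.diag(data.affine)[:3])
        smoothed = gaussian_smooth(data.data, fwhm_mm, vox)
        return VolumeSeries(data=smoothed, tr=data.tr, affine=data.affine,
                            subject_id=data.subject_id)
    arr = np.asarray(data, dtype=float)
    if fwhm_mm == 0:
        return arr.copy()
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    sigma = tuple(fwhm_mm / FWHM_TO_SIGMA / v for v in voxel_size)
    if arr.ndim == 4:
        sigma = sigma + (0.0,)
    elif arr.ndim != 3:
        raise ValueError("expected a 3-D map or 4-D series")
    smoothed = gaussian_filter(arr, sigma=sigma, mode="constant")
    norm = gaussian_filter(np.ones(arr.shape[:3]), sigma=sigma[:3],
                           mode="constant")
    if arr.ndim == 4:
        norm = norm[..., None]
    return smoothed / norm


def write_cohort(series: Sequence[VolumeSeries], out_dir: str | Path,
                 seeds: Sequence[int] | None = None) -> Path:
    """Write per-subject NIfTI files plus a tab-separated manifest."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, vs in enumerate(series):
        path = out_dir / f"{vs.subject_id}_bold.nii.gz"
        vs.save(path)
        rows.append((vs.subject_id, str(path),
                     seeds[i] if seeds is not None else ""))
    manifest = out_dir / "cohort.tsv"
    pd.DataFrame(rows, columns=["subject", "path", "seed"]).to_csv(
        manifest, sep="\t", index=False)
    return manifest
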