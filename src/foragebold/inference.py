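"""Permutation-based family-wise-error-corrected inference on group maps.

Corrected significance comes from the permutation distribution of the
maximal statistic: for each resample the largest t value over the search
volume (peak-level correction) and the size of the largest supra-threshold
cluster (cluster-level correction, cluster-defining threshold expressed as
an uncorrected one-sided p) are recorded.  For a one-sample design the
exchangeable resampling scheme is random sign flipping of the subject
contrast maps (valid under symmetric errors); for a two-sample design it is
random relabelling of group membership.  When the group is small enough that
all sign patterns fit in the requested budget, the null is enumerated
exhaustively and p-values are exact; otherwise p = (1 + #{null >= observed})
/ (1 + n_perm), which counts the identity permutation and can never reach
zero.  Tests are one-sided (contrasts are directional); ties count against
the observed value.

Search volumes are whole-volume masks or region-of-interest boxes; the
built-in ventral-striatum box spans x -12..+12, y 0..+12, z -12..+6 mm
(5184 mm^3).  A configurable "midbrain" surrogate box is provided for
small-volume correction around the VTA/SN; it is schematic and makes no
claim of anatomical equivalence to a hand-drawn mask.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import t as t_dist

from .glm import second_level

CONNECTIVITY_STRUCTS = {6: 1, 18: 2, 26: 3}

BUILTIN_ROIS: dict[str, tuple[tuple[float, float], ...]] = {
    # ventral-striatum box, world-mm bounds per axis
    "ventral_striatum": ((-12.0, 12.0), (0.0, 12.0), (-12.0, 6.0)),
    # schematic midbrain box around the VTA/SN
    "midbrain": ((-14.0, 14.0), (-34.0, -6.0), (-24.0, 0.0)),
}


@dataclass
class ROIMask:
    mask: np.ndarray
    name: str
    volume_mm3: float           # analytic volume of the defining box
    voxel_volume: float

    @property
    def rasterized_volume(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume


@dataclass
class PermutationNull:
    n_perm: int
    max_peak: np.ndarray
    max_cluster: np.ndarray
    cdt_p: float
    threshold: float
    connectivity: int
    seed: int
    exhaustive: bool


@dataclass
class Cluster:
    label: int
    extent: int
    peak_index: tuple[int, int, int]
    peak_t: float
    p_cluster: float
    p_peak: float


@dataclass
class PermutationResult:
    null: PermutationNull
    t_map: np.ndarray
    dof: int
    mask: np.ndarray
    clusters: list[Cluster]
    p_peak_map: np.ndarray      # corrected peak-level p per in-mask voxel


# ---------------------------------------------------------------------------
# regions of interest


def world_coords(shape: Sequence[int], affine: np.ndarray) -> np.ndarray:
    """(x, y, z, 3) array of voxel-centre world coordinates."""
    idx = np.indices(tuple(shape)).reshape(3, -1)
    hom = np.vstack([idx, np.ones(idx.shape[1])])
    xyz = (np.asarray(affine) @ hom)[:3]
    return xyz.T.reshape(tuple(shape) + (3,))


def box_roi(name: str, bounds: Sequence[tuple[float, float]],
            shape: Sequence[int], affine: np.ndarray) -> ROIMask:
    """Rasterise an axis-aligned world-space box onto the analysis grid.

    Voxels whose centres fall in the half-open box [lo, hi) are included;
    the reported volume is the analytic box volume, which the rasterised
    voxel count matches to within one voxel layer.
    """
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    for ax, (lo, hi) in enumerate(bounds):
        if hi <= lo:
            raise ValueError(f"degenerate ROI box on axis {ax}: ({lo}, {hi})")
    coords = world_coords(shape, affine)
    mask = np.ones(tuple(shape), dtype=bool)
    for ax, (lo, hi) in enumerate(bounds):
        mask &= (coords[..., ax] >= lo) & (coords[..., ax] < hi)
    volume = float(np.prod([hi - lo for lo, hi in bounds]))
    voxvol = float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))
    return ROIMask(mask=mask, name=name, volume_mm3=volume,
                   voxel_volume=voxvol)


def builtin_roi(name: str, shape: Sequence[int],
                affine: np.ndarray) -> ROIMask:
    """Named built-in ROI box ('ventral_striatum' or 'midbrain')."""
    if name not in BUILTIN_ROIS:
        raise ValueError(f"unknown ROI {name!r}; available: "
                         f"{sorted(BUILTIN_ROIS)}")
    return box_roi(name, BUILTIN_ROIS[name], shape, affine)


# ---------------------------------------------------------------------------
# clustering


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(
        3, CONNECTIVITY_STRUCTS[connectivity])


def define_clusters(stat_map: np.ndarray, threshold: float,
                    mask: np.ndarray | None = None,
                    connectivity: int = 18) -> tuple[np.ndarray, int]:
    """Connected supra-threshold components within the mask.

    Default 18-connectivity merges face- or edge-touching voxels; corner
    contact only merges under 26-connectivity.
    """
    if mask is None:
        mask = np.ones(stat_map.shape, dtype=bool)
    if not mask.any():
        raise ValueError("cluster search mask is empty")
    supra = np.where(np.isnan(stat_map), False, stat_map > threshold) & mask
    return ndimage.label(supra, structure=_structure(connectivity))


def _max_cluster_size(stat_vals: np.ndarray, mask: np.ndarray,
                      threshold: float, structure: np.ndarray,
                      buf: np.ndarray) -> int:
    buf[mask] = stat_vals
    supra = buf > threshold
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels[supra]).max())


# ---------------------------------------------------------------------------
# permutation engine


def _sign_matrix(n: int, n_perm: int, rng: np.random.Generator
                 ) -> tuple[np.ndarray, bool]:
    if 2 ** n <= n_perm:
        warnings.warn(
            f"2^{n} = {2 ** n} sign patterns <= {n_perm} requested "
            "permutations; enumerating the null exhaustively", stacklevel=3)
        signs = np.array(list(itertools.product((-1.0, 1.0), repeat=n)))
        return signs, True
    return rng.choice((-1.0, 1.0), size=(n_perm, n)), False


def _one_sample_t(signs: np.ndarray, data: np.ndarray,
                  ss: np.ndarray) -> np.ndarray:
    """t maps for a block of sign-flip resamples (signs is B x n)."""
    n = data.shape[0]
    means = signs @ data / n
    var = (ss - n * means ** 2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    return np.where(var > 0, t, 0.0)


def _perm_p(count: int | np.ndarray, total: int, exhaustive: bool):
    if exhaustive:
        return np.maximum(count, 1) / total
    return (1 + count) / (1 + total)


def permutation_correct(maps, mask: np.ndarray | None = None,
                        n_perm: int = 6000, cdt_p: float = 0.001,
                        analysis_type: str = "one_sample",
                        labels: Sequence[int] | None = None,
                        connectivity: int = 18, seed: int = 0,
                        compute_clusters: bool = True,
                        block: int = 500) -> PermutationResult:
    """Max-statistic permutation correction of a group analysis.

    Builds the null distributions of the largest peak t and largest cluster
    size over the search volume, and attaches corrected p-values to the
    observed peaks and clusters.  ``cdt_p`` is the uncorrected one-sided
    cluster-defining threshold (conventionally 0.001 whole-volume, 0.01
    within a region of interest).
    """
    data4 = np.asarray(list(maps) if not isinstance(maps, np.ndarray)
                       else maps, dtype=float)
    n = data4.shape[0]
    shape = data4.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    if not mask.any():
        raise ValueError("search mask is empty")
    if analysis_type not in ("one_sample", "two_sample"):
        raise ValueError(f"unknown analysis type {analysis_type!r}")

    group = second_level(data4, analysis_type, labels)
    t_map = group.t
    dof = group.dof
    threshold = float(t_dist.isf(cdt_p, dof))
    structure = _structure(connectivity)
    rng = np.random.default_rng(seed)
    data = data4[:, mask]                       # (n, V)

    if analysis_type == "one_sample":
        signs, exhaustive = _sign_matrix(n, n_perm, rng)
        n_draws = signs.shape[0]
        ss = (data ** 2).sum(axis=0)
        max_peak = np.empty(n_draws)
        max_cluster = np.zeros(n_draws, dtype=int)
        buf = np.full(shape, -np.inf)
        for start in range(0, n_draws, block):
            t_null = _one_sample_t(signs[start:start + block], data, ss)
            max_peak[start:start + len(t_null)] = t_null.max(axis=1)
            if compute_clusters:
                for j, row in enumerate(t_null):
                    max_cluster[start + j] = _max_cluster_size(
                        row, mask, threshold, structure, buf)
    else:
        labels = np.asarray(labels)
        n1 = int((labels == 1).sum())
        exhaustive = comb(n, n1) <= n_perm
        if exhaustive:
            warnings.warn(
                f"C({n},{n1}) = {comb(n, n1)} relabellings <= {n_perm} "
                "requested permutations; enumerating exhaustively",
                stacklevel=2)
            combos = itertools.combinations(range(n), n1)
            lab_draws = np.zeros((comb(n, n1), n), dtype=int)
            for i, idx in enumerate(combos):
                lab_draws[i, list(idx)] = 1
        else:
            lab_draws = np.array([rng.permutation(labels)
                                  for _ in range(n_perm)])
        n_draws = lab_draws.shape[0]
        max_peak = np.empty(n_draws)
        max_cluster = np.zeros(n_draws, dtype=int)
        buf = np.full(shape, -np.inf)
        for i, lab in enumerate(lab_draws):
            g = second_level(data, "two_sample", lab)
            row = np.where(np.isnan(g.t), 0.0, g.t)
            max_peak[i] = row.max()
            if compute_clusters:
                max_cluster[i] = _max_cluster_size(row, mask, threshold,
                                                   structure, buf)

    null = PermutationNull(n_perm=n_draws, max_peak=max_peak,
                           max_cluster=max_cluster, cdt_p=cdt_p,
                           threshold=threshold, connectivity=connectivity,
                           seed=seed, exhaustive=exhaustive)

    # corrected peak-level p per in-mask voxel
    sorted_peaks = np.sort(max_peak)
    tvec = np.where(np.isnan(t_map[mask]), -np.inf, t_map[mask])
    counts = n_draws - np.searchsorted(sorted_peaks, tvec, side="left")
    p_peak_map = np.full(shape, np.nan)
    p_peak_map[mask] = _perm_p(counts, n_draws, exhaustive)

    clusters: list[Cluster] = []
    if compute_clusters:
        label_img, n_clusters = define_clusters(t_map, threshold, mask,
                                                connectivity)
        sorted_sizes = np.sort(max_cluster)
        for lab in range(1, n_clusters + 1):
            voxels = np.argwhere(label_img == lab)
            ts = t_map[tuple(voxels.T)]
            peak_pos = voxels[int(np.argmax(ts))]
            extent = int(voxels.shape[0])
            k_count = n_draws - int(np.searchsorted(sorted_sizes, extent,
                                                    side="left"))
            p_count = n_draws - int(np.searchsorted(sorted_peaks,
                                                    float(ts.max()),
                                                    side="left"))
            clusters.append(Cluster(
                label=lab, extent=extent,
                peak_index=tuple(int(v) for v in peak_pos),
                peak_t=float(ts.max()),
                p_cluster=float(_perm_p(k_count, n_draws, exhaustive)),
                p_peak=float(_perm_p(p_count, n_draws, exhaustive))))
        clusters.sort(key=lambda c: c.peak_t, reverse=True)
    return PermutationResult(null=null, t_map=t_map, dof=dof, mask=mask,
                             clusters=clusters, p_peak_map=p_peak_map)


def cluster_report(result: PermutationResult,
                   affine: np.ndarray | None = None) -> pd.DataFrame:
    """Cluster table: peak world coordinates, extent, corrected p-values."""
    rows = []
    for c in result.clusters:
        if affine is not None:
            xyz = (np.asarray(affine)
                   @ np.array([*c.peak_index, 1.0]))[:3]
        else:
            xyz = np.asarray(c.peak_index, dtype=float)
        rows.append((c.label, *np.round(xyz, 3), c.extent, c.p_cluster,
                     c.peak_t, c.p_peak))
    return pd.DataFrame(rows, columns=["cluster", "x", "y", "z", "k",
                                       "p_cluster", "t", "p_peak"])
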