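"""Voxel-based morphometry between diagnostic groups.

Mass-univariate two-sample t-tests (classical pooled-variance, two-tailed)
at every masked voxel for each group pair, Bonferroni correction over the
mask (p < alpha / m), zeroing of non-significant voxels, min-max
normalization of the surviving |t| values and a final > 0.75 cut -- the
same rendering rule as the activation brains, so the two surfaces are
directly comparable. For TLE contrasts, left-lateralized subjects'
volumes are mirrored about the midsagittal plane first so results read as
ipsilateral/contralateral.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import AtlasDefinition
from .grids import GridSpec

__all__ = [
    "VBMMap",
    "voxelwise_ttest",
    "bonferroni_threshold_normalize",
    "vbm_roi_summary",
    "run_vbm_contrast",
]


@dataclass
class VBMMap:
    """Min-max-normalized surviving |t| map for one group pair."""

    pair: tuple[str, str]
    data: np.ndarray                     # normalized |t|, 0 off-support
    grid: GridSpec
    n_a: int
    n_b: int
    raw_t: np.ndarray = field(repr=False, default=None)
    raw_p: np.ndarray = field(repr=False, default=None)
    n_tests: int = 0


def voxelwise_ttest(
    group_a: np.ndarray,
    group_b: np.ndarray,
    mask: np.ndarray,
    welch: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel classical (pooled-variance) two-sample t, two-tailed p.

    ``group_a``/``group_b`` are stacks (n_subjects, *grid); voxels outside
    ``mask`` get t = 0, p = 1. Zero pooled variance at a voxel yields
    p = 1 (logged), never NaN. ``welch=True`` drops the equal-variance
    assumption.
    """
    if group_a.shape[0] < 2 or group_b.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    if group_a.shape[1:] != group_b.shape[1:] or group_a.shape[1:] != mask.shape:
        raise ValueError("groups and mask must share one grid")
    a = group_a.reshape(group_a.shape[0], -1)[:, mask.ravel()]
    b = group_b.reshape(group_b.shape[0], -1)[:, mask.ravel()]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} voxels with zero pooled variance; p set to 1"
        )
        t[bad] = 0.0
        p[bad] = 1.0
    t_grid = np.zeros(mask.shape, dtype=np.float64)
    p_grid = np.ones(mask.shape, dtype=np.float64)
    t_grid[mask] = t
    p_grid[mask] = p
    return t_grid, p_grid


def bonferroni_threshold_normalize(
    t_grid: np.ndarray,
    p_grid: np.ndarray,
    mask: np.ndarray,
    grid: GridSpec,
    pair: tuple[str, str] = ("A", "B"),
    alpha: float = 0.05,
    cut: float = 0.75,
    n_a: int = 0,
    n_b: int = 0,
) -> VBMMap:
    """Keep voxels with p < alpha/m (m = masked voxel count), min-max
    normalize the surviving |t| values, then keep values > ``cut``.

    A single survivor normalizes to 1 (max maps to 1 in the degenerate
    case); no survivors yields an empty map with a warning.
    """
    m = int(mask.sum())
    if m == 0:
        raise ValueError("empty analysis mask")
    thr = alpha / m
    surviving = mask & (p_grid < thr)
    out = np.zeros_like(t_grid, dtype=np.float64)
    if not surviving.any():
        warnings.warn(f"no Bonferroni-surviving voxels for {pair} (p < {thr:g})")
    else:
        vals = np.abs(t_grid[surviving])
        lo, hi = vals.min(), vals.max()
        norm = (vals - lo) / (hi - lo) if hi > lo else np.ones_like(vals)
        norm = np.where(norm > cut, norm, 0.0)
        out[surviving] = norm
    return VBMMap(
        pair=pair, data=out, grid=grid, n_a=n_a, n_b=n_b,
        raw_t=t_grid, raw_p=p_grid, n_tests=m,
    )


def run_vbm_contrast(
    volumes_a: list[np.ndarray],
    volumes_b: list[np.ndarray],
    mask: np.ndarray,
    grid: GridSpec,
    pair: tuple[str, str],
    alpha: float = 0.05,
    cut: float = 0.75,
    mirror_a: np.ndarray | None = None,
    mirror_b: np.ndarray | None = None,
    welch: bool = False,
) -> VBMMap:
    """t-test + Bonferroni + normalization for one group pair.

    ``mirror_a``/``mirror_b`` are boolean per-subject flags marking
    volumes to reflect about the midsagittal plane before testing
    (left-lateralized TLE subjects)."""

    def stack(vols, flags):
        arr = np.stack([np.asarray(v, dtype=np.float64) for v in vols])
        if flags is not None:
            for i in np.flatnonzero(np.asarray(flags)):
                arr[i] = np.flip(arr[i], axis=0)
        return arr

    grid.mirror_index_map()  # validate before any flip
    a = stack(volumes_a, mirror_a)
    b = stack(volumes_b, mirror_b)
    t_grid, p_grid = voxelwise_ttest(a, b, mask, welch=welch)
    return bonferroni_threshold_normalize(
        t_grid, p_grid, mask, grid, pair=pair, alpha=alpha, cut=cut,
        n_a=len(volumes_a), n_b=len(volumes_b),
    )


def vbm_roi_summary(vbm_map: VBMMap, atlas: AtlasDefinition) -> pd.Series:
    """Per-ROI mean of the normalized map (one ROI-matrix row)."""
    if not vbm_map.grid.matches(atlas.grid):
        raise ValueError("atlas grid does not match VBM map grid")
    row = {}
    for rec in atlas.roi_table.itertuples(index=False):
        m = atlas.label_volume == rec.label
        col = f"{rec.name} ({rec.hemisphere})"
        row[col] = float(vbm_map.data[m].mean()) if m.any() else np.nan
    return pd.Series(row, name="-vs-".join(vbm_map.pair))
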