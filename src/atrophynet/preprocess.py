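"""Preprocessing downstream of normalization/segmentation.

Chain (in pipeline order): 10 mm FWHM Gaussian smoothing, gray-matter
probability thresholding (strictly > 0.20), extraction of the middle axial
slices (-29 to +28 mm on the full grid; 58 planes), labeling by diagnosis,
and voxel-wise linear age residualization fitted across participants.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .grids import GMVolume, GridSpec

__all__ = [
    "SliceRecord",
    "SliceDataset",
    "fwhm_to_sigma",
    "smooth_volume",
    "threshold_gm",
    "extract_slices",
    "AgeResidualizer",
    "preprocess_volumes",
    "build_slice_dataset",
]

_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma (mm) for a given full width at half maximum."""
    return fwhm_mm / _FWHM_FACTOR


def smooth_volume(vol: GMVolume, fwhm_mm: float = 10.0) -> GMVolume:
    """3D Gaussian smoothing with per-axis sigma converted to voxel units
    via the affine. Nearest-edge boundary handling preserves constants."""
    if fwhm_mm <= 0:
        raise ValueError(f"fwhm_mm must be positive, got {fwhm_mm}")
    sigma_vox = fwhm_to_sigma(fwhm_mm) / vol.grid.voxel_sizes
    out = ndimage.gaussian_filter(
        vol.data.astype(np.float64), sigma=sigma_vox, mode="nearest"
    )
    return vol.with_data(out)


def threshold_gm(
    vol: GMVolume, min_prob: float = 0.20
) -> tuple[GMVolume, np.ndarray]:
    """Keep voxels strictly above ``min_prob``; others are zeroed and
    excluded from the analysis mask. Returns (volume, boolean mask)."""
    mask = vol.data > min_prob
    out = np.where(mask, vol.data, 0.0)
    return vol.with_data(out), mask


@dataclass
class SliceRecord:
    """One labeled 2D axial slice, the classifier's unit of analysis."""

    pixels: np.ndarray
    z_mm: int
    subject_id: str
    label: str


def extract_slices(
    vol: GMVolume,
    label: str,
    z_lo_mm: int | None = None,
    z_hi_mm: int | None = None,
) -> list[SliceRecord]:
    """One SliceRecord per integer-mm axial plane with z in the closed
    interval [z_lo_mm, z_hi_mm], ordered by ascending z. Defaults come
    from the grid (full grid: [-29, +28] -> 58 slices)."""
    grid = vol.grid
    if z_lo_mm is None:
        z_lo_mm = grid.default_z_range[0]
    if z_hi_mm is None:
        z_hi_mm = grid.default_z_range[1]
    zmin, zmax = grid.z_range_mm()
    if z_lo_mm < zmin or z_hi_mm > zmax:
        raise ValueError(
            f"requested z-range [{z_lo_mm}, {z_hi_mm}] mm outside the "
            f"volume's axial extent [{zmin:g}, {zmax:g}] mm"
        )
    if z_lo_mm > z_hi_mm:
        raise ValueError("z_lo_mm must be <= z_hi_mm")
    records = []
    for z in range(int(np.ceil(z_lo_mm)), int(np.floor(z_hi_mm)) + 1):
        k = grid.index_of_z(z)
        k_int = int(round(k))
        if abs(k - k_int) > 1e-6:
            continue  # no voxel plane centered at this integer mm
        records.append(
            SliceRecord(
                pixels=np.asarray(vol.data[:, :, k_int]),
                z_mm=z,
                subject_id=vol.subject_id,
                label=label,
            )
        )
    return records


class AgeResidualizer(TransformerMixin, BaseEstimator):
    """Voxel-wise linear age regression.

    Fits, independently at every voxel, ordinary least squares of
    gray-matter value on age across the fit population, and replaces each
    value with its residual (observed minus the age-predicted value).
    Residuals may be negative; they are the classifier's input.

    The study design fits this on *all* participants (train, validation
    and test alike), which leaks distributional information across the
    split; callers wanting the leak-free variant simply fit on the
    training subjects only.

    Attributes
    ----------
    slope_ : ndarray, GM units per year, one per voxel/feature
    intercept_ : ndarray, GM units at age 0
    fit_population_ : list of subject ids used in the fit
    """

    def fit(self, X, age, subject_ids=None):
        X = np.asarray(X, dtype=np.float64)
        age = np.asarray(age, dtype=np.float64)
        if X.shape[0] != age.shape[0]:
            raise ValueError("X and age have different numbers of subjects")
        if np.unique(age).size < 2:
            raise ValueError("all ages identical: age regression is singular")
        if np.unique(age).size < 3:
            warnings.warn("fewer than 3 distinct ages; fit is exact but fragile")
        self._feature_shape = X.shape[1:]
        flat = X.reshape(X.shape[0], -1)
        a = age - age.mean()
        denom = (a**2).sum()
        slope = (a @ (flat - flat.mean(axis=0))) / denom
        intercept = flat.mean(axis=0) - slope * age.mean()
        self.slope_ = slope.reshape(self._feature_shape)
        self.intercept_ = intercept.reshape(self._feature_shape)
        self.fit_population_ = (
            list(subject_ids) if subject_ids is not None else list(range(len(age)))
        )
        return self

    def transform(self, X, age):
        if not hasattr(self, "slope_"):
            raise ValueError("AgeResidualizer is not fitted")
        X = np.asarray(X, dtype=np.float64)
        age = np.asarray(age, dtype=np.float64)
        if np.isnan(age).any():
            raise ValueError("missing age for at least one subject")
        if X.shape[1:] != self._feature_shape:
            raise ValueError(
                f"feature shape {X.shape[1:]} does not match the fitted "
                f"shape {self._feature_shape}"
            )
        pred = self.intercept_[None] + age.reshape(-1, *([1] * len(self._feature_shape))) * self.slope_[None]
        return X - pred

    def fit_transform(self, X, age, subject_ids=None):
        return self.fit(X, age, subject_ids=subject_ids).transform(X, age)


# ---------------------------------------------------------------------------
# Whole-chain convenience: volumes -> labeled, residualized slice dataset
# ---------------------------------------------------------------------------

@dataclass
class SliceDataset:
    """All extracted slices of a cohort in one array plus metadata.

    ``X`` has shape (n_slices, H, W); ``meta`` has one row per slice with
    subject_id, z_mm and label; ``demographics`` is the subject table.
    """

    X: np.ndarray
    meta: pd.DataFrame
    demographics: pd.DataFrame
    grid: GridSpec

    def __len__(self):
        return len(self.meta)

    def subject_rows(self, subject_ids) -> np.ndarray:
        return self.meta["subject_id"].isin(set(subject_ids)).to_numpy()


def preprocess_volumes(
    volumes: list[GMVolume],
    demographics: pd.DataFrame,
    fwhm_mm: float = 10.0,
    gm_threshold: float = 0.20,
    z_lo_mm: int | None = None,
    z_hi_mm: int | None = None,
) -> SliceDataset:
    """Smooth, threshold, slice and label every subject's volume."""
    groups = demographics.set_index("subject_id")["group"]
    pixel_stack, rows = [], []
    grid = volumes[0].grid
    for vol in volumes:
        sm = smooth_volume(vol, fwhm_mm=fwhm_mm)
        th, _ = threshold_gm(sm, min_prob=gm_threshold)
        for rec in extract_slices(th, groups[vol.subject_id], z_lo_mm, z_hi_mm):
            pixel_stack.append(rec.pixels)
            rows.append(
                dict(subject_id=rec.subject_id, z_mm=rec.z_mm, label=rec.label)
            )
    X = np.stack(pixel_stack).astype(np.float32)
    meta = pd.DataFrame(rows)
    return SliceDataset(X=X, meta=meta, demographics=demographics, grid=grid)


def build_slice_dataset(
    dataset: SliceDataset,
    fit_population: str = "all",
    train_ids=None,
) -> SliceDataset:
    """Age-residualize a slice dataset voxel-wise.

    The regression is fitted per (z-plane, pixel) across subjects, then
    applied to every subject. ``fit_population='all'`` mirrors the study
    design; ``'train'`` restricts the fit to ``train_ids``.
    """
    ages = dataset.demographics.set_index("subject_id")["age"]
    # regroup slices into per-subject stacks (subjects x H x W x n_z)
    subjects = dataset.demographics["subject_id"].tolist()
    zs = sorted(dataset.meta["z_mm"].unique())
    z_index = {z: i for i, z in enumerate(zs)}
    H, W = dataset.X.shape[1:]
    stacks = np.zeros((len(subjects), H, W, len(zs)), dtype=np.float64)
    sub_index = {s: i for i, s in enumerate(subjects)}
    for i, row in enumerate(dataset.meta.itertuples(index=False)):
        stacks[sub_index[row.subject_id], :, :, z_index[row.z_mm]] = dataset.X[i]
    age_arr = np.array([ages[s] for s in subjects])
    model = AgeResidualizer()
    if fit_population == "train":
        if train_ids is None:
            raise ValueError("fit_population='train' requires train_ids")
        sel = np.array([s in set(train_ids) for s in subjects])
        model.fit(stacks[sel], age_arr[sel], subject_ids=np.array(subjects)[sel])
    elif fit_population == "all":
        model.fit(stacks, age_arr, subject_ids=subjects)
    else:
        raise ValueError("fit_population must be 'all' or 'train'")
    resid = model.transform(stacks, age_arr)
    X = np.empty_like(dataset.X, dtype=np.float32)
    for i, row in enumerate(dataset.meta.itertuples(index=False)):
        X[i] = resid[sub_index[row.subject_id], :, :, z_index[row.z_mm]]
    return SliceDataset(
        X=X, meta=dataset.meta.copy(), demographics=dataset.demographics,
        grid=dataset.grid,
    )
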