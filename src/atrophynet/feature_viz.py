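"""Per-disease 3D activation brains from ReLU-3 maps.

Every (slice, model) pair yields a min-max-normalized 2D activation map;
maps are averaged over all participant-datum x model combinations per
(disease, axial plane) and stacked into a 3D "disease activation brain".
Each axial slice of that brain is then min-max renormalized and
thresholded at > 0.75. Left-lateralized TLE contributions are mirrored
about the midsagittal plane before averaging so the result reads as
ipsilateral/contralateral to the seizure focus; AD and HC maps are never
mirrored. ROI summaries are mean map values within each atlas region.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnn import SliceCNNClassifier
from .datasets import AtlasDefinition
from .grids import GridSpec
from .preprocess import SliceDataset

__all__ = [
    "ActivationBrain",
    "datum_activation_map",
    "minmax_normalize",
    "reconstruct_disease_brain",
    "threshold_map",
    "mirror_volume_data",
    "roi_mean_matrix",
    "build_activation_brains",
]


def minmax_normalize(arr: np.ndarray) -> np.ndarray:
    """(x - min)/(max - min); a constant array maps to all zeros."""
    lo, hi = float(np.min(arr)), float(np.max(arr))
    if hi == lo:
        return np.zeros_like(arr, dtype=np.float64)
    return (np.asarray(arr, dtype=np.float64) - lo) / (hi - lo)


def datum_activation_map(model: SliceCNNClassifier, pixels: np.ndarray) -> np.ndarray:
    """Normalized cumulative ReLU-3 activation for one slice datum."""
    return model.relu3_sum(pixels[None])[0]


@dataclass
class ActivationBrain:
    """Per-disease 3D reconstruction of activation maps.

    ``data`` lives on the first two grid axes x the extracted z-planes
    (ascending ``z_mms``); values are in [0, 1].
    """

    disease: str
    data: np.ndarray              # (H, W, n_z)
    z_mms: list[int]
    grid: GridSpec
    provenance: dict = field(default_factory=dict, repr=False)

    def to_volume(self) -> np.ndarray:
        """Embed into a full grid-shaped volume (planes outside the
        extraction range are zero)."""
        vol = np.zeros(self.grid.shape, dtype=np.float64)
        for i, z in enumerate(self.z_mms):
            vol[:, :, int(round(self.grid.index_of_z(z)))] = self.data[:, :, i]
        return vol


def reconstruct_disease_brain(
    maps_by_z: dict[int, list[np.ndarray]],
    disease: str,
    grid: GridSpec,
    provenance: dict | None = None,
) -> ActivationBrain:
    """Average per-z map collections into a 3D activation brain.

    ``maps_by_z`` maps each z (mm) to the list of normalized 2D maps from
    every (participant datum, model) combination; a flat unweighted mean
    is taken per plane. Every plane must have at least one map.
    """
    zs = sorted(maps_by_z)
    empty = [z for z in zs if len(maps_by_z[z]) == 0]
    if empty:
        raise ValueError(f"no activation maps for z planes {empty}")
    planes = [np.mean(np.stack(maps_by_z[z]), axis=0) for z in zs]
    data = np.stack(planes, axis=-1)
    return ActivationBrain(disease, data, zs, grid, provenance or {})


def threshold_map(brain: ActivationBrain, cut: float = 0.75) -> ActivationBrain:
    """Min-max renormalize each axial slice, then keep values strictly
    above ``cut`` (the rest set to 0)."""
    out = np.empty_like(brain.data, dtype=np.float64)
    for i in range(brain.data.shape[-1]):
        sl = minmax_normalize(brain.data[:, :, i])
        out[:, :, i] = np.where(sl > cut, sl, 0.0)
    return ActivationBrain(brain.disease, out, list(brain.z_mms), brain.grid,
                           dict(brain.provenance))


def mirror_volume_data(data: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Reflect 2D (H, W) or 3D data about the affine midsagittal plane."""
    grid.mirror_index_map()
    return np.flip(data, axis=0).copy()


def roi_mean_matrix(
    brains: list[ActivationBrain], atlas: AtlasDefinition
) -> pd.DataFrame:
    """Rows = diseases, columns = atlas ROIs ("name (hemisphere)"),
    cells = mean map value within the ROI restricted to the extracted
    z-range. ROIs with no voxels in range are NaN (missing), not 0."""
    rows = {}
    for brain in brains:
        if not brain.grid.matches(atlas.grid):
            raise ValueError("atlas grid does not match activation brain grid")
        ks = [int(round(brain.grid.index_of_z(z))) for z in brain.z_mms]
        labels = atlas.label_volume[:, :, ks]
        row = {}
        for rec in atlas.roi_table.itertuples(index=False):
            mask = labels == rec.label
            col = f"{rec.name} ({rec.hemisphere})"
            row[col] = float(brain.data[mask].mean()) if mask.any() else np.nan
        rows[brain.disease] = row
    return pd.DataFrame(rows).T


def build_activation_brains(
    models: list[SliceCNNClassifier],
    dataset: SliceDataset,
    cut: float = 0.75,
    mirror_tle: bool = True,
    averaging: str = "flat",
) -> list[ActivationBrain]:
    """Full feature-visualization pass: activation maps for every (slice,
    model) pair, grouped by (disease, z), averaged, renormalized and
    thresholded. Left-TLE maps are mirrored before averaging when
    ``mirror_tle`` is set (missing laterality is an error).

    ``averaging='flat'`` takes one unweighted mean over all (datum,
    model) pairs; ``'two_stage'`` averages within each model first, then
    across models (the two coincide when every model covers every datum).
    """
    if averaging not in ("flat", "two_stage"):
        raise ValueError("averaging must be 'flat' or 'two_stage'")
    demo = dataset.demographics.set_index("subject_id")
    lat = demo["laterality"] if "laterality" in demo else None
    grid = dataset.grid
    diseases = sorted(dataset.meta["label"].unique())
    maps = {d: {} for d in diseases}
    for model in models:
        all_maps = model.relu3_sum(dataset.X)
        per_model = {d: {} for d in diseases}
        for i, row in enumerate(dataset.meta.itertuples(index=False)):
            m = all_maps[i]
            if mirror_tle and row.label == "TLE":
                side = None if lat is None else lat.get(row.subject_id, None)
                if side not in ("left", "right"):
                    raise ValueError(
                        f"TLE subject {row.subject_id} has no laterality"
                    )
                if side == "left":
                    m = mirror_volume_data(m, grid)
            per_model[row.label].setdefault(int(row.z_mm), []).append(m)
        for d in diseases:
            for z, ms in per_model[d].items():
                if averaging == "two_stage":
                    maps[d].setdefault(z, []).append(np.mean(np.stack(ms), axis=0))
                else:
                    maps[d].setdefault(z, []).extend(ms)
    brains = []
    for d in diseases:
        brain = reconstruct_disease_brain(
            maps[d], d, grid,
            provenance={"n_models": len(models),
                        "n_maps": sum(len(v) for v in maps[d].values())},
        )
        brains.append(threshold_map(brain, cut=cut))
    return brains
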