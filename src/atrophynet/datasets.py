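"""Synthetic cohorts of normalized, segmented gray-matter volumes.

Real inputs to this kind of study are T1-weighted MRI normalized to MNI
space and segmented into gray-matter probability maps. Those data are not
distributable, so this module plants the relevant structure synthetically:
three diagnostic classes with class-specific regional atrophy (TLE:
lateralized medial-temporal/limbic plus milder diffuse extratemporal
involvement; AD: bilateral medial-temporal plus parietal; HC: none), a
linear gray-matter decline with age, and smooth per-subject noise fields
standing in for residual anatomical variability.

Default cohort sizes, age distributions and sex ratios follow the study's
demographic table: 157 TLE (38.77 +/- 12.44 y), 73 AD (75.71 +/- 8.10 y)
and 251 HC drawn from a two-component mixture (150 epilepsy-age-matched,
36.75 +/- 12.74 y; 101 elderly, 73.48 +/- 6.55 y) -- the age confound the
voxel-wise age regression stage must remove.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import FULL_GRID, GMVolume, GridSpec

__all__ = [
    "RoiSpec",
    "AtlasDefinition",
    "RoiEffect",
    "AtrophyModel",
    "CohortAgeParams",
    "DEFAULT_ROI_SPECS",
    "DEFAULT_ATROPHY_MODEL",
    "DEFAULT_COHORT_SIZES",
    "generate_atlas",
    "generate_cohort",
    "generate_gm_volume",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

GROUPS = ("TLE", "AD", "HC")


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiSpec:
    """One region, described in grid-relative units so it scales with the
    grid: ``center`` in fractions of the half-extent per axis (x > 0 is
    right of the midline), ``radii`` in fractions of the half-extent."""

    name: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    lobe: str
    paired: bool = True  # if True a mirrored left/right pair is generated


#: Toy mirror-symmetric stand-in for an anatomical parcellation: medial
#: temporal (hippocampus, amygdala), subcortical (thalamus), frontal,
#: parietal (precuneus) and occipital exemplars.
DEFAULT_ROI_SPECS: tuple[RoiSpec, ...] = (
    RoiSpec("hippocampus", (0.42, -0.25, -0.40), (0.14, 0.16, 0.15), "temporal"),
    RoiSpec("amygdala", (0.40, 0.14, -0.42), (0.12, 0.12, 0.12), "temporal"),
    RoiSpec("thalamus", (0.18, -0.10, 0.02), (0.13, 0.14, 0.14), "subcortical"),
    RoiSpec("superior_frontal", (0.35, 0.55, 0.35), (0.20, 0.22, 0.24), "frontal"),
    RoiSpec("precuneus", (0.16, -0.58, 0.32), (0.13, 0.17, 0.20), "parietal"),
    RoiSpec("lateral_occipital", (0.58, -0.58, -0.08), (0.15, 0.15, 0.18), "occipital"),
)


@dataclass
class AtlasDefinition:
    """Integer label volume plus a region table.

    Label 0 is background; every nonzero label has a row in ``roi_table``
    (columns: label, name, lobe, hemisphere). Left/right pairs are exact
    mirror images about the midsagittal plane of the affine. ``brain_mask``
    marks the brain (ellipsoid) within which gray matter is synthesized.
    """

    label_volume: np.ndarray
    roi_table: pd.DataFrame
    grid: GridSpec
    brain_mask: np.ndarray = field(repr=False, default=None)

    def labels_for(self, name: str, hemisphere: str | None = None) -> list[int]:
        t = self.roi_table
        sel = t["name"] == name
        if hemisphere is not None:
            sel &= t["hemisphere"] == hemisphere
        return [int(v) for v in t.loc[sel, "label"]]

    def mask_for_label(self, label: int) -> np.ndarray:
        return self.label_volume == label


def _ellipsoid_mask(grid: GridSpec, center_frac, radii_frac) -> np.ndarray:
    nx, ny, nz = grid.shape
    half = (np.array(grid.shape) - 1) / 2.0
    # grid-relative coordinates in [-1, 1] per axis
    idx = np.indices(grid.shape, dtype=float)
    rel = [(idx[a] - half[a]) / half[a] for a in range(3)]
    d = sum(((rel[a] - center_frac[a]) / radii_frac[a]) ** 2 for a in range(3))
    return d <= 1.0


def generate_atlas(
    grid: GridSpec = FULL_GRID,
    roi_specs: tuple[RoiSpec, ...] = DEFAULT_ROI_SPECS,
) -> AtlasDefinition:
    """Build a mirror-symmetric toy labeled atlas on ``grid``.

    Paired regions are placed in the right hemisphere and mirrored into
    the left by an exact sagittal index flip, which guarantees the
    left/right voxel sets are reflections of each other. Overlapping
    region definitions are rejected.
    """
    label_vol = np.zeros(grid.shape, dtype=np.int16)
    brain = _ellipsoid_mask(grid, (0.0, 0.0, 0.0), (0.95, 0.95, 0.95))
    rows = []
    next_label = 1
    for spec in roi_specs:
        masks = []
        if spec.paired:
            right = _ellipsoid_mask(grid, spec.center, spec.radii)
            left = np.flip(right, axis=0)
            grid.mirror_index_map()  # validate flip == reflection
            masks = [(left, "left"), (right, "right")]
        else:
            masks = [(_ellipsoid_mask(grid, spec.center, spec.radii), "both")]
        for mask, hemi in masks:
            mask &= brain
            if not mask.any():
                raise ValueError(f"ROI {spec.name}/{hemi} is empty on this grid")
            clash = label_vol[mask]
            if (clash != 0).any():
                other = int(clash[clash != 0][0])
                other_name = rows[other - 1]["name"]
                raise ValueError(
                    f"ROI {spec.name}/{hemi} overlaps {other_name} "
                    f"(labels {next_label} vs {other})"
                )
            label_vol[mask] = next_label
            rows.append(
                dict(label=next_label, name=spec.name, lobe=spec.lobe,
                     hemisphere=hemi)
            )
            next_label += 1
    table = pd.DataFrame(rows, columns=["label", "name", "lobe", "hemisphere"])
    return AtlasDefinition(label_vol, table, grid, brain_mask=brain)


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortAgeParams:
    """Group-wise age distributions (normal, or a mixture for HC)."""

    tle: tuple[float, float] = (38.77, 12.44)
    ad: tuple[float, float] = (75.71, 8.10)
    hc_components: tuple[tuple[float, float], ...] = ((36.75, 12.74), (73.48, 6.55))
    hc_weights: tuple[float, ...] = (150.0, 101.0)


DEFAULT_COHORT_SIZES = {"TLE": 157, "AD": 73, "HC": 251}

# female fraction per group / HC mixture component (from the demographic
# table: TLE 97/157, AD 29/73, HC young 73/150, HC elderly 50/101)
_SEX_F_FRAC = {"TLE": 97 / 157, "AD": 29 / 73}
_HC_F_FRAC = (73 / 150, 50 / 101)
_TLE_LEFT_FRAC = 92 / 157  # left- vs right-lateralized seizure focus


def generate_cohort(
    sizes: dict[str, int] | None = None,
    age_params: CohortAgeParams = CohortAgeParams(),
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a demographics table (subject_id, age, sex, group, laterality).

    Ages are truncated at 18 years (adult cohorts). TLE subjects receive a
    left/right laterality; AD and HC get ``none``.
    """
    sizes = dict(DEFAULT_COHORT_SIZES if sizes is None else sizes)
    for g, n in sizes.items():
        if n < 1:
            raise ValueError(f"cohort size for {g} must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    rows = []
    counter = 1

    def draw_age(mean, sd, n):
        ages = rng.normal(mean, sd, size=n)
        while (ages < 18).any():  # redraw truncation, keeps mean ~unbiased
            bad = ages < 18
            ages[bad] = rng.normal(mean, sd, size=bad.sum())
        return ages

    for group in GROUPS:
        n = sizes.get(group, 0)
        if n == 0:
            continue
        if group == "HC":
            w = np.asarray(age_params.hc_weights, dtype=float)
            comp = rng.choice(len(w), size=n, p=w / w.sum())
            ages = np.empty(n)
            sexes = np.empty(n, dtype=object)
            for c, (m, s) in enumerate(age_params.hc_components):
                k = int((comp == c).sum())
                ages[comp == c] = draw_age(m, s, k)
                sexes[comp == c] = np.where(
                    rng.random(k) < _HC_F_FRAC[c], "F", "M"
                )
        else:
            m, s = age_params.tle if group == "TLE" else age_params.ad
            ages = draw_age(m, s, n)
            sexes = np.where(rng.random(n) < _SEX_F_FRAC[group], "F", "M")
        if group == "TLE":
            lat = np.where(rng.random(n) < _TLE_LEFT_FRAC, "left", "right")
        else:
            lat = np.full(n, "none", dtype=object)
        for i in range(n):
            rows.append(
                dict(
                    subject_id=f"sub-{counter:04d}",
                    age=float(np.round(ages[i], 2)),
                    sex=str(sexes[i]),
                    group=group,
                    laterality=str(lat[i]),
                )
            )
            counter += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Atrophy model and volume synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiEffect:
    """Fractional GM reduction in one region: ipsilateral / contralateral
    to the seizure focus. For groups without laterality both hemispheres
    receive ``ipsi`` (set ipsi == contra for bilateral disease)."""

    ipsi: float
    contra: float | None = None

    def __post_init__(self):
        contra = self.ipsi if self.contra is None else self.contra
        object.__setattr__(self, "contra", contra)
        for e in (self.ipsi, self.contra):
            if not (0.0 <= e < 1.0):
                raise ValueError(f"atrophy effect must be in [0, 1), got {e}")


@dataclass(frozen=True)
class AtrophyModel:
    """Generative model of gray matter:

        GM = baseline * (1 - effect) + age_slope * (age - age_reference) + noise

    clipped to [0, 1]. ``effects`` maps group -> {roi name -> RoiEffect};
    ``global_effects`` maps group -> a mild fractional reduction applied
    across the whole brain (the diffuse atrophy component both diseases
    show on top of their regional topography); ``age_slope`` is in
    GM-probability units per year (negative: GM declines with age); noise
    is a white Gaussian field convolved to ``noise_fwhm_mm``, rescaled to
    unit variance, times ``noise_amplitude``.
    """

    effects: dict = field(default_factory=dict)
    global_effects: dict = field(default_factory=dict)
    age_slope: float = -0.0015
    age_reference: float = 50.0
    noise_fwhm_mm: float = 8.0
    noise_amplitude: float = 0.05
    roi_baseline: float = 0.8
    background_baseline: float = 0.5

    def __post_init__(self):
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")
        if not (0.0 < self.roi_baseline <= 1.0):
            raise ValueError("baseline must be in (0, 1]")


DEFAULT_ATROPHY_MODEL = AtrophyModel(
    effects={
        # lateralized medial-temporal/limbic core plus diffuse
        # extratemporal (subcortical, frontal, occipital) involvement
        "TLE": {
            "hippocampus": RoiEffect(ipsi=0.35, contra=0.12),
            "amygdala": RoiEffect(ipsi=0.30, contra=0.10),
            "thalamus": RoiEffect(ipsi=0.20, contra=0.10),
            "superior_frontal": RoiEffect(ipsi=0.12, contra=0.08),
            "lateral_occipital": RoiEffect(ipsi=0.10, contra=0.06),
        },
        # bilateral medial-temporal plus parietal topography
        "AD": {
            "hippocampus": RoiEffect(ipsi=0.30),
            "amygdala": RoiEffect(ipsi=0.20),
            "precuneus": RoiEffect(ipsi=0.30),
        },
        "HC": {},
    },
    global_effects={"TLE": 0.03, "AD": 0.08},
)


def baseline_volume(atlas: AtlasDefinition, model: AtrophyModel) -> np.ndarray:
    base = np.zeros(atlas.grid.shape, dtype=np.float64)
    base[atlas.brain_mask] = model.background_baseline
    base[atlas.label_volume > 0] = model.roi_baseline
    return base


def smooth_noise_field(
    grid: GridSpec, fwhm_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance smooth Gaussian random field on ``grid``."""
    white = rng.standard_normal(grid.shape)
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / grid.voxel_sizes
    fld = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = fld.std()
    return fld / sd if sd > 0 else fld


def generate_gm_volume(
    row: pd.Series | dict,
    atlas: AtlasDefinition,
    model: AtrophyModel = DEFAULT_ATROPHY_MODEL,
    seed: int = 0,
) -> GMVolume:
    """Synthesize one subject's gray-matter probability volume."""
    grid = atlas.grid
    base = baseline_volume(atlas, model)
    group = row["group"]
    laterality = row.get("laterality", "none") if isinstance(row, dict) else row["laterality"]
    reduction = np.ones(grid.shape, dtype=np.float64)
    g = float(model.global_effects.get(group, 0.0))
    if not (0.0 <= g < 1.0):
        raise ValueError(f"global effect must be in [0, 1), got {g}")
    # diffuse global atrophy everywhere; region-specific effects override
    # it inside their ROI so planted ROI means stay exactly (1-e)*baseline
    reduction[atlas.brain_mask] = 1.0 - g
    for roi_name, eff in model.effects.get(group, {}).items():
        for hemi in ("left", "right"):
            labels = atlas.labels_for(roi_name, hemi)
            if not labels:
                labels = atlas.labels_for(roi_name, "both")
            if not labels:
                raise ValueError(f"atrophy model names unknown ROI {roi_name!r}")
            if laterality in ("left", "right"):
                e = eff.ipsi if hemi == laterality else eff.contra
            else:
                e = eff.ipsi
            for lab in labels:
                reduction[atlas.label_volume == lab] = 1.0 - e
    data = base * reduction
    data += model.age_slope * (float(row["age"]) - model.age_reference) * atlas.brain_mask
    if model.noise_amplitude > 0:
        rng = np.random.default_rng(seed)
        data += model.noise_amplitude * smooth_noise_field(
            grid, model.noise_fwhm_mm, rng
        ) * atlas.brain_mask
    np.clip(data, 0.0, 1.0, out=data)
    return GMVolume(data=data, grid=grid, subject_id=str(row["subject_id"]))


def generate_dataset(
    cohort: pd.DataFrame,
    atlas: AtlasDefinition,
    model: AtrophyModel = DEFAULT_ATROPHY_MODEL,
    seed: int = 0,
) -> list[GMVolume]:
    """One volume per demographics row; per-subject noise seeds are spawned
    deterministically from ``seed``."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(cohort))
    return [
        generate_gm_volume(row, atlas, model, seed=int(child_seeds[i] % (2**31)))
        for i, (_, row) in enumerate(cohort.iterrows())
    ]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_dataset(
    cohort: pd.DataFrame,
    volumes: list[GMVolume],
    atlas: AtlasDefinition,
    out_dir: str | Path,
    seed: int | None = None,
    params: dict | None = None,
) -> dict:
    """Write a dataset directory: one NIfTI per subject, the atlas NIfTI,
    a demographics CSV and a JSON manifest. Returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vol_ids = [v.subject_id for v in volumes]
    if sorted(vol_ids) != sorted(cohort["subject_id"].tolist()):
        raise ValueError("subject ids of volumes do not match demographics table")
    grid = volumes[0].grid
    files = {}
    for vol in volumes:
        fn = f"{vol.subject_id}_gm.nii"
        nib.save(nib.Nifti1Image(vol.data.astype(np.float32), grid.affine), out / fn)
        files[vol.subject_id] = fn
    nib.save(
        nib.Nifti1Image(atlas.label_volume.astype(np.int16), grid.affine),
        out / "atlas.nii",
    )
    atlas.roi_table.to_csv(out / "atlas_rois.csv", index=False)
    nib.save(
        nib.Nifti1Image(atlas.brain_mask.astype(np.uint8), grid.affine),
        out / "brain_mask.nii",
    )
    cohort.to_csv(out / "demographics.csv", index=False)
    manifest = {
        "n_subjects": len(cohort),
        "grid_shape": list(grid.shape),
        "affine": grid.affine.tolist(),
        "default_z_range": list(grid.default_z_range),
        "seed": seed,
        "params": params or {},
        "volumes": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_dataset(
    in_dir: str | Path,
) -> tuple[pd.DataFrame, list[GMVolume], AtlasDefinition]:
    """Read back a dataset directory written by :func:`write_dataset`."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    grid = GridSpec(
        shape=tuple(manifest["grid_shape"]),
        affine=np.array(manifest["affine"]),
        default_z_range=tuple(manifest["default_z_range"]),
    )
    cohort = pd.read_csv(src / "demographics.csv")
    volumes = []
    for sid, fn in manifest["volumes"].items():
        img = nib.load(src / fn)
        if not np.allclose(img.affine, grid.affine):
            raise ValueError(f"affine mismatch between {fn} and manifest")
        volumes.append(GMVolume(np.asanyarray(img.dataobj), grid, sid))
    atlas_img = nib.load(src / "atlas.nii")
    if not np.allclose(atlas_img.affine, grid.affine):
        raise ValueError("affine mismatch between atlas and volumes")
    roi_table = pd.read_csv(src / "atlas_rois.csv")
    mask_path = src / "brain_mask.nii"
    brain_mask = (
        np.asanyarray(nib.load(mask_path).dataobj).astype(bool)
        if mask_path.exists()
        else np.asanyarray(atlas_img.dataobj) > 0
    )
    atlas = AtlasDefinition(
        np.asanyarray(atlas_img.dataobj).astype(np.int16), roi_table, grid,
        brain_mask=brain_mask,
    )
    return cohort, volumes, atlas
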