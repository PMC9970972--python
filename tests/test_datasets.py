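import numpy as np
import pandas as pd
import pytest

import atrophynet as an
from atrophynet import datasets as ds
from atrophynet.grids import FULL_GRID, REDUCED_GRID


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

def test_two_roi_atlas_on_tiny_grid():
    aff = np.eye(4)
    aff[:3, 3] = (-3.5, -3.5, -4.0)
    grid = an.GridSpec(shape=(8, 8, 8), affine=aff)
    specs = (
        ds.RoiSpec("hippocampus", (0.45, 0.0, 0.0), (0.3, 0.3, 0.3), "temporal"),
    )
    atlas = ds.generate_atlas(grid, specs)
    labels = np.unique(atlas.label_volume)
    assert set(labels) - {0} == {1, 2}  # hippocampus left/right pair
    for lab in (1, 2):
        assert (atlas.label_volume == lab).sum() > 0
    lmask = atlas.label_volume == atlas.labels_for("hippocampus", "left")[0]
    rmask = atlas.label_volume == atlas.labels_for("hippocampus", "right")[0]
    assert np.array_equal(np.flip(rmask, axis=0), lmask)


def test_left_right_rois_are_mirror_images(toy_atlas):
    grid = toy_atlas.grid
    for name in toy_atlas.roi_table["name"].unique():
        left = toy_atlas.labels_for(name, "left")
        right = toy_atlas.labels_for(name, "right")
        assert len(left) == len(right) == 1
        lmask = toy_atlas.label_volume == left[0]
        rmask = toy_atlas.label_volume == right[0]
        assert np.array_equal(np.flip(rmask, axis=0), lmask)


def test_full_grid_rois_all_have_100_voxels():
    atlas = ds.generate_atlas(FULL_GRID)
    for rec in atlas.roi_table.itertuples(index=False):
        assert (atlas.label_volume == rec.label).sum() >= 100


def test_overlapping_rois_rejected(reduced_grid):
    specs = (
        ds.RoiSpec("hippocampus", (0.4, 0.0, 0.0), (0.3, 0.3, 0.3), "temporal"),
        ds.RoiSpec("amygdala", (0.42, 0.02, 0.0), (0.3, 0.3, 0.3), "temporal"),
    )
    with pytest.raises(ValueError, match="overlaps"):
        ds.generate_atlas(reduced_grid, specs)


def test_roi_table_covers_all_labels(toy_atlas):
    present = set(np.unique(toy_atlas.label_volume)) - {0}
    assert present == set(toy_atlas.roi_table["label"])


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def test_default_cohort_matches_demographic_template():
    cohort = ds.generate_cohort(seed=0)
    counts = cohort["group"].value_counts()
    assert counts["TLE"] == 157 and counts["AD"] == 73 and counts["HC"] == 251
    tle = cohort[cohort["group"] == "TLE"]
    assert abs(tle["age"].mean() - 38.77) < 3.0
    ad = cohort[cohort["group"] == "AD"]
    assert abs(ad["age"].mean() - 75.71) < 3.0
    # HC is a young/old mixture: SD far exceeds either component's
    hc = cohort[cohort["group"] == "HC"]
    assert hc["age"].std() > 15


def test_cohort_invariants():
    cohort = ds.generate_cohort({"TLE": 30, "AD": 20, "HC": 40}, seed=3)
    assert cohort["subject_id"].is_unique
    assert (cohort["age"] > 0).all() and np.isfinite(cohort["age"]).all()
    is_tle = cohort["group"] == "TLE"
    assert set(cohort.loc[is_tle, "laterality"]) <= {"left", "right"}
    assert (cohort.loc[~is_tle, "laterality"] == "none").all()


def test_minimal_cohort_and_reproducibility():
    tiny = ds.generate_cohort({"TLE": 1, "AD": 1, "HC": 1}, seed=5)
    assert len(tiny) == 3 and tiny["subject_id"].is_unique
    again = ds.generate_cohort({"TLE": 1, "AD": 1, "HC": 1}, seed=5)
    pd.testing.assert_frame_equal(tiny, again)


def test_nonpositive_size_rejected():
    with pytest.raises(ValueError, match=">= 1"):
        ds.generate_cohort({"TLE": 0, "AD": 1, "HC": 1}, seed=0)


# ---------------------------------------------------------------------------
# volume synthesis
# ---------------------------------------------------------------------------

def _noiseless_model(**kw):
    defaults = dict(noise_amplitude=0.0, age_slope=-0.0015)
    defaults.update(kw)
    return ds.AtrophyModel(**defaults)


def test_zero_noise_zero_atrophy_reference_age_gives_baseline(toy_atlas):
    model = _noiseless_model()
    row = dict(subject_id="s1", age=model.age_reference, group="HC",
               laterality="none")
    vol = ds.generate_gm_volume(row, toy_atlas, model, seed=0)
    base = ds.baseline_volume(toy_atlas, model)
    assert np.allclose(vol.data, base)


def test_planted_effect_scales_roi_mean_exactly(toy_atlas):
    model = _noiseless_model(
        effects={"TLE": {"hippocampus": ds.RoiEffect(ipsi=0.20, contra=0.0)}}
    )
    row = dict(subject_id="s1", age=model.age_reference, group="TLE",
               laterality="right")
    vol = ds.generate_gm_volume(row, toy_atlas, model, seed=0)
    ipsi = toy_atlas.label_volume == toy_atlas.labels_for("hippocampus", "right")[0]
    contra = toy_atlas.label_volume == toy_atlas.labels_for("hippocampus", "left")[0]
    assert vol.data[ipsi].mean() == pytest.approx(0.8 * model.roi_baseline)
    assert vol.data[contra].mean() == pytest.approx(model.roi_baseline)


def test_age_slope_recovered_by_voxelwise_ols(toy_atlas):
    """Per-voxel OLS on a zero-noise HC cohort recovers the generative
    slope to within 1% relative error."""
    model = _noiseless_model()
    ages = np.linspace(20, 80, 40)
    stack = []
    for i, age in enumerate(ages):
        row = dict(subject_id=f"s{i}", age=age, group="HC", laterality="none")
        stack.append(ds.generate_gm_volume(row, toy_atlas, model, seed=0).data)
    stack = np.stack(stack).reshape(len(ages), -1)
    a = ages - ages.mean()
    slopes = a @ (stack - stack.mean(axis=0)) / (a**2).sum()
    # restrict to voxels unaffected by [0,1] clipping
    interior = (stack.min(axis=0) > 0.01) & (stack.max(axis=0) < 0.99)
    assert interior.any()
    rel_err = np.abs(slopes[interior] - model.age_slope) / abs(model.age_slope)
    assert rel_err.max() <= 0.01


def test_laterality_mirror_symmetry(toy_atlas):
    """Swapping a TLE subject's laterality equals reflecting the volume
    (zero-noise case)."""
    model = _noiseless_model(
        effects=ds.DEFAULT_ATROPHY_MODEL.effects,
        global_effects=ds.DEFAULT_ATROPHY_MODEL.global_effects,
    )
    base = dict(subject_id="s1", age=44.0, group="TLE")
    left = ds.generate_gm_volume({**base, "laterality": "left"}, toy_atlas, model)
    right = ds.generate_gm_volume({**base, "laterality": "right"}, toy_atlas, model)
    assert np.allclose(toy_atlas.grid.mirror_volume(left.data), right.data)


def test_generated_values_in_unit_interval(small_volumes):
    for vol in small_volumes:
        assert vol.data.min() >= 0.0 and vol.data.max() <= 1.0


def test_unknown_roi_in_atrophy_model_rejected(toy_atlas):
    with pytest.raises(ValueError):
        bad = ds.AtrophyModel(effects={"HC": {"nonexistent": ds.RoiEffect(0.1)}})
        ds.generate_gm_volume(
            dict(subject_id="s", age=50, group="HC", laterality="none"),
            toy_atlas, bad, seed=0,
        )


def test_effect_bounds_validated():
    with pytest.raises(ValueError, match="effect"):
        ds.RoiEffect(ipsi=1.2)
    with pytest.raises(ValueError, match="amplitude"):
        ds.AtrophyModel(noise_amplitude=-0.1)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def test_write_read_round_trip(tmp_path, toy_atlas):
    cohort = ds.generate_cohort({"TLE": 1, "AD": 1, "HC": 1}, seed=5)
    vols = ds.generate_dataset(cohort, toy_atlas, seed=6)
    manifest = ds.write_dataset(cohort, vols, toy_atlas, tmp_path, seed=6)
    assert len(manifest["volumes"]) == 3
    assert (tmp_path / "atlas.nii").exists()
    assert (tmp_path / "demographics.csv").exists()
    assert (tmp_path / "manifest.json").exists()

    cohort2, vols2, atlas2 = ds.read_dataset(tmp_path)
    pd.testing.assert_frame_equal(cohort, cohort2)
    by_id = {v.subject_id: v for v in vols2}
    for v in vols:
        # bit-identical at stored (float32) precision
        assert np.array_equal(v.data.astype(np.float32), by_id[v.subject_id].data)
    assert np.array_equal(atlas2.label_volume, toy_atlas.label_volume)


def test_write_dataset_rejects_id_mismatch(tmp_path, toy_atlas):
    cohort = ds.generate_cohort({"TLE": 1, "AD": 1, "HC": 1}, seed=5)
    vols = ds.generate_dataset(cohort, toy_atlas, seed=6)
    vols[0].subject_id = "sub-9999"
    with pytest.raises(ValueError, match="ids"):
        ds.write_dataset(cohort, vols, toy_atlas, tmp_path)


def test_manifest_seed_regenerates_identical_csv(tmp_path, toy_atlas):
    for d in ("a", "b"):
        cohort = ds.generate_cohort({"TLE": 2, "AD": 2, "HC": 2}, seed=9)
        vols = ds.generate_dataset(cohort, toy_atlas, seed=9)
        ds.write_dataset(cohort, vols, toy_atlas, tmp_path / d, seed=9)
    assert (tmp_path / "a" / "demographics.csv").read_bytes() == (
        tmp_path / "b" / "demographics.csv"
    ).read_bytes()
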