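import numpy as np
import pytest

import atrophynet as an
from atrophynet.grids import FULL_GRID, REDUCED_GRID, GMVolume
from atrophynet.preprocess import (
    AgeResidualizer,
    extract_slices,
    fwhm_to_sigma,
    smooth_volume,
    threshold_gm,
)


def _vol(data, grid=REDUCED_GRID, sid="s1"):
    return GMVolume(np.asarray(data, dtype=np.float32), grid, sid)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def test_fwhm_sigma_closed_form():
    assert fwhm_to_sigma(10.0) == pytest.approx(4.2466, abs=1e-4)


def test_impulse_half_maximum_at_half_fwhm():
    grid = FULL_GRID
    data = np.zeros(grid.shape)
    data[56, 68, 56] = 1.0
    sm = smooth_volume(_vol(data, grid), fwhm_mm=10.0)
    peak = sm.data[56, 68, 56]
    at_5mm = sm.data[61, 68, 56]  # 5 mm = half the FWHM from the peak
    assert at_5mm / peak == pytest.approx(0.5, rel=0.02)


def test_constant_volume_unchanged_by_smoothing(reduced_grid):
    sm = smooth_volume(_vol(np.full(reduced_grid.shape, 0.7)), fwhm_mm=10.0)
    assert np.allclose(sm.data, 0.7, atol=1e-12)


def test_smoothing_conserves_interior_mass(reduced_grid):
    data = np.zeros(reduced_grid.shape)
    data[12:20, 16:24, 12:20] = 0.5  # supported well inside the volume
    sm = smooth_volume(_vol(data), fwhm_mm=3.0)
    assert sm.data.sum() == pytest.approx(data.sum(), rel=1e-3)


def test_nonpositive_fwhm_rejected(reduced_grid):
    with pytest.raises(ValueError, match="positive"):
        smooth_volume(_vol(np.zeros(reduced_grid.shape)), fwhm_mm=0.0)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "value,kept", [(0.19, False), (0.20, False), (0.21, True)]
)
def test_threshold_is_strictly_greater_than(reduced_grid, value, kept):
    data = np.zeros(reduced_grid.shape)
    data[0, 0, 0] = value
    out, mask = threshold_gm(_vol(data), min_prob=0.20)
    assert mask[0, 0, 0] is np.bool_(kept)
    assert out.data[0, 0, 0] == (np.float32(value) if kept else 0.0)


def test_threshold_idempotent(rng, reduced_grid):
    v = _vol(rng.random(reduced_grid.shape))
    once, m1 = threshold_gm(v)
    twice, m2 = threshold_gm(once)
    assert np.array_equal(once.data, twice.data)
    assert np.array_equal(m1, m2)


# ---------------------------------------------------------------------------
# slice extraction
# ---------------------------------------------------------------------------

def test_default_full_grid_extraction_yields_58_slices():
    vol = _vol(np.zeros(FULL_GRID.shape), FULL_GRID)
    recs = extract_slices(vol, label="HC")
    assert len(recs) == 58
    zs = [r.z_mm for r in recs]
    assert zs == list(range(-29, 29))  # ascending, closed interval


def test_single_plane_extraction():
    vol = _vol(np.zeros(FULL_GRID.shape), FULL_GRID)
    recs = extract_slices(vol, label="TLE", z_lo_mm=0, z_hi_mm=0)
    assert len(recs) == 1 and recs[0].z_mm == 0
    assert recs[0].pixels.shape == (113, 137)


def test_reduced_grid_scaled_range_yields_16_slices(reduced_grid):
    vol = _vol(np.zeros(reduced_grid.shape))
    recs = extract_slices(vol, label="AD", z_lo_mm=-8, z_hi_mm=7)
    assert len(recs) == 16


def test_out_of_range_extraction_names_valid_range(reduced_grid):
    vol = _vol(np.zeros(reduced_grid.shape))
    with pytest.raises(ValueError, match=r"\[-16, 15\]"):
        extract_slices(vol, label="HC", z_lo_mm=-29, z_hi_mm=28)


def test_slices_carry_subject_and_label(small_slices, small_cohort):
    groups = small_cohort.set_index("subject_id")["group"]
    assert (
        small_slices.meta["label"].to_numpy()
        == groups[small_slices.meta["subject_id"]].to_numpy()
    ).all()
    # every subject contributes the same 16 planes
    per = small_slices.meta.groupby("subject_id")["z_mm"].count()
    assert (per == 16).all()


# ---------------------------------------------------------------------------
# age regression
# ---------------------------------------------------------------------------

def test_exact_linear_data_gives_zero_residuals(rng):
    ages = np.array([20.0, 40.0, 60.0, 80.0])
    slope = rng.normal(size=(5, 4))
    intercept = rng.normal(size=(5, 4))
    X = intercept[None] + ages[:, None, None] * slope[None]
    model = AgeResidualizer().fit(X, ages)
    assert np.allclose(model.slope_, slope, atol=1e-10)
    assert np.allclose(model.transform(X, ages), 0.0, atol=1e-9)


def test_constant_voxel_gives_zero_slope():
    ages = np.array([20.0, 50.0, 80.0])
    X = np.full((3, 4), 0.6)
    model = AgeResidualizer().fit(X, ages)
    assert np.allclose(model.slope_, 0.0)
    assert np.allclose(model.intercept_, 0.6)


def test_residuals_orthogonal_to_age(rng):
    ages = rng.uniform(20, 80, size=30)
    X = rng.random((30, 6, 5))
    model = AgeResidualizer().fit(X, ages)
    resid = model.transform(X, ages).reshape(30, -1)
    a = ages - ages.mean()
    # per-voxel OLS slope of residuals on age is 0 to machine precision
    slopes = a @ resid / (a**2).sum()
    assert np.abs(slopes).max() < 1e-10


def test_residual_difference_is_slope_times_age_gap():
    ages_fit = np.array([20.0, 30.0, 60.0, 70.0])
    rng = np.random.default_rng(0)
    X = rng.random((4, 3, 3))
    model = AgeResidualizer().fit(X, ages_fit)
    model.slope_ = np.full((3, 3), 0.002)
    model.intercept_ = np.zeros((3, 3))
    same = np.full((2, 3, 3), 0.5)
    resid = model.transform(same, np.array([40.0, 50.0]))
    assert np.allclose(resid[0] - resid[1], 0.02)


def test_identical_ages_rejected():
    with pytest.raises(ValueError, match="identical"):
        AgeResidualizer().fit(np.random.rand(4, 3), np.full(4, 50.0))


def test_missing_age_rejected():
    ages = np.array([20.0, 40.0, 60.0])
    model = AgeResidualizer().fit(np.random.rand(3, 3), ages)
    with pytest.raises(ValueError, match="missing"):
        model.transform(np.random.rand(1, 3), np.array([np.nan]))


def test_generator_slope_recovered_via_residualizer(toy_atlas):
    from atrophynet import datasets as ds

    model = ds.AtrophyModel(noise_amplitude=0.0)
    ages = np.linspace(25, 75, 20)
    X = np.stack(
        [
            ds.generate_gm_volume(
                dict(subject_id=f"s{i}", age=a, group="HC", laterality="none"),
                toy_atlas, model,
            ).data
            for i, a in enumerate(ages)
        ]
    )
    fit = AgeResidualizer().fit(X, ages)
    inside = toy_atlas.brain_mask & (X.min(axis=0) > 0.01) & (X.max(axis=0) < 0.99)
    rel = np.abs(fit.slope_[inside] - model.age_slope) / abs(model.age_slope)
    assert rel.max() <= 0.01


def test_fit_population_train_only(small_cohort, small_volumes):
    raw = an.preprocess_volumes(small_volumes, small_cohort, fwhm_mm=3.0)
    train_ids = small_cohort["subject_id"].tolist()[:20]
    out = an.build_slice_dataset(raw, fit_population="train", train_ids=train_ids)
    assert out.X.shape == raw.X.shape
    with pytest.raises(ValueError, match="train_ids"):
        an.build_slice_dataset(raw, fit_population="train")
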