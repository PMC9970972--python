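"""End-to-end orchestration: simulate -> preprocess -> ensembles -> FDCI
-> feature visualization -> VBM, with all outputs written to a run
directory (NIfTI maps, CSV tables, JSON summaries, a log of seeds)."""
from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import datasets as ds
from .config import RunConfig
from .evaluation import compute_fdci, run_ensemble
from .feature_viz import build_activation_brains, roi_mean_matrix
from .grids import get_grid
from .preprocess import build_slice_dataset, preprocess_volumes
from .vbm import run_vbm_contrast, vbm_roi_summary

logger = logging.getLogger("atrophynet")

__all__ = ["run_full_pipeline", "simulate_stage", "preprocess_stage"]


def _spawn_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def simulate_stage(config: RunConfig, out_dir: str | Path):
    """Generate and write the synthetic dataset; returns its pieces."""
    grid = get_grid(config.grid)
    atlas = ds.generate_atlas(grid)
    model = ds.AtrophyModel(
        effects=ds.DEFAULT_ATROPHY_MODEL.effects,
        noise_amplitude=config.noise_amplitude,
        noise_fwhm_mm=config.noise_fwhm_mm,
    )
    cohort_seed, volume_seed = _spawn_seeds(config.seed, 2)
    cohort = ds.generate_cohort(config.cohort_sizes, seed=cohort_seed)
    volumes = ds.generate_dataset(cohort, atlas, model, seed=volume_seed)
    ds.write_dataset(
        cohort, volumes, atlas, out_dir, seed=config.seed,
        params={"cohort_sizes": config.cohort_sizes,
                "noise_amplitude": config.noise_amplitude,
                "noise_fwhm_mm": config.noise_fwhm_mm,
                "grid": config.grid},
    )
    return cohort, volumes, atlas


def preprocess_stage(config: RunConfig, cohort, volumes):
    z_lo, z_hi = (
        config.z_range_mm if config.z_range_mm is not None else (None, None)
    )
    raw = preprocess_volumes(
        volumes, cohort,
        fwhm_mm=config.smoothing_fwhm_mm,
        gm_threshold=config.gm_threshold,
        z_lo_mm=z_lo, z_hi_mm=z_hi,
    )
    return build_slice_dataset(raw, fit_population=config.fit_population)


def run_full_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write the run directory; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log = {"seed": config.seed, "stages": []}

    def stage(name):
        logger.info("stage: %s", name)
        log["stages"].append(name)

    try:
        stage("simulate")
        cohort, volumes, atlas = simulate_stage(config, out / "dataset")

        stage("preprocess")
        dataset = preprocess_stage(config, cohort, volumes)

        stage("ensembles")
        trained_seed, shuffled_seed = _spawn_seeds(config.seed + 1, 2)
        trained = run_ensemble(
            dataset, n_runs=config.ensemble_runs, mode="trained",
            master_seed=trained_seed, fractions=config.split_fractions,
            cnn_params=config.cnn_params(),
            shuffle_granularity=config.shuffle_granularity,
            keep_models=True,
        )
        shuffled = run_ensemble(
            dataset, n_runs=config.ensemble_runs, mode="shuffled",
            master_seed=shuffled_seed, fractions=config.split_fractions,
            cnn_params=config.cnn_params(),
            shuffle_granularity=config.shuffle_granularity,
        )
        metrics = pd.concat(
            [trained.runs.assign(mode="trained"),
             shuffled.runs.assign(mode="shuffled")],
            ignore_index=True,
        )
        metrics.to_csv(out / "metrics.csv", index=False)

        stage("fdci")
        fdci = compute_fdci(trained.macro_accuracies, shuffled.macro_accuracies)
        summary = {
            "fdci": fdci.fdci,
            "numerator": fdci.numerator,
            "denominator": fdci.denominator,
            "trained_mean": trained.mean,
            "trained_sd": trained.sd,
            "shuffled_mean": shuffled.mean,
            "shuffled_sd": shuffled.sd,
        }
        (out / "fdci.json").write_text(json.dumps(summary, indent=2))

        stage("featviz")
        models = trained.models
        if config.featviz_models is not None:
            models = models[: config.featviz_models]
        brains = build_activation_brains(
            models, dataset, cut=config.activation_cut,
            averaging=config.activation_averaging,
        )
        for brain in brains:
            nib.save(
                nib.Nifti1Image(brain.to_volume().astype(np.float32),
                                brain.grid.affine),
                out / f"activation_{brain.disease}.nii",
            )
        roi_mean_matrix(brains, atlas).to_csv(out / "activation_rois.csv")

        stage("vbm")
        _run_vbm_stage(config, cohort, volumes, atlas, dataset, out)
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {log['stages'][-1]!r}: {err}"
        ) from err

    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return out


def _run_vbm_stage(config, cohort, volumes, atlas, dataset, out: Path):
    from .preprocess import AgeResidualizer, smooth_volume, threshold_gm

    grid = volumes[0].grid
    # assemble the per-subject preprocessed volumes VBM compares
    stacks, masks = [], []
    for vol in volumes:
        sm = smooth_volume(vol, fwhm_mm=config.smoothing_fwhm_mm)
        th, m = threshold_gm(sm, min_prob=config.gm_threshold)
        stacks.append(th.data.astype(np.float64))
        masks.append(m)
    arr = np.stack(stacks)
    mask = np.logical_and.reduce(masks)
    if config.vbm_on_residuals:
        ages = cohort["age"].to_numpy()
        arr = AgeResidualizer().fit_transform(arr, ages)
    by_group = {
        g: np.flatnonzero((cohort["group"] == g).to_numpy())
        for g in ("TLE", "AD", "HC")
    }
    lat = cohort["laterality"].to_numpy()
    roi_rows = []
    for ga, gb in (("TLE", "AD"), ("TLE", "HC"), ("AD", "HC")):
        ia, ib = by_group[ga], by_group[gb]
        vbm_map = run_vbm_contrast(
            [arr[i] for i in ia], [arr[i] for i in ib], mask, grid,
            pair=(ga, gb), alpha=config.vbm_alpha, cut=config.vbm_cut,
            mirror_a=(lat[ia] == "left") if ga == "TLE" else None,
            mirror_b=None,
            welch=config.vbm_welch,
        )
        nib.save(
            nib.Nifti1Image(vbm_map.data.astype(np.float32), grid.affine),
            out / f"vbm_{ga}_vs_{gb}.nii",
        )
        roi_rows.append(vbm_roi_summary(vbm_map, atlas))
    pd.DataFrame(roi_rows).to_csv(out / "vbm_rois.csv")
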