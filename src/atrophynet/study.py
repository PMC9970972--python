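"""Desk-scale study conditions: the trained-vs-shuffled null comparison.

This module pins down the reduced-scale replication of the 100+100-model
design: a strongly separable synthetic cohort (60 subjects per group on
the reduced grid, planted regional effects up to 35%, smooth noise
amplitude 0.05), 10 properly trained and 10 shuffled-label models on
fresh random 60/15/25 splits, and the FDCI between the two macro
test-accuracy distributions. The same entry point backs the acceptance
script and the test suite so both report the identical computation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import datasets as ds
from .config import RunConfig
from .evaluation import EnsembleReport, FDCIResult, compute_fdci, run_ensemble
from .grids import get_grid
from .preprocess import SliceDataset, build_slice_dataset, preprocess_volumes

__all__ = ["NullComparison", "build_study_dataset", "run_null_comparison"]


@dataclass
class NullComparison:
    trained: EnsembleReport
    shuffled: EnsembleReport
    fdci: FDCIResult

    @property
    def shuffled_macro_recall_mean(self) -> float:
        return float(self.shuffled.runs["macro_recall"].mean())


def build_study_dataset(config: RunConfig) -> SliceDataset:
    """Generate and preprocess the synthetic cohort for ``config``."""
    grid = get_grid(config.grid)
    atlas = ds.generate_atlas(grid)
    model = ds.AtrophyModel(
        effects=ds.DEFAULT_ATROPHY_MODEL.effects,
        global_effects=ds.DEFAULT_ATROPHY_MODEL.global_effects,
        noise_amplitude=config.noise_amplitude,
        noise_fwhm_mm=config.noise_fwhm_mm,
    )
    ss = np.random.SeedSequence(config.seed)
    cohort_seed, vol_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    cohort = ds.generate_cohort(config.cohort_sizes, seed=cohort_seed)
    volumes = ds.generate_dataset(cohort, atlas, model, seed=vol_seed)
    raw = preprocess_volumes(
        volumes, cohort,
        fwhm_mm=config.smoothing_fwhm_mm,
        gm_threshold=config.gm_threshold,
    )
    return build_slice_dataset(raw, fit_population=config.fit_population)


def run_null_comparison(
    seed: int,
    n_runs: int = 10,
    config: RunConfig | None = None,
    dataset: SliceDataset | None = None,
) -> NullComparison:
    """Run ``n_runs`` trained and ``n_runs`` shuffled models and compare.

    All randomness (cohort, noise fields, splits, label permutations,
    weight initialization, batching) derives from ``seed``.
    """
    if config is None:
        config = RunConfig.reduced_preset(seed=seed, ensemble_runs=n_runs)
    if dataset is None:
        dataset = build_study_dataset(config)
    ss = np.random.SeedSequence(seed + 1)
    t_seed, s_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    trained = run_ensemble(
        dataset, n_runs=n_runs, mode="trained", master_seed=t_seed,
        fractions=config.split_fractions, cnn_params=config.cnn_params(),
    )
    shuffled = run_ensemble(
        dataset, n_runs=n_runs, mode="shuffled", master_seed=s_seed,
        fractions=config.split_fractions, cnn_params=config.cnn_params(),
        shuffle_granularity=config.shuffle_granularity,
    )
    fdci = compute_fdci(trained.macro_accuracies, shuffled.macro_accuracies)
    return NullComparison(trained=trained, shuffled=shuffled, fdci=fdci)
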