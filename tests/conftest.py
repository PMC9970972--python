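import numpy as np
import pandas as pd
import pytest

import atrophynet as an
from atrophynet import datasets as ds
from atrophynet.config import RunConfig
from atrophynet.study import build_study_dataset, run_null_comparison


@pytest.fixture(scope="session")
def reduced_grid():
    return an.REDUCED_GRID


@pytest.fixture(scope="session")
def toy_atlas(reduced_grid):
    return ds.generate_atlas(reduced_grid)


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects/group: enough for nonempty 60/15/25 splits."""
    return ds.generate_cohort({"TLE": 12, "AD": 12, "HC": 12}, seed=11)


@pytest.fixture(scope="session")
def small_volumes(small_cohort, toy_atlas):
    model = ds.AtrophyModel(
        effects=ds.DEFAULT_ATROPHY_MODEL.effects,
        global_effects=ds.DEFAULT_ATROPHY_MODEL.global_effects,
        noise_fwhm_mm=2.5,
        noise_amplitude=0.05,
    )
    return ds.generate_dataset(small_cohort, toy_atlas, model, seed=12)


@pytest.fixture(scope="session")
def small_slices(small_cohort, small_volumes):
    raw = an.preprocess_volumes(small_volumes, small_cohort, fwhm_mm=3.0)
    return an.build_slice_dataset(raw)


@pytest.fixture(scope="session")
def separable_slices():
    """Low-noise, strongly separable cohort for classifier-quality checks."""
    cfg = RunConfig.reduced_preset(seed=21, noise_amplitude=0.02)
    cfg.cohort_sizes = {"TLE": 40, "AD": 40, "HC": 40}
    return build_study_dataset(cfg)


@pytest.fixture(scope="session")
def null_comparison():
    """The desk-scale trained-vs-shuffled study (10 + 10 models).

    Session-scoped because it trains 20 CNNs; shared by the acceptance
    tests for the FDCI and the shuffled-recall checks.
    """
    return run_null_comparison(seed=1, n_runs=10)


@pytest.fixture()
def prediction_table():
    """Hand-enumerable 4-slice prediction table."""
    return pd.DataFrame(
        {
            "subject_id": ["s1", "s1", "s2", "s3"],
            "z_mm": [0, 1, 0, 0],
            "true": ["TLE", "TLE", "AD", "HC"],
            "predicted": ["TLE", "AD", "AD", "HC"],
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
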