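import numpy as np
import pandas as pd
import pytest

from hatkit import cohort_io, imputation
from hatkit import synthetic_cohorts as syn
from hatkit.hat_builder import enumerate_cutoff_grid, select_model


def small_generator_config(seed: int = 7, n: int = 400) -> syn.GeneratorConfig:
    cfg = syn.default_config(seed=seed)
    for c in cfg.cohorts:
        c.n_baseline = n
        c.indicator_missing_rate = 0.05
    return cfg


@pytest.fixture(scope="session")
def small_config():
    return small_generator_config()


@pytest.fixture(scope="session")
def small_tables(small_config):
    return syn.generate_all(small_config)


@pytest.fixture(scope="session")
def harmonized_small(small_config, small_tables):
    tables = dict(small_tables)
    pooled = pd.concat(tables.values(), ignore_index=True)
    model = imputation.fit_pmm(pooled)
    tables["cohort_b"] = imputation.impute(model, tables["cohort_b"], seed=7)
    harm, report = cohort_io.harmonize(list(tables.values()), impute_first=True)
    return harm


SMALL_GRID_SPEC = {
    "gait_speed": [[0.5, 1.0], [0.6, 1.0]],
    "mmse": [[24, 28]],
    "n_chronic": [[2, 5]],
    "iadl": [[1, 3]],
    "padl": [[1]],
}


@pytest.fixture(scope="session")
def hat_model_small(harmonized_small):
    grid = enumerate_cutoff_grid(SMALL_GRID_SPEC)
    model, report = select_model(grid, harmonized_small, n_splits=2, seed=7)
    return model, report


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
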