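"""Shared fixtures: small seeded cohorts and fitted models."""

import numpy as np
import pandas as pd
import pytest

from moe_subtyper import (
    CohortSpec,
    LabeledDataset,
    MOEConfig,
    fit_cn_glm,
    fit_moe,
    generate_cohort,
    residualize,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact 68-ROI cohort with the default planted subtypes."""
    spec = CohortSpec(n_cn=60, n_ad=60, n_mci=45, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_residuals(small_cohort):
    fit = fit_cn_glm(small_cohort.thickness, small_cohort.subjects)
    return residualize(small_cohort.thickness, small_cohort.subjects, fit), fit


@pytest.fixture(scope="session")
def small_dataset(small_cohort, small_residuals):
    residuals, _ = small_residuals
    return LabeledDataset.from_frames(residuals, small_cohort.subjects)


@pytest.fixture(scope="session")
def fitted_model(small_dataset):
    config = MOEConfig(K=3, seed=3, n_restarts=2)
    return fit_moe(small_dataset, config)


@pytest.fixture()
def tiny_dataset():
    """Five subjects, three features, both classes; for exact-arithmetic tests."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(5, 3))
    y = np.array([1, 1, 1, -1, -1])
    return LabeledDataset(X=X, y=y, ids=tuple(f"s{i}" for i in range(5)))


def separable_dataset(n_per=30, gap=4.0, seed=0, p=6):
    """Two well-separated classes along the first feature axis."""
    rng = np.random.default_rng(seed)
    X = rng.normal(scale=0.3, size=(2 * n_per, p))
    X[:n_per, 0] += gap
    y = np.array([1] * n_per + [-1] * n_per)
    return LabeledDataset(X=X, y=y, ids=tuple(f"s{i}" for i in range(2 * n_per)))
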