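"""Shared fixtures: small synthetic cohorts and their feature tables.

Everything is generated programmatically at test time from fixed seeds; the
small cohort (12 subjects, 20 ROIs) keeps unit tests fast, while the
acceptance suite builds its own 24-subject cohort.
"""

import numpy as np
import pytest

import netstate as ns


@pytest.fixture(scope="session")
def small_config() -> ns.SimConfig:
    return ns.SimConfig(n_subjects=12, n_rois=20, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> ns.CohortDataset:
    return ns.make_cohort(small_config)


@pytest.fixture(scope="session")
def ba_table(small_cohort) -> ns.FeatureTable:
    return ns.ba_feature_table(small_cohort)


@pytest.fixture(scope="session")
def dfc_table(small_cohort) -> ns.FeatureTable:
    return ns.dfc_feature_table(small_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    # function-scoped: every test sees the same deterministic stream
    # regardless of execution order
    return np.random.default_rng(20240)
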