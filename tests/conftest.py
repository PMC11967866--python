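import numpy as np
import pandas as pd
import pytest

from msnpipe import CohortSpec, make_cohort, ms_table


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-region, 20+20-subject cohort with a planted d = 0.8 MS effect."""
    spec = CohortSpec(
        n_regions=40, n_subjects_per_group=20, effect_size_d=0.8, seed=11
    )
    groups, ledger = make_cohort(spec)
    return spec, groups, ledger


@pytest.fixture(scope="session")
def small_ms(small_cohort):
    """Subject x region regional-MS tables for the small cohort."""
    _, groups, ledger = small_cohort
    return ms_table(groups["case"]), ms_table(groups["control"]), ledger


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_feature_table(rng, n_regions=20, n_features=9):
    vals = rng.standard_normal((n_regions, n_features))
    return pd.DataFrame(
        vals,
        index=pd.Index([f"r{i:03d}" for i in range(n_regions)], name="region_id"),
        columns=list("ABCDEFGHIJKLMNOP"[:n_features]),
    )
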