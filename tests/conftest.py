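import numpy as np
import pandas as pd
import pytest

from pathmir import ExpressionMatrix, SurvivalTable, simulate_cohort, modulator_scan


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    return ExpressionMatrix(
        pd.DataFrame(
            [[10.0, 20.0, 30.0], [5.0, 6.0, 7.0], [1.0, 0.0, 2.0]],
            index=["fa", "fb", "fc"],
            columns=["s1", "s2", "s3"],
        ),
        unit_tag="count",
    )


@pytest.fixture
def toy_survival():
    # the classic hand-workable six-subject follow-up
    return SurvivalTable(
        pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], "event": [1, 1, 0, 1, 0, 1]},
            index=[f"p{i}" for i in range(6)],
        )
    )


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(seed=1)


@pytest.fixture(scope="session")
def default_scan(default_cohort):
    c = default_cohort
    records, skipped = modulator_scan(
        c.mirna, c.mrna, c.purity, c.gene_sets["PATHWAY_PLANTED"], n_perm=10_000, seed=1
    )
    return records, skipped
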