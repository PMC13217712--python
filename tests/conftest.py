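import numpy as np
import pandas as pd
import pytest

from idiomap import cohort, variability


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic balanced cohort shared by read-only tests."""
    cfg = cohort.balanced_config(seed=7, n_per_group=20, n_rois=60)
    return cohort.generate_cohort(cfg)


@pytest.fixture(scope="session")
def table1_cohort():
    cfg = cohort.table1_config(seed=0, n_rois=120)
    return cohort.generate_cohort(cfg)


def group_mean_variability(phenotype: pd.DataFrame,
                           matrix: pd.DataFrame) -> pd.Series:
    """Mean whole-sample variability per group (test helper)."""
    D = variability.distance_matrix(matrix)
    scores = variability.variability_scores(D, phenotype,
                                            schemes=("whole",))
    merged = scores.join(phenotype.set_index("id")["group"])
    return merged.groupby("group")["variability_whole"].mean()
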