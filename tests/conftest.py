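import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import metabophen as mp
from metabophen.synthdata import EffectPlan, generate_tables

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """Study-shaped cohort: 3 x 10 samples, 7F/3M, 2 batches."""
    return mp.generate_cohort(seed=11)


@pytest.fixture(scope="session")
def small_tables(cohort):
    """Small two-matrix dataset with planted single and ratio effects."""
    plan = EffectPlan(
        n_affected_cells=3, n_affected_media=3, effect=2.0,
        n_ratio_pairs=2, ratio_effect=2.0,
    )
    return generate_tables(
        cohort, n_cell_mets=60, n_media_mets=50, n_shared=30,
        n_panel=12, n_panel_cells_only=1, n_panel_media_only=1,
        plan=plan, seed=12,
    )


@pytest.fixture(scope="session")
def normalized(small_tables):
    return (
        mp.normalize_matrix(small_tables.cells),
        mp.normalize_matrix(small_tables.media),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_table():
    """3 samples x 2 metabolites, one missing value, single batch."""
    values = pd.DataFrame(
        {"MA": [2.0, 4.0, 6.0], "MB": [1.0, np.nan, 3.0]},
        index=["S1", "S2", "S3"],
    )
    batch = pd.Series([0, 0, 0], index=values.index, name="batch")
    return mp.RawAbundanceTable("MEDIA", values, batch)
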