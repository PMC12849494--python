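import numpy as np
import pandas as pd
import pytest

from salivaflux import (
    MetaboliteTable,
    FeatureTable,
    SimulationParams,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    params = SimulationParams(n_control=15, n_t2d=15, n_metabolites=30,
                              n_taxa=40, seed=7)
    return generate_cohort(params)


@pytest.fixture()
def tiny_metabolite_table():
    """Hand-built 4-sample, 3-metabolite table with IS column."""
    values = pd.DataFrame(
        {
            "glucose": [10.0, 8.0, 8.0, 6.0],
            "fructose": [4.0, 4.0, 2.0, 2.0],
            "ribitol": [2.0, 4.0, 1.0, 1.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    sample_meta = pd.DataFrame(
        {
            "fluid": "plasma",
            "participant": ["p1", "p2", "p3", "p4"],
            "timepoint": "baseline",
            "injection_order": [0, 1, 2, 3],
            "batch": "b1",
            "role": "biological",
            "sample_amount": [1.0, 1.0, 0.5, 2.0],
        },
        index=values.index,
    )
    metabolite_meta = pd.DataFrame(
        {"internal_standard": [False, False, True]}, index=values.columns
    )
    return MetaboliteTable(values, sample_meta, metabolite_meta)


def make_feature_table(values: np.ndarray, level: str = "species",
                       feature_names=None, sample_names=None) -> FeatureTable:
    values = np.asarray(values, float)
    m, n = values.shape
    feature_names = feature_names or [f"f{i+1}" for i in range(m)]
    sample_names = sample_names or [f"s{j+1}" for j in range(n)]
    df = pd.DataFrame(values, index=feature_names, columns=sample_names)
    meta = pd.DataFrame({"level": level, "phylum": None}, index=df.index)
    return FeatureTable(df, meta)
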