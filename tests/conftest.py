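import numpy as np
import pandas as pd
import pytest

from podqsar import (
    FeatureTable,
    ForestSpec,
    PODDataset,
    SelectionSpec,
    simulate,
)
from podqsar.ingest import EffectCategory


@pytest.fixture
def small_table() -> FeatureTable:
    """5 chemicals x 3 features (one binary), one missing cell."""
    ids = [f"DTXSID{i}" for i in range(1, 6)]
    values = pd.DataFrame(
        {
            "WS": [1.0, 2.0, np.nan, 4.0, 5.0],
            "LogP": [0.1, -0.2, 0.3, 0.4, -0.5],
            "Biodeg": [0.0, 1.0, 1.0, 0.0, 1.0],
        },
        index=pd.Index(ids, name="DTXSID"),
    )
    return FeatureTable(values=values)


@pytest.fixture
def labeled_data():
    """Small synthetic labeled set: 3 informative of 8 features, n=90."""
    spec = simulate.SyntheticSpec(
        n_chemicals=90,
        n_features=8,
        informative_features=((0, 1.2), (1, 1.0), (2, 1.0)),
        binary_features=(6, 7),
        noise_sd=0.3,
        missingness=0.05,
        seed=42,
    )
    return simulate.generate_labeled_data(spec)


@pytest.fixture
def fast_specs():
    """Deliberately small forest/selection settings for quick tests."""
    return (
        ForestSpec(n_trees=25, seed=0),
        SelectionSpec(k=4, inner_repeats=1, n_permutations=3, seed=0),
    )


def make_pods(ids, log10_pod, study_count=None,
              category=EffectCategory.GENERAL_NONCANCER) -> PODDataset:
    n = len(ids)
    return PODDataset(
        category,
        pd.DataFrame(
            {
                "log10_pod": np.asarray(log10_pod, dtype=float),
                "study_count": study_count if study_count is not None
                else np.full(n, 5),
            },
            index=pd.Index(ids, name="DTXSID"),
        ),
    )
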