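import numpy as np
import pandas as pd
import pytest

from ratioage import FeatureTable, SyntheticSpec, simulate_cohort


def make_table(values, ages=None, batches=None, sexes=None):
    """Hand-built FeatureTable from a 2-D array; metadata filled with defaults."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = pd.Index([f"S{i}" for i in range(n)])
    feature_ids = pd.Index([f"M{100 + j}T{10 + j}" for j in range(p)])
    meta = pd.DataFrame(
        {
            "age": ages if ages is not None else np.linspace(20, 60, n),
            "batch": batches if batches is not None else ["B0"] * n,
            "sex": sexes if sexes is not None else ["M"] * n,
            "date": pd.Timestamp("2018-06-01"),
        },
        index=sample_ids,
    )
    return FeatureTable(pd.DataFrame(values, index=sample_ids, columns=feature_ids), meta)


@pytest.fixture
def toy_table():
    return make_table(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [5.0, 1.0, 2.0, 8.0]],
        ages=[20.0, 30.0, 40.0],
    )


@pytest.fixture(scope="session")
def clean_cohort():
    """Small noise-free-technical cohort with a strong planted signal."""
    spec = SyntheticSpec(
        n_samples=300, n_features=40, n_batches=5, n_informative=10,
        effect_size_range=(0.45, 0.55), dilution_cv=0.0, batch_shift_sd=0.0,
        missing_rate_range=(0.0, 0.0), seed=7,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Cohort with dilution, batch effects and missingness."""
    spec = SyntheticSpec(
        n_samples=400, n_features=60, n_batches=8, n_informative=12,
        dilution_cv=0.3, batch_shift_sd=0.5, missing_rate_range=(0.0, 0.1),
        seed=11,
    )
    return simulate_cohort(spec)
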