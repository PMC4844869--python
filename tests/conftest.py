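import numpy as np
import pytest

from mirocc import FeatureTable, OUTLIER, TARGET, SyntheticSpec, gen_feature_table


def make_table(values, labels, feature_names=None, sample_ids=None) -> FeatureTable:
    values = np.asarray(values, dtype=float)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(values.shape[1])]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(values.shape[0])]
    return FeatureTable(
        sample_ids=sample_ids,
        feature_names=feature_names,
        values=values,
        labels=np.asarray(labels, dtype=object),
    )


@pytest.fixture
def tiny_table() -> FeatureTable:
    """6 samples x 3 features; f0 separates the classes perfectly."""
    values = [
        [0.0, 1.0, 5.0],
        [0.1, 2.0, 5.0],
        [0.2, 3.0, 5.0],
        [1.0, 1.5, 5.0],
        [1.1, 2.5, 5.0],
        [1.2, 3.5, 5.0],
    ]
    labels = [TARGET] * 3 + [OUTLIER] * 3
    return make_table(values, labels)


@pytest.fixture
def planted_table() -> FeatureTable:
    """Small planted benchmark: informative, redundant, sparse, noise groups."""
    spec = SyntheticSpec(
        n_target=60,
        n_outlier=80,
        n_informative=5,
        delta=2.5,
        n_redundant_clusters=4,
        cluster_size=4,
        rho=0.95,
        n_sparse=6,
        sparse_p=0.7,
        n_noise=40,
        seed=11,
    )
    return gen_feature_table(spec)
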