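import numpy as np
import pandas as pd
import pytest

from refsel import (
    RefsConfig,
    SynthConfig,
    encode_labels,
    generate_cohort,
    zscore_normalize,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-gene planted cohort at the study's group sizes, z-scored."""
    cfg = SynthConfig(n_genes=300, seed=11)
    matrix, labels, truth = generate_cohort(cfg)
    return zscore_normalize(matrix), labels, truth


@pytest.fixture(scope="session")
def tiny_xy():
    """20 samples x 8 features with one feature equal to the class."""
    rng = np.random.default_rng(0)
    y = np.array([0, 1] * 10)
    X = rng.normal(size=(8, 20))
    X[0] = y * 4.0 - 2.0  # feature G01 separates perfectly
    matrix = pd.DataFrame(X, index=[f"G{i + 1:02d}" for i in range(8)], columns=[f"s{i}" for i in range(20)])
    return matrix, y


@pytest.fixture
def fast_cfg():
    """A 2-fold roster config for cheap unit tests."""
    return RefsConfig(n_folds=2, n_runs=2, seed=0)


@pytest.fixture
def three_group_labels():
    groups = {"s1": "responder", "s2": "nonresponder", "s3": "control", "s4": "responder"}
    return encode_labels(groups, ["s1", "s2", "s3", "s4"])
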