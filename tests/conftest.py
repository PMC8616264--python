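import pandas as pd
import pytest

from mbdpipe import (
    CountSimConfig,
    FeatureCountMatrix,
    simulate_annotation,
    simulate_counts,
)


@pytest.fixture(scope="session")
def toy_annotation():
    """Small random annotation (50 islands) shared across tests."""
    return simulate_annotation(50, seed=7)


@pytest.fixture(scope="session")
def toy_dataset(toy_annotation):
    """Simulated count matrix with planted effects plus its ground truth."""
    features, _ = toy_annotation
    cfg = CountSimConfig(seed=11, planted_fraction=0.2)
    return simulate_counts(cfg, features)


@pytest.fixture
def tiny_matrix():
    """Hand-sized 4-feature, 4-sample matrix for rule-level tests."""
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 5, 3],
            "s2": [12, 0, 7, 2],
            "s3": [9, 0, 6, 4],
            "s4": [11, 0, 8, 1],
        },
        index=["chr1:100-200", "chr1:300-400", "chr1:500-600", "chr1:700-800"],
    )
    classes = pd.Series(
        ["island", "island", "shore", "inter"], index=counts.index
    )
    groups = pd.Series(
        ["case", "case", "control", "control"], index=counts.columns
    )
    return FeatureCountMatrix(counts, classes, groups)
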