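import numpy as np
import pandas as pd
import pytest

from emabench.data_model import (
    EMADataset,
    FeatureSchema,
    FeatureSpec,
    TargetSpec,
)
from emabench.synthetic_ema import GeneratorConfig, generate


def make_dataset(rows, feature_kinds, raw_kind="continuous_0_1", n_classes=5):
    """Build an EMADataset from (id, user, iso-time, target, *features) tuples."""
    names = list(feature_kinds)
    frame = pd.DataFrame(
        rows,
        columns=["assessment_id", "user_id", "timestamp", "target_raw", *names],
    )
    schema = FeatureSchema(tuple(FeatureSpec(n, k) for n, k in feature_kinds.items()))
    return EMADataset(frame, schema, TargetSpec("target", raw_kind, n_classes))


@pytest.fixture
def two_user_dataset():
    """Two users, 3 + 2 assessments, one numeric and one categorical feature."""
    rows = [
        ("a1", "alice", "2021-01-01T00:00:00Z", 0.10, 1.0, "x"),
        ("a2", "alice", "2021-01-01T10:00:00Z", 0.30, np.nan, "x"),
        ("a3", "alice", "2021-01-01T22:00:00Z", 0.55, 4.0, "y"),
        ("b1", "bob", "2021-01-02T00:00:00Z", 0.90, 2.0, np.nan),
        ("b2", "bob", "2021-01-03T00:00:00Z", 1.00, 2.0, "z"),
    ]
    return make_dataset(rows, {"mood": "numeric", "context": "categorical"})


@pytest.fixture(scope="session")
def small_synthetic():
    return generate(GeneratorConfig(n_users=40, count_dist=(6.0, 0.8), seed=7))
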