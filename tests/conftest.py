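import numpy as np
import pytest

from healthycore.datamodel import (
    FeatureDescriptor,
    FeatureTable,
    SubjectRecord,
    default_desikan_features,
)


def make_table(values, site="DS1", group="HC", features=None, prefix=None, sexes=None):
    """FeatureTable from a raw matrix with minimal synthetic metadata."""
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    if features is None:
        features = small_features(d)
    prefix = prefix or f"{site}_{group}"
    subjects = [
        SubjectRecord(
            subject_id=f"{prefix}_{i:03d}",
            site_id=site,
            group=group,
            age=30.0 + i,
            sex=(sexes[i] if sexes is not None else ("F" if i % 2 == 0 else "M")),
        )
        for i in range(n)
    ]
    return FeatureTable(subjects=subjects, features=list(features), values=values)


def small_features(d):
    """First d descriptors of the full atlas, canonical order."""
    full = default_desikan_features()
    assert d <= len(full)
    return full[:d]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_pair(rng):
    """Two iid standard-Gaussian cohorts of 30 x 6."""
    A = make_table(rng.standard_normal((30, 6)), site="DS1")
    B = make_table(rng.standard_normal((30, 6)), site="DS2")
    return A, B
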