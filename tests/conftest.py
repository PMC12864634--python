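import numpy as np
import pytest

from metabf import MetaDataset, StudyRecord


def make_dataset(pairs, start_year=2000, label_prefix="s"):
    """MetaDataset from a list of (y, se) pairs with sequential years."""
    return MetaDataset(tuple(
        StudyRecord(f"{label_prefix}{i}", start_year + i, y=float(y), se=float(se))
        for i, (y, se) in enumerate(pairs)
    ))


@pytest.fixture
def three_study_dataset():
    """Small heterogeneous dataset used across modules."""
    return make_dataset([(-0.5, 0.3), (-0.2, 0.25), (-0.8, 0.4)])


@pytest.fixture
def five_study_dataset():
    return make_dataset([(-0.5, 0.3), (-0.2, 0.25), (-0.8, 0.4),
                         (0.1, 0.2), (-0.3, 0.35)])


@pytest.fixture
def single_study_dataset():
    return make_dataset([(0.0, 1.0)])
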