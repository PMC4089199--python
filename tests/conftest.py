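import numpy as np
import pytest

from protsel import (
    LabeledDataset,
    ProteinSequence,
    encode_dataset,
    enumerate_feature_space,
)

#: the five worked-example sequences used throughout the encoding tests
SAMPLE_SEQUENCES = [
    "MKVLIFACM",
    "MKLCMKVL",
    "ACMKVLIFAC",
    "MKLIFACM",
    "CMKVIFACM",
]


@pytest.fixture(scope="session")
def space3():
    return enumerate_feature_space(3)


@pytest.fixture(scope="session")
def sample_records():
    return [ProteinSequence(f"s{i+1}", s) for i, s in enumerate(SAMPLE_SEQUENCES)]


@pytest.fixture()
def tiny_dataset():
    """Two classes x three sequences, long enough for all three k-blocks."""
    mk = lambda label, i, s: ProteinSequence(f"{label}{i}", s)
    seqs_a = [
        mk("a", 1, "MKVLIFACMMKV"),
        mk("a", 2, "MKVACDEFGHIK"),
        mk("a", 3, "MKVMKVLIFACM"),
    ]
    seqs_b = [
        mk("b", 1, "WYWYWYACDEFG"),
        mk("b", 2, "WYACDEFGHIKL"),
        mk("b", 3, "WYWYACDACDEF"),
    ]
    return LabeledDataset(classes=["alpha", "beta"], sequences={"alpha": seqs_a, "beta": seqs_b})


@pytest.fixture()
def tiny_matrix(tiny_dataset, space3):
    matrix, labels, ids = encode_dataset(tiny_dataset, space3)
    return matrix, labels, ids


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
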