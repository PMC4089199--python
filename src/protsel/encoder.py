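"""Fixed n-gram descriptor universe and frequency encoding.

Every protein sequence is mapped to a vector over the full ordered universe
of k-grams of the 20 standard amino acids for k = 1..n_max (20 + 400 + 8000
= 8420 descriptors for n_max = 3). Within each k-block a descriptor's value
is its overlapping-window count divided by the number of valid windows
(L - k + 1 for a clean sequence), so each populated block sums to 1.

Windows that overlap a flagged non-standard residue (policy ``drop_ngrams``
at read time) are excluded from both the counts and the denominator.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import DatasetError, ParameterError
from .io import AMINO_ACIDS, LabeledDataset, ProteinSequence

MAX_NMAX = 5  # 20^6 descriptors would be unreasonable to materialize


@dataclass(frozen=True)
class NGramFeatureSpace:
    """Ordered universe of all k-grams, k ascending then lexicographic."""

    n_max: int
    descriptors: tuple[str, ...]
    index: dict[str, int] = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.descriptors)

    def block_range(self, k: int) -> tuple[int, int]:
        """Half-open column range [start, stop) of the k-gram block."""
        if not 1 <= k <= self.n_max:
            raise ParameterError(f"k={k} outside 1..{self.n_max}")
        start = sum(20**i for i in range(1, k))
        return start, start + 20**k


def enumerate_feature_space(n_max: int = 3) -> NGramFeatureSpace:
    """Materialize the descriptor universe for k = 1..n_max."""
    if not isinstance(n_max, int) or not 1 <= n_max <= MAX_NMAX:
        raise ParameterError(f"n_max must be an integer in 1..{MAX_NMAX}, got {n_max!r}")
    descriptors: list[str] = []
    for k in range(1, n_max + 1):
        descriptors.extend("".join(p) for p in itertools.product(AMINO_ACIDS, repeat=k))
    index = {d: i for i, d in enumerate(descriptors)}
    return NGramFeatureSpace(n_max=n_max, descriptors=tuple(descriptors), index=index)


@dataclass(frozen=True)
class FeatureVector:
    """One sequence's sparse frequency vector (absent index = 0)."""

    sequence_id: str
    values: dict[int, float]


def count_kgrams(seq: ProteinSequence, k: int) -> tuple[Counter, int]:
    """Overlapping k-gram counts and the number of valid windows.

    A window starting at p is valid iff none of p..p+k-1 is a flagged
    non-standard position. Sequences shorter than k yield empty counts and
    denominator 0.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    s = seq.residues
    n_windows = len(s) - k + 1
    counts: Counter = Counter()
    if n_windows <= 0:
        return counts, 0
    if seq.is_clean:
        for p in range(n_windows):
            counts[s[p : p + k]] += 1
        return counts, n_windows
    invalid = set(seq.invalid_positions)
    denominator = 0
    for p in range(n_windows):
        if any(q in invalid for q in range(p, p + k)):
            continue
        counts[s[p : p + k]] += 1
        denominator += 1
    return counts, denominator


def encode_sequence(seq: ProteinSequence, space: NGramFeatureSpace) -> FeatureVector:
    """Frequency-encode one sequence over the full descriptor universe."""
    values: dict[int, float] = {}
    for k in range(1, space.n_max + 1):
        counts, denom = count_kgrams(seq, k)
        if denom == 0:
            continue
        for gram, c in counts.items():
            values[space.index[gram]] = c / denom
    return FeatureVector(sequence_id=seq.id, values=values)


def encode_dataset(
    ds: LabeledDataset, space: NGramFeatureSpace
) -> tuple[sp.csr_matrix, np.ndarray, list[str]]:
    """Encode a dataset into a sparse matrix.

    Returns ``(matrix, labels, sequence_ids)`` with rows in class order then
    within-class input order, columns aligned with ``space.descriptors``.
    """
    if not ds.classes or ds.n_sequences == 0:
        raise DatasetError("cannot encode an empty dataset")
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    labels: list[str] = []
    ids: list[str] = []
    r = 0
    for label, seq in ds.iter_rows():
        fv = encode_sequence(seq, space)
        for j, v in fv.values.items():
            rows.append(r)
            cols.append(j)
            data.append(v)
        labels.append(label)
        ids.append(seq.id)
        r += 1
    matrix = sp.csr_matrix(
        (data, (rows, cols)), shape=(r, space.size), dtype=np.float64
    )
    return matrix, np.asarray(labels, dtype=object), ids


def format_frequency(x: float, decimals: int = 2) -> str:
    """Display formatting: truncate toward zero (2/7 -> '0.28', 1/6 -> '0.16').

    Internal arithmetic is never truncated; this is purely presentational.
    """
    scale = 10**decimals
    # guard against 0.1*100 = 10.000000000000002-style float noise
    truncated = math.floor(x * scale + 1e-9) / scale
    return f"{truncated:.{decimals}f}"
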