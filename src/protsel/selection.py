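"""Statistical metric-based feature subset selection.

For each superfamily i the per-feature mean X̄_i(j) and sample variance
S_i²(j) (divisor N_i − 1) are computed over its encoded sequences. For every
unordered class pair (p, q) a separation statistic vd_pq(j) is formed, the
final metric vd(j) is the minimum over all pairs, and the features with the
largest final metric — those that discriminate *every* pair simultaneously —
are selected.

Two forms of the pair statistic are provided:

``as_printed`` (default)
    vd_pq(j) = |X̄_p − X̄_q| / (S_p²/N_total + S_q²/N_total), where N_total is
    the feature-space size. No square root.
``welch``
    vd_pq(j) = |X̄_p − X̄_q| / sqrt(S_p²/N_p + S_q²/N_q), the standard Welch
    two-sample statistic that the first form closely resembles.

A zero denominator with a zero numerator gives 0; with a positive numerator
it gives +inf (such a feature separates the pair perfectly and outranks all
finite values).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.sparse as sp

from .errors import DegenerateClassError, ParameterError, ShapeError

VARIANTS = ("as_printed", "welch")


@dataclass(frozen=True)
class ClassStatistics:
    """Per-class mean and sample variance vectors over the feature space."""

    class_label: str
    n_sequences: int
    mean: np.ndarray
    variance: np.ndarray


@dataclass(frozen=True)
class SelectionResult:
    pair_labels: tuple[tuple[str, str], ...]
    pair_metric: np.ndarray  # (n_pairs, n_features)
    final_metric: np.ndarray  # (n_features,)
    ranking: np.ndarray  # all feature indices, best first
    selected: np.ndarray  # first k of ranking (or threshold subset)
    k: int
    variant: str


def class_statistics(
    matrix: sp.spmatrix | np.ndarray, labels: np.ndarray, class_label: str
) -> ClassStatistics:
    """Mean and sample variance of one class's rows (full precision)."""
    mask = np.asarray(labels) == class_label
    n = int(mask.sum())
    if n < 2:
        raise DegenerateClassError(
            f"class {class_label!r} has {n} row(s); variance needs N_i - 1 >= 1"
        )
    rows = matrix[mask]
    if sp.issparse(rows):
        mean = np.asarray(rows.mean(axis=0)).ravel()
        sumsq = np.asarray(rows.multiply(rows).sum(axis=0)).ravel()
    else:
        rows = np.asarray(rows, dtype=np.float64)
        mean = rows.mean(axis=0)
        sumsq = (rows * rows).sum(axis=0)
    variance = (sumsq - n * mean * mean) / (n - 1)
    np.maximum(variance, 0.0, out=variance)  # clamp negative rounding residue
    return ClassStatistics(class_label, n, mean, variance)


def pairwise_metric(
    stats_p: ClassStatistics,
    stats_q: ClassStatistics,
    n_total: int,
    variant: str = "as_printed",
) -> np.ndarray:
    """Per-feature separation statistic for one class pair."""
    if variant not in VARIANTS:
        raise ParameterError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if stats_p.mean.shape != stats_q.mean.shape:
        raise ShapeError(
            f"feature spaces differ: {stats_p.mean.shape} vs {stats_q.mean.shape}"
        )
    num = np.abs(stats_p.mean - stats_q.mean)
    if variant == "as_printed":
        denom = stats_p.variance / n_total + stats_q.variance / n_total
    else:
        denom = np.sqrt(
            stats_p.variance / stats_p.n_sequences
            + stats_q.variance / stats_q.n_sequences
        )
    out = np.zeros_like(num)
    pos = denom > 0
    out[pos] = num[pos] / denom[pos]
    out[(~pos) & (num > 0)] = np.inf
    return out


def final_metric(pair_metrics: np.ndarray) -> np.ndarray:
    """Elementwise minimum over pair rows; +inf rows participate normally."""
    pair_metrics = np.asarray(pair_metrics)
    if pair_metrics.ndim != 2 or pair_metrics.shape[0] < 1:
        raise ShapeError("pair_metrics must be a non-empty 2-D (pairs x features) array")
    return pair_metrics.min(axis=0)


def rank_features(metric: np.ndarray) -> np.ndarray:
    """Indices sorted by metric descending, ties broken by ascending index."""
    metric = np.asarray(metric)
    return np.lexsort((np.arange(metric.size), -metric))


def select_features(
    pair_labels: tuple[tuple[str, str], ...],
    pair_metric: np.ndarray,
    k: int,
    variant: str = "as_printed",
    min_metric: float | None = None,
) -> SelectionResult:
    """Assemble a :class:`SelectionResult` keeping the top-k features.

    With ``min_metric`` set, the selected set is additionally restricted to
    features whose final metric meets the threshold.
    """
    vd = final_metric(pair_metric)
    n_total = vd.size
    if not 1 <= k <= n_total:
        raise ParameterError(f"k={k} outside 1..{n_total}")
    ranking = rank_features(vd)
    selected = ranking[:k]
    if min_metric is not None:
        selected = selected[vd[selected] >= min_metric]
    return SelectionResult(
        pair_labels=tuple(pair_labels),
        pair_metric=np.asarray(pair_metric),
        final_metric=vd,
        ranking=ranking,
        selected=selected,
        k=k,
        variant=variant,
    )


def fit_selection(
    matrix: sp.spmatrix | np.ndarray,
    labels: np.ndarray,
    k: int = 50,
    variant: str = "as_printed",
    min_metric: float | None = None,
) -> SelectionResult:
    """End-to-end selection on a labeled feature matrix.

    Classes are taken in first-appearance order of ``labels``; for C classes
    the pair statistic matrix has C(C-1)/2 rows.
    """
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels.tolist()))
    if len(classes) < 2:
        raise DegenerateClassError("selection needs at least 2 classes")
    n_total = matrix.shape[1]
    stats = {c: class_statistics(matrix, labels, c) for c in classes}
    pair_labels = tuple(combinations(classes, 2))
    pair_metric = np.vstack(
        [pairwise_metric(stats[p], stats[q], n_total, variant) for p, q in pair_labels]
    )
    return select_features(pair_labels, pair_metric, k, variant, min_metric)
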