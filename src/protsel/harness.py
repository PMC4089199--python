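"""Experimental protocol: repeated stratified 70/30 splits, train-only
feature selection, interchangeable classifier back-ends.

Each run draws its own stratified split (seed + run index), fits the class
statistics and the feature selection on the *training partition only*,
restricts both partitions to the selected columns, trains the configured
classifier and evaluates on the held-out partition. Aggregates report the
mean and standard deviation of each metric over runs. An optional k-fold
cross-validation mode replaces the repeated splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import DatasetError, ParameterError
from .metrics import EvaluationReport, ConfusionMatrix, compute_report, confusion_from_predictions
from .selection import SelectionResult, fit_selection

CLASSIFIERS = ("naive_bayes", "decision_tree", "random_forest", "neural_network", "svm")

AGGREGATE_METRICS = ("accuracy", "sensitivity", "specificity", "precision", "F-measure", "MCC")


@dataclass
class ExperimentConfig:
    n_runs: int = 10
    train_fraction: float = 0.70
    classifier: str = "naive_bayes"
    classifier_params: dict = field(default_factory=dict)
    k_features: int | None = 50  # None = no selection, use all features
    variant: str = "as_printed"
    seed: int = 0
    split: str = "stratified"  # or "prefix" (literal first-70% reading)
    cv_folds: int | None = None  # k-fold CV instead of repeated splits

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ParameterError(f"train_fraction must be in (0,1), got {self.train_fraction}")
        if self.n_runs < 1:
            raise ParameterError(f"n_runs must be >= 1, got {self.n_runs}")
        if self.classifier not in CLASSIFIERS:
            raise ParameterError(f"classifier must be one of {CLASSIFIERS}")
        if self.split not in ("stratified", "prefix"):
            raise ParameterError(f"split must be 'stratified' or 'prefix', got {self.split!r}")
        if self.cv_folds is not None and self.cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")


@dataclass
class RunResult:
    run_index: int
    selected_features: np.ndarray | None
    selection: SelectionResult | None
    confusion: ConfusionMatrix
    report: EvaluationReport
    train_indices: np.ndarray
    test_indices: np.ndarray


def stratified_split(
    labels: np.ndarray, train_fraction: float, seed: int, mode: str = "stratified"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split closest to ``train_fraction`` with >= 1 row each side.

    ``mode='prefix'`` takes the first rows of each class in input order
    instead of shuffling (deterministic, seed-independent).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_parts: list[np.ndarray] = []
    test_parts: list[np.ndarray] = []
    for c in dict.fromkeys(labels.tolist()):
        idx = np.flatnonzero(labels == c)
        n = idx.size
        if n < 2:
            raise DatasetError(f"class {c!r} has {n} row(s); cannot split")
        n_train = int(np.floor(n * train_fraction + 0.5))
        n_train = min(max(n_train, 1), n - 1)
        if mode == "stratified":
            idx = rng.permutation(idx)
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    return np.concatenate(train_parts), np.concatenate(test_parts)


def make_classifier(name: str, params: dict, seed: int):
    """Instantiate a back-end with ecosystem defaults (the back-ends are
    plumbing, not the contribution). The neural network uses one hidden
    layer of 10 units and up to 500 epochs."""
    if name == "naive_bayes":
        return GaussianNB(**params)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if name == "neural_network":
        defaults = dict(hidden_layer_sizes=(10,), max_iter=500)
        defaults.update(params)
        return MLPClassifier(random_state=seed, **defaults)
    if name == "svm":
        return SVC(random_state=seed, **params)
    raise ParameterError(f"unknown classifier {name!r}")


def _dense(matrix, rows: np.ndarray, cols: np.ndarray | None) -> np.ndarray:
    sub = matrix[rows]
    if cols is not None:
        sub = sub[:, cols]
    return sub.toarray() if sp.issparse(sub) else np.asarray(sub)


def _one_run(matrix, labels, classes, config, run_index, train_idx, test_idx) -> RunResult:
    selection = None
    cols = None
    if config.k_features is not None:
        selection = fit_selection(
            matrix[train_idx],
            labels[train_idx],
            k=config.k_features,
            variant=config.variant,
        )
        cols = selection.selected
    x_train = _dense(matrix, train_idx, cols)
    x_test = _dense(matrix, test_idx, cols)
    clf = make_classifier(
        config.classifier, dict(config.classifier_params), config.seed + run_index
    )
    try:
        clf.fit(x_train, labels[train_idx])
        predicted = clf.predict(x_test)
    except Exception as exc:  # surface context per the harness contract
        counts = {c: int((labels[train_idx] == c).sum()) for c in classes}
        raise RuntimeError(
            f"classifier {config.classifier!r} failed on run {run_index} "
            f"(train class counts {counts}): {exc}"
        ) from exc
    cm = confusion_from_predictions(labels[test_idx], predicted, classes)
    return RunResult(
        run_index=run_index,
        selected_features=cols,
        selection=selection,
        confusion=cm,
        report=compute_report(cm),
        train_indices=train_idx,
        test_indices=test_idx,
    )


def run_experiment(
    matrix, labels, config: ExperimentConfig
) -> tuple[list[RunResult], dict]:
    """Execute the full protocol; returns per-run results and aggregates.

    Aggregates carry ``mean`` and ``sd`` of accuracy and the macro-averaged
    panel metrics over runs, plus the summed confusion matrix.
    """
    config.validate()
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels.tolist()))
    if len(classes) < 2:
        raise DatasetError("need at least 2 classes")

    runs: list[RunResult] = []
    if config.cv_folds is not None:
        skf = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.seed
        )
        for r, (train_idx, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
            runs.append(_one_run(matrix, labels, classes, config, r, train_idx, test_idx))
    else:
        for r in range(config.n_runs):
            train_idx, test_idx = stratified_split(
                labels, config.train_fraction, config.seed + r, mode=config.split
            )
            runs.append(_one_run(matrix, labels, classes, config, r, train_idx, test_idx))

    aggregate = _aggregate(runs, classes)
    return runs, aggregate


def _aggregate(runs: list[RunResult], classes: list[str]) -> dict:
    values: dict[str, list[float]] = {m: [] for m in AGGREGATE_METRICS}
    summed = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for rr in runs:
        values["accuracy"].append(rr.report.accuracy)
        for m in AGGREGATE_METRICS[1:]:
            values[m].append(rr.report.macro[m])
        summed += rr.confusion.counts
    out = {
        m: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
        for m, v in values.items()
    }
    out["n_runs"] = len(runs)
    out["confusion_sum"] = ConfusionMatrix(tuple(classes), summed)
    return out
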