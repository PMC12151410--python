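"""Repeated split-sample evaluation of a feature-selection configuration.

One run = one seeded stratified 70/30 partition; feature selection sees
only the training rows, a classifier is trained on the selected features
and scored on the held-out rows with the five confusion-matrix metrics
(minority class = positive). Repeating over seeds gives mean +/- SD per
metric plus a per-feature selection-frequency table, the usual way
selection stability is reported across resamples.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .containers import ExpressionMatrix, LabelVector
from .exceptions import (
    ConfigurationError,
    EmptyRefinementError,
    InsufficientClassError,
    MWRDSError,
    StageError,
    ValidationError,
)
from .selection import SelectorConfig, mwrds_select

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f1", "precision")

CLASSIFIERS = {
    "rf": lambda seed: RandomForestClassifier(random_state=seed),
    "svm": lambda seed: SVC(),
    "wknn": lambda seed: KNeighborsClassifier(weights="distance"),
}


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with the minority class as positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, sensitivity, specificity, F1 and precision in [0, 1].

    ``degenerate`` names the metrics whose denominator was 0 and which
    were therefore reported as 0 rather than NaN.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    precision: float
    degenerate: tuple = ()

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass(frozen=True)
class RunRecord:
    """One split-sample run: seed, selected features, test metrics."""

    seed: int
    selected: tuple
    metrics: MetricSet


@dataclass(frozen=True)
class RepeatedEvalSummary:
    """Mean +/- SD per metric plus feature selection frequencies."""

    n_runs: int
    mean: dict
    sd: dict
    runs: tuple
    selection_frequency: dict = field(default_factory=dict)


def stratified_split(
    X: ExpressionMatrix,
    labels: LabelVector,
    train_frac: float = 0.7,
    seed: int = 0,
):
    """Seeded per-class proportional split into train and test.

    Each class contributes ``round(train_frac * n_class)`` training
    samples, clamped so both partitions keep at least one sample of each
    class; partitions are disjoint and exhaustive.
    """
    if not 0 < train_frac < 1:
        raise ConfigurationError(f"train_frac must lie in (0, 1), got {train_frac}")
    if len(labels) != X.n_samples:
        raise ValidationError("labels do not match the matrix")
    rng = np.random.default_rng(seed)
    train_idx: list = []
    test_idx: list = []
    for cls in labels.classes:
        idx = np.flatnonzero(labels.labels == cls)
        if idx.size < 2:
            raise InsufficientClassError(
                f"class {cls!r} has {idx.size} sample(s); need >= 2 to split"
            )
        n_train = int(np.floor(train_frac * idx.size + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx = np.sort(np.asarray(train_idx))
    test_idx = np.sort(np.asarray(test_idx))
    return (
        (X.subset_samples(train_idx), labels.subset(train_idx)),
        (X.subset_samples(test_idx), labels.subset(test_idx)),
    )


def confusion_metrics(counts: ConfusionCounts) -> MetricSet:
    """The five metrics; any 0/0 denominator yields 0 and is flagged."""
    if counts.total == 0:
        raise ValidationError("empty confusion matrix")
    degenerate = []

    def ratio(name, num, den):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    acc = (counts.tp + counts.tn) / counts.total
    sens = ratio("sensitivity", counts.tp, counts.tp + counts.fn)
    spec = ratio("specificity", counts.tn, counts.tn + counts.fp)
    prec = ratio("precision", counts.tp, counts.tp + counts.fp)
    f1 = ratio("f1", 2 * prec * sens, prec + sens)
    return MetricSet(acc, sens, spec, f1, prec, tuple(degenerate))


def _count_confusion(y_true_minority: np.ndarray, y_pred_minority: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(np.sum(y_true_minority & y_pred_minority)),
        fp=int(np.sum(~y_true_minority & y_pred_minority)),
        tn=int(np.sum(~y_true_minority & ~y_pred_minority)),
        fn=int(np.sum(y_true_minority & ~y_pred_minority)),
    )


def evaluate_once(
    train: tuple,
    test: tuple,
    selector_config: Optional[SelectorConfig] = None,
    classifier_id: str = "rf",
    seed: int = 0,
) -> RunRecord:
    """Select features on the training partition, score on the test one.

    The selector never sees test rows. The classifier (``rf``, ``svm`` or
    ``wknn``) runs at library defaults on the selected columns; metrics
    treat the minority class as positive.
    """
    if classifier_id not in CLASSIFIERS:
        raise ConfigurationError(
            f"unknown classifier {classifier_id!r}; choose from {sorted(CLASSIFIERS)}"
        )
    X_tr, y_tr = train
    X_te, y_te = test
    if selector_config is None:
        selector_config = SelectorConfig(seed=seed)
    try:
        result = mwrds_select(X_tr, y_tr, selector_config)
    except EmptyRefinementError as exc:
        raise MWRDSError(
            f"selector returned 0 features ({exc}); enable backfill to "
            f"guarantee a non-empty final set"
        ) from exc
    if not result.final_set:
        raise MWRDSError(
            "selector returned 0 features; enable backfill to guarantee a "
            "non-empty final set"
        )
    id_to_idx = {f: i for i, f in enumerate(X_tr.feature_ids)}
    cols = [id_to_idx[f] for f in result.final_set]

    clf = CLASSIFIERS[classifier_id](seed)
    try:
        clf.fit(X_tr.values[:, cols], y_tr.signed())
        pred = clf.predict(X_te.values[:, cols])
    except Exception as exc:
        raise StageError(f"classifier:{classifier_id}", exc) from exc

    minority = y_tr.minority_label
    true_min = y_te.labels == minority
    counts = _count_confusion(true_min, pred == 1)
    return RunRecord(seed=seed, selected=result.final_set,
                     metrics=confusion_metrics(counts))


def repeated_evaluation(
    X: ExpressionMatrix,
    labels: LabelVector,
    selector_config: Optional[SelectorConfig] = None,
    classifier_id: str = "rf",
    n_runs: int = 500,
    base_seed: int = 0,
    train_frac: float = 0.7,
) -> RepeatedEvalSummary:
    """Repeat seeded 70/30 split-sample runs and aggregate.

    Runs use seeds ``base_seed .. base_seed + n_runs - 1`` for the split,
    the selector's cross-validation folds and the classifier alike, so two
    invocations with the same base seed are identical. SD uses the sample
    definition (n-1) and is 0 for a single run.
    """
    if n_runs < 1:
        raise ConfigurationError(f"n_runs must be >= 1, got {n_runs}")
    if selector_config is None:
        selector_config = SelectorConfig()
    runs = []
    freq: Counter = Counter()
    for k in range(n_runs):
        seed = base_seed + k
        try:
            train, test = stratified_split(X, labels, train_frac, seed)
            cfg = SelectorConfig(**{**selector_config.__dict__, "seed": seed})
            rec = evaluate_once(train, test, cfg, classifier_id, seed)
        except MWRDSError as exc:
            raise MWRDSError(
                f"run {k} (seed {seed}) failed after {len(runs)} completed "
                f"runs: {exc}"
            ) from exc
        runs.append(rec)
        freq.update(rec.selected)

    values = {m: np.array([getattr(r.metrics, m) for r in runs]) for m in METRIC_NAMES}
    mean = {m: float(v.mean()) for m, v in values.items()}
    sd = {m: float(v.std(ddof=1)) if n_runs > 1 else 0.0 for m, v in values.items()}
    return RepeatedEvalSummary(
        n_runs=n_runs,
        mean=mean,
        sd=sd,
        runs=tuple(runs),
        selection_frequency=dict(freq.most_common()),
    )
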