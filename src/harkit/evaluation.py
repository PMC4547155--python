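"""Recognition-performance evaluation.

Confusion-matrix algebra, the five per-class metrics standard in
activity recognition (sensitivity, specificity, positive and negative
predictive value, F-score), repeated stratified k-fold
cross-validation, and the delay-aligned online protocol.

Conventions, fixed here once:

* metrics are computed one-vs-rest from the multi-class confusion
  matrix; a 0/0 ratio is reported as 0.0 and flagged as degenerate
  (never a silent NaN);
* repeated CV sums confusion counts over all folds and repetitions and
  derives the metric table once from the aggregate, so the total count
  equals repetitions x windows;
* repetition ``r`` shuffles with seed ``base_seed + r``;
* online evaluation compares each window-end prediction against the
  truth samples of the window it summarizes; windows whose truth labels
  are not unanimous (transitions) or that touch the null class (0) are
  excluded from scoring, mirroring a system without null-class
  rejection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .classification import ModelSpec, predict, train
from .features import FeatureMatrix

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricsReport",
    "CVSpec",
    "confusion_matrix",
    "fscore",
    "class_metrics",
    "compute_report",
    "cv_fold_indices",
    "repeated_kfold_cv",
    "online_evaluate",
]


@dataclass
class ConfusionMatrix:
    """K x K integer counts; rows are actual classes, columns predicted."""

    classes: tuple[int, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.classes = tuple(int(c) for c in self.classes)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def diagonal_sum(self) -> int:
        return int(np.trace(self.counts))

    def support(self, class_code: int) -> int:
        return int(self.counts[self.classes.index(class_code)].sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("cannot add confusion matrices over different classes")
        return ConfusionMatrix(self.classes, self.counts + other.counts)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("actual\\predicted\t" + "\t".join(str(c) for c in self.classes) + "\n")
            for c, row in zip(self.classes, self.counts):
                fh.write(str(c) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "ConfusionMatrix":
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            classes = tuple(int(c) for c in header[1:])
            rows = []
            for line in fh:
                cells = line.rstrip("\n").split("\t")
                if len(cells) != len(classes) + 1:
                    raise ValueError(f"{path}: malformed confusion row {cells!r}")
                rows.append([int(v) for v in cells[1:]])
        return cls(classes, np.array(rows, dtype=np.int64))


def confusion_matrix(
    actual: Sequence[int],
    predicted: Sequence[int],
    classes: Sequence[int],
) -> ConfusionMatrix:
    """Tally (actual, predicted) pairs over an explicit class list."""
    actual = np.asarray(actual, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted differ in length")
    classes = tuple(int(c) for c in classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for a, p in zip(actual, predicted):
        if int(a) not in index:
            raise ValueError(f"actual label {a} not in class list")
        if int(p) not in index:
            raise ValueError(f"predicted label {p} not in class list")
        counts[index[int(a)], index[int(p)]] += 1
    return ConfusionMatrix(classes, counts)


def fscore(se: float, ppv: float) -> float:
    """Harmonic mean of sensitivity and precision; 0 when both are 0."""
    if not (0.0 <= se <= 1.0) or not (0.0 <= ppv <= 1.0):
        raise ValueError("fscore arguments must lie in [0, 1]")
    if se + ppv == 0.0:
        return 0.0
    return 2.0 * ppv * se / (ppv + se)


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics for a single class.

    ``degenerate`` names the ratios that were 0/0 and reported as 0.
    """

    se: float
    sp: float
    ppv: float
    npv: float
    f: float
    degenerate: frozenset = frozenset()


def _ratio(num: int, den: int) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def class_metrics(cm: ConfusionMatrix, class_code: int) -> ClassMetrics:
    """SE, SP, PPV, NPV and F for one class, one-vs-rest."""
    if class_code not in cm.classes:
        raise ValueError(f"class {class_code} not in confusion matrix")
    i = cm.classes.index(class_code)
    counts = cm.counts
    tp = int(counts[i, i])
    fn = int(counts[i].sum() - tp)
    fp = int(counts[:, i].sum() - tp)
    tn = int(counts.sum() - tp - fn - fp)
    degenerate = set()
    se, d1 = _ratio(tp, tp + fn)
    sp, d2 = _ratio(tn, tn + fp)
    ppv, d3 = _ratio(tp, tp + fp)
    npv, d4 = _ratio(tn, tn + fn)
    for flag, name in ((d1, "se"), (d2, "sp"), (d3, "ppv"), (d4, "npv")):
        if flag:
            degenerate.add(name)
    f = fscore(se, ppv)
    if se + ppv == 0.0:
        degenerate.add("f")
    return ClassMetrics(se, sp, ppv, npv, f, frozenset(degenerate))


@dataclass
class MetricsReport:
    """Per-class metric table plus macro (unweighted) averages."""

    per_class: dict[int, ClassMetrics]

    @property
    def macro_se(self) -> float:
        return float(np.mean([m.se for m in self.per_class.values()]))

    @property
    def macro_sp(self) -> float:
        return float(np.mean([m.sp for m in self.per_class.values()]))

    @property
    def macro_ppv(self) -> float:
        return float(np.mean([m.ppv for m in self.per_class.values()]))

    @property
    def macro_npv(self) -> float:
        return float(np.mean([m.npv for m in self.per_class.values()]))

    @property
    def macro_f(self) -> float:
        return float(np.mean([m.f for m in self.per_class.values()]))

    def to_tsv(self, path) -> None:
        """Write the per-class table (two-decimal rendering) as TSV."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("Activity\tSE\tSP\tPPV\tNPV\tF-score\n")
            for code, m in sorted(self.per_class.items()):
                fh.write(
                    f"L{code}\t{m.se:.2f}\t{m.sp:.2f}\t{m.ppv:.2f}\t{m.npv:.2f}\t{m.f:.2f}\n"
                )
            fh.write(
                f"macro\t{self.macro_se:.2f}\t{self.macro_sp:.2f}\t"
                f"{self.macro_ppv:.2f}\t{self.macro_npv:.2f}\t{self.macro_f:.2f}\n"
            )


def compute_report(cm: ConfusionMatrix) -> MetricsReport:
    return MetricsReport({c: class_metrics(cm, c) for c in cm.classes})


@dataclass(frozen=True)
class CVSpec:
    """Repeated k-fold cross-validation settings."""

    k: int = 10
    repetitions: int = 100
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def cv_fold_indices(
    labels: np.ndarray, cv: CVSpec
) -> Iterator[tuple[int, int, np.ndarray, np.ndarray]]:
    """Yield (repetition, fold, train_idx, test_idx) for every fold.

    Each repetition is a fresh seeded shuffle (seed + repetition) split
    into k near-equal folds, stratified by label unless disabled; every
    row lands in a test fold exactly once per repetition.
    """
    labels = np.asarray(labels)
    if cv.stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < cv.k:
            raise ValueError(
                f"smallest class has {counts.min()} members < k={cv.k}; "
                "use stratified=False or a smaller k"
            )
    for rep in range(cv.repetitions):
        splitter_cls = StratifiedKFold if cv.stratified else KFold
        splitter = splitter_cls(n_splits=cv.k, shuffle=True, random_state=cv.seed + rep)
        for fold, (train_idx, test_idx) in enumerate(splitter.split(labels[:, None], labels)):
            yield rep, fold, train_idx, test_idx


def repeated_kfold_cv(
    features: FeatureMatrix, spec: ModelSpec, cv: CVSpec
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Repeated k-fold CV with confusion counts summed over everything.

    Trains a fresh model per fold, tests each window exactly once per
    repetition, and aggregates all (actual, predicted) tallies into one
    confusion matrix; the metric table is derived from that aggregate,
    so its total equals ``repetitions * n_windows``.
    """
    classes = tuple(int(c) for c in np.unique(features.labels))
    total = np.zeros((len(classes), len(classes)), dtype=np.int64)
    index = {c: i for i, c in enumerate(classes)}
    for _rep, _fold, train_idx, test_idx in cv_fold_indices(features.labels, cv):
        model = train(features.subset(train_idx), spec)
        predicted = predict(model, features.subset(test_idx))
        for a, p in zip(features.labels[test_idx], predicted):
            total[index[int(a)], index[int(p)]] += 1
    cm = ConfusionMatrix(classes, total)
    return cm, compute_report(cm)


def online_evaluate(
    predicted: Sequence[tuple[float, int]],
    truth_labels: Sequence[int],
    sampling_rate: float,
    window_seconds: float,
    classes: Sequence[int] | None = None,
) -> ConfusionMatrix:
    """Score a stream of window-end predictions against per-sample truth.

    Each prediction ``(end_time, label)`` summarizes the truth samples
    in ``[end_time - window_seconds, end_time)``.  Windows whose truth
    labels are not unanimous, or that contain the null class 0, are
    transitions and are excluded from scoring.  A prediction whose
    window falls outside the truth timeline is an error.
    """
    truth = np.asarray(truth_labels, dtype=np.int64)
    n = int(math.floor(window_seconds * sampling_rate + 1e-9))
    if n < 1:
        raise ValueError("window holds no samples at this rate")
    pairs: list[tuple[int, int]] = []
    for end_time, label in predicted:
        end = int(round(end_time * sampling_rate))
        start = end - n
        if start < 0 or end > len(truth):
            raise ValueError(
                f"prediction at t={end_time} s falls outside the truth timeline"
            )
        segment = truth[start:end]
        if (segment == 0).any() or not (segment == segment[0]).all():
            continue  # transition or null-class window: excluded
        pairs.append((int(segment[0]), int(label)))
    if classes is None:
        classes = sorted({a for a, _ in pairs} | {p for _, p in pairs})
    return confusion_matrix(
        [a for a, _ in pairs], [p for _, p in pairs], tuple(classes)
    )
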