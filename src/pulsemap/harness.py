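"""Subject-grouped training and evaluation of the emotion classifier.

Evaluation follows leave-k-subjects-out cross-validation (default k = 5):
subjects are shuffled deterministically and partitioned into disjoint test
groups, so no subject's clips ever appear in both the train and test side of
a fold — classification must generalize across identities, not memorize
them.  Imbalanced classes are handled with a weighted loss
(``w_c = N / (n_classes * N_c)``, inverse class frequency) rather than
resampling, and training inputs are augmented with random 90/180/270-degree
rotations and random temporal pixel zeroing (each spatial pixel's depth
vector dropped with probability 1/124).

Reported metrics: per-fold 5 x 5 confusion matrices; per-class precision,
recall and F1 distributions across folds; macro (unweighted class-mean)
metrics with mean and SD; overall accuracy = trace of the summed matrix over
the total test count; and the row-normalized summed confusion matrix.
Undefined 0/0 precision/recall values are reported as 0 and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .nn import TrainConfig, build_model
from .synthetic import EMOTION_CLASSES

__all__ = [
    "CVPlan",
    "LabeledFeatureSet",
    "EvalReport",
    "make_cv_splits",
    "class_weights",
    "augment",
    "train_and_evaluate",
    "confusion_metrics",
]


@dataclass(frozen=True)
class CVPlan:
    """Leave-k-subjects-out fold plan."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train, test) per fold
    group_size: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass
class LabeledFeatureSet:
    """Classifier inputs with labels and subject identities."""

    blocks: np.ndarray  # (N, H, W, D)
    labels: Sequence[str]
    subject_ids: Sequence[str]
    classes: tuple[str, ...] = EMOTION_CLASSES

    def __post_init__(self) -> None:
        self.blocks = np.asarray(self.blocks)
        if not (len(self.blocks) == len(self.labels) == len(self.subject_ids)):
            raise ValueError("blocks, labels and subject_ids must have equal length")
        bad = set(self.labels) - set(self.classes)
        if bad:
            raise ValueError(f"labels outside the class alphabet: {sorted(bad)}")

    def label_indices(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.asarray([lut[l] for l in self.labels])


@dataclass
class EvalReport:
    """Cross-validation evaluation summary."""

    classes: tuple[str, ...]
    fold_matrices: list[np.ndarray]  # 5x5 counts, rows = true class
    summed_matrix: np.ndarray
    row_normalized: np.ndarray
    per_class_precision: np.ndarray  # (n_folds, n_classes)
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    fold_accuracies: np.ndarray
    accuracy: float
    macro: dict[str, tuple[float, float]]  # metric -> (mean, sd) across folds
    n_undefined: int = 0
    predictions: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def make_cv_splits(
    subject_ids: Sequence[str], group_size: int = 5, seed: int = 0
) -> CVPlan:
    """Partition subjects into disjoint test groups of ``group_size``.

    Subjects are deduplicated (first-appearance order), shuffled under the
    seed and split into consecutive groups; each fold tests one group and
    trains on all remaining subjects.  110 subjects with groups of 5 give
    22 folds.  A non-divisible count leaves a smaller final fold (warned).
    """
    subjects = list(dict.fromkeys(subject_ids))
    if group_size > len(subjects):
        raise ValueError(
            f"group_size {group_size} exceeds the {len(subjects)} distinct subjects"
        )
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    if len(subjects) % group_size:
        warnings.warn(
            f"{len(subjects)} subjects not divisible by {group_size}; "
            "last fold will be smaller",
            stacklevel=2,
        )
    folds = []
    for start in range(0, len(order), group_size):
        test = tuple(order[start : start + group_size])
        train = tuple(s for s in order if s not in test)
        folds.append((train, test))
    return CVPlan(folds=tuple(folds), group_size=group_size)


def class_weights(
    labels: Sequence[str], classes: Sequence[str] = EMOTION_CLASSES
) -> dict[str, float]:
    """Inverse-frequency class weights ``w_c = N / (n_classes * N_c)``.

    Balanced labels give weight 1 for every class; smaller classes get
    proportionally larger weights.  Raises if any class is absent.
    """
    labels = list(labels)
    counts = {c: labels.count(c) for c in classes}
    missing = [c for c, n in counts.items() if n == 0]
    if missing:
        raise ValueError(f"classes absent from labels: {missing}")
    total = len(labels)
    k = len(classes)
    return {c: total / (k * n) for c, n in counts.items()}


def augment(
    block: np.ndarray,
    rng: np.random.Generator,
    pixel_drop_p: float = 1.0 / 124.0,
) -> np.ndarray:
    """Training augmentation: random right-angle rotation + temporal pixel drop.

    A rotation from {0, 90, 180, 270} degrees is applied with equal
    probability in the spatial plane; independently, each spatial pixel's
    full depth vector is zeroed with probability ``pixel_drop_p``.
    """
    if block.shape[0] != block.shape[1]:
        raise ValueError("augment expects square spatial dims")
    k = int(rng.integers(0, 4))
    out = np.rot90(block, k, axes=(0, 1)).copy()
    if pixel_drop_p > 0:
        drop = rng.random(out.shape[:2]) < pixel_drop_p
        out[drop] = 0
    return out


ModelFactory = Callable[[int, int, int, int], object]  # depth, classes, hw, seed


def _default_factory(depth: int, n_classes: int, hw: int, seed: int):
    return build_model(depth, n_classes, backbone="tiny", input_hw=hw, seed=seed)


def train_and_evaluate(
    data: LabeledFeatureSet,
    plan: CVPlan,
    cfg: TrainConfig | None = None,
    seed: int = 0,
    model_factory: ModelFactory | None = None,
) -> EvalReport:
    """Run the full cross-validation: fit per fold, predict, aggregate.

    Each fold trains a freshly initialized model (weighted loss +
    augmentation per the configuration) on the training subjects and records
    the 5 x 5 confusion matrix on the held-out subjects.
    """
    cfg = cfg or TrainConfig()
    factory = model_factory or _default_factory
    y = data.label_indices()
    subj = np.asarray(data.subject_ids)
    plan_subjects = {s for tr, te in plan.folds for s in tr + te}
    if not plan_subjects <= set(subj):
        raise ValueError("plan references subjects absent from the data")

    n_classes = len(data.classes)
    blocks = data.blocks
    if cfg.normalize_inputs:
        mean = blocks.mean(axis=(1, 2, 3), keepdims=True)
        sd = blocks.std(axis=(1, 2, 3), keepdims=True)
        blocks = (blocks - mean) / np.maximum(sd, 1e-8)
    hw = blocks.shape[1]
    depth = blocks.shape[3]
    fold_matrices: list[np.ndarray] = []
    predictions = []
    for fi, (train_subjects, test_subjects) in enumerate(plan.folds):
        tr = np.isin(subj, train_subjects)
        te = np.isin(subj, test_subjects)
        if not te.any() or not tr.any():
            raise ValueError(f"fold {fi} has an empty train or test side")
        weights_map = class_weights(
            [data.labels[i] for i in np.flatnonzero(tr)], data.classes
        )
        cw = np.asarray([weights_map[c] for c in data.classes])
        rng = np.random.default_rng((seed, fi))
        model = factory(depth, n_classes, hw, int(rng.integers(2**31 - 1)))
        model.fit(
            blocks[tr], y[tr], cw, cfg, rng,
            augment_fn=(
                (lambda b, r: augment(b, r, cfg.pixel_drop_p)) if cfg.augment else None
            ),
        )
        pred = np.asarray(model.predict(blocks[te]))
        mat = np.zeros((n_classes, n_classes), dtype=int)
        np.add.at(mat, (y[te], pred), 1)
        fold_matrices.append(mat)
        predictions.append((y[te], pred))

    report = confusion_metrics(fold_matrices, classes=data.classes)
    report.predictions = predictions
    return report


def confusion_metrics(
    folds: Sequence[np.ndarray], classes: Sequence[str] = EMOTION_CLASSES
) -> EvalReport:
    """Metric suite from per-fold confusion matrices (rows = true class).

    precision_c = TP_c / (TP_c + FP_c), recall_c = TP_c / (TP_c + FN_c),
    F1_c their harmonic mean, per fold; macro metrics are unweighted class
    means, summarized as (mean, SD) across folds.  0/0 is reported as 0 and
    counted in ``n_undefined``.
    """
    if not folds:
        raise ValueError("need at least one confusion matrix")
    mats = [np.asarray(m) for m in folds]
    k = mats[0].shape[0]
    n_folds = len(mats)
    precision = np.zeros((n_folds, k))
    recall = np.zeros((n_folds, k))
    f1 = np.zeros((n_folds, k))
    fold_acc = np.zeros(n_folds)
    undefined = 0
    for fi, m in enumerate(mats):
        tp = np.diag(m).astype(float)
        col = m.sum(axis=0).astype(float)
        row = m.sum(axis=1).astype(float)
        undefined += int(np.count_nonzero(col == 0) + np.count_nonzero(row == 0))
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(col > 0, tp / np.maximum(col, 1e-300), 0.0)
            r = np.where(row > 0, tp / np.maximum(row, 1e-300), 0.0)
            f = np.where(p + r > 0, 2 * p * r / np.maximum(p + r, 1e-300), 0.0)
        precision[fi], recall[fi], f1[fi] = p, r, f
        fold_acc[fi] = tp.sum() / m.sum()
    summed = np.sum(mats, axis=0)
    row_sums = summed.sum(axis=1, keepdims=True).astype(float)
    row_normalized = np.zeros(summed.shape, dtype=float)
    np.divide(summed, row_sums, out=row_normalized, where=row_sums > 0)
    accuracy = float(np.trace(summed) / summed.sum())

    def mean_sd(values: np.ndarray) -> tuple[float, float]:
        return float(values.mean()), float(values.std(ddof=1)) if n_folds > 1 else 0.0

    macro = {
        "accuracy": mean_sd(fold_acc),
        "precision": mean_sd(precision.mean(axis=1)),
        "recall": mean_sd(recall.mean(axis=1)),
        "f1": mean_sd(f1.mean(axis=1)),
    }
    return EvalReport(
        classes=tuple(classes),
        fold_matrices=mats,
        summed_matrix=summed,
        row_normalized=row_normalized,
        per_class_precision=precision,
        per_class_recall=recall,
        per_class_f1=f1,
        fold_accuracies=fold_acc,
        accuracy=accuracy,
        macro=macro,
        n_undefined=undefined,
    )
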