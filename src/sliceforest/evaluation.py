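"""Cross-validated accuracy, threshold-k selection, and recovery experiments.

The expensive part of the pipeline — training a bank and predicting decision
vectors — is independent of the run-length threshold k, so the per-subject
decision vectors from a cross-validation pass are cached and every k in a grid
is evaluated as pure post-processing over the same vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier_bank import BankConfig, DecisionVectors, predict_decision_vectors, train_bank
from .decision import diagnose, lesion_mask
from .localization import localization_overlap
from .synthetic_data import PhantomConfig, generate_cohort
from .volume_io import Cohort, LesionMask, split_folds

__all__ = [
    "EvalResult",
    "KSelection",
    "RecoveryResult",
    "collect_cv_decision_vectors",
    "cross_validate",
    "select_k",
    "mean_lesion_iou",
    "recovery_experiment",
]


@dataclass
class EvalResult:
    """Pooled cross-validation outcome at one threshold k.

    ``confusion`` is a 2x2 table indexed [true label, predicted label];
    ``overall_accuracy`` is the micro-average (TP + TN) / total over pooled
    held-out predictions.
    """

    per_fold_accuracy: list[float]
    overall_accuracy: float
    confusion: np.ndarray
    k: int
    predictions: dict[str, int]
    labels: dict[str, int]
    decision_vectors: dict[str, DecisionVectors]
    folds: list[tuple[tuple[str, ...], tuple[str, ...]]]


@dataclass
class KSelection:
    accuracy_by_k: dict[int, float]
    best_k: int
    results: dict[int, EvalResult]


@dataclass
class RecoveryResult:
    accuracy: float
    mean_iou: float
    predictions: dict[str, int]


def collect_cv_decision_vectors(
    cohort: Cohort, bank_config: BankConfig, n_folds: int, seed: int
) -> tuple[dict[str, DecisionVectors], list[tuple[tuple[str, ...], tuple[str, ...]]]]:
    """Train one bank per fold; predict decision vectors for held-out subjects.

    Each fold's bank seed is derived from (seed, fold index) so the whole pass
    is deterministic and independent of execution order.
    """
    folds = split_folds(cohort, n_folds, seed)
    vectors: dict[str, DecisionVectors] = {}
    for fold_index, (train_ids, test_ids) in enumerate(folds):
        fold_seed = int(
            np.random.SeedSequence(entropy=(seed & 0x7FFFFFFF, fold_index)).generate_state(1)[0]
            % (2**31)
        )
        fold_config = BankConfig(
            n_trees=bank_config.n_trees,
            max_depth=bank_config.max_depth,
            min_samples_split=bank_config.min_samples_split,
            seed=fold_seed,
            features_per_split=bank_config.features_per_split,
            class_weight=bank_config.class_weight,
        )
        bank = train_bank(cohort.subset(train_ids), fold_config)
        for sid in test_ids:
            vectors[sid] = predict_decision_vectors(bank, cohort.get(sid))
    return vectors, folds


def _evaluate_at_k(
    cohort: Cohort,
    vectors: dict[str, DecisionVectors],
    folds: list[tuple[tuple[str, ...], tuple[str, ...]]],
    k: int,
) -> EvalResult:
    labels = {v.subject_id: int(v.label) for v in cohort}
    predictions = {sid: diagnose(dv, k) for sid, dv in vectors.items()}
    per_fold = []
    for _, test_ids in folds:
        correct = sum(predictions[sid] == labels[sid] for sid in test_ids)
        per_fold.append(correct / len(test_ids))
    confusion = np.zeros((2, 2), dtype=int)
    for sid, pred in predictions.items():
        confusion[labels[sid], pred] += 1
    overall = float(np.trace(confusion) / confusion.sum())
    return EvalResult(
        per_fold_accuracy=per_fold,
        overall_accuracy=overall,
        confusion=confusion,
        k=k,
        predictions=predictions,
        labels=labels,
        decision_vectors=vectors,
        folds=folds,
    )


def cross_validate(
    cohort: Cohort, bank_config: BankConfig, k: int, n_folds: int, seed: int
) -> EvalResult:
    """Stratified k-fold CV: train per fold, diagnose held-out subjects, pool."""
    vectors, folds = collect_cv_decision_vectors(cohort, bank_config, n_folds, seed)
    return _evaluate_at_k(cohort, vectors, folds, k)


def select_k(
    cohort: Cohort,
    bank_config: BankConfig,
    k_grid: list[int],
    n_folds: int,
    seed: int,
) -> KSelection:
    """Evaluate every k on identical folds and banks; pick the ACC argmax.

    Banks are trained once — predictions are k-independent — so accuracy
    differences across the grid stem only from the decision rule.  Ties
    resolve to the smallest k.
    """
    if not k_grid or any(k < 1 for k in k_grid):
        raise ValueError("k_grid must be nonempty with all k >= 1")
    vectors, folds = collect_cv_decision_vectors(cohort, bank_config, n_folds, seed)
    results = {k: _evaluate_at_k(cohort, vectors, folds, k) for k in sorted(set(k_grid))}
    accuracy_by_k = {k: r.overall_accuracy for k, r in results.items()}
    best_k = min(k for k, acc in accuracy_by_k.items() if acc == max(accuracy_by_k.values()))
    return KSelection(accuracy_by_k=accuracy_by_k, best_k=best_k, results=results)


def mean_lesion_iou(result: EvalResult, truth: LesionMask) -> float:
    """Mean IoU between true-positive subjects' masks and the truth mask.

    Convention: 0.0 when there are no true positives.
    """
    ious = []
    for sid, pred in result.predictions.items():
        if pred == 1 and result.labels[sid] == 1:
            mask, _ = lesion_mask(result.decision_vectors[sid], result.k)
            ious.append(localization_overlap(mask, truth))
    return float(np.mean(ious)) if ious else 0.0


def recovery_experiment(
    config: PhantomConfig, bank_config: BankConfig, k: int, seed: int | None = None
) -> RecoveryResult:
    """Plant a lesion, train on half the phantom cohort, recover it on the rest.

    Uses a single stratified 50/50 split (first fold of a 2-fold partition).
    Reports held-out diagnostic accuracy and the mean IoU between each true
    positive's predicted mask and the planted truth mask (0.0 if none).
    """
    if seed is None:
        seed = config.seed
    phantom = generate_cohort(config)
    cohort = phantom.cohort
    train_ids, test_ids = split_folds(cohort, 2, seed)[0]
    bank = train_bank(cohort.subset(train_ids), bank_config)
    predictions: dict[str, int] = {}
    ious = []
    correct = 0
    for sid in test_ids:
        volume = cohort.get(sid)
        dv = predict_decision_vectors(bank, volume)
        pred = diagnose(dv, k)
        predictions[sid] = pred
        correct += int(pred == volume.label)
        if pred == 1 and volume.label == 1:
            mask, _ = lesion_mask(dv, k)
            ious.append(localization_overlap(mask, phantom.truth_mask))
    return RecoveryResult(
        accuracy=correct / len(test_ids),
        mean_iou=float(np.mean(ious)) if ious else 0.0,
        predictions=predictions,
    )
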