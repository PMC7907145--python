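"""Tenfold cross-validation harness for image-sequence classifiers.

Each fold holds out one tenth of the samples for testing; the remainder is
split 8:1 into training and validation.  Per-band min-max normalization is
fitted on the training portion only and applied to all three splits, so no
test-set statistics leak into the image scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from eegtopo.classify.network import HybridNet
from eegtopo.classify.train import TrainConfig, evaluate, train
from eegtopo.topomap import MinMaxNormalizer

__all__ = ["FoldResult", "kfold_indices", "crossvalidate"]


@dataclass
class FoldResult:
    fold_index: int
    train_accuracy: float
    val_accuracy: float
    test_accuracy: float
    train_loss: float
    val_loss: float
    test_loss: float
    confusion: List[List[int]]  # [true][predicted]
    n_train: int
    n_val: int
    n_test: int

    def to_dict(self) -> dict:
        return {
            "fold_index": self.fold_index,
            "train_accuracy": self.train_accuracy,
            "val_accuracy": self.val_accuracy,
            "test_accuracy": self.test_accuracy,
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "test_loss": self.test_loss,
            "confusion": self.confusion,
            "n_train": self.n_train,
            "n_val": self.n_val,
            "n_test": self.n_test,
        }


def kfold_indices(n: int, k: int, rng: np.random.Generator) -> List[np.ndarray]:
    """Random partition of range(n) into k near-equal disjoint folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} folds but only {n} samples")
    order = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(order, k)]


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 2) -> List[List[int]]:
    mat = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[t, p] += 1
    return mat.tolist()


def crossvalidate(
    images: np.ndarray,
    labels: np.ndarray,
    model_factory: Callable[[int], HybridNet],
    train_cfg: TrainConfig,
    k: int = 10,
    seed: int = 0,
    normalize: bool = True,
    train_subsample: Optional[int] = None,
    folds: Optional[List[np.ndarray]] = None,
    retrain_below: Optional[float] = None,
    max_retrains: int = 2,
    eval_train: bool = True,
    subtract_mean_image: bool = True,
) -> Tuple[List[FoldResult], Dict]:
    """k-fold CV of a model factory on raw (unnormalized) image sequences.

    ``model_factory(seed)`` must return a fresh model.  ``train_subsample``
    caps the per-fold training-set size (desk-scale speed knob); validation
    and test splits are never subsampled.  Explicit ``folds`` (a disjoint
    partition of sample indices, e.g. grouped by subject) override the
    random trial-level partition.  ``retrain_below``: if the selected
    model's validation accuracy is at or below this level, reinitialize
    with a fresh seed and retrain (random restarts; at most
    ``max_retrains`` extra attempts, best attempt kept).

    ``subtract_mean_image`` removes the training-split mean image after
    normalization (VGG-style centering).  Topographic frames share a large
    common scalp pattern; without centering it dominates the network's
    activations and training spends its first epochs stuck in a
    majority-class plateau.
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    n = len(images)
    if len(labels) != n:
        raise ValueError("images and labels length mismatch")
    rng = np.random.default_rng(seed)
    if folds is None:
        folds = kfold_indices(n, k, rng)
    else:
        folds = [np.asarray(f) for f in folds]
        k = len(folds)
    results: List[FoldResult] = []
    for fold_index, test_idx in enumerate(folds):
        rest = np.setdiff1d(np.arange(n), test_idx)
        rest = rng.permutation(rest)
        n_val = max(1, len(rest) // 9)  # 8:1 train:validation within the fold
        val_idx = rest[:n_val]
        train_idx = rest[n_val:]
        if train_subsample is not None and len(train_idx) > train_subsample:
            train_idx = train_idx[:train_subsample]

        if normalize:
            norm = MinMaxNormalizer().fit(images[train_idx])
            x_train = norm.transform(images[train_idx])
            x_val = norm.transform(images[val_idx])
            x_test = norm.transform(images[test_idx])
        else:
            x_train, x_val, x_test = images[train_idx], images[val_idx], images[test_idx]
        if subtract_mean_image:
            mean_image = x_train.mean(axis=0, keepdims=True)
            x_train = x_train - mean_image
            x_val = x_val - mean_image
            x_test = x_test - mean_image
        y_train, y_val, y_test = labels[train_idx], labels[val_idx], labels[test_idx]

        best_model = None
        best_val = -1.0
        for attempt in range(1 + (max_retrains if retrain_below is not None else 0)):
            model = model_factory(int(rng.integers(2**31)))
            fold_cfg = replace(
                train_cfg, seed=train_cfg.seed + fold_index + 1000 * attempt
            )
            history = train(model, x_train, y_train, fold_cfg, x_val, y_val)
            _, attempt_val = evaluate(model, x_val, y_val)
            if attempt_val > best_val:
                best_val = attempt_val
                best_model = model
                best_history = history
            if retrain_below is None or best_val > retrain_below:
                break
        model = best_model
        if eval_train:
            train_loss, train_acc = evaluate(model, x_train, y_train)
        else:  # running training-mode estimate from the kept attempt
            train_loss = best_history["train_loss"][-1]
            train_acc = best_history["train_acc"][-1]
        val_loss, val_acc = evaluate(model, x_val, y_val)
        test_loss, test_acc = evaluate(model, x_test, y_test)
        y_pred = model.predict(x_test)
        results.append(
            FoldResult(
                fold_index=fold_index,
                train_accuracy=train_acc,
                val_accuracy=val_acc,
                test_accuracy=test_acc,
                train_loss=train_loss,
                val_loss=val_loss,
                test_loss=test_loss,
                confusion=_confusion(y_test, y_pred),
                n_train=len(train_idx),
                n_val=len(val_idx),
                n_test=len(test_idx),
            )
        )
    test_accs = [r.test_accuracy for r in results]
    summary = {
        "k": k,
        "n": n,
        "mean_test_accuracy": float(np.mean(test_accs)),
        "std_test_accuracy": float(np.std(test_accs)),
        "mean_val_accuracy": float(np.mean([r.val_accuracy for r in results])),
        "fold_test_accuracies": [float(a) for a in test_accs],
    }
    return results, summary
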