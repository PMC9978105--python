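"""Subject-wise cross-validation, confusion counts and derived metrics.

Folds are built over *subjects*, never trials, so a held-out subject's data
never influences training.  After every training epoch each fold's model is
evaluated on its held-out subjects, the four confusion counts are recorded
(Related is the positive class), the per-epoch metrics are averaged across
folds, and the epoch with the highest mean accuracy is reported as the
operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import ErpTransformerClassifier
from .data import EpochDataset

POSITIVE_LABEL = "Related"
NEGATIVE_LABEL = "Unrelated"


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false Related/Unrelated counts (Related is positive)."""

    tr: int   # true Related
    tu: int   # true Unrelated
    fr: int   # false Related (Unrelated predicted Related)
    fu: int   # false Unrelated (Related predicted Unrelated)

    @property
    def total(self) -> int:
        return self.tr + self.tu + self.fr + self.fu

    @classmethod
    def from_labels(cls, y_true, y_pred,
                    positive: str = POSITIVE_LABEL) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t, pos_p = y_true == positive, y_pred == positive
        return cls(
            tr=int(np.sum(pos_t & pos_p)),
            tu=int(np.sum(~pos_t & ~pos_p)),
            fr=int(np.sum(~pos_t & pos_p)),
            fu=int(np.sum(pos_t & ~pos_p)),
        )


def compute_metrics(counts: ConfusionCounts):
    """``(accuracy, precision, recall)``; undefined ratios are ``None``.

    accuracy = (TR+TU)/total, precision = TR/(TR+FR), recall = TR/(TR+FU).
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics for zero evaluated trials")
    accuracy = (counts.tr + counts.tu) / counts.total
    precision = (counts.tr / (counts.tr + counts.fr)
                 if counts.tr + counts.fr > 0 else None)
    recall = (counts.tr / (counts.tr + counts.fu)
              if counts.tr + counts.fu > 0 else None)
    return accuracy, precision, recall


def subject_folds(subject_ids, k: int = 5, seed=None, shuffle: bool = False):
    """Partition the distinct subjects into ``k`` folds of near-equal size.

    Default assignment is contiguous blocks of the sorted subject IDs; with
    ``shuffle=True`` the order is permuted by a seeded RNG first.  Fold sizes
    differ by at most one subject.
    """
    subjects = np.unique(np.asarray(subject_ids, dtype=str))
    if len(subjects) < k:
        raise ValueError(
            f"need at least {k} distinct subjects for {k} folds, got {len(subjects)}"
        )
    if shuffle:
        rng = np.random.default_rng(seed)
        subjects = subjects[rng.permutation(len(subjects))]
    return [set(part) for part in np.array_split(subjects, k)]


@dataclass
class CVResult:
    """Per-(fold, epoch) confusion counts and per-epoch fold means."""

    counts: list = field(default_factory=list)     # counts[fold][epoch]
    fold_subjects: list = field(default_factory=list)
    mean_accuracy: np.ndarray = None               # (n_epochs,)
    mean_precision: np.ndarray = None
    mean_recall: np.ndarray = None
    best_epoch: int = -1
    best_mean_accuracy: float = np.nan

    def to_dict(self) -> dict:
        return {
            "folds": [
                {
                    "subjects": sorted(subs),
                    "epochs": [
                        {"TR": c.tr, "TU": c.tu, "FR": c.fr, "FU": c.fu,
                         "accuracy": compute_metrics(c)[0],
                         "precision": compute_metrics(c)[1],
                         "recall": compute_metrics(c)[2]}
                        for c in fold_counts
                    ],
                }
                for subs, fold_counts in zip(self.fold_subjects, self.counts)
            ],
            "mean_accuracy": list(map(float, self.mean_accuracy)),
            "best_epoch": int(self.best_epoch),
            "best_mean_accuracy": float(self.best_mean_accuracy),
        }


def run_cv(dataset: EpochDataset, k: int = 5, n_epochs: int = 100,
           batch_size: int = 256, lr: float = 5e-4, seed: int = 0,
           shuffle_subjects: bool = False, model_params: dict | None = None
           ) -> CVResult:
    """Subject-wise k-fold CV of the transformer classifier.

    Each fold trains a fresh model on the other folds' subjects and is
    evaluated on the held-out subjects after every epoch; the best epoch is
    the argmax of the across-fold mean accuracy.
    """
    model_params = dict(model_params or {})
    folds = subject_folds(dataset.subject_ids, k=k, seed=seed,
                          shuffle=shuffle_subjects)
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(k)]
    result = CVResult()
    for fold, (held_out, fold_seed) in enumerate(zip(folds, fold_seeds)):
        test_mask = np.isin(dataset.subject_ids, sorted(held_out))
        if not np.any(test_mask) or np.all(test_mask):
            raise ValueError(f"fold {fold} has an empty train or test split")
        X_tr, y_tr = dataset.data[~test_mask], dataset.labels[~test_mask]
        X_te, y_te = dataset.data[test_mask], dataset.labels[test_mask]
        clf = ErpTransformerClassifier(
            n_epochs=n_epochs, batch_size=batch_size, lr=lr,
            random_state=fold_seed, **model_params,
        )
        clf.fit(X_tr, y_tr, eval_set=(X_te, y_te))
        fold_counts = [ConfusionCounts.from_labels(y_te, pred)
                       for pred in clf.eval_pred_history_]
        result.counts.append(fold_counts)
        result.fold_subjects.append(held_out)

    accs = np.array([[compute_metrics(c)[0] for c in fold_counts]
                     for fold_counts in result.counts])        # (k, epochs)
    result.mean_accuracy = accs.mean(axis=0)

    def _mean_optional(metric_ix):
        vals = []
        for e in range(n_epochs):
            per_fold = [compute_metrics(result.counts[f][e])[metric_ix]
                        for f in range(k)]
            per_fold = [v for v in per_fold if v is not None]
            vals.append(float(np.mean(per_fold)) if per_fold else np.nan)
        return np.array(vals)

    result.mean_precision = _mean_optional(1)
    result.mean_recall = _mean_optional(2)
    result.best_epoch = int(np.argmax(result.mean_accuracy))
    result.best_mean_accuracy = float(result.mean_accuracy[result.best_epoch])
    return result
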