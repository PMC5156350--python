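"""Cross-validation, accuracy and significance protocol; participant inclusion.

The cross-validation is leave-pair-out: each test fold holds one randomly
chosen trial of each class, drawn without replacement, repeated until every
trial has been tested exactly once.  With unequal class sizes the leftover
majority-class trials are tested in singleton folds, so exclusivity and
coverage still hold.  Fold accuracies are pooled over all predictions (not
averaged per fold, which would weight singleton folds unequally) and compared
against chance with a one-sided exact binomial test at p < 0.05.

Within every fold, normalization statistics, the 70/30 train/validation
split, class balancing, and all model fitting use that fold's training trials
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .types import EpochSet, FORGOTTEN, REMEMBERED, label_trials  # noqa: F401


@dataclass
class FoldPlan:
    """List of (test indices, train indices) pairs covering every trial once."""

    folds: list

    @property
    def k(self) -> int:
        return len(self.folds)


@dataclass
class CVResult:
    predictions: np.ndarray  # per trial, aligned with input order
    labels: np.ndarray
    accuracy: float
    n_correct: int
    n_total: int
    p_value: float
    significant: bool
    fold_sizes: list = field(default_factory=list)


@dataclass
class ParticipantRecord:
    participant_id: str
    n_remembered: int
    n_forgotten: int
    response_bias: float
    included: bool = True
    reason: str = ""


def make_folds(labels: np.ndarray, seed: int = 0) -> FoldPlan:
    """Leave-pair-out folds: one trial per class per fold, each tested once.

    With n_r remembered and n_f forgotten trials there are min(n_r, n_f)
    paired folds plus singleton folds for the leftover majority-class trials.
    Deterministic given ``seed``.
    """
    labels = np.asarray(labels, int)
    rng = np.random.default_rng(seed)
    idx_f = rng.permutation(np.flatnonzero(labels == FORGOTTEN))
    idx_r = rng.permutation(np.flatnonzero(labels == REMEMBERED))
    if len(idx_f) == 0 or len(idx_r) == 0:
        raise ValueError("both classes must be present to build folds")
    n_pairs = min(len(idx_f), len(idx_r))
    all_idx = np.arange(len(labels))
    folds = []
    for i in range(n_pairs):
        test = np.array(sorted([idx_f[i], idx_r[i]]))
        folds.append((test, np.setdiff1d(all_idx, test)))
    for j in range(n_pairs, max(len(idx_f), len(idx_r))):
        extra = idx_f[j] if len(idx_f) > len(idx_r) else idx_r[j]
        test = np.array([extra])
        folds.append((test, np.setdiff1d(all_idx, test)))
    for test, train in folds:
        if len(train) == 0:
            raise ValueError("a fold has an empty training set; too few trials")
    return FoldPlan(folds=folds)


def binomial_significance(n_correct: int, n_total: int) -> float:
    """One-sided exact binomial tail P(X >= n_correct | n_total, 0.5)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must be in [0, n_total]")
    return float(sp_stats.binomtest(n_correct, n_total, 0.5, alternative="greater").pvalue)


def cross_validate(
    epochs: EpochSet,
    model,
    window: str = "entire",
    seed: int = 0,
    alpha: float = 0.05,
    **model_kwargs,
) -> CVResult:
    """Leave-pair-out cross-validation of a classifier on labeled epochs.

    ``model`` is a classifier name understood by
    :func:`conveegnn.baselines.make_classifier` ("conveegnn", "lda", "ann1",
    "ann2", "svm", "svm+lda", "cwt+svm") or an object with the same
    ``fit(epochs, train_idx, seed)`` / ``predict(epochs, idx)`` contract.
    All per-fold fitting (feature extraction statistics included) sees that
    fold's training trials only.
    """
    labels = np.asarray(epochs.labels, int)
    if np.any(labels < 0):
        raise ValueError("all trials must be labeled before cross-validation")
    plan = make_folds(labels, seed=seed)
    if isinstance(model, str):
        from .baselines import make_classifier

        model = make_classifier(model, window=window, **model_kwargs)

    rng = np.random.default_rng(seed)
    predictions = np.full(len(labels), -1, dtype=int)
    fold_sizes = []
    for fold_id, (test, train_idx) in enumerate(plan.folds):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        try:
            model.fit(epochs, train_idx, seed=fold_seed)
            predictions[test] = model.predict(epochs, test)
        except Exception as exc:  # surface which fold failed
            raise RuntimeError(f"training failed in fold {fold_id}: {exc}") from exc
        fold_sizes.append(len(test))

    n_correct = int(np.sum(predictions == labels))
    n_total = len(labels)
    p = binomial_significance(n_correct, n_total)
    return CVResult(
        predictions=predictions,
        labels=labels,
        accuracy=n_correct / n_total,
        n_correct=n_correct,
        n_total=n_total,
        p_value=p,
        significant=p < alpha,
        fold_sizes=fold_sizes,
    )


def response_bias(new_word_keys: Sequence[int]) -> float:
    """Tendency to call new words familiar: P(key in {1, 2} | new word)."""
    keys = np.asarray(new_word_keys, int)
    if keys.size == 0:
        raise ValueError("no memory-test responses to new words")
    return float(np.mean(keys <= 2))


def select_participants(records: Sequence[ParticipantRecord]) -> tuple[list, pd.DataFrame]:
    """Apply inclusion rules: >= 15 trials per class and response bias <= 0.2.

    Returns the included records and a per-participant report with the reason
    for every exclusion.
    """
    rows = []
    included = []
    for rec in records:
        if rec.n_remembered < 15 or rec.n_forgotten < 15:
            rec.included, rec.reason = False, "count"
        elif rec.response_bias > 0.2:
            rec.included, rec.reason = False, "bias"
        else:
            rec.included, rec.reason = True, ""
            included.append(rec)
        rows.append(
            {
                "participant": rec.participant_id,
                "n_remembered": rec.n_remembered,
                "n_forgotten": rec.n_forgotten,
                "response_bias": rec.response_bias,
                "included": rec.included,
                "reason": rec.reason,
            }
        )
    return included, pd.DataFrame(rows)
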