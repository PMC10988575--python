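"""Evaluation metrics: MAE, multilabel F-scores, multi-seed summaries.

MAE = (1/N) Σ |y_i − x_i| over true values y and predictions x; a perfect
model scores 0.  For multilabel classification the per-class F1 is computed
from class-wise contingency counts across molecules and then averaged —
unweighted (macro) or weighted by class support (weighted).  Classes with no
positive truth instances contribute F1 = 0 to macro and weight 0 to weighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import f1_score

DEFAULT_DECISION_THRESHOLD = 0.5


@dataclass
class LabelMatrix:
    """Per-molecule binary label vectors over an ordered class vocabulary."""

    values: np.ndarray  # (n_molecules, n_classes), entries in {0, 1}
    class_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.class_names):
            raise ValueError("label matrix width must match class_names")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("label matrix entries must be binary")


def threshold_probabilities(
    probs: np.ndarray,
    class_names: list[str],
    threshold: float = DEFAULT_DECISION_THRESHOLD,
) -> LabelMatrix:
    """Binarize per-class probabilities at a decision threshold."""
    return LabelMatrix((np.asarray(probs) >= threshold).astype(int), class_names)


def mae(y_true, y_pred) -> float:
    """Mean absolute error between true and predicted values."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("cannot compute MAE of empty vectors")
    return float(np.mean(np.abs(y_true - y_pred)))


def multilabel_fscore(truth: LabelMatrix, predicted: LabelMatrix, average: str) -> float:
    """Macro or support-weighted mean of per-class F1 scores."""
    if average not in ("macro", "weighted"):
        raise ValueError("average must be 'macro' or 'weighted'")
    if truth.values.shape != predicted.values.shape:
        raise ValueError("truth and prediction shapes differ")
    if truth.class_names != predicted.class_names:
        raise ValueError("class orderings differ")
    return float(
        f1_score(truth.values, predicted.values, average=average, zero_division=0)
    )


def summarize_runs(scores) -> tuple[float, float]:
    """Mean and standard error (sample std / √n) over repeated-seed runs."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 runs to summarize")
    return float(scores.mean()), float(scores.std(ddof=1) / np.sqrt(scores.size))


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination of predictions against truth."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        return 0.0 if ss_res > 0 else 1.0
    return 1.0 - ss_res / ss_tot
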