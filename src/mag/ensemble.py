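"""Combine per-atlas model predictions: majority vote, sum, weighted sum.

Hard votes are the argmax of each model's softmax output (probability ties
resolve to the positive MDD class). Majority-vote ties across models (2–2
with four models) are broken by the vote of the model with the highest
validation accuracy; accuracy ties fall back to the fixed model order
(Dose, AAL, CK, HO by default). Weighted-sum weights are the
validation-accuracy shares w_j = Acc_j / Σ_i Acc_i; the plain "sum" method is
the uniform-weight special case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .cohort import MDD


@dataclass
class PredictionSet:
    """Aligned per-model class probabilities for a common subject list."""

    subject_ids: List[str]
    probabilities: Dict[str, np.ndarray]  # model -> (n_subjects, 2), cols (HC, MDD)
    val_accuracies: Dict[str, float]
    model_order: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.model_order:
            self.model_order = list(self.probabilities)
        n = len(self.subject_ids)
        for name, p in self.probabilities.items():
            if p.shape != (n, 2):
                raise ValueError(f"model {name}: probabilities shape {p.shape} != ({n}, 2)")
            if np.max(np.abs(p.sum(axis=1) - 1.0)) > 1e-6:
                raise ValueError(f"model {name}: probability rows must sum to 1")

    def hard_labels(self) -> Dict[str, np.ndarray]:
        """Per-model argmax votes; exact probability ties go to MDD."""
        out = {}
        for name, p in self.probabilities.items():
            out[name] = np.where(p[:, MDD] >= p[:, 1 - MDD], MDD, 1 - MDD)
        return out


@dataclass
class EnsembleResult:
    method: str
    subject_ids: List[str]
    final_labels: np.ndarray
    final_probabilities: Optional[np.ndarray] = None  # (n, 2) for sum methods
    tie_log: List[str] = field(default_factory=list)


def majority_vote(preds: PredictionSet) -> EnsembleResult:
    """Per subject, the modal hard vote; documented tie-break on even splits."""
    models = preds.model_order
    if len(models) < 2:
        raise ValueError("majority vote needs at least 2 models")
    votes = preds.hard_labels()
    # tie-break order: highest validation accuracy, then fixed model order
    ranked = sorted(models, key=lambda m: (-preds.val_accuracies[m], models.index(m)))
    best_model = ranked[0]
    n = len(preds.subject_ids)
    labels = np.empty(n, dtype=int)
    ties: List[str] = []
    for i in range(n):
        tally = sum(votes[m][i] for m in models)
        if 2 * tally > len(models):
            labels[i] = 1
        elif 2 * tally < len(models):
            labels[i] = 0
        else:
            labels[i] = votes[best_model][i]
            ties.append(preds.subject_ids[i])
    return EnsembleResult("majority", preds.subject_ids, labels, tie_log=ties)


def ensemble_weights(accs: Dict[str, float] | List[float]) -> np.ndarray:
    """Accuracy shares w_j = Acc_j / Σ_i Acc_i (sum to 1)."""
    vals = np.asarray(list(accs.values()) if isinstance(accs, dict) else accs, dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    total = vals.sum()
    if total <= 0:
        raise ValueError("cannot derive weights from all-zero accuracies")
    return vals / total


def weighted_sum_vote(preds: PredictionSet, weights: np.ndarray | None = None,
                      method: str = "weighted_sum") -> EnsembleResult:
    """argmax of the weighted per-class probability sums.

    ``weights=None`` derives accuracy-share weights; uniform weights give the
    plain "sum" method. argmax ties resolve to the MDD class and are logged.
    """
    models = preds.model_order
    if weights is None:
        weights = ensemble_weights({m: preds.val_accuracies[m] for m in models})
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(models):
        raise ValueError(f"{len(weights)} weights for {len(models)} models")
    combined = np.zeros((len(preds.subject_ids), 2))
    for w, m in zip(weights, models):
        combined += w * preds.probabilities[m]
    norm = combined / combined.sum(axis=1, keepdims=True)
    labels = np.where(norm[:, MDD] >= norm[:, 1 - MDD], MDD, 1 - MDD)
    ties = [sid for sid, row in zip(preds.subject_ids, norm)
            if abs(row[0] - row[1]) < 1e-12]
    return EnsembleResult(method, preds.subject_ids, labels,
                          final_probabilities=norm, tie_log=ties)


def sum_vote(preds: PredictionSet) -> EnsembleResult:
    """Unweighted probability-sum ensemble (uniform weights)."""
    k = len(preds.model_order)
    return weighted_sum_vote(preds, weights=np.full(k, 1.0 / k), method="sum")
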