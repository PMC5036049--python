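"""Per-residue evaluation metrics and structure-grouped cross-validation.

Folds always partition structures, never residues, so no chain straddles
the train/test boundary; the pair-weight matrix, propensity table, scaling
statistics and both SVMs are re-fit inside every training fold, and a test
query never uses its own fold's structures as templates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .predictors import (
    SCORE_COLUMNS,
    CRHunterModel,
    FeatureCache,
    FusionConfig,
    QueryRecord,
    SVMConfig,
)
from .tessellation import DEFAULT_FACET_CUTOFF

__all__ = ["EvaluationReport", "threshold_metrics", "auc", "assign_folds", "cross_validate"]


def threshold_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Recall, precision, F1, accuracy and MCC at ``score >= threshold``.

    Degenerate denominators (no predicted positives, single-class MCC)
    yield 0 rather than NaN.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0 or scores.shape != labels.shape:
        raise ValueError("scores and labels must be equal-length and non-empty")
    pred = scores >= threshold
    true = labels == 1
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    tn = int(np.sum(~pred & ~true))
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    acc = (tp + tn) / (tp + fp + fn + tn)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return {"recall": recall, "precision": precision, "f1": f1, "acc": acc, "mcc": mcc}


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) ROC AUC; ties contribute 1/2.

    Raises
    ------
    ValueError
        If only one class is present.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class EvaluationReport:
    """Pooled and per-fold performance of every predictor."""

    pooled_auc: dict[str, float]
    fold_auc: dict[str, list[float]]
    mean_fold_auc: dict[str, float]
    auc_stderr: dict[str, float]
    threshold: float
    threshold_metrics: dict[str, dict[str, float]]
    fold_assignment: dict[str, int]
    n_residues: int = 0
    n_catalytic: int = 0
    scores: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "pooled_auc": self.pooled_auc,
            "fold_auc": self.fold_auc,
            "mean_fold_auc": self.mean_fold_auc,
            "auc_stderr": self.auc_stderr,
            "threshold": self.threshold,
            "threshold_metrics": self.threshold_metrics,
            "fold_assignment": self.fold_assignment,
            "n_residues": self.n_residues,
            "n_catalytic": self.n_catalytic,
        }


def assign_folds(structure_ids: Sequence[str], k: int, seed: int) -> dict[str, int]:
    """Deterministic shuffle-and-split of structures into ``k`` folds."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if len(structure_ids) < k:
        raise ValueError(f"{len(structure_ids)} structures cannot fill {k} folds")
    order = np.random.default_rng(seed).permutation(len(structure_ids))
    assignment = {}
    for rank, idx in enumerate(order):
        assignment[structure_ids[idx]] = rank % k
    return assignment


def cross_validate(
    records: Sequence[QueryRecord],
    k: int,
    template_annotations: Mapping[str, frozenset[int] | set[int]] | None = None,
    svm_config: SVMConfig | None = None,
    fusion_config: FusionConfig | None = None,
    facet_cutoff: int = DEFAULT_FACET_CUTOFF,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Structure-grouped k-fold cross-validation of the full ensemble.

    Every fold re-trains the pair-weight matrix, propensity, scalers and
    both SVMs on its training structures only; template hits pointing at a
    test structure of the current fold are excluded before top-template
    selection.  Reports pooled AUC over all test residues plus per-fold
    AUCs with their standard error, and threshold metrics on the pooled
    scores.
    """
    svm_config = svm_config or SVMConfig(seed=seed)
    fusion_config = fusion_config or FusionConfig()
    cache = FeatureCache(facet_cutoff)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate structure ids in dataset")
    assignment = assign_folds(ids, k, seed)

    all_scores: list[pd.DataFrame] = []
    all_labels: list[np.ndarray] = []
    fold_auc: dict[str, list[float]] = {c: [] for c in SCORE_COLUMNS}
    for fold in range(k):
        train = [r for r in records if assignment[r.id] != fold]
        test = [r for r in records if assignment[r.id] == fold]
        test_ids = {r.id for r in test}
        model = CRHunterModel.fit(
            train,
            template_annotations=template_annotations,
            svm_config=svm_config,
            fusion_config=fusion_config,
            facet_cutoff=facet_cutoff,
            cache=cache,
        )
        fold_scores = []
        fold_labels = []
        for record in test:
            scored = model.predict(record, cache=cache, exclude_template_ids=test_ids)
            scored.insert(0, "structure_id", record.id)
            scored["fold"] = fold
            fold_scores.append(scored)
            fold_labels.append(record.annotation.labels(len(record.structure)))
        scores_frame = pd.concat(fold_scores, ignore_index=False)
        labels_vec = np.concatenate(fold_labels)
        for column in SCORE_COLUMNS:
            if len(np.unique(labels_vec)) == 2:
                fold_auc[column].append(auc(scores_frame[column].to_numpy(), labels_vec))
        all_scores.append(scores_frame)
        all_labels.append(labels_vec)

    pooled = pd.concat(all_scores, ignore_index=False)
    labels = np.concatenate(all_labels)
    pooled_auc = {c: auc(pooled[c].to_numpy(), labels) for c in SCORE_COLUMNS}
    mean_fold = {c: float(np.mean(v)) if v else float("nan") for c, v in fold_auc.items()}
    stderr = {
        c: float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else float("nan")
        for c, v in fold_auc.items()
    }
    metrics = {
        c: threshold_metrics(pooled[c].to_numpy(), labels, threshold) for c in SCORE_COLUMNS
    }
    pooled = pooled.assign(label=labels)
    return EvaluationReport(
        pooled_auc=pooled_auc,
        fold_auc=fold_auc,
        mean_fold_auc=mean_fold,
        auc_stderr=stderr,
        threshold=threshold,
        threshold_metrics=metrics,
        fold_assignment=assignment,
        n_residues=int(len(labels)),
        n_catalytic=int(labels.sum()),
        scores=pooled,
    )
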