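"""Agreement and discrimination metrics.

The classifier is compared with the clinicians' final calls two ways: the
Jaccard coefficient J(Ann, MD) = |Ann ∩ MD| / |Ann ∪ MD| between the two
positive-decision sets, and the ROC curve with its area computed from the
Mann-Whitney midrank statistic (identical to trapezoidal integration of the
empirical ROC).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix, roc_curve

logger = logging.getLogger(__name__)

__all__ = ["jaccard", "decision_agreement", "roc_auc", "EvaluationReport", "evaluate_classifier"]


def jaccard(ann_positive: Iterable, md_positive: Iterable) -> float:
    """Jaccard coefficient between two positive-decision sets.

    By convention two empty sets agree perfectly (1.0): on an all-negative
    cohort both deciders made the same call for every patient.
    """
    a, m = set(ann_positive), set(md_positive)
    if not a and not m:
        logger.info("both decision sets empty; Jaccard defined as 1.0")
        return 1.0
    return len(a & m) / len(a | m)


def decision_agreement(y_ann: np.ndarray, y_md: np.ndarray) -> float:
    """Per-patient agreement fraction (simple matching, not the default
    set-based Jaccard)."""
    y_ann = np.asarray(y_ann)
    y_md = np.asarray(y_md)
    if y_ann.shape != y_md.shape:
        raise ValueError("decision vectors differ in length")
    return float(np.mean(y_ann == y_md))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and AUC.

    The AUC is the Mann-Whitney statistic computed from midranks (ties get
    the average rank), which equals the trapezoidal area under the empirical
    ROC; the returned points are (false-positive-rate, true-positive-rate)
    over all score thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"labels must contain exactly two classes, got {classes}")
    pos = labels == classes[1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores, method="average")
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(pos.astype(int), scores)
    return np.column_stack([fpr, tpr]), float(auc)


@dataclass
class EvaluationReport:
    """Flat summary of one classifier-vs-clinician comparison."""

    jaccard: float
    auc: float
    roc_points: np.ndarray
    tp: int
    fp: int
    tn: int
    fn: int
    n: int
    threshold: float

    def to_dict(self) -> dict:
        return {
            "jaccard": self.jaccard,
            "auc": self.auc,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n": self.n,
            "threshold": self.threshold,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def roc_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.roc_points, columns=["fpr", "tpr"]).to_csv(path, index=False)


def evaluate_classifier(
    y_true: np.ndarray,
    scores: np.ndarray,
    threshold: float = 0.5,
    patient_ids: list | None = None,
) -> EvaluationReport:
    """Score continuous classifier outputs against the reference decisions."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if patient_ids is None:
        patient_ids = list(range(len(y_true)))
    y_pred = (scores >= threshold).astype(int)
    roc_points, auc = roc_auc(scores, y_true)
    ann_pos = {p for p, d in zip(patient_ids, y_pred) if d == 1}
    md_pos = {p for p, d in zip(patient_ids, y_true) if d == 1}
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    return EvaluationReport(
        jaccard=jaccard(ann_pos, md_pos),
        auc=auc,
        roc_points=roc_points,
        tp=int(tp),
        fp=int(fp),
        tn=int(tn),
        fn=int(fn),
        n=len(y_true),
        threshold=threshold,
    )
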