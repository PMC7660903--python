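"""Ensemble scoring, confidence calibration, and evaluation.

The ensemble score of a query is the per-class sum of the softmax
outputs of the 10 cross-validation networks, so scores range from 0 to
10 and sum to 10 over the classes; the query is assigned the argmax
class (ties broken by class-list order), optionally abstaining below a
score threshold.

The confidence table turns a raw score into an empirical precision:
for class c and score s it records the fraction of held-out test
queries predicted as c with score >= s whose true class is c. At the
lowest threshold this equals the per-class precision on the test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    auc,
    confusion_matrix as _sk_confusion,
    precision_recall_fscore_support,
    roc_curve,
)

from phagenn.seqio import ClassList

logger = logging.getLogger(__name__)

NOT_CLASSIFIED = "not classified"


def ensemble_score(member_softmax: np.ndarray) -> np.ndarray:
    """Sum member softmax outputs over the first axis.

    ``member_softmax`` is (n_members, n_classes) for one query or
    (n_members, n_queries, n_classes) for a batch; rows must each sum
    to 1. Returns per-class scores in [0, n_members].
    """
    member_softmax = np.asarray(member_softmax)
    if member_softmax.ndim not in (2, 3):
        raise ValueError("expected a (members, classes) or (members, queries, classes) array")
    sums = member_softmax.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-5):
        raise ValueError("member outputs must each sum to 1 (softmax rows)")
    return member_softmax.sum(axis=0)


def classify(
    scores: np.ndarray,
    classes: ClassList,
    abstain_threshold: float | None = None,
) -> tuple[str, float]:
    """Argmax class and its score; ties go to the earlier class in the
    class list. With an abstain threshold, sub-threshold maxima return
    ``"not classified"`` (the score is still reported)."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(classes),):
        raise ValueError(f"expected {len(classes)} scores, got {scores.shape}")
    best = int(np.argmax(scores))  # np.argmax returns the first maximum
    top = float(scores[best])
    if abstain_threshold is not None and top < abstain_threshold:
        return NOT_CLASSIFIED, top
    return classes.names[best], top


@dataclass(frozen=True)
class ScoreReport:
    id: str
    scores: np.ndarray
    predicted_class: str
    top_score: float
    confidence: float | None = None

    @property
    def classified(self) -> bool:
        return self.predicted_class != NOT_CLASSIFIED


def score_reports(
    ids: Sequence[str],
    member_softmax: np.ndarray,
    classes: ClassList,
    abstain_threshold: float | None = None,
    confidence_table: "ConfidenceTable | None" = None,
) -> list[ScoreReport]:
    """Build one ScoreReport per query from the (members, queries,
    classes) softmax array."""
    totals = ensemble_score(member_softmax)
    if totals.ndim == 1:
        totals = totals[None, :]
    if len(ids) != totals.shape[0]:
        raise ValueError("ids and member_softmax disagree on query count")
    reports = []
    for i, rec_id in enumerate(ids):
        cls, top = classify(totals[i], classes, abstain_threshold)
        conf = None
        if confidence_table is not None and cls != NOT_CLASSIFIED:
            conf = confidence_table.lookup(cls, top)
        reports.append(ScoreReport(id=rec_id, scores=totals[i],
                                   predicted_class=cls, top_score=top,
                                   confidence=conf))
    return reports


@dataclass
class ConfidenceTable:
    """Per-class score→confidence lookup built on held-out test data.

    For each class the table holds thresholds (a fixed 0.0–10.0 grid at
    step 0.1 plus every observed score) and, per threshold s, the
    fraction of test queries predicted as the class with score >= s
    that were correct. Thresholds above the highest observed score
    carry the nearest lower defined value and a sparse-data flag.
    """

    classes: ClassList
    thresholds: dict[str, np.ndarray]
    values: dict[str, np.ndarray]
    sparse: dict[str, np.ndarray]
    never_predicted: set[str] = field(default_factory=set)

    def lookup(self, class_name: str, score: float) -> float | None:
        """Confidence at the largest tabulated threshold <= score;
        None when the class was never predicted in calibration."""
        if class_name in self.never_predicted:
            return None
        t = self.thresholds[class_name]
        i = int(np.searchsorted(t, score, side="right")) - 1
        if i < 0:
            i = 0
        return float(self.values[class_name][i])

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for cls in self.classes:
            if cls in self.never_predicted:
                continue
            for t, v, s in zip(self.thresholds[cls], self.values[cls], self.sparse[cls]):
                rows.append({"class": cls, "threshold": t, "confidence": v, "sparse": int(s)})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, classes: ClassList) -> "ConfidenceTable":
        df = pd.read_csv(path)
        thresholds, values, sparse = {}, {}, {}
        for name, grp in df.groupby("class", sort=False):
            thresholds[name] = grp["threshold"].to_numpy(float)
            values[name] = grp["confidence"].to_numpy(float)
            sparse[name] = grp["sparse"].to_numpy(bool)
        never = {c for c in classes if c not in thresholds}
        return cls(classes=classes, thresholds=thresholds, values=values,
                   sparse=sparse, never_predicted=never)


def build_confidence_table(
    test_reports: Sequence[ScoreReport],
    truth: Mapping[str, str],
    classes: ClassList,
    n_members: int = 10,
    grid_step: float = 0.1,
) -> ConfidenceTable:
    """Calibrate score→confidence on test-set predictions.

    confidence(c, s) = #(predicted c, score >= s, truth == c)
                     / #(predicted c, score >= s)
    """
    missing = [r.id for r in test_reports if r.id not in truth]
    if missing:
        raise ValueError(f"{len(missing)} report ids lack truth labels")
    grid = np.round(np.arange(0.0, n_members + grid_step / 2, grid_step), 10)
    thresholds: dict[str, np.ndarray] = {}
    values: dict[str, np.ndarray] = {}
    sparse: dict[str, np.ndarray] = {}
    never: set[str] = set()
    for cls in classes:
        cls_scores = np.array([r.top_score for r in test_reports if r.predicted_class == cls])
        cls_correct = np.array(
            [truth[r.id] == cls for r in test_reports if r.predicted_class == cls],
            dtype=bool,
        )
        if len(cls_scores) == 0:
            never.add(cls)
            logger.warning("class %r never predicted in calibration data", cls)
            continue
        ts = np.unique(np.concatenate([grid, cls_scores]))
        vals = np.empty(len(ts))
        sp = np.zeros(len(ts), dtype=bool)
        last = np.nan
        for i, s in enumerate(ts):
            at = cls_scores >= s - 1e-12
            n_pred = int(at.sum())
            if n_pred == 0:
                vals[i] = last  # carry the nearest lower-threshold value
                sp[i] = True
            else:
                vals[i] = cls_correct[at].sum() / n_pred
                last = vals[i]
        thresholds[cls] = ts
        values[cls] = vals
        sparse[cls] = sp
    return ConfidenceTable(classes=classes, thresholds=thresholds,
                           values=values, sparse=sparse, never_predicted=never)


@dataclass
class MetricsReport:
    """Per-class and averaged classification metrics at one score cutoff."""

    classes: ClassList
    cutoff: float
    retained_fraction: float
    n_retained: int
    per_class: pd.DataFrame  # precision, recall, f1, support per class
    accuracy: float
    macro: dict[str, float]
    weighted: dict[str, float]
    confusion: np.ndarray
    roc: dict[str, dict] = field(default_factory=dict)  # class -> {fpr, tpr, auc}

    @property
    def defined(self) -> bool:
        return self.n_retained > 0

    def confusion_normalized(self) -> np.ndarray:
        """Row-normalized confusion matrix; all-zero rows stay zero."""
        row_sums = self.confusion.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(row_sums > 0, self.confusion / row_sums, 0.0)
        return out


def evaluate(
    reports: Sequence[ScoreReport],
    truth: Mapping[str, str],
    classes: ClassList,
    score_cutoffs: Sequence[float] = (0.0,),
    compute_roc: bool = False,
) -> list[MetricsReport]:
    """Metrics at each score cutoff.

    At cutoff s, queries whose top score falls below s are excluded
    ("not classified") and the retained fraction is reported. ROC
    curves are one-vs-rest on the per-class score scaled to [0, 1].
    """
    labels = list(classes.names)
    n_total = len(reports)
    out: list[MetricsReport] = []
    for cutoff in score_cutoffs:
        kept = [r for r in reports if r.top_score >= cutoff and r.classified]
        n_kept = len(kept)
        if n_kept == 0:
            logger.warning("no queries retained at cutoff %.2f; metrics undefined", cutoff)
            out.append(MetricsReport(
                classes=classes, cutoff=cutoff, retained_fraction=0.0, n_retained=0,
                per_class=pd.DataFrame(index=labels,
                                       columns=["precision", "recall", "f1", "support"]),
                accuracy=float("nan"), macro={}, weighted={},
                confusion=np.zeros((len(labels), len(labels)), dtype=int),
            ))
            continue
        y_true = [truth[r.id] for r in kept]
        y_pred = [r.predicted_class for r in kept]
        prec, rec, f1, support = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=0
        )
        per_class = pd.DataFrame(
            {"precision": prec, "recall": rec, "f1": f1, "support": support},
            index=labels,
        )
        macro_p, macro_r, macro_f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average="macro", zero_division=0
        )
        w_p, w_r, w_f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average="weighted", zero_division=0
        )
        report = MetricsReport(
            classes=classes,
            cutoff=cutoff,
            retained_fraction=n_kept / n_total if n_total else 0.0,
            n_retained=n_kept,
            per_class=per_class,
            accuracy=float(np.mean(np.array(y_true) == np.array(y_pred))),
            macro={"precision": float(macro_p), "recall": float(macro_r), "f1": float(macro_f)},
            weighted={"precision": float(w_p), "recall": float(w_r), "f1": float(w_f)},
            confusion=_sk_confusion(y_true, y_pred, labels=labels),
        )
        if compute_roc:
            scores = np.vstack([r.scores for r in kept])
            n_members = scores.sum(axis=1).mean()
            graded = scores / n_members
            for ci, cls in enumerate(labels):
                y_bin = np.array([t == cls for t in y_true], dtype=int)
                if y_bin.sum() in (0, len(y_bin)):
                    continue  # ROC undefined for a one-class column
                fpr, tpr, _ = roc_curve(y_bin, graded[:, ci])
                report.roc[cls] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}
        out.append(report)
    return out


def reports_to_csv(
    reports: Sequence[ScoreReport],
    classes: ClassList,
    path: str | Path,
) -> None:
    """Prediction CSV: id, predicted_class, score, confidence, then one
    score column per class."""
    rows = []
    for r in reports:
        row = {
            "id": r.id,
            "predicted_class": r.predicted_class,
            "score": r.top_score,
            "confidence": "" if r.confidence is None else r.confidence,
        }
        for ci, cls in enumerate(classes):
            row[f"score_{cls}"] = r.scores[ci]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
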