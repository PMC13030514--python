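"""Multiclass evaluation surface: confusion matrix, P/R/F1, accuracies,
log loss and log-loss reduction.

Definitions (per class, counts from the confusion matrix with rows = true):

    Precision = TP / (TP + FP) * 100      Recall = TP / (TP + FN) * 100
    F1 = 2 P R / (P + R)

Macro accuracy is the unweighted mean of per-class recall (a fraction);
micro accuracy is trace/total, which for single-label classification equals
overall accuracy — asserted on every report.  Log loss is the mean negative
natural log of the probability assigned to the true class; the reduction is
1 - model / prior, where the prior predictor emits the training class
frequencies (negative reduction = worse-than-baseline probabilities).

A class with no predictions (or no true members) has undefined precision
(recall); it is reported as 0 and flagged, so macro averages stay defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import FeatureMatrix, TrainedClassifier

PROB_CLIP = 1e-15


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, classes: list[str]
) -> np.ndarray:
    """Count matrix with entry (i, j) = # samples of true class i predicted j."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    for label in np.concatenate([y_true, y_pred]):
        if label not in index:
            raise ValueError(f"label {label!r} not in the class list")
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[index[t], index[p]] += 1
    return mat


def precision_recall_f1(confusion: np.ndarray) -> pd.DataFrame:
    """Per-class precision, recall and F1 in percent, with degeneracy flags."""
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(confusion < 0):
        raise ValueError("confusion matrix counts must be non-negative")
    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    rows = []
    for i in range(len(tp)):
        flag = ""
        if tp[i] + fp[i] == 0 and tp[i] + fn[i] == 0:
            p = r = f1 = 0.0
            flag = "undefined: no true or predicted samples"
        else:
            p = 100.0 * tp[i] / (tp[i] + fp[i]) if tp[i] + fp[i] > 0 else 0.0
            r = 100.0 * tp[i] / (tp[i] + fn[i]) if tp[i] + fn[i] > 0 else 0.0
            if tp[i] + fp[i] == 0:
                flag = "undefined precision: no predictions for class"
            elif tp[i] + fn[i] == 0:
                flag = "undefined recall: no true samples"
            f1 = 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0
        rows.append({"tp": int(tp[i]), "fp": int(fp[i]), "fn": int(fn[i]),
                     "precision": p, "recall": r, "f1": f1, "flag": flag})
    return pd.DataFrame(rows)


def log_loss(probabilities: np.ndarray, y_true: np.ndarray, classes: list[str]) -> float:
    """Mean negative natural log probability of the true class (nats)."""
    probabilities = np.asarray(probabilities, dtype=float)
    y_true = np.asarray(y_true)
    if probabilities.shape != (len(y_true), len(classes)):
        raise ValueError("probability matrix shape must be (n_samples, n_classes)")
    sums = probabilities.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1 (+/- 1e-6)")
    index = {c: i for i, c in enumerate(classes)}
    p_true = probabilities[np.arange(len(y_true)), [index[t] for t in y_true]]
    return float(-np.mean(np.log(np.clip(p_true, PROB_CLIP, 1.0))))


def log_loss_reduction(model_ll: float, prior_ll: float) -> float:
    """1 - model/prior; 1 for perfect, 0 at the prior, negative when worse."""
    if prior_ll <= 0:
        raise ValueError("prior log loss must be positive")
    return 1.0 - model_ll / prior_ll


@dataclass
class EvaluationReport:
    algorithm: str
    classes: list[str]
    confusion: np.ndarray
    per_class: pd.DataFrame
    overall_accuracy: float  # percent
    macro_accuracy: float  # fraction (mean per-class recall)
    micro_accuracy: float  # fraction (trace / total)
    log_loss: float
    log_loss_reduction: float
    flags: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Metrics x species table mirroring the survey's comparison layout."""
        df = self.per_class[["precision", "recall", "f1"]].T
        df.columns = self.classes
        df.index = ["Precision", "Recall", "F1-score"]
        return df


def evaluate(
    clf: TrainedClassifier, test: FeatureMatrix, algorithm_name: str | None = None
) -> EvaluationReport:
    """Score a trained classifier on held-out ROIs."""
    classes = [str(c) for c in clf.classes]
    y_pred = clf.predict(test.X)
    conf = confusion_matrix(test.labels, y_pred, classes)
    per_class = precision_recall_f1(conf)
    total = conf.sum()
    micro = float(np.trace(conf) / total) if total else 0.0
    macro = float(per_class["recall"].mean() / 100.0)
    overall = 100.0 * micro

    proba = clf.predict_proba(test.X)
    ll = log_loss(proba, test.labels, classes)
    priors = np.array([clf.class_priors.get(c, 0.0) for c in classes])
    priors = np.clip(priors, PROB_CLIP, 1.0)
    priors = priors / priors.sum()
    prior_ll = log_loss(np.tile(priors, (len(test.labels), 1)), test.labels, classes)
    llr = log_loss_reduction(ll, prior_ll)

    flags = {f"class {classes[i]}": f for i, f in enumerate(per_class["flag"]) if f}
    flags["macro_accuracy_definition"] = "unweighted mean of per-class recall"
    flags["micro_accuracy_definition"] = "trace of confusion / total samples"
    flags["log_loss_base"] = "natural log (nats)"
    return EvaluationReport(
        algorithm=algorithm_name or clf.algorithm,
        classes=classes,
        confusion=conf,
        per_class=per_class,
        overall_accuracy=overall,
        macro_accuracy=macro,
        micro_accuracy=micro,
        log_loss=ll,
        log_loss_reduction=llr,
        flags=flags,
    )


def compare_report(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Ranked summary: by overall accuracy descending, ties by log loss ascending."""
    if not reports:
        raise ValueError("compare_report needs at least one report")
    rows = [
        {"algorithm": r.algorithm, "overall_accuracy": r.overall_accuracy,
         "macro_accuracy": r.macro_accuracy, "micro_accuracy": r.micro_accuracy,
         "log_loss": r.log_loss, "log_loss_reduction": r.log_loss_reduction}
        for r in reports
    ]
    df = pd.DataFrame(rows).sort_values(
        ["overall_accuracy", "log_loss"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.index = df.index + 1
    df.index.name = "rank"
    return df
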