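"""ROC/PR analysis, Youden-J threshold selection and the ablation harness.

The threshold list is the set of distinct observed scores plus a
sentinel above the maximum (at which nothing is predicted positive);
a pair is called positive when its score is >= the threshold. The
"optimal" operating point maximizes Youden's J = TPR - FPR over that
list, with ties broken toward the larger (more conservative) threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class EvalError(ValueError):
    """Scores/labels unusable for the requested curve."""


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    """Curves plus scalar metrics at the Youden-optimal threshold."""

    roc: list[tuple[float, float, float]]  # (threshold, FPR, TPR)
    pr: list[tuple[float, float, float]]  # (threshold, recall, precision)
    auc: float
    aupr: float
    opt_threshold: float
    confusion: ConfusionCounts
    acc: float
    f1: float
    precision: float
    recall: float


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise EvalError(f"scores and labels must be equal-length vectors, got {s.shape} vs {y.shape}")
    if not np.isin(y, (0, 1)).all():
        raise EvalError("labels must be 0/1")
    return s, y.astype(np.int64)


def _threshold_list(scores: np.ndarray) -> np.ndarray:
    """Distinct scores, descending, preceded by a sentinel above the max."""
    distinct = np.unique(scores)[::-1]
    return np.concatenate([[distinct[0] + 1.0], distinct])


def roc_points(scores, labels) -> list[tuple[float, float, float]]:
    """(threshold, FPR, TPR) at every threshold in the list.

    The first point is (0, 0) at the sentinel and the last is (1, 1) at
    the minimum score (everything predicted positive); FPR is
    non-decreasing as the threshold decreases.
    """
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvalError("ROC requires both classes present")
    pts = []
    for t in _threshold_list(s):
        pred = s >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        pts.append((float(t), fp / n_neg, tp / n_pos))
    return pts


def auc(points: list[tuple[float, float, float]]) -> float:
    """Trapezoidal area under the ROC curve (over the FPR axis).

    Equals the rank statistic P(score+ > score-) + 0.5 P(tie) on the
    same data.
    """
    if len(points) < 2:
        raise EvalError("need at least two ROC points")
    fpr = np.array([p[1] for p in points])
    tpr = np.array([p[2] for p in points])
    return float(np.trapezoid(tpr, fpr))


def roc_auc_score(scores, labels) -> float:
    """Convenience: AUC straight from scores and labels."""
    return auc(roc_points(scores, labels))


def pr_points(scores, labels) -> list[tuple[float, float, float]]:
    """(threshold, recall, precision) at every threshold.

    At the sentinel (no predicted positives) precision is taken as 1.0
    by convention; at the lowest threshold precision equals the class
    prevalence and recall is 1.
    """
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise EvalError("PR curve requires at least one positive label")
    pts = []
    for t in _threshold_list(s):
        pred = s >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
        pts.append((float(t), tp / n_pos, precision))
    return pts


def aupr(points: list[tuple[float, float, float]]) -> float:
    """Trapezoidal area under the precision-recall curve (over recall)."""
    if len(points) < 2:
        raise EvalError("need at least two PR points")
    rec = np.array([p[1] for p in points])
    prec = np.array([p[2] for p in points])
    return float(np.trapezoid(prec, rec))


def optimal_threshold(points: list[tuple[float, float, float]]) -> float:
    """Threshold maximizing Youden's J = TPR - FPR over the ROC points.

    Ties break toward the larger threshold; with no ranking signal
    (J = 0 everywhere) this returns the sentinel.
    """
    if len(points) < 2:
        raise EvalError("need at least two ROC points")
    best_t, best_j = None, -np.inf
    for t, fpr, tpr in points:  # points are in descending-threshold order
        j = tpr - fpr
        if j > best_j:  # strict: first (largest) threshold wins ties
            best_j, best_t = j, t
    return float(best_t)


def thresholded_metrics(scores, labels, threshold: float):
    """Confusion counts and ACC/F1/precision/recall at ``score >= t``.

    F1 is defined as 0 when precision + recall = 0 (no predicted and/or
    no true positives); the degenerate case is logged.
    """
    s, y = _as_arrays(scores, labels)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    acc = (tp + tn) / counts.total
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    if precision + recall == 0:
        logger.info("degenerate operating point (no true or predicted positives); F1 := 0")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return counts, acc, f1, precision, recall


def evaluate_scores(scores, labels) -> EvalReport:
    """Full report: curves, areas, Youden threshold and metrics there."""
    roc = roc_points(scores, labels)
    pr = pr_points(scores, labels)
    t = optimal_threshold(roc)
    counts, acc, f1, precision, recall = thresholded_metrics(scores, labels, t)
    return EvalReport(roc=roc, pr=pr, auc=auc(roc), aupr=aupr(pr), opt_threshold=t,
                      confusion=counts, acc=acc, f1=f1, precision=precision, recall=recall)


# ---------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------

ABLATION_CONFIGS: dict[str, tuple[str, ...]] = {
    # one channel within its entity, the other entity's channels intact
    "Protein_CNN": ("protein_cnn", "drug_cnn", "drug_fingerprints"),
    "Protein_transformer": ("protein_transformer", "drug_cnn", "drug_fingerprints"),
    "Drug_CNN": ("protein_cnn", "protein_transformer", "drug_cnn"),
    "Drug_fingerprints": ("protein_cnn", "protein_transformer", "drug_fingerprints"),
    "ALL": ("protein_cnn", "protein_transformer", "drug_cnn", "drug_fingerprints"),
}


@dataclass
class AblationRun:
    """One trained configuration: its test report, raw scores and model."""

    report: EvalReport
    scores: np.ndarray
    model: object  # MultiViewDTI (kept untyped to avoid an import cycle)
    history: object  # TrainHistory


def run_ablation(split, model_cfg, train_cfg) -> dict[str, AblationRun]:
    """Train and evaluate each channel configuration on the test set.

    Five rows: each single-channel-within-its-entity variant plus the
    full model. Raw test scores are kept per row so every metric can be
    recomputed from them.
    """
    from .encode import encode_records  # local import: avoid cycle at module load
    from .train import build_vocabularies, train_model

    vocabs = build_vocabularies(split)
    results: dict[str, AblationRun] = {}
    for name, channels in ABLATION_CONFIGS.items():
        cfg = model_cfg.with_channels(channels)
        model, history = train_model(split, cfg, train_cfg, vocabularies=vocabs)
        enc_test = encode_records(split.test, *vocabs, cfg.protein_length, cfg.drug_length)
        scores = model.predict(enc_test)
        report = evaluate_scores(scores, enc_test.labels)
        logger.info("ablation %s: AUC %.3f AUPR %.3f ACC %.3f F1 %.3f",
                    name, report.auc, report.aupr, report.acc, report.f1)
        results[name] = AblationRun(report=report, scores=scores, model=model, history=history)
    return results


def ablation_table(results: dict[str, AblationRun]):
    """The five-row summary table as a pandas DataFrame."""
    import pandas as pd

    rows = [
        {"Channels": name, "AUC": run.report.auc, "AUPR": run.report.aupr,
         "F1-Score": run.report.f1, "ACC": run.report.acc,
         "Threshold": run.report.opt_threshold}
        for name, run in results.items()
    ]
    return pd.DataFrame(rows)
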