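"""Evaluation metrics for heavily skewed binary prediction.

Threshold metrics follow the textbook confusion-matrix formulas:

    Accuracy  = (TP + TN) / (TP + TN + FP + FN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F1        = 2 * Precision * Recall / (Precision + Recall)

Precision/recall/F1 with a zero denominator are reported as NaN, never
silently 0 — an all-negative predictor has *undefined* precision.

Ranking metrics: AUROC is the trapezoidal area under the ROC traced by
sweeping a threshold over the distinct score values (ties grouped; equal to
the rank statistic P(score_pos > score_neg) + 0.5 P(tie)). Average precision
is the step sum  AP = sum_n (R_n - R_{n-1}) * P_n  over the same sweep with
the curve anchored at recall 0 — deliberately not a PR trapezoid, which
differs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RepeatedReport",
    "threshold_calls",
    "confusion_counts",
    "roc_points",
    "pr_points",
    "auroc_score",
    "average_precision",
    "compute_metrics",
    "aggregate_reports",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def threshold_calls(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Binary calls with the ties-to-positive convention: call = 1 iff score >= t."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    return (np.asarray(scores, dtype=float) >= threshold).astype(np.int8)


def confusion_counts(
    labels: np.ndarray, scores: np.ndarray, threshold: float
) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=np.int8)
    calls = threshold_calls(scores, threshold)
    if labels.shape != calls.shape:
        raise ValueError("labels and scores differ in length")
    return ConfusionCounts(
        tp=int(((labels == 1) & (calls == 1)).sum()),
        tn=int(((labels == 0) & (calls == 0)).sum()),
        fp=int(((labels == 0) & (calls == 1)).sum()),
        fn=int(((labels == 1) & (calls == 0)).sum()),
    )


def _ranked_cumulatives(labels: np.ndarray, scores: np.ndarray):
    """Cumulative TP/FP after each distinct score, descending (ties grouped)."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # last index of each tie group
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tps = np.cumsum(y == 1)[distinct].astype(float)
    fps = np.cumsum(y == 0)[distinct].astype(float)
    return tps, fps


def roc_points(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(FPR, TPR) points from (0,0) to (1,1), one per distinct score."""
    labels = np.asarray(labels, np.int8)
    scores = np.asarray(scores, float)
    n_pos, n_neg = int((labels == 1).sum()), int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    tps, fps = _ranked_cumulatives(labels, scores)
    fpr = np.r_[0.0, fps / n_neg]
    tpr = np.r_[0.0, tps / n_pos]
    return np.column_stack([fpr, tpr])


def pr_points(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(recall, precision) points anchored at recall 0 (precision 1 by convention)."""
    labels = np.asarray(labels, np.int8)
    scores = np.asarray(scores, float)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("PR curve requires at least one positive")
    tps, fps = _ranked_cumulatives(labels, scores)
    recall = np.r_[0.0, tps / n_pos]
    precision = np.r_[1.0, tps / (tps + fps)]
    return np.column_stack([recall, precision])


def auroc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    pts = roc_points(labels, scores)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def average_precision(labels: np.ndarray, scores: np.ndarray) -> float:
    """Step-sum AP over the ranked sweep: sum (R_n - R_{n-1}) * P_n."""
    pts = pr_points(labels, scores)
    recall, precision = pts[:, 0], pts[:, 1]
    return float(np.sum(np.diff(recall) * precision[1:]))


@dataclass
class MetricsReport:
    """Full evaluation at one decision threshold plus the ranking curves."""

    threshold: float
    confusion: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    auroc: float
    ap: float
    roc: np.ndarray = field(repr=False)
    prc: np.ndarray = field(repr=False)

    _METRICS = ("accuracy", "precision", "recall", "f1", "auroc", "ap")

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "confusion": vars(self.confusion),
            **{m: getattr(self, m) for m in self._METRICS},
        }

    def summary(self) -> str:
        c = self.confusion
        lines = [
            f"evaluation at threshold {self.threshold:g} "
            f"(n={c.total}, positives={c.tp + c.fn})",
            f"  TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn}",
        ]
        for m in self._METRICS:
            v = getattr(self, m)
            lines.append(f"  {m:<10}{'NaN' if math.isnan(v) else f'{v:.4f}'}")
        return "\n".join(lines)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else float("nan")


def compute_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Confusion metrics at ``threshold`` plus ROC/AUROC and PRC/AP."""
    labels = np.asarray(labels, np.int8)
    scores = np.asarray(scores, float)
    if labels.size == 0 or labels.shape != scores.shape:
        raise ValueError("labels and scores must be equal-length and non-empty")
    c = confusion_counts(labels, scores, threshold)
    precision = _safe_div(c.tp, c.tp + c.fp)
    recall = _safe_div(c.tp, c.tp + c.fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    both_classes = 0 < (labels == 1).sum() < labels.size
    return MetricsReport(
        threshold=threshold,
        confusion=c,
        accuracy=_safe_div(c.tp + c.tn, c.total),
        precision=precision,
        recall=recall,
        f1=f1,
        auroc=auroc_score(labels, scores) if both_classes else float("nan"),
        ap=average_precision(labels, scores) if (labels == 1).any() else float("nan"),
        roc=roc_points(labels, scores) if both_classes else np.empty((0, 2)),
        prc=pr_points(labels, scores) if (labels == 1).any() else np.empty((0, 2)),
    )


@dataclass
class RepeatedReport:
    """Mean +/- standard error of each metric over k repeated runs."""

    runs: list[MetricsReport]

    def __post_init__(self) -> None:
        if len(self.runs) < 2:
            raise ValueError("a repeated report needs at least two runs")

    @property
    def k(self) -> int:
        return len(self.runs)

    def mean_se(self, metric: str) -> tuple[float, float]:
        vals = np.array([getattr(r, metric) for r in self.runs], dtype=float)
        # SE = sample standard deviation / sqrt(k); NaN runs propagate to NaN
        return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(self.k))

    def as_dict(self) -> dict:
        out = {"k": self.k}
        for m in MetricsReport._METRICS:
            mean, se = self.mean_se(m)
            out[m] = {"mean": mean, "se": se}
        return out

    def summary(self) -> str:
        lines = [f"mean +/- SE over {self.k} seeds"]
        for m in MetricsReport._METRICS:
            mean, se = self.mean_se(m)
            if math.isnan(mean):
                lines.append(f"  {m:<10}NaN")
            else:
                lines.append(f"  {m:<10}{mean:.2f} +/- {se:.2f}")
        return "\n".join(lines)


def aggregate_reports(runs: list[MetricsReport]) -> RepeatedReport:
    return RepeatedReport(runs)
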