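"""Evaluation metrics and significance machinery.

Accuracy is the fraction of exact label matches. Per-class
precision-recall curves are computed one-vs-rest by walking the distinct
score thresholds in descending order (ties at a threshold handled
jointly), and integrated by the trapezoidal rule over recall; the
class-weighted AUC-PR weights each class by its support in the evaluated
fold. Run-level comparisons use the pooled-variance independent-samples
t-test together with Cohen's d on the same pooled standard deviation, so
the two statistics satisfy t = d * sqrt(n_a n_b / (n_a + n_b)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PRCurve:
    """Aligned precision/recall sequences for one class (one-vs-rest)."""

    recall: np.ndarray
    precision: np.ndarray
    class_id: int = 0

    def __post_init__(self) -> None:
        self.recall = np.asarray(self.recall, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        if self.recall.shape != self.precision.shape:
            raise ValueError("recall and precision must be aligned")
        for arr, name in ((self.recall, "recall"), (self.precision, "precision")):
            if np.isnan(arr).any():
                raise ValueError(f"{name} contains NaN")
            if np.any((arr < -1e-12) | (arr > 1 + 1e-12)):
                raise ValueError(f"{name} values must lie in [0, 1]")


@dataclass(frozen=True)
class RunMetrics:
    """Test-fold metrics of one training run."""

    split_id: int
    repeat_id: int
    accuracy: float
    weighted_auc_pr: float

    def __post_init__(self) -> None:
        for value in (self.accuracy, self.weighted_auc_pr):
            if not 0.0 <= value <= 1.0:
                raise ValueError("run metrics must lie in [0, 1]")


@dataclass(frozen=True)
class SignificanceReport:
    """Pooled t-test and effect size for one two-group comparison."""

    t_statistic: float
    p_value: float
    cohens_d: float
    n_a: int
    n_b: int


def accuracy(predicted: Sequence, truth: Sequence) -> float:
    """Fraction of samples whose predicted label equals the true label."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if predicted.size == 0:
        raise ValueError("accuracy of an empty sample set is undefined")
    return float(np.mean(predicted == truth))


def pr_curve(scores: Sequence[float], truth: Sequence[int], class_id: int = 0) -> PRCurve:
    """Precision-recall points at every distinct score threshold.

    At threshold s, samples with score >= s are predicted positive; ties
    at a threshold therefore enter jointly. The recall-zero endpoint is
    anchored at the precision of the highest threshold (no interpolation
    to 1).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(truth.sum())
    if n_pos == 0:
        raise ValueError("PR curve undefined without positive labels")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_truth = truth[order]
    tp_cum = np.cumsum(sorted_truth)
    pred_cum = np.arange(1, len(scores) + 1)
    # last index of each run of tied scores = joint threshold handling
    is_last_of_tie = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tp = tp_cum[is_last_of_tie]
    npred = pred_cum[is_last_of_tie]
    precision = tp / npred
    recall = tp / n_pos
    # anchor the curve at recall 0 with the highest-threshold precision
    recall = np.r_[0.0, recall]
    precision = np.r_[precision[0], precision]
    return PRCurve(recall=recall, precision=precision, class_id=class_id)


def auc_pr_trapezoid(curve: PRCurve) -> float:
    """Trapezoidal area under the PR curve over recall-sorted points."""
    if len(curve.recall) < 2:
        raise ValueError("need at least two PR points to integrate")
    order = np.argsort(curve.recall, kind="stable")
    r = curve.recall[order]
    p = curve.precision[order]
    return float(np.sum((r[1:] - r[:-1]) * (p[1:] + p[:-1]) / 2.0))


def weighted_auc_pr(per_class: Sequence[float], counts: Sequence[int]) -> float:
    """Support-weighted mean of per-class AUC-PR values."""
    per_class = np.asarray(per_class, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if per_class.shape != counts.shape:
        raise ValueError("per-class AUCs and counts must align")
    if np.any(counts <= 0):
        raise ValueError("class counts must be positive")
    total = counts.sum()
    if total == 0:
        raise ValueError("zero total count")
    return float((counts / total * per_class).sum())


def weighted_auc_pr_from_scores(probs: np.ndarray, truth: Sequence[int]) -> float:
    """One-vs-rest weighted AUC-PR from an (N, C) probability matrix.

    Class weights are the class frequencies of the evaluated fold;
    classes absent from the fold carry zero weight.
    """
    probs = np.asarray(probs, dtype=float)
    truth = np.asarray(truth).astype(int)
    aucs, counts = [], []
    for c in range(probs.shape[1]):
        binary = (truth == c).astype(int)
        if binary.sum() == 0:
            continue
        aucs.append(auc_pr_trapezoid(pr_curve(probs[:, c], binary, class_id=c)))
        counts.append(int(binary.sum()))
    if not counts:
        raise ValueError("no class has positive support")
    return weighted_auc_pr(aucs, counts)


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float(np.sqrt(var))


def t_test_independent(group_a: Sequence[float], group_b: Sequence[float]
                       ) -> tuple[float, float]:
    """Two-sided pooled-variance (Student) independent-samples t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if _pooled_sd(a, b) == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    sd = _pooled_sd(a, b)
    if sd == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    return float((a.mean() - b.mean()) / sd)


def compare_groups(group_a: Sequence[float], group_b: Sequence[float]
                   ) -> SignificanceReport:
    t, p = t_test_independent(group_a, group_b)
    return SignificanceReport(
        t_statistic=t, p_value=p, cohens_d=cohens_d(group_a, group_b),
        n_a=len(list(group_a)), n_b=len(list(group_b)),
    )


def runs_to_frame(runs: Sequence[RunMetrics], label: str = "") -> pd.DataFrame:
    rows = [
        {
            "configuration": label,
            "split_id": r.split_id,
            "repeat_id": r.repeat_id,
            "accuracy": r.accuracy,
            "weighted_auc_pr": r.weighted_auc_pr,
        }
        for r in runs
    ]
    return pd.DataFrame(rows)


def comparison_report(
    runs_a: Sequence[RunMetrics],
    runs_b: Sequence[RunMetrics],
    label_a: str = "multi-head",
    label_b: str = "single-head",
) -> pd.DataFrame:
    """Per-metric mean +/- SD of both configurations plus t, p and d.

    One row per metric, mirroring the usual published layout of model
    comparisons (group summaries alongside the test statistics).
    """
    frame_a = runs_to_frame(runs_a, label_a)
    frame_b = runs_to_frame(runs_b, label_b)
    rows = []
    for metric in ("accuracy", "weighted_auc_pr"):
        a = frame_a[metric].to_numpy()
        b = frame_b[metric].to_numpy()
        try:
            report = compare_groups(a, b)
        except ValueError:
            # degenerate groups (zero pooled variance): the summary columns
            # remain informative, the test statistics are undefined
            report = SignificanceReport(np.nan, np.nan, np.nan, len(a), len(b))
        rows.append(
            {
                "metric": metric,
                f"{label_a}_mean": a.mean(),
                f"{label_a}_sd": a.std(ddof=1),
                f"{label_b}_mean": b.mean(),
                f"{label_b}_sd": b.std(ddof=1),
                "t_statistic": report.t_statistic,
                "p_value": report.p_value,
                "cohens_d": report.cohens_d,
            }
        )
    return pd.DataFrame(rows)
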