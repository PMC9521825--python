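"""Dataset splitting, classification metrics and report generation.

Splitting follows the 80/10/10 train/validation/test convention, with
stratification by class as the default because the curation corpus is
strongly imbalanced.  Metrics use the standard formulas

    precision = TP/(TP+FP)      recall = TP/(TP+FN)
    F1 = 2PR/(P+R)              accuracy = (TP+TN)/total
    specificity = TN/(TN+FP)    FPR = FP/(FP+TN)

with any 0/0 ratio reported as 0 and flagged.  ROC and precision-recall
curves are swept over the unique scores; AUC is trapezoidal, auPRC uses
step-wise interpolation (precision held constant between recall steps).
Displayed numbers follow truncation (0.9167 -> 0.916, 93.68% -> 93.6%);
stored values keep full precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SplitSpec",
    "ConfusionCounts",
    "EvaluationReport",
    "split",
    "confusion_from_predictions",
    "binary_metrics",
    "multiclass_metrics",
    "roc_prc",
    "truncate",
]


def truncate(x: float, decimals: int = 3) -> float:
    """Truncate (not round) towards zero at the given decimal place."""
    factor = 10 ** decimals
    return math.trunc(x * factor) / factor


@dataclass(frozen=True)
class SplitSpec:
    train: float = 0.8
    validation: float = 0.1
    test: float = 0.1
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.train, self.validation, self.test) < 0:
            raise ValueError("split fractions must be non-negative")


def _apportion(n: int, fractions: Sequence[float]) -> list[int]:
    exact = np.asarray(fractions) * n
    counts = np.floor(exact).astype(int)
    for i in np.argsort(exact - counts)[::-1][: n - counts.sum()]:
        counts[i] += 1
    return [int(c) for c in counts]


def split(labels: Sequence, spec: SplitSpec = SplitSpec()
          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, seed-deterministic index partition
    (train, validation, test); stratified mode preserves the class
    proportions of ``labels`` within rounding."""
    y = np.asarray(labels)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 records to split")
    rng = np.random.default_rng(spec.seed)
    fractions = (spec.train, spec.validation, spec.test)
    parts: list[list[int]] = [[], [], []]
    if spec.stratified:
        for c in np.unique(y):
            idx = rng.permutation(np.flatnonzero(y == c))
            a, b, _ = _apportion(len(idx), fractions)
            parts[0] += list(idx[:a])
            parts[1] += list(idx[a:a + b])
            parts[2] += list(idx[a + b:])
    else:
        idx = rng.permutation(n)
        a, b, _ = _apportion(n, fractions)
        parts = [list(idx[:a]), list(idx[a:a + b]), list(idx[a + b:])]
    return tuple(np.sort(np.asarray(p, dtype=int)) for p in parts)


@dataclass(frozen=True)
class ConfusionCounts:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


@dataclass
class EvaluationReport:
    """Confusion counts plus the derived metrics; optional curve data."""

    counts: Optional[ConfusionCounts] = None
    matrix: Optional[list[list[int]]] = None
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    accuracy: float = 0.0
    specificity: Optional[float] = None
    fpr: Optional[float] = None
    auc: Optional[float] = None
    auprc: Optional[float] = None
    per_class: Optional[dict] = None
    averaging: Optional[str] = None
    roc_points: Optional[list] = None
    prc_points: Optional[list] = None
    #: names of ratios that were 0/0 and reported as 0
    undefined: list = field(default_factory=list)

    def display(self) -> dict[str, str]:
        """Truncated presentation values (3 decimals; F1 also as one-decimal
        percent)."""
        out = {k: f"{truncate(v, 3):.3f}"
               for k, v in (("precision", self.precision),
                            ("recall", self.recall), ("f1", self.f1),
                            ("accuracy", self.accuracy))}
        out["f1_percent"] = f"{truncate(self.f1 * 100, 1):.1f}"
        return out

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, default=float)


def _ratio(num: float, den: float, name: str, flags: list) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def binary_metrics(counts: ConfusionCounts) -> EvaluationReport:
    """Standard binary metrics from a confusion-count quadruple."""
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    flags: list[str] = []
    p = _ratio(counts.tp, counts.tp + counts.fp, "precision", flags)
    r = _ratio(counts.tp, counts.tp + counts.fn, "recall", flags)
    f1 = _ratio(2 * p * r, p + r, "f1", flags)
    acc = (counts.tp + counts.tn) / counts.total
    spec = _ratio(counts.tn, counts.tn + counts.fp, "specificity", flags)
    fpr = _ratio(counts.fp, counts.fp + counts.tn, "fpr", flags)
    return EvaluationReport(counts=counts, precision=p, recall=r, f1=f1,
                            accuracy=acc, specificity=spec, fpr=fpr,
                            undefined=flags)


def confusion_from_predictions(y_true: Sequence, y_pred: Sequence,
                               classes: Sequence | None = None) -> np.ndarray:
    """C x C confusion matrix; rows are truth, columns predictions."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    c = len(classes)
    out = np.zeros((c, c), dtype=int)
    ti = np.searchsorted(classes, y_true)
    pi = np.searchsorted(classes, y_pred)
    np.add.at(out, (ti, pi), 1)
    return out


def multiclass_metrics(matrix: np.ndarray,
                       averaging: str = "weighted") -> EvaluationReport:
    """One-vs-rest per-class precision/recall/F1 plus a macro or weighted
    average from a C x C confusion matrix (rows = truth)."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if averaging not in ("macro", "weighted"):
        raise ValueError("averaging must be 'macro' or 'weighted'")
    c = m.shape[0]
    flags: list[str] = []
    per_class: dict[int, dict[str, float]] = {}
    ps, rs, f1s = [], [], []
    support = m.sum(axis=1)
    for i in range(c):
        tp = m[i, i]
        p = _ratio(tp, m[:, i].sum(), f"precision[{i}]", flags)
        r = _ratio(tp, support[i], f"recall[{i}]", flags)
        f1 = _ratio(2 * p * r, p + r, f"f1[{i}]", flags)
        per_class[i] = {"precision": p, "recall": r, "f1": f1,
                        "support": int(support[i])}
        ps.append(p)
        rs.append(r)
        f1s.append(f1)
    if averaging == "macro":
        w = np.full(c, 1 / c)
    else:
        w = support / support.sum() if support.sum() else np.full(c, 1 / c)
    avg_p, avg_r, avg_f1 = (float(np.dot(w, v)) for v in (ps, rs, f1s))
    acc = float(np.trace(m) / m.sum()) if m.sum() else 0.0
    return EvaluationReport(matrix=m.tolist(), precision=avg_p, recall=avg_r,
                            f1=avg_f1, accuracy=acc, per_class=per_class,
                            averaging=averaging, undefined=flags)


def roc_prc(scores: Sequence[float], truth: Sequence[int]
            ) -> EvaluationReport:
    """ROC and precision-recall curves by a sweep over unique scores.

    AUC is trapezoidal over (FPR, TPR); auPRC is the step-wise sum
    sum((R_i - R_{i-1}) * P_i) over increasing recall.  Raises when the
    truth contains a single class (AUC undefined).
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=int)
    if s.shape != t.shape or s.ndim != 1:
        raise ValueError("scores and truth must be aligned 1-D arrays")
    n_pos = int(t.sum())
    n_neg = len(t) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined for single-class truth")
    order = np.argsort(-s, kind="stable")
    s, t = s[order], t[order]
    # cumulative counts at each distinct-score cut (predict positive if
    # score >= threshold)
    distinct = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], int)
    cuts = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(t)[cuts]
    fp = (cuts + 1) - tp
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    recall = tp / n_pos
    precision = tp / (tp + fp)
    auprc = float(np.sum(np.diff(np.concatenate([[0.0], recall])) * precision))
    roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    prc_points = list(zip(recall.tolist(), precision.tolist()))
    return EvaluationReport(auc=auc, auprc=auprc, roc_points=roc_points,
                            prc_points=prc_points)
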