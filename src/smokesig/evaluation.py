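"""ROC/AUC, thresholded confusion summaries, multiclass metrics, calibration
bins, and the three-way questionnaire/cotinine/methylation concordance
partition.

AUC is the Mann-Whitney probability that a random positive outscores a
random negative, with ties credited 1/2 (computed via scikit-learn).
Positive calls use a strictly-greater-than threshold.  Accuracy confidence
intervals are exact Clopper-Pearson binomial intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ClassificationReport",
    "ConcordancePartition",
    "roc_auc",
    "confusion_at",
    "multiclass_report",
    "calibration_bins",
    "concordance_partition",
]


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; errors when only one class is present."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC is undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion summary at a probability threshold.

    Sensitivity or specificity is NaN (with a flag) when its denominator is
    empty; ``auc`` is None when it was not computable or not requested.
    """

    threshold: float | None
    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    auc: float | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n": self.n,
            "accuracy": self.accuracy,
            "accuracy_ci_low": self.accuracy_ci[0],
            "accuracy_ci_high": self.accuracy_ci[1],
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def confusion_at(
    probs,
    labels,
    threshold: float = 0.5,
    with_auc: bool = True,
) -> ClassificationReport:
    """Confusion matrix at ``prob > threshold`` with an exact accuracy CI."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.size == 0:
        raise ValueError("empty input")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    calls = probs > threshold
    pos = labels == 1
    tp = int(np.sum(calls & pos))
    fp = int(np.sum(calls & ~pos))
    fn = int(np.sum(~calls & pos))
    tn = int(np.sum(~calls & ~pos))
    n = len(labels)
    correct = tp + tn
    accuracy = correct / n
    lo, hi = proportion_confint(correct, n, alpha=0.05, method="beta")
    flags: list[str] = []
    if tp + fn > 0:
        sens = tp / (tp + fn)
    else:
        sens, flags = math.nan, flags + ["sensitivity_undefined"]
    if tn + fp > 0:
        spec = tn / (tn + fp)
    else:
        spec, flags = math.nan, flags + ["specificity_undefined"]
    auc = None
    if with_auc and len(np.unique(labels)) == 2:
        auc = roc_auc(probs, labels)
    return ClassificationReport(
        threshold=threshold,
        n=n,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=accuracy,
        accuracy_ci=(float(lo), float(hi)),
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        flags=tuple(flags),
    )


def multiclass_report(
    prob_matrix: pd.DataFrame,
    labels,
) -> dict[str, ClassificationReport]:
    """Per-category one-vs-rest reports from argmax predictions.

    Sensitivity and specificity come from the argmax confusion matrix; the
    per-category AUC uses that category's probability column one-vs-rest.
    """
    probs = prob_matrix.to_numpy(float)
    row_sums = probs.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-8):
        raise ValueError("probability rows must sum to 1")
    labels = np.asarray([str(v) for v in np.asarray(labels)])
    cats = [str(c) for c in prob_matrix.columns]
    missing = set(labels) - set(cats)
    if missing:
        raise ValueError(f"labels not among probability columns: {sorted(missing)}")
    pred = np.asarray(cats)[np.argmax(probs, axis=1)]
    out: dict[str, ClassificationReport] = {}
    for j, cat in enumerate(cats):
        y = (labels == cat).astype(int)
        call = pred == cat
        tp = int(np.sum(call & (y == 1)))
        fp = int(np.sum(call & (y == 0)))
        fn = int(np.sum(~call & (y == 1)))
        tn = int(np.sum(~call & (y == 0)))
        n = len(y)
        correct = tp + tn
        lo, hi = proportion_confint(correct, n, alpha=0.05, method="beta")
        flags: list[str] = []
        sens = tp / (tp + fn) if tp + fn else math.nan
        spec = tn / (tn + fp) if tn + fp else math.nan
        if math.isnan(sens):
            flags.append("sensitivity_undefined")
        auc = roc_auc(probs[:, j], y) if len(np.unique(y)) == 2 else None
        out[cat] = ClassificationReport(
            threshold=None,
            n=n,
            tp=tp,
            fp=fp,
            tn=tn,
            fn=fn,
            accuracy=correct / n,
            accuracy_ci=(float(lo), float(hi)),
            sensitivity=sens,
            specificity=spec,
            auc=auc,
            flags=tuple(flags),
        )
    return out


def calibration_bins(probs, labels, n_bins: int = 10) -> pd.DataFrame:
    """Equal-width probability bins with the accuracy of the 0.5-threshold call.

    Returns a DataFrame with bin bounds, the sample count per bin, and the
    fraction of samples whose ``prob > 0.5`` call matches the label (NaN for
    empty bins).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(probs, edges[1:-1], right=False), 0, n_bins - 1)
    correct = (probs > 0.5).astype(int) == labels
    rows = []
    for b in range(n_bins):
        mask = idx == b
        count = int(mask.sum())
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "count": count,
                "accuracy": float(correct[mask].mean()) if count else math.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConcordancePartition:
    """The 8-cell questionnaire x cotinine x methylation agreement partition.

    ``cells`` maps ``(questionnaire, cotinine, cpg)`` binary triples (1 =
    called smoker) to participant counts.
    """

    cells: dict[tuple[int, int, int], int]

    @property
    def n(self) -> int:
        return sum(self.cells.values())

    def margin(self, method: str) -> int:
        """Number of smoker calls by one method ('questionnaire'|'cotinine'|'cpg')."""
        k = {"questionnaire": 0, "cotinine": 1, "cpg": 2}[method]
        return sum(c for key, c in self.cells.items() if key[k] == 1)

    def vs_questionnaire(self, method: str) -> tuple[float, float]:
        """(sensitivity, specificity) of cotinine or the CpG model against
        self-report."""
        k = {"cotinine": 1, "cpg": 2}[method]
        tp = sum(c for key, c in self.cells.items() if key[0] == 1 and key[k] == 1)
        fn = sum(c for key, c in self.cells.items() if key[0] == 1 and key[k] == 0)
        tn = sum(c for key, c in self.cells.items() if key[0] == 0 and key[k] == 0)
        fp = sum(c for key, c in self.cells.items() if key[0] == 0 and key[k] == 1)
        return tp / (tp + fn), tn / (tn + fp)

    def smoker_overlap(self, of: str) -> float:
        """Among one method's correctly-called smokers, the fraction the other
        method also called smokers.

        ``of="cpg"``: of the CpG-correct smokers, fraction also cotinine-called.
        ``of="cotinine"``: of the cotinine-correct smokers, fraction also
        CpG-called.
        """
        both = self.cells.get((1, 1, 1), 0)
        if of == "cpg":
            denom = both + self.cells.get((1, 0, 1), 0)
        elif of == "cotinine":
            denom = both + self.cells.get((1, 1, 0), 0)
        else:
            raise ValueError("of must be 'cpg' or 'cotinine'")
        return both / denom

    def nonsmoker_overlap(self, of: str) -> float:
        """Same as :meth:`smoker_overlap` for correctly-called non-smokers."""
        both = self.cells.get((0, 0, 0), 0)
        if of == "cpg":
            denom = both + self.cells.get((0, 1, 0), 0)
        elif of == "cotinine":
            denom = both + self.cells.get((0, 0, 1), 0)
        else:
            raise ValueError("of must be 'cpg' or 'cotinine'")
        return both / denom

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"questionnaire": q, "cotinine": c, "cpg_model": m, "count": v}
            for (q, c, m), v in sorted(self.cells.items(), reverse=True)
        ]
        return pd.DataFrame(rows)


def concordance_partition(
    questionnaire_calls,
    cotinine_calls,
    cpg_calls,
) -> ConcordancePartition:
    """Cross-tabulate three equal-length binary call vectors into 8 cells."""
    q = np.asarray(questionnaire_calls, dtype=int)
    c = np.asarray(cotinine_calls, dtype=int)
    m = np.asarray(cpg_calls, dtype=int)
    if not (len(q) == len(c) == len(m)):
        raise ValueError("call vectors must have equal length")
    cells = {
        (a, b, d): int(np.sum((q == a) & (c == b) & (m == d)))
        for a in (0, 1)
        for b in (0, 1)
        for d in (0, 1)
    }
    return ConcordancePartition(cells)
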