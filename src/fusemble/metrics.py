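"""One-vs-rest multiclass metrics, macro averaging, confidence intervals, ROC/AUC.

Each class is evaluated one-vs-rest from its TP/FP/FN/TN counts; macro values
are unweighted means over classes.  ``accuracy`` in all reports is *overall*
accuracy (trace of the confusion matrix over N); the mean of per-class
one-vs-rest accuracies is exposed separately as ``macro.class_accuracy``
because the two differ whenever C > 2 (see docs/methods.md).

Undefined ratios (0/0, e.g. precision with no positive predictions) are
carried as NaN — an explicit undefined marker, never silently zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .data import ClassCounts

__all__ = [
    "ClassMetrics",
    "MetricReport",
    "class_metrics",
    "macro_report",
    "proportion_ci",
    "macro_ci",
    "ovr_roc_auc",
    "macro_auc",
]

MACRO_FIELDS = ("precision", "sensitivity", "specificity", "f1", "class_accuracy")


def _ratio(num: float, den: float) -> float:
    """num/den with 0/0 -> NaN (the undefined marker)."""
    return num / den if den > 0 else math.nan


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics for a single class."""

    precision: float
    sensitivity: float
    specificity: float
    f1: float
    class_accuracy: float
    counts: ClassCounts

    @property
    def defined(self) -> bool:
        return not any(
            math.isnan(getattr(self, f)) for f in MACRO_FIELDS
        )


def class_metrics(c: ClassCounts) -> ClassMetrics:
    """Precision, sensitivity (recall), specificity, F1 and one-vs-rest
    accuracy from a single class's counts."""
    precision = _ratio(c.tp, c.tp + c.fp)
    sensitivity = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.tn + c.fp)
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = math.nan if (math.isnan(precision) or math.isnan(sensitivity)) else 0.0
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    class_accuracy = _ratio(c.tp + c.tn, c.n)
    return ClassMetrics(precision, sensitivity, specificity, f1, class_accuracy, c)


def proportion_ci(successes: int, n: int, method: str = "wilson", level: float = 0.95):
    """Two-sided binomial CI for a proportion, clipped to [0, 1].

    ``wilson`` is the score interval (the standard reading of the Newcombe
    method for a single proportion); ``wald`` is the normal approximation
    p ± z·sqrt(p(1-p)/n).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    sm_method = {"wilson": "wilson", "wald": "normal"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    low, high = proportion_confint(successes, n, alpha=1 - level, method=sm_method)
    # boundary counts pin the corresponding bound exactly
    if successes == 0:
        low = 0.0
    if successes == n:
        high = 1.0
    return (float(np.clip(low, 0, 1)), float(np.clip(high, 0, 1)))


def macro_ci(intervals: Sequence[tuple]) -> tuple:
    """Macro-average of per-class intervals: mean of lower bounds and mean of
    upper bounds, computed on unrounded per-class bounds."""
    lows, highs = zip(*intervals)
    return (float(np.mean(lows)), float(np.mean(highs)))


@dataclass
class MetricReport:
    """Per-class and macro-averaged one-vs-rest metrics for one classifier.

    ``macro[x]`` is the unweighted mean of per-class ``x``;
    ``overall_accuracy`` is sum(tp)/N.  When CIs were requested, ``cis`` maps
    ``(scope, metric)`` — scope a class name or ``"macro"``/``"overall"`` —
    to ``(low, high)``.
    """

    per_class: Mapping[str, ClassMetrics]
    macro: Mapping[str, float]
    overall_accuracy: float
    n: int
    cis: dict = field(default_factory=dict)
    auc: dict = field(default_factory=dict)

    def summary(self, digits: int = 3) -> pd.DataFrame:
        rows = []
        for name, m in self.per_class.items():
            rows.append(
                {
                    "class": name,
                    "precision": m.precision,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "f1": m.f1,
                    "class_accuracy": m.class_accuracy,
                    "auc": self.auc.get(name, math.nan),
                }
            )
        rows.append(
            {
                "class": "macro",
                "precision": self.macro["precision"],
                "sensitivity": self.macro["sensitivity"],
                "specificity": self.macro["specificity"],
                "f1": self.macro["f1"],
                "class_accuracy": self.overall_accuracy,
                "auc": self.auc.get("macro", math.nan),
            }
        )
        return pd.DataFrame(rows).round(digits)

    def to_json(self, path=None) -> str:
        payload = {
            "overall_accuracy": self.overall_accuracy,
            "n": self.n,
            "macro": dict(self.macro),
            "per_class": {
                k: {f: getattr(m, f) for f in MACRO_FIELDS} for k, m in self.per_class.items()
            },
            "cis": {f"{s}/{metric}": list(v) for (s, metric), v in self.cis.items()},
            "auc": dict(self.auc),
        }
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def macro_report(
    counts: Mapping[str, ClassCounts],
    ci: str = None,
    level: float = 0.95,
    undefined: str = "propagate",
) -> MetricReport:
    """Macro-averaged metric report from per-class one-vs-rest counts.

    Parameters
    ----------
    counts : mapping class name -> ClassCounts, covering every class.
    ci : None, "wilson" or "wald" — also compute 95% (or ``level``) CIs for
        each per-class proportion, their macro averages (mean of unrounded
        per-class bounds), and overall accuracy.
    undefined : "propagate" (NaN per-class metrics make the macro NaN) or
        "omit" (macro averages over the defined classes only).
    """
    if undefined not in ("propagate", "omit"):
        raise ValueError("undefined policy must be 'propagate' or 'omit'")
    per_class = {name: class_metrics(c) for name, c in counts.items()}
    ns = {c.n for c in counts.values()}
    if len(ns) != 1:
        raise ValueError(f"inconsistent N across classes: {sorted(ns)}")
    n = ns.pop()
    total_tp = sum(c.tp for c in counts.values())

    macro = {}
    for f in MACRO_FIELDS:
        vals = np.array([getattr(m, f) for m in per_class.values()])
        if undefined == "omit":
            vals = vals[~np.isnan(vals)]
        macro[f] = float(np.mean(vals)) if len(vals) else math.nan

    report = MetricReport(
        per_class=per_class,
        macro=macro,
        overall_accuracy=total_tp / n,
        n=n,
    )

    if ci is not None:
        ci_specs = {
            "precision": lambda c: (c.tp, c.tp + c.fp),
            "sensitivity": lambda c: (c.tp, c.tp + c.fn),
            "specificity": lambda c: (c.tn, c.tn + c.fp),
        }
        for metric, spec in ci_specs.items():
            per = {}
            for name, c in counts.items():
                k, d = spec(c)
                if d > 0:
                    per[name] = proportion_ci(k, d, method=ci, level=level)
                    report.cis[(name, metric)] = per[name]
            if len(per) == len(counts):
                report.cis[("macro", metric)] = macro_ci(list(per.values()))
        report.cis[("overall", "accuracy")] = proportion_ci(total_tp, n, method=ci, level=level)
    return report


# ----------------------------------------------------------------------
# One-vs-rest ROC AUC
# ----------------------------------------------------------------------

def ovr_roc_auc(probs: np.ndarray, truth: np.ndarray, class_index: int) -> float:
    """One-vs-rest ROC AUC for one class, using that class's probability
    column as the score.  Equals the Mann–Whitney pair statistic with ties
    counted one half.  Returns NaN when the class has no positives or no
    negatives in ``truth``.
    """
    truth = np.asarray(truth)
    y = (truth == class_index).astype(int)
    if y.min() == y.max():
        return math.nan
    return float(roc_auc_score(y, np.asarray(probs, dtype=float)[:, class_index]))


def macro_auc(probs: np.ndarray, truth: np.ndarray) -> float:
    """Unweighted mean of per-class one-vs-rest AUCs (NaN classes propagate)."""
    c = np.asarray(probs).shape[1]
    return float(np.mean([ovr_roc_auc(probs, truth, i) for i in range(c)]))
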