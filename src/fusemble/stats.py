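"""Paired-classifier comparison (McNemar) and ensemble-diversity diagnostics.

McNemar's test compares two classifiers on the same items through their
discordant counts: chi2 = (n01 - n10)^2 / (n01 + n10) on 1 degree of freedom,
uncorrected by default.  Diversity is the pairwise Pearson correlation of the
integer-encoded predicted-label vectors; pairs at or above the redundancy
threshold (default 0.95) are flagged as adding little to an ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import contingency

from .data import PredictionSet, ValidationError

__all__ = ["McNemarResult", "DiversityMatrix", "mcnemar", "diversity", "cramers_v_matrix"]

REDUNDANCY_THRESHOLD = 0.95


@dataclass(frozen=True)
class McNemarResult:
    """Paired contingency of per-item correctness plus the chi-square test.

    n00: both correct; n01: classifier 1 only correct; n10: classifier 2 only
    correct; n11: both wrong.  ``degenerate`` marks n01 + n10 == 0, where the
    statistic is 0 and p = 1 by convention.
    """

    n00: int
    n01: int
    n10: int
    n11: int
    chi2: float
    p: float
    degenerate: bool = False
    corrected: bool = False

    @property
    def n(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p <= alpha


def mcnemar(truth, pred1, pred2, correction: bool = False) -> McNemarResult:
    """McNemar's test from per-item correctness of two classifiers.

    ``correction=True`` applies the continuity correction
    (|n01 - n10| - 1)^2 / (n01 + n10); the default is the plain statistic.
    """
    truth = np.asarray(truth)
    pred1 = np.asarray(pred1)
    pred2 = np.asarray(pred2)
    if not (truth.shape == pred1.shape == pred2.shape):
        raise ValidationError("truth, pred1, pred2 must have equal length")
    c1 = pred1 == truth
    c2 = pred2 == truth
    n00 = int(np.sum(c1 & c2))
    n01 = int(np.sum(c1 & ~c2))
    n10 = int(np.sum(~c1 & c2))
    n11 = int(np.sum(~c1 & ~c2))
    disc = n01 + n10
    if disc == 0:
        return McNemarResult(n00, n01, n10, n11, 0.0, 1.0, degenerate=True,
                             corrected=correction)
    num = (abs(n01 - n10) - 1) ** 2 if correction else (n01 - n10) ** 2
    num = max(num, 0)
    stat = num / disc
    p = float(_chi2.sf(stat, df=1))
    return McNemarResult(n00, n01, n10, n11, float(stat), p, corrected=correction)


@dataclass
class DiversityMatrix:
    """Pairwise Pearson correlations of predicted-label vectors.

    Symmetric with unit diagonal; a constant label vector yields NaN in its
    row/column (correlation undefined).  ``redundant_pairs`` lists pairs at or
    above the threshold.
    """

    corr: pd.DataFrame
    threshold: float = REDUNDANCY_THRESHOLD

    @property
    def classifiers(self) -> tuple:
        return tuple(self.corr.index)

    @property
    def redundant_pairs(self) -> tuple:
        out = []
        names = list(self.corr.index)
        for a, b in combinations(names, 2):
            v = self.corr.loc[a, b]
            if not math.isnan(v) and v >= self.threshold:
                out.append((a, b, float(v)))
        return tuple(out)

    def offdiagonal(self) -> np.ndarray:
        v = self.corr.to_numpy()
        return v[~np.eye(len(v), dtype=bool)]

    def to_lower_triangle_csv(self, path) -> None:
        """Lower-triangle layout (diagonal included, upper left blank)."""
        names = list(self.corr.index)
        m = self.corr.to_numpy()
        rows = []
        for i, name in enumerate(names):
            row = {"classifier": name}
            for j in range(i + 1):
                row[names[j]] = round(float(m[i, j]), 3)
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


def diversity(ps: PredictionSet, threshold: float = REDUNDANCY_THRESHOLD) -> DiversityMatrix:
    """Pearson correlation matrix of the members' predicted-label vectors.

    Labels are encoded as the registry's 0-based class indices — faithful to
    the common practice but encoding-sensitive; see :func:`cramers_v_matrix`
    for an encoding-free alternative.
    """
    if ps.m < 2:
        raise ValueError("diversity needs at least 2 classifiers")
    labels = ps.label_matrix().astype(float)  # (m, N)
    m = ps.m
    out = np.full((m, m), np.nan)
    sd = labels.std(axis=1)
    for i in range(m):
        out[i, i] = 1.0
        for j in range(i + 1, m):
            if sd[i] == 0 or sd[j] == 0:
                continue  # constant vector: correlation undefined
            out[i, j] = out[j, i] = float(np.corrcoef(labels[i], labels[j])[0, 1])
    corr = pd.DataFrame(out, index=list(ps.classifiers), columns=list(ps.classifiers))
    return DiversityMatrix(corr=corr, threshold=threshold)


def cramers_v_matrix(ps: PredictionSet) -> pd.DataFrame:
    """Cramér's V between members' predicted labels — an association measure
    that does not depend on how class labels are numbered."""
    labels = ps.label_matrix()
    m = ps.m
    out = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            table = pd.crosstab(labels[i], labels[j]).to_numpy()
            out[i, j] = out[j, i] = contingency.association(table, method="cramer")
    return pd.DataFrame(out, index=list(ps.classifiers), columns=list(ps.classifiers))
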