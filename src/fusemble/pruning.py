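"""Ranking-method ensemble pruning: order members by standalone accuracy and
sweep every fusion method over the top-k prefixes.

The sweep re-fits each ensemble from scratch at every k (weights re-optimized,
the stack re-fit), evaluates the full one-vs-rest metric suite, and reports
the best k per method alongside the top-1 single-classifier baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import PredictionSet, confusion
from .fusion import FusionModel, FusionResults, StackingConfig
from .metrics import macro_report

__all__ = ["Ranking", "SweepResult", "rank", "rank_from_counts", "sweep"]


@dataclass
class Ranking:
    """Classifiers ordered by standalone overall accuracy (descending)."""

    order: tuple
    accuracy: Mapping[str, float]
    macro_f1: Mapping[str, float]
    ties: tuple = ()

    def top(self, k: int) -> tuple:
        return self.order[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "classifier": list(self.order),
                "accuracy": [self.accuracy[c] for c in self.order],
                "macro_f1": [self.macro_f1[c] for c in self.order],
                "rank": np.arange(1, len(self.order) + 1),
            }
        )


def _standalone_report(ps: PredictionSet, clf: str):
    cm = confusion(ps.truth, ps.labels(clf), ps.registry)
    counts = {name: cm.ovr(i) for i, name in enumerate(ps.registry.names)}
    return macro_report(counts)


def _make_ranking(names, acc, f1) -> Ranking:
    # NaN macro F1 (degenerate member) sorts below any defined value
    def key(c):
        v = f1[c]
        return (-acc[c], -(v if v == v else float("-inf")), c)

    order = sorted(names, key=key)
    ties = tuple(f"{a}~{b}" for a, b in zip(order, order[1:]) if acc[a] == acc[b])
    return Ranking(order=tuple(order), accuracy=acc, macro_f1=f1, ties=ties)


def rank(ps: PredictionSet) -> Ranking:
    """Rank classifiers by overall accuracy, ties broken by macro F1 then id.

    Tie-broken pairs are logged in ``ties``.
    """
    acc, f1 = {}, {}
    for clf in ps.classifiers:
        rep = _standalone_report(ps, clf)
        acc[clf] = rep.overall_accuracy
        f1[clf] = rep.macro["f1"]
    return _make_ranking(ps.classifiers, acc, f1)


def rank_from_counts(tables) -> Ranking:
    """Rank classifiers from per-class one-vs-rest count tables
    (``{classifier: {class: ClassCounts}}``, e.g. a packaged fixture)."""
    acc, f1 = {}, {}
    for clf, counts in tables.items():
        rep = macro_report(dict(counts))
        acc[clf] = rep.overall_accuracy
        f1[clf] = rep.macro["f1"]
    return _make_ranking(list(tables), acc, f1)


@dataclass
class SweepResult:
    """Grid of fused ensembles over (method, k) with per-cell metrics.

    ``grid`` has one row per (method, k); ``best_k[method]`` is the smallest k
    attaining that method's maximum accuracy; ``baseline`` is the top-ranked
    single classifier and its accuracy.
    """

    grid: pd.DataFrame
    best_k: Mapping[str, int]
    ranking: Ranking
    baseline: tuple  # (classifier id, accuracy)
    results: dict = field(default_factory=dict)  # (method, k) -> FusionResults

    def best(self, method: str) -> FusionResults:
        return self.results[(method, self.best_k[method])]

    def summary(self, digits: int = 3) -> pd.DataFrame:
        rows = []
        for method, k in self.best_k.items():
            row = self.grid[(self.grid.method == method) & (self.grid.k == k)].iloc[0]
            rows.append(row)
        out = pd.DataFrame(rows).reset_index(drop=True)
        return out.round(digits)

    def to_csv(self, path) -> None:
        self.grid.to_csv(path, index=False, float_format="%.6g")

    def plot(self, ax=None):
        """Accuracy vs ensemble size per method, with 95% CI whiskers."""
        import matplotlib.pyplot as plt

        from .metrics import proportion_ci

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        n = int(self.grid["n"].iloc[0])
        for method, block in self.grid.groupby("method"):
            block = block.sort_values("k")
            lows, highs = [], []
            for a in block.accuracy:
                lo, hi = proportion_ci(int(round(a * n)), n, method="wilson")
                lows.append(a - lo)
                highs.append(hi - a)
            ax.errorbar(
                block.k, block.accuracy, yerr=[lows, highs], marker="o",
                capsize=2, label=method.upper(),
            )
        ax.axhline(self.baseline[1], color="grey", ls="--", lw=1,
                   label=f"top-1 ({self.baseline[0]})")
        ax.set_xlabel("ensemble size k (top-k by accuracy)")
        ax.set_ylabel("overall accuracy")
        ax.legend()
        return ax


def sweep(
    ps: PredictionSet,
    methods: Sequence[str] = ("sv", "wav", "whv", "stack"),
    k_range: Sequence[int] = None,
    seed: int = 0,
    budget: int = 200,
    paper_mode: bool = False,
    stacking: StackingConfig = None,
    keep_results: bool = True,
) -> SweepResult:
    """Prune-and-fuse sweep: for each method and each k in ``k_range``
    (default 2..m), fuse the top-k ranking prefix and evaluate.

    Weights are re-optimized and the stack re-fit at every k; all randomness
    derives from ``seed``.  The grid is complete — |methods| x |k_range| rows,
    none skipped.
    """
    if ps.m < 2:
        raise ValueError("sweep needs at least 2 classifiers")
    ranking = rank(ps)
    k_values = list(k_range) if k_range is not None else list(range(2, ps.m + 1))
    if any(k < 1 or k > ps.m for k in k_values):
        raise ValueError(f"k values must lie in 1..{ps.m}")

    rows = []
    results = {}
    for method in methods:
        for k in k_values:
            members = ranking.top(k)
            model = FusionModel(ps, method, members=members, stacking=stacking)
            res = model.fit(seed=seed, budget=budget, paper_mode=paper_mode)
            rep = res.metric_report(with_auc=res.fused_probs is not None)
            rows.append(
                {
                    "method": method,
                    "k": k,
                    "accuracy": res.accuracy,
                    "precision": rep.macro["precision"],
                    "sensitivity": rep.macro["sensitivity"],
                    "specificity": rep.macro["specificity"],
                    "f1": rep.macro["f1"],
                    "auc": rep.auc.get("macro", float("nan")),
                    "ties": res.result.tie_count,
                    "n": ps.n,
                    "members": "|".join(members),
                }
            )
            if keep_results:
                results[(method, k)] = res

    grid = pd.DataFrame(rows)
    best_k = {}
    for method in methods:
        block = grid[grid.method == method]
        best_acc = block.accuracy.max()
        best_k[method] = int(block[block.accuracy == best_acc].k.min())
    top1 = ranking.order[0]
    return SweepResult(
        grid=grid,
        best_k=best_k,
        ranking=ranking,
        baseline=(top1, ranking.accuracy[top1]),
        results=results,
    )
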