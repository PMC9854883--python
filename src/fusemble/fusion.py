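"""Classifier fusion: soft voting, weighted average voting, weighted hard
voting, and cross-validated stacking, plus voting-weight optimization.

The four methods share one container (:class:`PredictionSet`) and one result
type.  Soft voting (SV) averages member probability vectors; weighted average
voting (WAV) is the same operation with optimized non-uniform weights.  Hard
voting sums (weighted) member votes; stacking (ST) trains a meta-learner on
the concatenated member probabilities via stratified out-of-fold
cross-validation, so every fused prediction is out-of-fold.

A statsmodels-style front door is provided: ``FusionModel(ps, method).fit()``
returns a :class:`FusionResults` carrying fused labels/probabilities, the
fitted weights, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._bayesopt import maximize_on_unit_box
from .data import ClassCounts, PredictionSet, confusion
from .metrics import MetricReport, macro_auc, macro_report

__all__ = [
    "WeightVector",
    "StackingConfig",
    "FusionResult",
    "FusionModel",
    "FusionResults",
    "ProbabilityError",
    "StratificationError",
    "soft_vote",
    "hard_vote",
    "optimize_weights",
    "stack",
]


class ProbabilityError(ValueError):
    """A probability-dependent operation was given a hard-label-only member."""


class StratificationError(ValueError):
    """Stratified folds cannot be formed (some class rarer than the fold count)."""


@dataclass(frozen=True)
class WeightVector:
    """Non-negative voting weights, one per member, stored normalized to sum 1.

    Argmax decisions are invariant to positive rescaling, so normalization
    loses nothing; ``provenance`` records how the weights arose (``uniform``,
    ``user``, or an ``optimized`` record with objective/budget/seed).
    """

    weights: np.ndarray
    provenance: object = "user"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1:
            raise ValueError("weights must be a 1-D vector")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("at least one weight must be positive")
        object.__setattr__(self, "weights", w / total)

    @classmethod
    def uniform(cls, m: int) -> "WeightVector":
        return cls(np.full(m, 1.0 / m), provenance="uniform")

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class StackingConfig:
    """Configuration of the stacking meta-learner.

    folds : outer stratified CV folds producing out-of-fold predictions.
    meta_learner : ``"gbdt"`` (LightGBM, multiclass log-loss with early
        stopping) or ``"logistic"`` (multinomial logistic regression — fast,
        deterministic fallback).
    num_boost_round / early_stopping : boosting-round cap and patience.
    search_trials : budget of the seeded random hyperparameter search, run
        within each training split only (0 = library defaults, no search).
    """

    folds: int = 5
    meta_learner: str = "gbdt"
    num_boost_round: int = 1000
    early_stopping: int = 50
    search_trials: int = 50

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.num_boost_round < 1 or self.early_stopping < 1:
            raise ValueError("boosting caps must be positive")
        if self.meta_learner not in ("gbdt", "logistic"):
            raise ValueError(f"unknown meta_learner {self.meta_learner!r}")


@dataclass
class FusionResult:
    """Raw output of one fusion: labels, probabilities (soft methods only),
    members, weights, and the tie events logged by hard voting."""

    fused_labels: np.ndarray
    method: str
    members: tuple
    fused_probs: Optional[np.ndarray] = None
    weights: Optional[WeightVector] = None
    tie_items: tuple = ()

    @property
    def tie_count(self) -> int:
        return len(self.tie_items)


def _resolve(ps: PredictionSet, members) -> tuple:
    members = tuple(ps.classifiers) if members is None else tuple(str(c) for c in members)
    if len(members) == 0:
        raise ValueError("member list is empty")
    return members


def soft_vote(
    ps: PredictionSet,
    members: Sequence[str] = None,
    weights: WeightVector = None,
) -> FusionResult:
    """Weighted average of member probability vectors; label = argmax.

    With uniform weights this is soft voting (SV); with non-uniform weights it
    is weighted average voting (WAV) — the same operation, different weights.
    """
    members = _resolve(ps, members)
    sub = ps.subset(members)
    if sub.prob_free.any():
        bad = [c for c, pf in zip(members, sub.prob_free) if pf]
        raise ProbabilityError(f"soft voting needs probabilities; label-only members: {bad}")
    if weights is None:
        weights = WeightVector.uniform(len(members))
    if len(weights) != len(members):
        raise ValueError("one weight per member required")
    fused = np.tensordot(weights.weights, sub.probs, axes=(0, 0))
    fused = fused / fused.sum(axis=1, keepdims=True)
    method = "sv" if isinstance(weights.provenance, str) and weights.provenance == "uniform" else "wav"
    return FusionResult(
        fused_labels=np.argmax(fused, axis=1),
        fused_probs=fused,
        method=method,
        members=members,
        weights=weights,
    )


def hard_vote(
    ps: PredictionSet,
    members: Sequence[str] = None,
    weights: WeightVector = None,
    tie_rule: str = "rank",
) -> FusionResult:
    """Weighted majority vote over member hard labels.

    Per item, each class scores the summed weight of the members voting for
    it; the fused label is the argmax.  Exact ties are resolved by
    ``tie_rule`` and logged:

    - ``"rank"`` (default): the class predicted by the highest-ranked member
      (earliest in ``members``) among those voting for a tied class; if no
      member supports any tied class (possible with zero weights), the lowest
      class index.
    - ``"lowest"``: the lowest tied class index.
    """
    members = _resolve(ps, members)
    sub = ps.subset(members)
    if weights is None:
        weights = WeightVector.uniform(len(members))
    if len(weights) != len(members):
        raise ValueError("one weight per member required")
    if tie_rule not in ("rank", "lowest"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")

    votes = sub.label_matrix()  # (m, N)
    n, c = sub.n, sub.n_classes
    scores = np.zeros((n, c))
    for j in range(len(members)):
        np.add.at(scores, (np.arange(n), votes[j]), weights.weights[j])

    top = scores.max(axis=1)
    # exact ties only: weight sums of tied classes are identical floats
    tied_mask = (scores == top[:, None]).sum(axis=1) > 1
    labels = np.argmax(scores, axis=1)
    tie_items = tuple(int(i) for i in np.flatnonzero(tied_mask))
    if tie_rule == "rank":
        for i in tie_items:
            tied_classes = set(np.flatnonzero(scores[i] == top[i]).tolist())
            for j in range(len(members)):
                if votes[j, i] in tied_classes:
                    labels[i] = votes[j, i]
                    break
            else:
                labels[i] = min(tied_classes)
    else:
        for i in tie_items:
            labels[i] = int(np.flatnonzero(scores[i] == top[i])[0])

    return FusionResult(
        fused_labels=labels,
        method="hv" if weights.provenance == "uniform" else "whv",
        members=members,
        weights=weights,
        tie_items=tie_items,
    )


def optimize_weights(
    ps: PredictionSet,
    members: Sequence[str] = None,
    method: str = "sv",
    items: np.ndarray = None,
    budget: int = 200,
    seed: int = 0,
    tie_rule: str = "rank",
) -> WeightVector:
    """Sequential model-based (Bayesian) search for voting weights.

    The objective is the overall accuracy of the corresponding fusion
    (``method="sv"`` for weighted average voting, ``"hv"`` for weighted hard
    voting) on ``items`` (default: all items of ``ps``).  The search space is
    the unit box [0, 1]^m with post-hoc normalization; the uniform vector is
    always evaluated first, so the returned weights never score below uniform
    on the objective set.  Deterministic under a fixed seed.
    """
    members = _resolve(ps, members)
    if method not in ("sv", "hv"):
        raise ValueError("objective method must be 'sv' or 'hv'")
    target = ps if items is None else ps.take_items(items)
    if target.n == 0:
        raise ValueError("objective item set is empty")
    sub = target.subset(members)

    fuse = soft_vote if method == "sv" else hard_vote
    kwargs = {} if method == "sv" else {"tie_rule": tie_rule}

    def objective(w: np.ndarray) -> float:
        res = fuse(sub, weights=WeightVector(np.maximum(w, 0) + 1e-12), **kwargs)
        return float(np.mean(res.fused_labels == sub.truth))

    opt = maximize_on_unit_box(
        objective,
        dim=len(members),
        budget=budget,
        seed=seed,
        first_point=np.full(len(members), 0.5),  # == uniform after normalization
    )
    return WeightVector(
        np.maximum(opt.x, 0) + 1e-12,
        provenance={
            "kind": "optimized",
            "objective": method,
            "budget": budget,
            "seed": seed,
            "n_evals": opt.n_evals,
            "objective_value": opt.value,
            "n_objective_items": int(target.n),
        },
    )


# ----------------------------------------------------------------------
# Stacking
# ----------------------------------------------------------------------

def _sample_gbdt_params(rng: np.random.Generator) -> dict:
    return {
        "num_leaves": int(rng.integers(8, 64)),
        "learning_rate": float(10 ** rng.uniform(-2, -0.5)),
        "min_child_samples": int(rng.integers(5, 50)),
        "colsample_bytree": float(rng.uniform(0.6, 1.0)),
        "reg_lambda": float(10 ** rng.uniform(-3, 1)),
    }


def _fit_gbdt(X_tr, y_tr, X_val, y_val, cfg: StackingConfig, params: dict, seed: int):
    import lightgbm as lgb

    model = lgb.LGBMClassifier(
        objective="multiclass",
        n_estimators=cfg.num_boost_round,
        random_state=seed,
        n_jobs=1,
        verbose=-1,
        **params,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(
            X_tr,
            y_tr,
            eval_set=[(X_val, y_val)],
            eval_metric="multi_logloss",
            callbacks=[
                lgb.early_stopping(cfg.early_stopping, verbose=False),
                lgb.log_evaluation(0),
            ],
        )
        proba = model.predict_proba(X_val)
    return model, float(log_loss(y_val, proba, labels=np.unique(y_tr)))


def _fit_meta(X_tr, y_tr, cfg: StackingConfig, seed: int):
    """Fit the meta-learner on one training split, tuning inside it only."""
    if cfg.meta_learner == "logistic":
        model = LogisticRegression(max_iter=2000)
        model.fit(X_tr, y_tr)
        return model
    # inner stratified split for early stopping + hyperparameter scoring
    idx_tr, idx_val = train_test_split(
        np.arange(len(y_tr)), test_size=0.2, stratify=y_tr, random_state=seed
    )
    Xi, yi, Xv, yv = X_tr[idx_tr], y_tr[idx_tr], X_tr[idx_val], y_tr[idx_val]
    rng = np.random.default_rng(seed)
    best_model, best_loss = None, np.inf
    for _ in range(max(1, cfg.search_trials)):
        params = _sample_gbdt_params(rng) if cfg.search_trials > 0 else {}
        model, loss = _fit_gbdt(Xi, yi, Xv, yv, cfg, params, seed)
        if loss < best_loss:
            best_model, best_loss = model, loss
    return best_model


def stack(
    ps: PredictionSet,
    members: Sequence[str] = None,
    config: StackingConfig = None,
    seed: int = 0,
) -> FusionResult:
    """Stacking: a meta-learner over member probabilities, fit out-of-fold.

    Meta-features per item are the concatenated member probability vectors
    (m·C columns).  A stratified k-fold scheme trains the meta-learner on
    k−1 folds and predicts the held-out fold, so every fused probability is
    out-of-fold; hyperparameter tuning happens within each training split.
    """
    config = config or StackingConfig()
    members = _resolve(ps, members)
    sub = ps.subset(members)
    if sub.prob_free.any():
        bad = [c for c, pf in zip(members, sub.prob_free) if pf]
        raise ProbabilityError(f"stacking needs probabilities; label-only members: {bad}")
    if sub.n < config.folds:
        raise StratificationError(f"N={sub.n} < folds={config.folds}")
    counts = np.bincount(sub.truth, minlength=sub.n_classes)
    if counts.min() < config.folds:
        raise StratificationError(
            f"class support {counts.min()} < folds={config.folds}; use fewer folds"
        )

    X = sub.probs.transpose(1, 0, 2).reshape(sub.n, -1)
    y = sub.truth
    oof = np.zeros((sub.n, sub.n_classes))
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = _fit_meta(X[tr], y[tr], config, seed=seed * 1000 + fold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            proba = model.predict_proba(X[te])
        # meta-learner class order follows the labels it saw in training
        classes = np.asarray(model.classes_, dtype=int)
        full = np.zeros((len(te), sub.n_classes))
        full[:, classes] = proba
        oof[te] = full
    oof = oof / oof.sum(axis=1, keepdims=True)
    return FusionResult(
        fused_labels=np.argmax(oof, axis=1),
        fused_probs=oof,
        method="stack",
        members=members,
    )


# ----------------------------------------------------------------------
# Model / Results front door
# ----------------------------------------------------------------------

_METHODS = ("sv", "wav", "hv", "whv", "stack")


class FusionModel:
    """A fusion method bound to a prediction set, fit like a statistical model.

    Parameters
    ----------
    ps : the prediction set (members' probabilities + ground truth).
    method : "sv", "wav", "hv", "whv" or "stack".
    members : classifier subset (default: all, in registry order).
    weights : fixed user weights for wav/whv; when omitted those methods
        optimize weights during :meth:`fit`.
    stacking : StackingConfig for method="stack".
    tie_rule : hard-voting tie resolution (see :func:`hard_vote`).

    Examples
    --------
    >>> res = FusionModel(ps, "wav").fit(seed=7, budget=200)
    >>> res.accuracy, res.weights.weights
    """

    def __init__(
        self,
        ps: PredictionSet,
        method: str,
        members: Sequence[str] = None,
        weights: WeightVector = None,
        stacking: StackingConfig = None,
        tie_rule: str = "rank",
    ):
        if method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        self.ps = ps
        self.method = method
        self.members = _resolve(ps, members)
        self.weights = weights
        self.stacking = stacking or StackingConfig()
        self.tie_rule = tie_rule

    def _objective_items(self, seed: int, paper_mode: bool, objective_items):
        if objective_items is not None:
            return np.asarray(objective_items, dtype=int)
        if paper_mode:
            return None  # optimize on the full evaluation set, as the study did
        idx, _ = train_test_split(
            np.arange(self.ps.n),
            train_size=0.5,
            stratify=self.ps.truth,
            random_state=seed,
        )
        return np.sort(idx)

    def fit(
        self,
        seed: int = 0,
        budget: int = 200,
        paper_mode: bool = False,
        objective_items: np.ndarray = None,
    ) -> "FusionResults":
        """Fit weights / meta-learner as the method requires and fuse.

        For "wav"/"whv" without user weights, voting weights are optimized by
        seeded Bayesian search with the given evaluation ``budget``; the
        objective set is a stratified half split by default, the full set
        when ``paper_mode=True`` (mirroring optimization on the reported
        evaluation set itself) or an explicit ``objective_items`` index array.
        "sv"/"hv" need no fitting; "stack" fits the configured meta-learner
        out-of-fold.
        """
        method = self.method
        if method == "sv":
            result = soft_vote(self.ps, self.members)
        elif method == "hv":
            result = hard_vote(self.ps, self.members, tie_rule=self.tie_rule)
        elif method in ("wav", "whv"):
            w = self.weights
            if w is None:
                items = self._objective_items(seed, paper_mode, objective_items)
                w = optimize_weights(
                    self.ps,
                    self.members,
                    method="sv" if method == "wav" else "hv",
                    items=items,
                    budget=budget,
                    seed=seed,
                    tie_rule=self.tie_rule,
                )
            if method == "wav":
                result = soft_vote(self.ps, self.members, weights=w)
            else:
                result = hard_vote(self.ps, self.members, weights=w, tie_rule=self.tie_rule)
            result = replace(result, method=method)
        else:
            result = stack(self.ps, self.members, config=self.stacking, seed=seed)
        return FusionResults(self, result, seed=seed)


class FusionResults:
    """Results of a fitted fusion: labels, probabilities, weights, metrics."""

    def __init__(self, model: FusionModel, result: FusionResult, seed: int):
        self.model = model
        self.result = result
        self.seed = seed

    # -- pass-throughs ---------------------------------------------------
    @property
    def fused_labels(self) -> np.ndarray:
        return self.result.fused_labels

    @property
    def fused_probs(self):
        return self.result.fused_probs

    @property
    def weights(self):
        return self.result.weights

    @property
    def tie_events(self) -> tuple:
        return self.result.tie_items

    # -- evaluation ------------------------------------------------------
    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fused_labels == self.model.ps.truth))

    def confusion(self):
        return confusion(self.model.ps.truth, self.fused_labels, self.model.ps.registry)

    def metric_report(self, ci: str = None, with_auc: bool = False) -> MetricReport:
        cm = self.confusion()
        counts = {
            name: cm.ovr(i) for i, name in enumerate(self.model.ps.registry.names)
        }
        report = macro_report(counts, ci=ci)
        if with_auc and self.fused_probs is not None:
            from .metrics import ovr_roc_auc

            truth = self.model.ps.truth
            for i, name in enumerate(self.model.ps.registry.names):
                report.auc[name] = ovr_roc_auc(self.fused_probs, truth, i)
            report.auc["macro"] = macro_auc(self.fused_probs, truth)
        return report

    def summary(self, digits: int = 3) -> str:
        rep = self.metric_report()
        lines = [
            f"Fusion method: {self.result.method.upper()}  "
            f"(k={len(self.result.members)} members, N={self.model.ps.n})",
            f"Members: {', '.join(self.result.members)}",
            f"Overall accuracy: {self.accuracy:.{digits}f}",
            f"Macro precision/sensitivity/specificity/F1: "
            f"{rep.macro['precision']:.{digits}f} / {rep.macro['sensitivity']:.{digits}f} / "
            f"{rep.macro['specificity']:.{digits}f} / {rep.macro['f1']:.{digits}f}",
        ]
        if self.weights is not None:
            w = ", ".join(f"{c}={v:.{digits}f}" for c, v in zip(self.result.members, self.weights.weights))
            lines.append(f"Weights: {w}")
        if self.result.method in ("hv", "whv"):
            lines.append(f"Tie events: {self.result.tie_count}")
        return "\n".join(lines)

    def to_prediction_set(self, name: str = None) -> PredictionSet:
        """Wrap the fused output as a one-classifier PredictionSet so it can
        feed back into metrics, diversity, or further fusion."""
        name = name or f"{self.result.method}{len(self.result.members)}"
        ps = self.model.ps
        if self.fused_probs is not None:
            return PredictionSet(
                classifiers=(name,),
                probs=self.fused_probs[None],
                truth=ps.truth,
                registry=ps.registry,
                item_ids=ps.item_ids,
            )
        return PredictionSet.from_labels(
            (name,), self.fused_labels, ps.truth, ps.registry, item_ids=ps.item_ids
        )
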