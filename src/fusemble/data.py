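"""Domain types, validation, and delimited-text I/O for multiclass prediction sets.

A *prediction set* bundles the outputs of ``m`` base classifiers on the same
``N`` items: per classifier an ``N x C`` row-stochastic matrix of class
probabilities (hard-label-only classifiers are stored one-hot and flagged),
plus the ground-truth label of every item and a fixed, ordered class registry.
Everything downstream — fusion, pruning, metrics, diversity — consumes this
container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ClassRegistry",
    "PredictionSet",
    "ClassCounts",
    "ConfusionMatrix",
    "ValidationError",
    "AlignmentError",
    "RegistryError",
    "confusion",
    "ovr_counts",
    "read_prediction_set",
    "write_prediction_set",
]

#: probability rows whose sum deviates from 1 by at most this are renormalized
ROW_SUM_RENORM_TOL = 1e-3
#: rows must sum to 1 within this after renormalization
ROW_SUM_STRICT_TOL = 1e-6


class ValidationError(ValueError):
    """A prediction table violates a structural invariant (e.g. row sums)."""


class AlignmentError(ValueError):
    """Item ids do not line up across input files."""


class RegistryError(KeyError):
    """A class label is unknown to the registry, or the registry is invalid."""


class ClassRegistry:
    """Fixed, ordered set of class labels with a label -> index mapping.

    The order is significant: every matrix, report and serialized artifact is
    laid out in registry order, and the integer encoding used for label
    vectors (and hence for the Pearson diversity diagnostic) is the 0-based
    position in this order.
    """

    def __init__(self, names: Sequence[str]):
        names = tuple(str(n) for n in names)
        if len(names) == 0:
            raise RegistryError("registry needs at least one class")
        if any(n == "" for n in names):
            raise RegistryError("class names must be non-empty")
        if len(set(names)) != len(names):
            raise RegistryError(f"duplicate class names in {names!r}")
        self.names = names
        self._index = {n: i for i, n in enumerate(names)}

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise RegistryError(
                f"unknown class {name!r}; registry has {list(self.names)}"
            ) from None

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __eq__(self, other) -> bool:
        return isinstance(other, ClassRegistry) and self.names == other.names

    def __repr__(self) -> str:
        return f"ClassRegistry({list(self.names)})"


def _validate_prob_matrix(probs: np.ndarray, who: str) -> np.ndarray:
    """Check shape/range/row sums; renormalize rows off by <= 1e-3, else raise."""
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2:
        raise ValidationError(f"{who}: probability matrix must be 2-D")
    if np.any(probs < -ROW_SUM_RENORM_TOL) or np.any(probs > 1 + ROW_SUM_RENORM_TOL):
        bad = int(np.argwhere((probs < -ROW_SUM_RENORM_TOL) | (probs > 1 + ROW_SUM_RENORM_TOL))[0][0])
        raise ValidationError(f"{who}: probability outside [0, 1] in row {bad}")
    sums = probs.sum(axis=1)
    off = np.abs(sums - 1.0)
    if np.any(off > ROW_SUM_RENORM_TOL):
        bad = int(np.argmax(off))
        raise ValidationError(
            f"{who}: row {bad} sums to {sums[bad]:.6g}, outside "
            f"[1-{ROW_SUM_RENORM_TOL:g}, 1+{ROW_SUM_RENORM_TOL:g}]"
        )
    if np.any(off > ROW_SUM_STRICT_TOL):
        probs = probs / sums[:, None]
    return np.clip(probs, 0.0, 1.0)


@dataclass
class PredictionSet:
    """Outputs of ``m`` classifiers on ``N`` shared items over ``C`` classes.

    Parameters
    ----------
    classifiers : ordered classifier identifiers, length m.
    probs : float array of shape (m, N, C); each row stochastic.
    truth : int array of shape (N,) with values in ``range(C)``.
    registry : the class registry fixing label order and encoding.
    prob_free : boolean mask, length m — True where the classifier supplied
        hard labels only (stored one-hot); probability-dependent operations
        (soft voting, ROC) refuse such members.
    item_ids : optional item identifiers, length N.
    """

    classifiers: tuple
    probs: np.ndarray
    truth: np.ndarray
    registry: ClassRegistry
    prob_free: np.ndarray = None
    item_ids: tuple = None

    def __post_init__(self):
        self.classifiers = tuple(str(c) for c in self.classifiers)
        if len(set(self.classifiers)) != len(self.classifiers):
            raise ValidationError("duplicate classifier identifiers")
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[0] != len(self.classifiers):
            raise ValidationError(
                f"probs must be (m, N, C) with m={len(self.classifiers)}; got {self.probs.shape}"
            )
        if self.probs.shape[2] != len(self.registry):
            raise ValidationError(
                f"probs has {self.probs.shape[2]} classes, registry has {len(self.registry)}"
            )
        self.probs = np.stack(
            [_validate_prob_matrix(self.probs[j], self.classifiers[j]) for j in range(self.m)]
        )
        self.truth = np.asarray(self.truth, dtype=int)
        if self.truth.shape != (self.n,):
            raise ValidationError(f"truth must have shape ({self.n},)")
        if np.any((self.truth < 0) | (self.truth >= len(self.registry))):
            raise ValidationError("truth contains indices outside the registry")
        if self.prob_free is None:
            self.prob_free = np.zeros(self.m, dtype=bool)
        else:
            self.prob_free = np.asarray(self.prob_free, dtype=bool)
            if self.prob_free.shape != (self.m,):
                raise ValidationError("prob_free mask must have one entry per classifier")
        if self.item_ids is not None:
            self.item_ids = tuple(str(i) for i in self.item_ids)
            if len(self.item_ids) != self.n:
                raise ValidationError("item_ids length != N")
            if len(set(self.item_ids)) != self.n:
                raise ValidationError("item_ids must be unique")

    # -- basic geometry -------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.classifiers)

    @property
    def n(self) -> int:
        return self.probs.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.registry)

    def _jdx(self, classifier: str) -> int:
        try:
            return self.classifiers.index(str(classifier))
        except ValueError:
            raise KeyError(f"unknown classifier {classifier!r}") from None

    # -- derived views ---------------------------------------------------
    def labels(self, classifier: str) -> np.ndarray:
        """Predicted class indices (row argmax) for one classifier."""
        return np.argmax(self.probs[self._jdx(classifier)], axis=1)

    def label_matrix(self) -> np.ndarray:
        """(m, N) matrix of predicted class indices, registry-encoded."""
        return np.argmax(self.probs, axis=2)

    def accuracy(self, classifier: str) -> float:
        return float(np.mean(self.labels(classifier) == self.truth))

    def subset(self, members: Iterable[str]) -> "PredictionSet":
        """Restrict to the given classifiers (order preserved as given)."""
        members = [str(c) for c in members]
        idx = [self._jdx(c) for c in members]
        return PredictionSet(
            classifiers=tuple(members),
            probs=self.probs[idx],
            truth=self.truth,
            registry=self.registry,
            prob_free=self.prob_free[idx],
            item_ids=self.item_ids,
        )

    def take_items(self, items: np.ndarray) -> "PredictionSet":
        """Restrict to a subset of items (integer indices)."""
        items = np.asarray(items, dtype=int)
        return PredictionSet(
            classifiers=self.classifiers,
            probs=self.probs[:, items, :],
            truth=self.truth[items],
            registry=self.registry,
            prob_free=self.prob_free,
            item_ids=None if self.item_ids is None else tuple(self.item_ids[i] for i in items),
        )

    @classmethod
    def from_labels(
        cls,
        classifiers: Sequence[str],
        labels: np.ndarray,
        truth: np.ndarray,
        registry: ClassRegistry,
        item_ids: Sequence[str] = None,
    ) -> "PredictionSet":
        """Build from hard labels only: one-hot probabilities, flagged prob-free."""
        labels = np.asarray(labels, dtype=int)
        if labels.ndim == 1:
            labels = labels[None, :]
        m, n = labels.shape
        probs = np.zeros((m, n, len(registry)))
        for j in range(m):
            probs[j, np.arange(n), labels[j]] = 1.0
        return cls(
            classifiers=tuple(classifiers),
            probs=probs,
            truth=truth,
            registry=registry,
            prob_free=np.ones(m, dtype=bool),
            item_ids=item_ids,
        )


@dataclass(frozen=True)
class ClassCounts:
    """One-vs-rest TP/FP/FN/TN counts for a single class of one classifier."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValidationError(f"{name}={v} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def support(self) -> int:
        """Number of truly-positive items for this class."""
        return self.tp + self.fn


@dataclass
class ConfusionMatrix:
    """C x C contingency of actual (rows) vs predicted (columns) classes."""

    counts: np.ndarray
    registry: ClassRegistry

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.registry)
        if self.counts.shape != (c, c):
            raise ValidationError(f"confusion matrix must be {c}x{c}")
        if np.any(self.counts < 0):
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def ovr(self, class_index: int) -> ClassCounts:
        return ovr_counts(self, class_index)

    def to_frame(self) -> pd.DataFrame:
        names = list(self.registry.names)
        return pd.DataFrame(self.counts, index=names, columns=names)


def confusion(truth: np.ndarray, pred: np.ndarray, registry: ClassRegistry) -> ConfusionMatrix:
    """Confusion matrix with rows = actual class, columns = predicted class."""
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if truth.shape != pred.shape:
        raise ValidationError(f"length mismatch: truth {truth.shape} vs pred {pred.shape}")
    counts = _sk_confusion(truth, pred, labels=np.arange(len(registry)))
    return ConfusionMatrix(counts=counts, registry=registry)


def ovr_counts(cm: ConfusionMatrix, class_index: int) -> ClassCounts:
    """One-vs-rest counts for one class: tp = diagonal cell, fn = rest of the
    row, fp = rest of the column, tn = everything else."""
    c = len(cm.registry)
    if not 0 <= class_index < c:
        raise IndexError(f"class index {class_index} outside range({c})")
    m = cm.counts
    tp = int(m[class_index, class_index])
    fn = int(m[class_index].sum()) - tp
    fp = int(m[:, class_index].sum()) - tp
    tn = cm.total - tp - fn - fp
    return ClassCounts(tp=tp, fp=fp, fn=fn, tn=tn)


# ----------------------------------------------------------------------
# Delimited-text I/O
#
# Combined prediction file: columns item_id, classifier, <class1>...<classC>.
# Per-classifier file: columns item_id, <class1>...<classC>.
# Truth file: columns item_id, label.
# ----------------------------------------------------------------------

def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_prediction_set(
    paths,
    truth_path,
    registry: ClassRegistry = None,
) -> PredictionSet:
    """Read a prediction set from delimited text.

    ``paths`` is either a single combined file (with a ``classifier`` column)
    or a sequence of per-classifier files, one per classifier, whose stem
    names the classifier.  Items are aligned across classifiers by
    ``item_id``, never by file order; the truth file fixes the item order of
    the returned set.
    """
    if isinstance(paths, (str, Path)):
        frames = [pd.read_csv(paths, sep=_sep_for(paths), dtype={"item_id": str})]
        if "classifier" not in frames[0].columns:
            raise ValidationError(f"{paths}: combined file needs a 'classifier' column")
    else:
        frames = []
        for p in paths:
            df = pd.read_csv(p, sep=_sep_for(p), dtype={"item_id": str})
            if "classifier" not in df.columns:
                df = df.assign(classifier=Path(p).stem)
            frames.append(df)
    pred = pd.concat(frames, ignore_index=True)
    if "item_id" not in pred.columns:
        raise ValidationError("prediction file needs an 'item_id' column")

    class_cols = [c for c in pred.columns if c not in ("item_id", "classifier")]
    if registry is None:
        registry = ClassRegistry(class_cols)
    else:
        missing = set(registry.names) - set(class_cols)
        if missing:
            raise RegistryError(f"prediction file missing class columns {sorted(missing)}")
        extra = set(class_cols) - set(registry.names)
        if extra:
            raise RegistryError(f"prediction file has unknown class columns {sorted(extra)}")

    truth_df = pd.read_csv(truth_path, sep=_sep_for(truth_path), dtype={"item_id": str})
    if not {"item_id", "label"} <= set(truth_df.columns):
        raise ValidationError("truth file needs columns item_id, label")
    if truth_df["item_id"].duplicated().any():
        raise AlignmentError("duplicate item_id in truth file")
    item_ids = truth_df["item_id"].tolist()
    truth = np.array([registry.index(str(v)) for v in truth_df["label"]])

    classifiers = list(dict.fromkeys(pred["classifier"].astype(str)))
    want = set(item_ids)
    mats = []
    for clf in classifiers:
        block = pred[pred["classifier"].astype(str) == clf]
        have = set(block["item_id"])
        if have != want:
            missing = sorted(want - have)[:10]
            surplus = sorted(have - want)[:10]
            raise AlignmentError(
                f"classifier {clf!r}: item ids do not match truth "
                f"(missing {missing}, unexpected {surplus})"
            )
        if block["item_id"].duplicated().any():
            raise AlignmentError(f"classifier {clf!r}: duplicate item ids")
        block = block.set_index("item_id").loc[item_ids]
        mats.append(block[list(registry.names)].to_numpy(dtype=float))

    # one-hot rows are probability-free only if declared; infer nothing here
    return PredictionSet(
        classifiers=tuple(classifiers),
        probs=np.stack(mats),
        truth=truth,
        registry=registry,
        item_ids=item_ids,
    )


def write_prediction_set(ps: PredictionSet, pred_path, truth_path=None) -> None:
    """Write the combined prediction file (and optionally the truth file)."""
    ids = ps.item_ids or tuple(f"item{i:05d}" for i in range(ps.n))
    rows = []
    for j, clf in enumerate(ps.classifiers):
        df = pd.DataFrame(ps.probs[j], columns=list(ps.registry.names))
        df.insert(0, "classifier", clf)
        df.insert(0, "item_id", ids)
        rows.append(df)
    sep = _sep_for(pred_path)
    pd.concat(rows, ignore_index=True).to_csv(pred_path, sep=sep, index=False, float_format="%.12g")
    if truth_path is not None:
        pd.DataFrame(
            {"item_id": ids, "label": [ps.registry.names[t] for t in ps.truth]}
        ).to_csv(truth_path, sep=_sep_for(truth_path), index=False)
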