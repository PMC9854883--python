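"""Seeded generator of correlated multi-classifier prediction sets, plus
loaders for the packaged count-table fixtures.

The generator emulates the statistical structure of a bank of image
classifiers evaluated on one balanced test set: per item a latent shared
evidence vector (what every classifier sees in the image) is mixed with
per-classifier idiosyncratic noise, and a per-classifier bias toward the true
class sets its skill.  Two independent dials result: per-classifier overall
accuracy (the bias scale, calibrated by bisection) and inter-classifier
predicted-label correlation (the shared-signal fraction rho).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ClassCounts, ClassRegistry, PredictionSet

__all__ = [
    "GeneratorConfig",
    "generate",
    "load_fixture",
    "fixture_registry",
    "fixture_report",
    "DEFAULT_SKILLS",
]

#: Per-classifier target accuracies of the default 16-member bank — the
#: spread observed for a set of CNNs fine-tuned on the same 4-class task
#: (roughly 0.62-0.72, top to bottom of the ranking).
DEFAULT_SKILLS = (
    0.719, 0.715, 0.700, 0.699, 0.695, 0.694, 0.690, 0.686,
    0.684, 0.676, 0.664, 0.662, 0.661, 0.660, 0.628, 0.617,
)

#: Shared-signal fraction giving pairwise predicted-label correlations in the
#: 0.33-0.75 band typical of independently trained CNNs on one dataset.
DEFAULT_RHO = 0.45

FIXTURE_CLASSES = ("BLT", "LCY", "MLC", "PLC")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic prediction-set generator.

    n_items : test-set size (default 1000, balanced across classes).
    n_classes : number of classes (default 4); must divide n_items.
    n_classifiers : bank size (default 16).
    skills : per-classifier target overall accuracy in (1/C, 1); default is
        the 16-value 0.62-0.72 spread above (or an even spread over
        [0.62, 0.72] for other bank sizes).
    rho : shared-signal fraction in [0, 1) — 0 gives independent classifiers,
        larger values raise pairwise predicted-label correlation.
    temperature : softmax temperature for the probability outputs (sharper
        below 1); does not affect predicted labels.
    seed : master seed; generation is fully deterministic given the config.
    """

    n_items: int = 1000
    n_classes: int = 4
    n_classifiers: int = 16
    skills: Sequence[float] = None
    rho: float = DEFAULT_RHO
    temperature: float = 1.0
    seed: int = 0
    class_names: Sequence[str] = None

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_items % self.n_classes != 0:
            raise ValueError("n_items must be divisible by n_classes (balanced truth)")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.skills is None:
            if self.n_classifiers == len(DEFAULT_SKILLS):
                self.skills = DEFAULT_SKILLS
            else:
                self.skills = tuple(np.linspace(0.72, 0.62, self.n_classifiers))
        self.skills = tuple(float(s) for s in self.skills)
        if len(self.skills) != self.n_classifiers:
            raise ValueError("one skill per classifier required")
        chance = 1.0 / self.n_classes
        for s in self.skills:
            if not chance < s < 1:
                raise ValueError(f"skill {s} not attainable (must lie in ({chance}, 1))")
        if self.class_names is None:
            self.class_names = (
                FIXTURE_CLASSES if self.n_classes == 4
                else tuple(f"C{i}" for i in range(self.n_classes))
            )


def _calibrate_bias(gaps: np.ndarray, target: float, tol: float = 0.005) -> float:
    """Bisection for the true-class bias hitting ``target`` realized accuracy.

    ``gaps[i]`` is the margin by which the best wrong class beats the true
    class before any bias: item i is classified correctly iff bias > gaps[i],
    so accuracy(b) = mean(gaps < b) is a monotone step function and bisection
    converges to within ``tol`` of the target (step granularity permitting).
    Calibrating on the generation draw itself — rather than a held draw —
    removes the ~sqrt(p(1-p)/N) binomial wobble a frozen population bias
    would leave on realized accuracy, so skill targets reproduce under seed.
    """
    gaps = np.sort(gaps)
    n = len(gaps)
    lo, hi = 0.0, float(gaps[-1]) + 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        acc = np.searchsorted(gaps, mid) / n
        if abs(acc - target) <= tol:
            return mid
        if acc < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate(cfg: GeneratorConfig) -> PredictionSet:
    """Draw one correlated multi-classifier prediction set.

    Per item i with true class t: a shared evidence vector S_i ~ N(0, I_C) is
    drawn; classifier j's logits are sqrt(rho)·S_i + sqrt(1-rho)·E_ij with
    E_ij ~ N(0, I_C), plus a bias b_j on the true-class component.  Mixing
    with square-root weights keeps each logit's variance at 1, so b_j maps to
    accuracy independently of rho; b_j is calibrated to skill_j by bisection
    on the realized margins (see :func:`_calibrate_bias`).  Probabilities are
    softmax(logits / temperature).
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_truth, rng_shared, *rng_members = [
        np.random.default_rng(s) for s in ss.spawn(2 + cfg.n_classifiers)
    ]

    n, c, m = cfg.n_items, cfg.n_classes, cfg.n_classifiers
    truth = np.repeat(np.arange(c), n // c)
    rng_truth.shuffle(truth)

    shared = rng_shared.standard_normal((n, c))
    sq_r, sq_i = np.sqrt(cfg.rho), np.sqrt(1.0 - cfg.rho)

    probs = np.empty((m, n, c))
    wrong = np.ones((n, c), dtype=bool)
    wrong[np.arange(n), truth] = False
    for j in range(m):
        logits = sq_r * shared + sq_i * rng_members[j].standard_normal((n, c))
        own = logits[np.arange(n), truth]
        gaps = logits[wrong].reshape(n, c - 1).max(axis=1) - own
        bias = _calibrate_bias(gaps, cfg.skills[j])
        logits[np.arange(n), truth] += bias
        z = logits / cfg.temperature
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs[j] = e / e.sum(axis=1, keepdims=True)

    return PredictionSet(
        classifiers=tuple(f"m{j + 1:02d}" for j in range(m)),
        probs=probs,
        truth=truth,
        registry=ClassRegistry(cfg.class_names),
        item_ids=tuple(f"item{i:05d}" for i in range(n)),
    )


# ----------------------------------------------------------------------
# Packaged count-table fixtures
# ----------------------------------------------------------------------

_FIXTURES = {"counts16": "counts16.csv", "counts_ensembles": "counts_ensembles.csv"}


def fixture_registry() -> ClassRegistry:
    """The fixed 4-class registry of the fixture tables (BLT, LCY, MLC, PLC:
    benign liver tumor, liver cyst, metastatic and primary liver cancer)."""
    return ClassRegistry(FIXTURE_CLASSES)


def _fixture_frame(table: str) -> pd.DataFrame:
    try:
        fname = _FIXTURES[table]
    except KeyError:
        raise KeyError(f"unknown fixture {table!r}; have {sorted(_FIXTURES)}") from None
    with resources.files("fusemble.fixtures").joinpath(fname).open() as fh:
        return pd.read_csv(fh)


def load_fixture(table: str) -> Mapping[str, Mapping[str, ClassCounts]]:
    """Per-classifier, per-class one-vs-rest counts from a packaged table.

    ``counts16`` holds the 16-classifier bank; ``counts_ensembles`` the four
    best pruned ensembles (SV16, ST9, WAV7, WHV13).  Returns
    ``{classifier: {class: ClassCounts}}`` with classes in registry order.
    """
    df = _fixture_frame(table)
    out: dict = {}
    for _, row in df.iterrows():
        out.setdefault(row["classifier"], {})[row["class"]] = ClassCounts(
            tp=int(row.tp), fp=int(row.fp), fn=int(row.fn), tn=int(row.tn)
        )
    return out


def fixture_report(table: str, classifier: str, ci: str = None):
    """Convenience: the macro metric report for one fixture classifier."""
    from .metrics import macro_report

    counts = load_fixture(table)[classifier]
    ordered = {name: counts[name] for name in FIXTURE_CLASSES}
    return macro_report(ordered, ci=ci)
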