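"""Classification targets and the three loss terms of the two-head model.

The classifier distinguishes three lesion risk categories — Melanoma,
Malignant (non-melanoma) and Other — and trains two output heads against
two target forms:

* a *hard* one-hot label, scored with categorical cross-entropy, and
* a *soft* per-class probability vector, scored with a per-logit binary
  cross-entropy plus a Kullback-Leibler divergence toward the soft label.

Soft labels encode that Melanoma and Malignant lesions resemble each other
more than either resembles the benign Other class: Melanoma -> (0.7, 0.2,
0.1), Malignant -> (0.2, 0.7, 0.1), Other -> (0.1, 0.1, 0.8).

The total training objective is the weighted sum
``alpha*CE + beta*BCE + gamma*KL`` with all weights defaulting to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed class ordering used everywhere in the package.
CLASS_NAMES: tuple[str, ...] = ("Melanoma", "Malignant", "Other")

N_CLASSES = len(CLASS_NAMES)

#: Probability clamp applied before any logarithm.
EPS = 1e-7

def _exact_simplex(a: float, b: float) -> np.ndarray:
    # last entry defined by complement so the vector sums to 1.0 exactly
    return np.array([a, b, 1.0 - (a + b)])


_SOFT_TABLE = {
    "Melanoma": _exact_simplex(0.7, 0.2),
    "Malignant": _exact_simplex(0.2, 0.7),
    "Other": _exact_simplex(0.1, 0.1),
}


@dataclass(frozen=True)
class ClassLabel:
    """A lesion risk category with its fixed index in the class ordering."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in CLASS_NAMES:
            raise ValueError(
                f"unknown class label {self.name!r}; expected one of {CLASS_NAMES}"
            )

    @property
    def index(self) -> int:
        return CLASS_NAMES.index(self.name)

    @classmethod
    def from_index(cls, index: int) -> "ClassLabel":
        if not 0 <= index < N_CLASSES:
            raise ValueError(f"class index {index} out of range 0..{N_CLASSES - 1}")
        return cls(CLASS_NAMES[index])


@dataclass(frozen=True)
class LossWeights:
    """Nonnegative weights (alpha, beta, gamma) of the three loss terms."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"loss weight {name} must be nonnegative")


def soft_target(label: ClassLabel | str) -> np.ndarray:
    """Return the precomputed soft-label distribution for ``label``."""
    name = label.name if isinstance(label, ClassLabel) else label
    if name not in _SOFT_TABLE:
        raise ValueError(f"unknown class label {name!r}")
    return _SOFT_TABLE[name].copy()


def hard_target(label: ClassLabel | str) -> np.ndarray:
    """Return the one-hot vector for ``label``."""
    label = label if isinstance(label, ClassLabel) else ClassLabel(label)
    y = np.zeros(N_CLASSES)
    y[label.index] = 1.0
    return y


@dataclass(frozen=True)
class TargetPair:
    """Hard one-hot target and soft probability target for one sample."""

    hard: np.ndarray
    soft: np.ndarray

    def __post_init__(self) -> None:
        hard = np.asarray(self.hard, dtype=float)
        soft = np.asarray(self.soft, dtype=float)
        if hard.shape != soft.shape:
            raise ValueError("hard and soft targets must have equal length")
        if not (np.isclose(hard.sum(), 1.0) and np.count_nonzero(hard) == 1):
            raise ValueError("hard target must be one-hot")
        if np.any(soft < 0) or abs(soft.sum() - 1.0) > 1e-9:
            raise ValueError("soft target must be a probability vector")

    @classmethod
    def from_label(cls, label: ClassLabel | str) -> "TargetPair":
        return cls(hard=hard_target(label), soft=soft_target(label))


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), EPS, 1.0 - EPS)


def cross_entropy(hard: np.ndarray, probs: np.ndarray) -> float:
    """Categorical cross-entropy ``-sum_i y_i log p_i`` of a one-hot target."""
    hard = np.asarray(hard, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if hard.shape != probs.shape:
        raise ValueError(
            f"target and prediction lengths differ: {hard.shape} vs {probs.shape}"
        )
    return float(-(hard * np.log(_clamp(probs))).sum())


def binary_cross_entropy(soft: np.ndarray, probs: np.ndarray) -> float:
    """Per-output binary cross-entropy, averaged across the output vector.

    Each class output is treated as an independent binary decision against
    its soft-label entry q: ``-[q log p + (1-q) log(1-p)]``; the mean over
    outputs keeps the term on the same scale as the categorical loss.
    """
    soft = np.asarray(soft, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if soft.shape != probs.shape:
        raise ValueError(
            f"target and prediction lengths differ: {soft.shape} vs {probs.shape}"
        )
    if np.any((soft < 0) | (soft > 1)) or np.any((probs < 0) | (probs > 1)):
        raise ValueError("binary cross-entropy inputs must lie in [0, 1]")
    p = _clamp(probs)
    terms = -(soft * np.log(p) + (1.0 - soft) * np.log(1.0 - p))
    return float(terms.mean())


def kl_divergence(q: np.ndarray, p: np.ndarray) -> float:
    """Kullback-Leibler divergence ``KL(Q || P) = sum_i Q_i log(Q_i / P_i)``.

    ``q`` is the soft-label target distribution and ``p`` the prediction;
    the prediction is clamped away from zero before the logarithm.
    """
    q = np.asarray(q, dtype=float)
    p = np.asarray(p, dtype=float)
    if q.shape != p.shape:
        raise ValueError(f"distribution lengths differ: {q.shape} vs {p.shape}")
    p = _clamp(p)
    mask = q > 0
    return float((q[mask] * np.log(q[mask] / p[mask])).sum())


def total_loss(
    l_ce: float, l_bce: float, l_kl: float, weights: LossWeights = LossWeights()
) -> float:
    """Weighted sum ``alpha*CE + beta*BCE + gamma*KL`` of the head losses."""
    for name, value in (("CE", l_ce), ("BCE", l_bce), ("KL", l_kl)):
        if np.isnan(value):
            raise ValueError(f"{name} loss term is NaN")
    return float(weights.alpha * l_ce + weights.beta * l_bce + weights.gamma * l_kl)
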