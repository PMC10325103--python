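"""Condition-vector algebra: one-hot encoding, label simulation, morphing.

The generator is conditioned on the vertebral region through a length-3
vector c on the probability simplex: one-hot at the three vertices
(cervical, thoracic, lumbar; classes indexed 1..3) and linearly
interpolated between two vertices when morphing an image from a source
region k to a target region k': at step i of n, the weight on component k
is (n-i)/n and on component k' is i/n, the third component staying 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import LabeledImageSet

N_CLASSES = 3
_SUM_TOL = 1e-9


def _check_class(k: int, name: str = "k") -> None:
    if k not in (1, 2, 3):
        raise ValueError(f"{name} must be in {{1, 2, 3}}, got {k!r}")


@dataclass(frozen=True)
class ConditionVector:
    """A point on the 2-simplex; ``weights`` is a length-3 float array."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (N_CLASSES,):
            raise ValueError("condition vector must have 3 components")
        if (w < -_SUM_TOL).any() or abs(w.sum() - 1.0) > _SUM_TOL:
            raise ValueError("condition components must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w)

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.weights, dtype=dtype)


def one_hot(k: int) -> ConditionVector:
    """One-hot condition at class k in {1, 2, 3} (cervical/thoracic/lumbar)."""
    _check_class(k)
    w = np.zeros(N_CLASSES)
    w[k - 1] = 1.0
    return ConditionVector(w)


def morph_condition(k: int, k_prime: int, i: int, n: int) -> ConditionVector:
    """Condition at step i of an n-step morph from class k to class k'."""
    _check_class(k, "k")
    _check_class(k_prime, "k_prime")
    if k == k_prime:
        raise ValueError("source and target classes must differ")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= i <= n:
        raise ValueError(f"step i must satisfy 0 <= i <= n, got i={i}, n={n}")
    w = np.zeros(N_CLASSES)
    w[k - 1] = (n - i) / n
    w[k_prime - 1] = i / n
    return ConditionVector(w)


@dataclass(frozen=True)
class MorphSchedule:
    """Ordered conditions c^i for i = 0..n morphing class k into k'."""

    source: int
    target: int
    n_steps: int
    steps: tuple[ConditionVector, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(
            morph_condition(self.source, self.target, i, self.n_steps)
            for i in range(self.n_steps + 1)))

    def __iter__(self):
        return iter(self.steps)

    def __len__(self) -> int:
        return len(self.steps)


def sample_labels(probs, n: int, seed: int) -> np.ndarray:
    """Draw n i.i.d. class labels in {1,2,3} from a categorical distribution."""
    p = np.asarray(probs, dtype=np.float64)
    if p.shape != (N_CLASSES,) or (p < 0).any() or abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValueError("probs must be 3 non-negative numbers summing to 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.choice(np.array([1, 2, 3], dtype=np.int8), size=n, p=p / p.sum())


def empirical_distribution(data: LabeledImageSet, split: str) -> np.ndarray:
    """Class relative frequencies (cervical, thoracic, lumbar) in a split."""
    view = data.split_view(split)
    if len(view) == 0:
        raise ValueError(f"split {split!r} is empty")
    counts = np.array([(view.labels == k).sum() for k in (1, 2, 3)], dtype=float)
    return counts / counts.sum()


# label distribution used when generating the shareable synthetic dataset
GENERATION_DISTRIBUTION = (0.25, 0.55, 0.20)
# class distribution of the held-out test cohort as printed (sums to 1.01);
# normalized here so it is a valid categorical distribution
TEST_COHORT_DISTRIBUTION = tuple(np.array((0.23, 0.55, 0.23)) / 1.01)
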