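"""Divergence losses between discrete category distributions.

Parental selection on ordinal traits compares each candidate's predicted
probability mass function (pmf) over the trait's ordered categories with a
breeder-defined target pmf.  Three losses are supported:

* Kullback-Leibler divergence  ``D_KL(p||q) = sum_i p_i ln(p_i/q_i)``
* Bhattacharyya distance       ``D_B(p,q)  = -ln sum_i sqrt(p_i q_i)``
* Hellinger distance           ``D_H(p,q)  = sqrt(0.5 sum_i (sqrt(p_i)-sqrt(q_i))^2)``

All logarithms are natural.  For several traits the multitrait loss is the
unweighted sum of per-trait losses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CategoricalPMF",
    "TargetSpec",
    "kl_divergence",
    "bhattacharyya_distance",
    "hellinger_distance",
    "multitrait_loss",
    "METHODS",
]

METHODS = ("kl", "bhattacharyya", "hellinger")

_SUM_TOL = 1e-9


def _as_pmf_array(p, name: str, *, strict_positive: bool = False) -> np.ndarray:
    """Validate and return a pmf as a 1-D float array."""
    arr = np.asarray(getattr(p, "probs", p), dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"{name} must be a 1-D pmf with at least 2 categories")
    if np.any(arr < 0):
        raise ValueError(f"{name} has negative entries")
    if strict_positive and np.any(arr == 0):
        raise ValueError(f"{name} must be strictly positive (zero entries are not allowed)")
    if abs(arr.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"{name} entries sum to {arr.sum():.12g}, not 1")
    return arr


@dataclass(frozen=True)
class CategoricalPMF:
    """Probability vector over the ordered categories of one trait.

    Parameters
    ----------
    probs
        Length-C vector, C >= 2; non-negative, summing to 1 within 1e-9.
    strict_positive
        Require every entry > 0 (mandatory for target pmfs, where zero
        entries would make the KL divergence undefined).
    """

    probs: np.ndarray
    strict_positive: bool = field(default=False, compare=False)

    def __post_init__(self):
        arr = _as_pmf_array(self.probs, "pmf", strict_positive=self.strict_positive)
        object.__setattr__(self, "probs", arr)

    @property
    def n_categories(self) -> int:
        return self.probs.size

    def __len__(self) -> int:
        return self.probs.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.probs, dtype=dtype)


@dataclass(frozen=True)
class TargetSpec:
    """Breeder-defined target pmf for each trait under selection.

    Every target entry must be strictly positive: a zero target probability
    for an attainable category gives an infinite KL loss, so it is rejected
    at construction.
    """

    targets: tuple

    def __post_init__(self):
        tg = tuple(
            t if isinstance(t, CategoricalPMF) else CategoricalPMF(np.asarray(t, float), strict_positive=True)
            for t in self.targets
        )
        for t in tg:
            if np.any(t.probs == 0):
                raise ValueError("target pmfs must be strictly positive")
        if len(tg) == 0:
            raise ValueError("TargetSpec needs at least one trait")
        object.__setattr__(self, "targets", tg)

    @classmethod
    def from_sequences(cls, seqs: Iterable[Sequence[float]]) -> "TargetSpec":
        return cls(tuple(seqs))

    @property
    def n_traits(self) -> int:
        return len(self.targets)

    @property
    def n_categories(self) -> tuple:
        return tuple(t.n_categories for t in self.targets)

    def __iter__(self):
        return iter(self.targets)

    def __len__(self):
        return len(self.targets)

    def __getitem__(self, j):
        return self.targets[j]


def _check_same_length(p: np.ndarray, q: np.ndarray) -> None:
    if p.size != q.size:
        raise ValueError(f"pmf length mismatch: {p.size} vs {q.size}")


def kl_divergence(p, q) -> float:
    """Kullback-Leibler divergence ``sum_i p_i ln(p_i / q_i)`` (natural log).

    Asymmetric in (p, q); ``q`` must be strictly positive.  The convention
    ``0 * ln(0/q) = 0`` applies, so zeros in ``p`` are allowed.
    """
    p = _as_pmf_array(p, "p")
    q = _as_pmf_array(q, "q", strict_positive=True)
    _check_same_length(p, q)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def bhattacharyya_distance(p, q) -> float:
    """Bhattacharyya distance ``-ln BC`` with coefficient ``BC = sum_i sqrt(p_i q_i)``.

    Symmetric; zero iff ``p == q``.  Disjoint supports (BC = 0) return
    ``+inf`` with a warning rather than raising.
    """
    p = _as_pmf_array(p, "p")
    q = _as_pmf_array(q, "q")
    _check_same_length(p, q)
    bc = float(np.sum(np.sqrt(p * q)))
    if bc <= 0.0:
        warnings.warn("disjoint supports: Bhattacharyya coefficient is 0, distance is +inf")
        return float("inf")
    # clip tiny numerical overshoot of BC above 1
    return float(max(0.0, -np.log(min(bc, 1.0))))


def hellinger_distance(p, q) -> float:
    """Hellinger distance ``sqrt(0.5 sum_i (sqrt(p_i) - sqrt(q_i))^2)``, in [0, 1]."""
    p = _as_pmf_array(p, "p")
    q = _as_pmf_array(q, "q")
    _check_same_length(p, q)
    return float(np.sqrt(0.5 * np.sum((np.sqrt(p) - np.sqrt(q)) ** 2)))


_DISPATCH = {
    "kl": kl_divergence,
    "bhattacharyya": bhattacharyya_distance,
    "hellinger": hellinger_distance,
}


def resolve_method(method: str):
    """Map a loss-method name (case-insensitive) to its function."""
    key = str(method).lower()
    if key not in _DISPATCH:
        raise ValueError(f"unknown method {method!r}; valid methods: {', '.join(METHODS)}")
    return _DISPATCH[key]


def multitrait_loss(ps: Sequence, target: TargetSpec, method: str = "kl") -> float:
    """Sum of per-trait divergences between candidate pmfs and targets.

    Traits contribute with equal weight (a plain sum); traits with more
    categories can therefore dominate the total.
    """
    fn = resolve_method(method)
    if not isinstance(target, TargetSpec):
        target = TargetSpec(tuple(target))
    ps = list(ps)
    if len(ps) != target.n_traits:
        raise ValueError(f"trait count mismatch: {len(ps)} pmfs vs {target.n_traits} targets")
    return float(sum(fn(p, q) for p, q in zip(ps, target)))
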