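"""Effective dimensions of a model from its sensitivity indices.

Two reductions of a full index set:

* superposition sense, ``k_s`` — the smallest interaction order whose
  cumulative (clipped) index sum reaches a threshold ``p`` (default 0.99).
  Indices are routinely estimated only through order 3, so ``k_s`` is censored
  to ">=4" when the cumulative sum through the highest available order stays
  below ``p``.
* truncation sense, ``k_t`` — the number of parameters whose total-order
  index strictly exceeds a screening threshold ``q`` (default 0.05); these
  form the influential set C.

Negative index estimates (possible by Monte Carlo error) are clipped to zero
before summation so cumulative sums are monotone in order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .estimators import SensitivityIndices

__all__ = ["EffectiveDimensions", "KsResult", "k_superposition", "k_truncation", "effective_dimensions"]

DEFAULT_P = 0.99
DEFAULT_Q = 0.05


@dataclass(frozen=True)
class KsResult:
    """k_s with its censoring state and the cumulative sums that produced it.

    ``value`` is the determined order, or None when censored; ``label`` always
    renders (e.g. "2" or ">=4"); ``coded`` maps the censored case to
    (highest available order + 1) for rank statistics.
    """

    value: int | None
    censored: bool
    highest_available_order: int
    cumulative_by_order: dict[int, float]

    @property
    def label(self) -> str:
        if self.censored:
            return f">={self.highest_available_order + 1}"
        return str(self.value)

    @property
    def coded(self) -> int:
        return self.highest_available_order + 1 if self.censored else int(self.value)


@dataclass(frozen=True)
class EffectiveDimensions:
    """Joint (k_t, k_s) diagnostic for one model output."""

    k_t: int
    k_s: KsResult
    p: float
    q: float
    influential_set: tuple[int, ...]   # 1-based parameter indices with T_i > q
    cumulative_by_order: dict[int, float]


def k_superposition(indices: SensitivityIndices, p: float = DEFAULT_P) -> KsResult:
    """Smallest order whose cumulative clipped index sum reaches ``p``.

    Orders not estimated (no pair/triplet indices present) are treated as
    unavailable, not zero: if the sum through the highest available order is
    below ``p`` the result is censored to ">= order+1".
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie in (0, 1), got {p}")
    orders = indices.available_orders()
    cumulative: dict[int, float] = {}
    running = 0.0
    for o in orders:
        running += indices.sum_by_order(o, clip=True)
        cumulative[o] = running
        if running >= p:
            return KsResult(value=o, censored=False,
                            highest_available_order=o, cumulative_by_order=dict(cumulative))
    return KsResult(value=None, censored=True,
                    highest_available_order=orders[-1], cumulative_by_order=cumulative)


def k_truncation(total_order, q: float = DEFAULT_Q) -> tuple[int, tuple[int, ...]]:
    """Count of total-order indices strictly above ``q``; returns
    ``(k_t, influential_set)`` with 1-based parameter indices."""
    if not (0.0 <= q < 1.0):
        raise ValueError(f"q must lie in [0, 1), got {q}")
    T = np.asarray(total_order, dtype=float).ravel()
    if T.size == 0:
        raise ValueError("total-order vector is empty")
    if not np.all(np.isfinite(T)):
        raise ValueError("total-order vector contains non-finite values")
    mask = T > q
    influential = tuple(int(i) + 1 for i in np.nonzero(mask)[0])
    k_t = int(mask.sum())
    if k_t == 0:
        warnings.warn("no parameter exceeds the influence threshold q; k_t = 0", UserWarning, stacklevel=2)
    return k_t, influential


def effective_dimensions(
    indices: SensitivityIndices, p: float = DEFAULT_P, q: float = DEFAULT_Q
) -> EffectiveDimensions:
    """Compute both effective dimensions from one estimated index set."""
    if indices.total_order is None:
        raise ValueError("total-order indices are required for k_t")
    ks = k_superposition(indices, p=p)
    kt, influential = k_truncation(indices.total_order, q=q)
    return EffectiveDimensions(
        k_t=kt, k_s=ks, p=p, q=q,
        influential_set=influential,
        cumulative_by_order=ks.cumulative_by_order,
    )
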