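"""Analytic benchmark functions.

Sobol' G function with its closed-form index oracle and the coefficient
randomization used to generate model populations with varied interaction
structure, plus the registry of 13 univariate basis responses consumed by the
random metafunction generator.

For G, y = prod_i (|4 x_i - 2| + a_i) / (1 + a_i) on the unit hypercube with
a_i >= 0.  Partial variances factorize: V_i = (1/3)/(1+a_i)^2, the closed
variance of a subset u is prod_{i in u}(1+V_i) - 1, and the total variance is
the same product over all inputs.  Small a_i make an input influential; two
or more small a_i create genuine interactions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GFunctionSpec",
    "AnalyticIndices",
    "sobol_g",
    "g_analytic_indices",
    "sample_g_coefficients",
    "basis_function",
    "BASIS_REGISTRY",
    "G_COEFFICIENT_VALUES",
    "G_COEFFICIENT_WEIGHTS",
]

# Coefficient randomization: values and weights chosen to promote nonadditive
# functions (0.4 probability of a_i = 0, i.e. a maximally influential input).
G_COEFFICIENT_VALUES = (0.0, 1.0, 4.5, 9.0, 99.0)
G_COEFFICIENT_WEIGHTS = (0.4, 0.3, 0.2, 0.05, 0.05)


@dataclass(frozen=True)
class GFunctionSpec:
    """Coefficient vector of a G function; a_i >= 0, len(a) = k."""

    a: tuple[float, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("a must be a non-empty 1-D coefficient vector")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ValueError("all G coefficients must be finite and non-negative")
        object.__setattr__(self, "a", tuple(float(v) for v in a))

    @property
    def k(self) -> int:
        return len(self.a)

    def to_json(self) -> dict:
        return {"a": list(self.a)}

    @classmethod
    def from_json(cls, obj: dict) -> "GFunctionSpec":
        return cls(a=tuple(obj["a"]))


def sobol_g(x: np.ndarray, spec: GFunctionSpec) -> np.ndarray:
    """Evaluate the G function row-wise on points in [0, 1]^k."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != spec.k:
        raise ValueError(f"points have {x.shape[1]} columns but spec has k={spec.k}")
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError("points must lie in the unit hypercube [0, 1]^k")
    a = np.asarray(spec.a)
    return np.prod((np.abs(4.0 * x - 2.0) + a) / (1.0 + a), axis=1)


@dataclass(frozen=True)
class AnalyticIndices:
    """Closed-form variance decomposition of a G function.

    ``Vi`` are the factorized partial variances; any subset's closed/pure
    index is a product expression, so the oracle covers every order.
    """

    spec: GFunctionSpec
    Vi: tuple[float, ...]
    V: float

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def S(self) -> np.ndarray:
        return np.asarray(self.Vi) / self.V

    @property
    def T(self) -> np.ndarray:
        Vi = np.asarray(self.Vi)
        prod_all = np.prod(1.0 + Vi)
        return Vi * (prod_all / (1.0 + Vi)) / self.V

    def pure_index(self, u: tuple[int, ...]) -> float:
        """Pure interaction index of subset u (0-based indices)."""
        return float(np.prod([self.Vi[i] for i in u]) / self.V)

    def closed_index(self, u: tuple[int, ...]) -> float:
        return float((np.prod([1.0 + self.Vi[i] for i in u]) - 1.0) / self.V)

    def sum_pure_by_order(self, order: int) -> float:
        """Sum of all pure indices of a given order: the elementary symmetric
        polynomial e_order(V_1..V_k) over V."""
        e = _elementary_symmetric(np.asarray(self.Vi), order)
        return float(e / self.V)

    def oracle_k_s(self, p: float = 0.99, max_order: int = 3) -> int | None:
        """Exact k_s through ``max_order``; None means censored (>= max_order+1)."""
        running = 0.0
        for o in range(1, min(max_order, self.k) + 1):
            running += self.sum_pure_by_order(o)
            if running >= p:
                return o
        if self.k <= max_order:  # full decomposition seen; sums to 1 >= p
            return self.k
        return None

    def oracle_k_t(self, q: float = 0.05) -> int:
        return int(np.sum(self.T > q))


def _elementary_symmetric(v: np.ndarray, order: int) -> float:
    """e_order(v) via the Newton-girard style DP (exact for small k)."""
    if order < 1 or order > v.size:
        return 0.0
    e = np.zeros(order + 1)
    e[0] = 1.0
    for x in v:
        for o in range(min(order, v.size), 0, -1):
            e[o] += e[o - 1] * x
    return float(e[order])


def g_analytic_indices(spec: GFunctionSpec) -> AnalyticIndices:
    """Closed-form S_i, T_i, and subset indices of a G function."""
    a = np.asarray(spec.a)
    Vi = (1.0 / 3.0) / (1.0 + a) ** 2
    V = float(np.prod(1.0 + Vi) - 1.0)
    if V <= 0.0:
        raise ValueError("degenerate G function: total variance is zero")
    return AnalyticIndices(spec=spec, Vi=tuple(float(v) for v in Vi), V=V)


def sample_g_coefficients(k: int, rng: np.random.Generator) -> GFunctionSpec:
    """Draw k coefficients i.i.d. from {0, 1, 4.5, 9, 99} with weights
    {0.4, 0.3, 0.2, 0.05, 0.05}."""
    if k < 1:
        raise ValueError("k must be >= 1")
    a = rng.choice(G_COEFFICIENT_VALUES, size=k, replace=True, p=G_COEFFICIENT_WEIGHTS)
    return GFunctionSpec(a=tuple(float(v) for v in a))


# ---------------------------------------------------------------------------
# Univariate basis registry for the metafunction generator.
#
# Thirteen response shapes on [0, 1], from linear to multimodal.  Ids 1
# (cubic), 3 (scaled exponential) and 12 (quadratic) are fixed; the remaining
# shapes are this package's registry of common physical responses and can be
# overridden by registering alternatives.
# ---------------------------------------------------------------------------

_INV_LO = 1.0 / 1.1  # value of 1/(x+0.1) at x = 1
_INV_HI = 10.0       # value at x = 0


def _f_cubic(x):        return x ** 3
def _f_step(x):         return np.where(x > 0.5, 1.0, 0.0)
def _f_exponential(x):  return (np.exp(x) - 1.0) / (math.e - 1.0)
def _f_inverse(x):      return (1.0 / (x + 0.1) - _INV_LO) / (_INV_HI - _INV_LO)
def _f_linear(x):       return np.asarray(x, dtype=float)
def _f_none(x):         return np.zeros_like(np.asarray(x, dtype=float))
def _f_parabola(x):     return 4.0 * (x - 0.5) ** 2
def _f_periodic(x):     return np.sin(2.0 * np.pi * x) / 2.0
def _f_threshold(x):    return np.clip((x - 0.8) / 0.2, 0.0, None)
def _f_sigmoid(x):      return 1.0 / (1.0 + np.exp(-20.0 * (x - 0.5)))
def _f_multimodal(x):   return x * np.sin(6.0 * np.pi * x)
def _f_quadratic(x):    return x ** 2
def _f_sqrt(x):         return np.sqrt(x)


BASIS_REGISTRY: dict[int, tuple[str, object]] = {
    1: ("cubic", _f_cubic),
    2: ("discontinuous step", _f_step),
    3: ("scaled exponential", _f_exponential),
    4: ("inverse decay", _f_inverse),
    5: ("linear", _f_linear),
    6: ("no effect", _f_none),
    7: ("symmetric parabola", _f_parabola),
    8: ("periodic", _f_periodic),
    9: ("threshold ramp", _f_threshold),
    10: ("logistic sigmoid", _f_sigmoid),
    11: ("multimodal", _f_multimodal),
    12: ("quadratic", _f_quadratic),
    13: ("square root", _f_sqrt),
}


def basis_function(basis_id: int, x) -> np.ndarray:
    """Evaluate univariate basis ``basis_id`` (1..13) at points in [0, 1]."""
    try:
        _, f = BASIS_REGISTRY[int(basis_id)]
    except (KeyError, ValueError):
        raise ValueError(f"unknown basis id {basis_id!r}; valid ids are 1..13") from None
    return np.asarray(f(np.asarray(x, dtype=float)))


def basis_table() -> list[tuple[int, str]]:
    """(id, name) rows for documentation dumps."""
    return [(i, name) for i, (name, _) in sorted(BASIS_REGISTRY.items())]
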