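"""Random metafunction generator.

A metafunction assigns one of 13 univariate basis responses to each of k
inputs and activates interaction terms up to a chosen order n <= k:

    y = sum_i f_{u_i}(x_i)
        + sum_{(i,j)} f_{u_i}(x_i) f_{u_j}(x_j)
        + ... (all C(k, o) subsets for every active order o <= n)

Interaction terms are plain products of the same per-input basis evaluations
and are unweighted by default (an optional coefficient hook exists for
exploratory use).  With every subset of each active order present, the sum of
all interaction terms of order o equals the elementary symmetric polynomial
e_o of the per-input basis values, which is how evaluation is implemented;
it is exactly equivalent to enumerating the subset terms.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .test_functions import BASIS_REGISTRY, basis_function

__all__ = ["MetaFunctionSpec", "sample_metafunction", "evaluate_metafunction"]

N_BASES = 13


@dataclass
class MetaFunctionSpec:
    """One randomly generated test model.

    ``u`` holds the basis id (1..13) applied to each input; ``n`` is the
    highest active interaction order; ``interaction_sets[o]`` enumerates the
    active order-o subsets as sorted 0-based tuples (all C(k, o) of them
    unless a sparsity fraction below 1 was requested).
    """

    k: int
    u: tuple[int, ...]
    n: int
    interaction_sets: dict[int, list[tuple[int, ...]]] = field(default_factory=dict)
    seed: int | None = None
    sparsity: float = 1.0
    coefficients: dict[int, np.ndarray] | None = None  # optional per-term weights

    def __post_init__(self) -> None:
        if not (1 <= self.n <= self.k):
            raise ValueError(f"need 1 <= n <= k, got n={self.n}, k={self.k}")
        if len(self.u) != self.k or any(not (1 <= b <= N_BASES) for b in self.u):
            raise ValueError(f"u must hold {self.k} basis ids in 1..{N_BASES}")
        for o, rows in self.interaction_sets.items():
            for row in rows:
                if len(set(row)) != o or tuple(sorted(row)) != tuple(row) or not all(0 <= i < self.k for i in row):
                    raise ValueError(f"invalid order-{o} interaction row {row}")

    @property
    def is_dense(self) -> bool:
        return all(
            len(self.interaction_sets.get(o, ())) == _n_choose(self.k, o)
            for o in range(2, self.n + 1)
        )

    def to_json(self) -> dict:
        return {"k": self.k, "u": list(self.u), "n": self.n, "seed": self.seed, "sparsity": self.sparsity}

    @classmethod
    def from_json(cls, obj: dict) -> "MetaFunctionSpec":
        """Rebuild a spec; interaction sets are regenerated deterministically."""
        spec = cls(
            k=int(obj["k"]), u=tuple(int(b) for b in obj["u"]), n=int(obj["n"]),
            interaction_sets=_dense_sets(int(obj["k"]), int(obj["n"])),
            seed=obj.get("seed"), sparsity=float(obj.get("sparsity", 1.0)),
        )
        if spec.sparsity < 1.0:
            rng = np.random.default_rng(spec.seed)
            spec.interaction_sets = _sparsify(spec.interaction_sets, spec.sparsity, rng)
        return spec


def _n_choose(k: int, o: int) -> int:
    from math import comb
    return comb(k, o)


def _dense_sets(k: int, n: int) -> dict[int, list[tuple[int, ...]]]:
    return {o: list(itertools.combinations(range(k), o)) for o in range(2, n + 1)}


def _sparsify(sets: dict, fraction: float, rng: np.random.Generator) -> dict:
    out = {}
    for o, rows in sets.items():
        m = max(1, int(round(fraction * len(rows))))
        idx = sorted(rng.choice(len(rows), size=m, replace=False))
        out[o] = [rows[i] for i in idx]
    return out


def sample_metafunction(
    k: int,
    n: int | None = None,
    rng: np.random.Generator | int | None = None,
    sparsity: float = 1.0,
) -> MetaFunctionSpec:
    """Draw a random metafunction: basis ids uniform on 1..13, all C(k, o)
    subsets active for o <= n.  With ``n=None`` ("random-n" mode) the highest
    active order is drawn uniformly on {1, .., k}."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = rng
        rng = np.random.default_rng(rng)
    if n is None:
        n = int(rng.integers(1, k + 1))
    if not (1 <= n <= k):
        raise ValueError(f"need 1 <= n <= k, got n={n}, k={k}")
    u = tuple(int(b) for b in rng.integers(1, N_BASES + 1, size=k))
    sets = _dense_sets(k, n)
    if sparsity < 1.0:
        sets = _sparsify(sets, sparsity, rng)
    return MetaFunctionSpec(k=k, u=u, n=n, interaction_sets=sets, seed=seed, sparsity=sparsity)


def evaluate_metafunction(spec: MetaFunctionSpec, X: np.ndarray) -> np.ndarray:
    """Evaluate the metafunction row-wise on points in [0, 1]^k."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != spec.k:
        raise ValueError(f"points have {X.shape[1]} columns but spec has k={spec.k}")
    if np.any(X < 0.0) or np.any(X > 1.0):
        raise ValueError("points must lie in the unit hypercube [0, 1]^k")
    # Per-input basis values, shared by first-order and interaction terms.
    G = np.column_stack([basis_function(spec.u[i], X[:, i]) for i in range(spec.k)])

    if spec.coefficients is None and spec.is_dense:
        # Dense case: sum over all subsets of size <= n of row-wise products
        # = e_1 + ... + e_n of the basis values (elementary symmetric DP).
        n = spec.n
        E = np.zeros((X.shape[0], n + 1))
        E[:, 0] = 1.0
        for i in range(spec.k):
            top = min(n, i + 1)
            for o in range(top, 0, -1):
                E[:, o] += E[:, o - 1] * G[:, i]
        return E[:, 1:].sum(axis=1)

    # Sparse or weighted case: explicit term enumeration.
    y = G.sum(axis=1)
    for o in range(2, spec.n + 1):
        rows = spec.interaction_sets.get(o, [])
        coefs = None if spec.coefficients is None else spec.coefficients.get(o)
        for t, u_row in enumerate(rows):
            term = np.prod(G[:, list(u_row)], axis=1)
            y = y + (term if coefs is None else coefs[t] * term)
    return y
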