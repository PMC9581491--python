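"""Quasi-random sampling designs for variance-based sensitivity analysis.

The estimation scheme evaluates the model on a base Sobol' matrix ``Q`` of
dimension (N, 2k), split into left/right halves ``A`` and ``B``, plus derived
matrices in which single columns (``AB(i)``, ``BA(i)``) or whole column blocks
(``AB(u)`` for a subset ``u``) of ``A`` are replaced by the corresponding
columns of ``B``.  Marginal distributions are applied column-wise by the
inverse-CDF transform.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.stats import qmc

__all__ = [
    "MarginalSpec",
    "SampleDesign",
    "build_design",
    "apply_marginals",
    "evaluate_on_design",
    "split_outputs",
    "export_design",
    "import_outputs",
]

_MARGINAL_KINDS = {"uniform", "normal", "lognormal", "beta", "discrete", "constant"}


@dataclass(frozen=True)
class MarginalSpec:
    """One parameter's marginal distribution, in natural units.

    Parameters by kind:
      uniform:   low, high
      normal:    mean, sd
      lognormal: mu, sigma     (log-scale location/scale)
      beta:      a, b          (optionally low, high for an affine rescale)
      discrete:  values, weights (weights sum to 1)
      constant:  value
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _MARGINAL_KINDS:
            raise ValueError(f"unknown marginal kind {self.kind!r}; expected one of {sorted(_MARGINAL_KINDS)}")
        p = self.params
        if self.kind == "uniform":
            if not p.get("high", 1.0) > p.get("low", 0.0):
                raise ValueError("uniform marginal requires high > low")
        elif self.kind == "normal":
            if not p.get("sd", 1.0) > 0:
                raise ValueError("normal marginal requires sd > 0")
        elif self.kind == "lognormal":
            if not p.get("sigma", 1.0) > 0:
                raise ValueError("lognormal marginal requires sigma > 0")
        elif self.kind == "beta":
            if not (p.get("a", 1.0) > 0 and p.get("b", 1.0) > 0):
                raise ValueError("beta marginal requires a > 0 and b > 0")
        elif self.kind == "discrete":
            values = p.get("values")
            weights = p.get("weights")
            if not values or not weights or len(values) != len(weights):
                raise ValueError("discrete marginal requires matching values and weights")
            w = np.asarray(weights, dtype=float)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
                raise ValueError("discrete weights must be non-negative and sum to 1 within 1e-12")
        elif self.kind == "constant":
            if "value" not in p:
                raise ValueError("constant marginal requires a value")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Inverse cumulative distribution applied to uniforms in [0, 1)."""
        u = np.asarray(u, dtype=float)
        p = self.params
        if self.kind == "uniform":
            low, high = p.get("low", 0.0), p.get("high", 1.0)
            return low + (high - low) * u
        if self.kind == "normal":
            return stats.norm.ppf(u, loc=p.get("mean", 0.0), scale=p.get("sd", 1.0))
        if self.kind == "lognormal":
            return stats.lognorm.ppf(u, s=p.get("sigma", 1.0), scale=math.exp(p.get("mu", 0.0)))
        if self.kind == "beta":
            x = stats.beta.ppf(u, p.get("a", 1.0), p.get("b", 1.0))
            low, high = p.get("low", 0.0), p.get("high", 1.0)
            return low + (high - low) * x
        if self.kind == "discrete":
            # Partition [0,1) by cumulative weights; half-open intervals.
            cum = np.cumsum(p["weights"])
            idx = np.searchsorted(cum, u, side="right")
            idx = np.minimum(idx, len(p["values"]) - 1)
            return np.asarray(p["values"], dtype=float)[idx]
        # constant
        return np.full_like(u, float(p["value"]))


@dataclass
class SampleDesign:
    """The base quasi-random matrix and its swapped-column derivatives.

    ``AB[i]`` equals ``A`` except column ``i``, which comes from ``B`` (and
    symmetrically for ``BA[i]``).  ``swapped_subsets[u]`` equals ``A`` except
    the columns indexed by the sorted tuple ``u`` (0-based), which come from
    ``B``.  All matrices are (N, k); untransformed entries lie in [0, 1).
    """

    N: int
    k: int
    base: np.ndarray                      # (N, 2k)
    A: np.ndarray                         # (N, k)
    B: np.ndarray                         # (N, k)
    AB: list[np.ndarray]                  # k matrices
    BA: list[np.ndarray]                  # k matrices
    swapped_subsets: dict[tuple[int, ...], np.ndarray] = field(default_factory=dict)
    swapped_subsets_ba: dict[tuple[int, ...], np.ndarray] = field(default_factory=dict)
    transformed: bool = False
    scramble_seed: int | None = None

    @property
    def subset_orders(self) -> tuple[int, ...]:
        return tuple(sorted({len(u) for u in self.swapped_subsets}))

    @property
    def evaluation_budget(self) -> int:
        """Total model-run count: N·(2 + 2k + Σ_o C(k, o)), plus another
        N·Σ_o C(k, o) when the BA-side subset matrices were requested."""
        return self.N * (2 + 2 * self.k + len(self.swapped_subsets) + len(self.swapped_subsets_ba))

    def matrices_in_order(self) -> list[tuple[str, np.ndarray]]:
        """Named matrices in canonical evaluation order: A, B, AB(1..k),
        BA(1..k), AB-subsets lexicographically, then BA-subsets if present."""
        out: list[tuple[str, np.ndarray]] = [("A", self.A), ("B", self.B)]
        out += [(f"AB_{i + 1}", self.AB[i]) for i in range(self.k)]
        out += [(f"BA_{i + 1}", self.BA[i]) for i in range(self.k)]
        for u in sorted(self.swapped_subsets):
            name = "AB_" + "_".join(str(i + 1) for i in u)
            out.append((name, self.swapped_subsets[u]))
        for u in sorted(self.swapped_subsets_ba):
            name = "BA_" + "_".join(str(i + 1) for i in u)
            out.append((name, self.swapped_subsets_ba[u]))
        return out

    def stacked(self) -> np.ndarray:
        """All matrices stacked row-wise in canonical order."""
        return np.vstack([m for _, m in self.matrices_in_order()])


def _is_power_of_two(n: int) -> bool:
    return n > 0 and (n & (n - 1)) == 0


def build_design(
    N: int,
    k: int,
    subset_orders: Sequence[int] = (),
    scramble_seed: int | None = None,
    subset_sides: str = "ab",
) -> SampleDesign:
    """Build the (N, 2k) Sobol' base matrix and every swapped-column matrix.

    By default the sequence is unscrambled and the leading all-zeros point is
    dropped (it breaks inverse-CDF transforms at distribution bounds).  Pass
    ``scramble_seed`` for Owen-scrambled points.  ``subset_orders`` requests
    block-swapped matrices AB(u) for every subset u of each given size
    (2 and/or 3), used for closed second/third-order indices.

    ``subset_sides="both"`` additionally builds the mirrored BA(u) matrices,
    doubling the subset evaluation budget but allowing closed subset indices
    to be estimated with the full paired-matrix (ratio-form) estimator, whose
    error is several times smaller than the one-sided correlation form.
    """
    if subset_sides not in ("ab", "both"):
        raise ValueError(f"subset_sides must be 'ab' or 'both', got {subset_sides!r}")
    if not (isinstance(N, (int, np.integer)) and N >= 2):
        raise ValueError(f"N must be an integer >= 2, got {N!r}")
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError(f"k must be a positive integer, got {k!r}")
    subset_orders = tuple(sorted(set(int(o) for o in subset_orders)))
    for o in subset_orders:
        if o not in (2, 3):
            raise ValueError(f"subset orders must be in {{2, 3}}, got {o}")
        if o > k:
            raise ValueError(f"subset order {o} exceeds the number of parameters k={k}")
    if not _is_power_of_two(N):
        warnings.warn(
            f"N={N} is not a power of 2; Sobol' designs lose balance properties",
            UserWarning,
            stacklevel=2,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # scipy balance warning; ours above
        if scramble_seed is None:
            sob = qmc.Sobol(d=2 * k, scramble=False)
            base = sob.random(N + 1)[1:]  # drop the all-zeros first point
        else:
            sob = qmc.Sobol(d=2 * k, scramble=True, rng=int(scramble_seed))
            base = sob.random(N)

    A = base[:, :k].copy()
    B = base[:, k:].copy()
    AB, BA = [], []
    for i in range(k):
        m = A.copy()
        m[:, i] = B[:, i]
        AB.append(m)
        m = B.copy()
        m[:, i] = A[:, i]
        BA.append(m)
    swapped: dict[tuple[int, ...], np.ndarray] = {}
    swapped_ba: dict[tuple[int, ...], np.ndarray] = {}
    for o in subset_orders:
        for u in itertools.combinations(range(k), o):
            m = A.copy()
            m[:, list(u)] = B[:, list(u)]
            swapped[u] = m
            if subset_sides == "both":
                m = B.copy()
                m[:, list(u)] = A[:, list(u)]
                swapped_ba[u] = m
    return SampleDesign(
        N=int(N), k=int(k), base=base, A=A, B=B, AB=AB, BA=BA,
        swapped_subsets=swapped, swapped_subsets_ba=swapped_ba,
        transformed=False, scramble_seed=scramble_seed,
    )


def apply_marginals(design: SampleDesign, marginals: Sequence[MarginalSpec]) -> SampleDesign:
    """Map every column of every matrix through its marginal's inverse CDF.

    Returns a new design flagged ``transformed``; the input is not modified.
    """
    if design.transformed:
        raise ValueError("design is already transformed")
    if len(marginals) != design.k:
        raise ValueError(f"expected {design.k} marginals, got {len(marginals)}")

    def tr(m: np.ndarray) -> np.ndarray:
        cols = [marginals[j].ppf(m[:, j]) for j in range(design.k)]
        return np.column_stack(cols)

    base = np.hstack([tr(design.base[:, : design.k]), tr(design.base[:, design.k:])])
    return replace(
        design,
        base=base,
        A=tr(design.A),
        B=tr(design.B),
        AB=[tr(m) for m in design.AB],
        BA=[tr(m) for m in design.BA],
        swapped_subsets={u: tr(m) for u, m in design.swapped_subsets.items()},
        swapped_subsets_ba={u: tr(m) for u, m in design.swapped_subsets_ba.items()},
        transformed=True,
    )


def evaluate_on_design(f: Callable[[np.ndarray], np.ndarray], design: SampleDesign) -> dict:
    """Run a row-wise model over every matrix; returns the split output dict
    accepted by the estimators (keys yA, yB, yAB, yBA, y_subsets)."""
    y = np.asarray(f(design.stacked()), dtype=float).ravel()
    return split_outputs(design, y)


def split_outputs(design: SampleDesign, y: np.ndarray) -> dict:
    """Split a concatenated output vector back into per-matrix vectors.

    ``y`` must follow the canonical evaluation order of
    :meth:`SampleDesign.matrices_in_order`.
    """
    y = np.asarray(y, dtype=float).ravel()
    n_ab = len(design.swapped_subsets)
    n_mats = 2 + 2 * design.k + n_ab + len(design.swapped_subsets_ba)
    if y.size != n_mats * design.N:
        raise ValueError(
            f"output length {y.size} does not match budget {n_mats * design.N} "
            f"(= {n_mats} matrices x N={design.N})"
        )
    blocks = y.reshape(n_mats, design.N)
    k = design.k
    out = {
        "yA": blocks[0],
        "yB": blocks[1],
        "yAB": [blocks[2 + i] for i in range(k)],
        "yBA": [blocks[2 + k + i] for i in range(k)],
        "y_subsets": {},
        "y_subsets_ba": {},
    }
    for j, u in enumerate(sorted(design.swapped_subsets)):
        out["y_subsets"][u] = blocks[2 + 2 * k + j]
    for j, u in enumerate(sorted(design.swapped_subsets_ba)):
        out["y_subsets_ba"][u] = blocks[2 + 2 * k + n_ab + j]
    return out


def export_design(design: SampleDesign, directory: str | Path) -> Path:
    """Write one CSV per matrix (columns x1..xk) plus a JSON sidecar.

    Model outputs are expected back as a single-column numeric CSV in the
    concatenated canonical row order.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = ",".join(f"x{j + 1}" for j in range(design.k))
    for name, m in design.matrices_in_order():
        np.savetxt(directory / f"{name}.csv", m, delimiter=",", header=header, comments="")
    sidecar = {
        "N": design.N,
        "k": design.k,
        "scramble_seed": design.scramble_seed,
        "subset_sides": "both" if design.swapped_subsets_ba else "ab",
        "subsets": [[i + 1 for i in u] for u in sorted(design.swapped_subsets)],
        "transformed": design.transformed,
        "matrix_order": [name for name, _ in design.matrices_in_order()],
        "evaluation_budget": design.evaluation_budget,
    }
    (directory / "design.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def import_outputs(design: SampleDesign, path: str | Path) -> dict:
    """Read a single-column outputs CSV (canonical row order) and split it."""
    y = np.loadtxt(path, delimiter=",", ndmin=1)
    if y.ndim > 1:
        y = y.ravel()
    return split_outputs(design, y)
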