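"""Variance-based sensitivity index estimators.

First- and total-order indices use the Azzini paired-matrix estimators

    S_i = 2 Σ_v (yBA_i − yB)(yA − yAB_i)
          ─────────────────────────────────────────
          Σ_v [(yA − yB)² + (yBA_i − yAB_i)²]

    T_i = Σ_v [(yB − yBA_i)² + (yA − yAB_i)²]
          ─────────────────────────────────────────
          Σ_v [(yA − yB)² + (yBA_i − yAB_i)²]

Closed indices of parameter subsets come from block-swapped matrices AB(u)
via the correlation-form estimator V_u = E[yB·(yAB(u) − yA)]; pure
interaction indices follow by inclusion–exclusion.  Estimates are stored raw
(they may leave [0,1] by Monte Carlo error) and are only clipped downstream,
inside effective-dimension summation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateOutputError, MissingSubsetError, NearZeroMeanError
from .sampling import SampleDesign, evaluate_on_design

__all__ = [
    "SensitivityIndices",
    "estimate_first_order",
    "estimate_total_order",
    "estimate_interactions",
    "estimate_indices",
    "coefficient_of_variation",
]


@dataclass
class SensitivityIndices:
    """Estimated variance fractions for one model output.

    ``interactions`` maps a sorted 0-based index tuple to the pure interaction
    index (closed minus all contained lower-order effects); ``closed`` maps the
    same tuples to the closed index of the subset.  The inclusion–exclusion
    identity holds exactly on the stored values, by construction.
    """

    first_order: np.ndarray
    total_order: np.ndarray | None = None
    interactions: dict[tuple[int, ...], float] = field(default_factory=dict)
    closed: dict[tuple[int, ...], float] = field(default_factory=dict)
    output_variance: float = float("nan")
    N_effective: int = 0

    @property
    def k(self) -> int:
        return len(self.first_order)

    def sum_by_order(self, order: int, clip: bool = True) -> float:
        """Sum of stored indices of the given interaction order (1, 2 or 3).

        With ``clip`` the *sum* is floored at zero: slightly negative index
        estimates are Monte Carlo noise, and clipping each term separately
        would bias the sum upward by the folded noise of every subset, while
        the order-level floor keeps cumulative sums monotone without that
        bias.
        """
        if order == 1:
            vals = np.asarray(self.first_order, dtype=float)
        else:
            vals = np.array([v for u, v in self.interactions.items() if len(u) == order], dtype=float)
        total = float(vals.sum())
        return max(0.0, total) if clip else total

    def available_orders(self) -> tuple[int, ...]:
        orders = {1} | {len(u) for u in self.interactions}
        return tuple(sorted(orders))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: subset, order, index_type, estimate (1-based labels)."""
        rows = []
        for i, s in enumerate(self.first_order):
            rows.append((str(i + 1), 1, "Si", float(s)))
        if self.total_order is not None:
            for i, t in enumerate(self.total_order):
                rows.append((str(i + 1), 1, "Ti", float(t)))
        for u in sorted(self.closed):
            label = ",".join(str(i + 1) for i in u)
            rows.append((label, len(u), "Sij_closed" if len(u) == 2 else "Sijl_closed", self.closed[u]))
        for u in sorted(self.interactions):
            label = ",".join(str(i + 1) for i in u)
            rows.append((label, len(u), "Sij" if len(u) == 2 else "Sijl", self.interactions[u]))
        return pd.DataFrame(rows, columns=["subset", "order", "index_type", "estimate"])


def _as_vectors(yA, yB, yAB, yBA) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    yA = np.asarray(yA, dtype=float).ravel()
    yB = np.asarray(yB, dtype=float).ravel()
    yAB = np.atleast_2d(np.asarray(yAB, dtype=float))
    yBA = np.atleast_2d(np.asarray(yBA, dtype=float))
    N = yA.size
    if yB.size != N or yAB.shape[1] != N or yBA.shape[1] != N or yAB.shape[0] != yBA.shape[0]:
        raise ValueError("output vectors must all have the same length N and one row per parameter")
    if N < 2:
        raise ValueError("need at least N=2 rows per matrix")
    return yA, yB, yAB, yBA


def _denominator(yA, yB, yAB, yBA) -> np.ndarray:
    den = ((yA - yB) ** 2).sum() + ((yBA - yAB) ** 2).sum(axis=1)
    if np.any(den <= 0.0):
        raise DegenerateOutputError(
            "zero pooled output variance (constant model output); sensitivity indices are undefined"
        )
    return den


def estimate_first_order(yA, yB, yAB, yBA) -> np.ndarray:
    """Azzini first-order indices S_i, one per parameter; returned unclipped."""
    yA, yB, yAB, yBA = _as_vectors(yA, yB, yAB, yBA)
    num = 2.0 * ((yBA - yB[None, :]) * (yA[None, :] - yAB)).sum(axis=1)
    return num / _denominator(yA, yB, yAB, yBA)


def estimate_total_order(yA, yB, yAB, yBA) -> np.ndarray:
    """Azzini total-order indices T_i, one per parameter; returned unclipped."""
    yA, yB, yAB, yBA = _as_vectors(yA, yB, yAB, yBA)
    num = ((yB[None, :] - yBA) ** 2).sum(axis=1) + ((yA[None, :] - yAB) ** 2).sum(axis=1)
    return num / _denominator(yA, yB, yAB, yBA)


def estimate_interactions(
    yA,
    yB,
    y_subsets: Mapping[tuple[int, ...], np.ndarray],
    subsets: Sequence[tuple[int, ...]],
    first_order: np.ndarray,
    y_subsets_ba: Mapping[tuple[int, ...], np.ndarray] | None = None,
) -> tuple[dict[tuple[int, ...], float], dict[tuple[int, ...], float]]:
    """Closed and pure interaction indices for the requested subsets.

    The closed index of subset u comes from the block-swapped outputs: with
    both AB(u) and BA(u) available (``y_subsets_ba``), the paired ratio-form
    estimator (the block generalisation of the first-order formula) is used —
    its numerator and denominator share sampling error, which largely
    cancels.  With only AB(u), the one-sided correlation estimator
    V_u = E[yB·(yAB(u) − yA)] normalised by the pooled variance is the
    fallback.

    Pairs: S_ij = closed(i,j) − S_i − S_j.  Triplets subtract the three
    contained pure pairs (which must therefore also be requested) and the
    three first-order terms.  Returns ``(interactions, closed)``.
    """
    yA = np.asarray(yA, dtype=float).ravel()
    yB = np.asarray(yB, dtype=float).ravel()
    first_order = np.asarray(first_order, dtype=float)
    pooled = np.concatenate([yA, yB])
    variance = float(np.var(pooled, ddof=1))
    if variance <= 0.0:
        raise DegenerateOutputError("zero pooled output variance; interaction indices are undefined")
    y_subsets_ba = y_subsets_ba or {}

    subsets = [tuple(sorted(u)) for u in subsets]
    closed: dict[tuple[int, ...], float] = {}
    for u in subsets:
        if u not in y_subsets:
            raise MissingSubsetError(f"subset {tuple(i + 1 for i in u)} has no swapped matrix in the design")
        yABu = np.asarray(y_subsets[u], dtype=float).ravel()
        if u in y_subsets_ba:
            yBAu = np.asarray(y_subsets_ba[u], dtype=float).ravel()
            num = 2.0 * np.sum((yBAu - yB) * (yA - yABu))
            den = np.sum((yA - yB) ** 2) + np.sum((yBAu - yABu) ** 2)
            if den <= 0.0:
                raise DegenerateOutputError("zero pooled output variance; interaction indices are undefined")
            closed[u] = float(num / den)
        else:
            closed[u] = float(np.mean(yB * (yABu - yA)) / variance)

    interactions: dict[tuple[int, ...], float] = {}
    for u in sorted(subsets, key=len):
        if len(u) == 2:
            i, j = u
            interactions[u] = closed[u] - first_order[i] - first_order[j]
        elif len(u) == 3:
            pairs = [(u[0], u[1]), (u[0], u[2]), (u[1], u[2])]
            for p in pairs:
                if p not in interactions:
                    raise MissingSubsetError(
                        f"triplet {tuple(i + 1 for i in u)} requires its contained pairs to be estimated"
                    )
            interactions[u] = (
                closed[u]
                - sum(interactions[p] for p in pairs)
                - sum(first_order[i] for i in u)
            )
        else:
            raise ValueError("only subsets of size 2 or 3 are supported")
    return interactions, closed


def estimate_indices(design: SampleDesign, f=None, outputs: dict | None = None) -> SensitivityIndices:
    """End-to-end estimation on a design: pass either a row-wise callable ``f``
    or a pre-split ``outputs`` dict (from :func:`effdim.sampling.split_outputs`)."""
    if (f is None) == (outputs is None):
        raise ValueError("pass exactly one of f or outputs")
    if outputs is None:
        outputs = evaluate_on_design(f, design)
    yA, yB = outputs["yA"], outputs["yB"]
    yAB = np.vstack(outputs["yAB"])
    yBA = np.vstack(outputs["yBA"])
    S = estimate_first_order(yA, yB, yAB, yBA)
    T = estimate_total_order(yA, yB, yAB, yBA)
    pooled = np.concatenate([yA, yB])
    result = SensitivityIndices(
        first_order=S,
        total_order=T,
        output_variance=float(np.var(pooled, ddof=1)),
        N_effective=int(yA.size),
    )
    subsets = sorted(outputs.get("y_subsets", {}), key=lambda u: (len(u), u))
    if subsets:
        interactions, closed = estimate_interactions(
            yA, yB, outputs["y_subsets"], subsets, S,
            y_subsets_ba=outputs.get("y_subsets_ba"),
        )
        result.interactions = interactions
        result.closed = closed
    return result


def coefficient_of_variation(y, rel_floor: float = 1e-9) -> float:
    """Sample standard deviation over sample mean (ddof=1).

    Raises :class:`NearZeroMeanError` when |mean| < rel_floor·sd (or both are
    exactly zero): the CV is then numerically meaningless as an uncertainty
    proxy and an alternative dispersion measure should be used.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need at least two output values")
    m = float(np.mean(y))
    s = float(np.std(y, ddof=1))
    if s <= abs(m) * 1e-12:  # constant vector up to float rounding
        s = 0.0
    if abs(m) < rel_floor * s or (m == 0.0 and s == 0.0):
        raise NearZeroMeanError(
            f"output mean {m:.3g} is within {rel_floor:g} of zero relative to sd {s:.3g}; "
            "CV is not a meaningful dispersion measure here"
        )
    return s / m
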