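"""Population-of-models experiments.

Two sweeps link model complexity to output uncertainty:

* ``run_g_randomization`` — draw many G functions with randomized
  coefficients, estimate indices through order 3 on a quasi-random design,
  and record (k, k_t, k_s, order-wise index sums, CV) per simulation.
* ``run_metamodel_sweep`` — draw many random metafunctions across model
  dimensionalities k and highest active interaction orders n, recording the
  output CV per draw; summarised as median and SD per (k, n) cell.

Every record is a pure function of (config, seed): per-simulation generators
are spawned from one seed sequence, and the unscrambled quasi-random design
is cached per (N, k) since it carries no randomness of its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effective_dimension import effective_dimensions
from .errors import DegenerateOutputError, NearZeroMeanError
from .estimators import coefficient_of_variation, estimate_indices
from .metamodel import MetaFunctionSpec, evaluate_metafunction, sample_metafunction
from .metamodel import _dense_sets


def _respec(k: int, u: tuple[int, ...], n: int) -> MetaFunctionSpec:
    """A metafunction with a fixed basis assignment truncated at order n."""
    return MetaFunctionSpec(k=k, u=u, n=n, interaction_sets=_dense_sets(k, n))
from .sampling import build_design, evaluate_on_design
from .test_functions import sample_g_coefficients, sobol_g

__all__ = ["run_g_randomization", "run_metamodel_sweep", "summarize_sweep"]

RECORD_COLUMNS = [
    "sim_id", "k", "n_active", "k_t", "k_s", "k_s_coded",
    "sum_Si", "sum_Sij", "sum_Sijl", "CV", "excluded", "seed", "N",
]


class _DesignCache:
    def __init__(self, subset_orders=(2, 3), subset_sides="both"):
        self.subset_orders = subset_orders
        self.subset_sides = subset_sides
        self._cache: dict[tuple[int, int], object] = {}

    def get(self, N: int, k: int):
        key = (N, k)
        if key not in self._cache:
            orders = tuple(o for o in self.subset_orders if o <= k)
            self._cache[key] = build_design(N, k, subset_orders=orders,
                                            subset_sides=self.subset_sides)
        return self._cache[key]


def run_g_randomization(
    n_sims: int,
    N: int = 2 ** 10,
    k_range: tuple[int, ...] = (),
    seed: int | None = None,
    p: float = 0.99,
    q: float = 0.05,
) -> pd.DataFrame:
    """Randomize G-function coefficients ``n_sims`` times and audit each draw.

    Per simulation: draw k uniformly from ``k_range``, draw coefficients from
    {0, 1, 4.5, 9, 99} with weights {.4, .3, .2, .05, .05}, estimate indices
    through order 3 at sample size ``N``, and record k_t, k_s, the order-wise
    index sums, and the output CV.
    """
    if n_sims < 0:
        raise ValueError("n_sims must be >= 0")
    k_range = tuple(int(k) for k in k_range)
    if n_sims > 0 and not k_range:
        raise ValueError("k_range must be non-empty")
    cache = _DesignCache(subset_orders=(2, 3))
    children = np.random.SeedSequence(seed).spawn(n_sims)
    rows = []
    for sim_id, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        k = int(rng.choice(k_range))
        spec = sample_g_coefficients(k, rng)
        design = cache.get(N, k)
        outputs = evaluate_on_design(lambda X: sobol_g(X, spec), design)
        indices = estimate_indices(design, outputs=outputs)
        dims = effective_dimensions(indices, p=p, q=q)
        pooled = np.concatenate([outputs["yA"], outputs["yB"]])
        try:
            cv = coefficient_of_variation(pooled)
            excluded = False
        except NearZeroMeanError:
            cv, excluded = float("nan"), True
        rows.append(dict(
            sim_id=sim_id, k=k, n_active=np.nan,
            k_t=dims.k_t, k_s=dims.k_s.label, k_s_coded=dims.k_s.coded,
            sum_Si=indices.sum_by_order(1),
            sum_Sij=indices.sum_by_order(2),
            sum_Sijl=indices.sum_by_order(3),
            CV=cv, excluded=excluded, seed=seed, N=N,
        ))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def run_metamodel_sweep(
    mode: str,
    N: int = 2 ** 11,
    k_range: tuple[int, ...] | None = None,
    k_fixed: int = 15,
    n_grid: tuple[int, ...] | None = None,
    reps: int = 30,
    seed: int | None = None,
    estimate_dims: bool = False,
    p: float = 0.99,
    q: float = 0.05,
    paired: bool = False,
) -> pd.DataFrame:
    """Sweep random metafunctions over dimensionality/interaction order.

    Modes:
      ``vary-k-random-n``  — for each k in ``k_range``, ``reps`` draws with the
        highest active order n drawn uniformly on {1..k} (pass ``n_grid=(1,)``
        semantics by instead fixing n via ``fixed-k-vary-n``).
      ``fixed-k-vary-n``   — k = ``k_fixed``; for each n in ``n_grid``,
        ``reps`` random metafunctions with that exact highest order.

    CV is computed from the pooled A/B sample; draws whose output mean is too
    close to zero are flagged ``excluded`` and dropped by the summary view.
    With ``estimate_dims=True`` each draw additionally gets indices through
    order min(3, k) and its (k_t, k_s).

    ``paired=True`` (``fixed-k-vary-n`` only) applies common random numbers
    across the n grid: each replicate draws one basis assignment and re-uses
    it at every n, so the summary isolates the effect of activating
    interaction orders from the sampling of functional forms.
    """
    if mode not in ("vary-k-random-n", "fixed-k-vary-n"):
        raise ValueError(f"unknown mode {mode!r}")
    if reps < 0:
        raise ValueError("reps must be >= 0")
    if mode == "vary-k-random-n":
        if not k_range:
            raise ValueError("k_range must be non-empty in mode vary-k-random-n")
        cells = [(int(k), None) for k in k_range]
    else:
        if not n_grid:
            raise ValueError("n_grid must be non-empty in mode fixed-k-vary-n")
        if any(n > k_fixed for n in n_grid):
            raise ValueError("n_grid entries must not exceed k_fixed")
        cells = [(int(k_fixed), int(n)) for n in n_grid]

    if paired and mode != "fixed-k-vary-n":
        raise ValueError("paired draws require mode fixed-k-vary-n")

    subset_orders = (2, 3) if estimate_dims else ()
    cache = _DesignCache(subset_orders=subset_orders)
    rows = []
    sim_id = 0
    if paired:
        # one basis assignment per replicate, re-used at every n in the grid
        paired_bases = [
            sample_metafunction(k_fixed, n=k_fixed, rng=np.random.default_rng(ss)).u
            for ss in np.random.SeedSequence(seed).spawn(reps)
        ]
    else:
        children = np.random.SeedSequence(seed).spawn(len(cells) * reps)

    for k, n in cells:
        design = cache.get(N, k)
        for rep in range(reps):
            if paired:
                spec = _respec(k, paired_bases[rep], n)
            else:
                rng = np.random.default_rng(children[sim_id])
                spec = sample_metafunction(k, n=n, rng=rng)
            record = dict(
                sim_id=sim_id, k=k, n_active=spec.n,
                k_t=np.nan, k_s="", k_s_coded=np.nan,
                sum_Si=np.nan, sum_Sij=np.nan, sum_Sijl=np.nan,
                CV=np.nan, excluded=False, seed=seed, N=N,
            )
            if estimate_dims:
                outputs = evaluate_on_design(lambda X: evaluate_metafunction(spec, X), design)
                try:
                    indices = estimate_indices(design, outputs=outputs)
                except DegenerateOutputError:
                    # e.g. every input drew the "no effect" basis
                    record["excluded"] = True
                    rows.append(record)
                    sim_id += 1
                    continue
                dims = effective_dimensions(indices, p=p, q=q)
                record.update(
                    k_t=dims.k_t, k_s=dims.k_s.label, k_s_coded=dims.k_s.coded,
                    sum_Si=indices.sum_by_order(1),
                    sum_Sij=indices.sum_by_order(2) if 2 in indices.available_orders() else np.nan,
                    sum_Sijl=indices.sum_by_order(3) if 3 in indices.available_orders() else np.nan,
                )
                pooled = np.concatenate([outputs["yA"], outputs["yB"]])
            else:
                # CV only: the pooled A/B sample suffices, no swapped matrices.
                yA = evaluate_metafunction(spec, design.A)
                yB = evaluate_metafunction(spec, design.B)
                pooled = np.concatenate([yA, yB])
            try:
                record["CV"] = coefficient_of_variation(pooled)
            except NearZeroMeanError:
                record["excluded"] = True
            rows.append(record)
            sim_id += 1
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def summarize_sweep(records: pd.DataFrame) -> pd.DataFrame:
    """Median and SD of CV per (k, n_active) cell, excluding flagged draws.

    Columns: k, n, median_CV, sd_CV, n_records, n_excluded.
    """
    rows = []
    for (k, n), cell in records.groupby(["k", "n_active"], dropna=False):
        good = cell.loc[~cell["excluded"]]
        rows.append(dict(
            k=k, n=n,
            median_CV=float(good["CV"].median()) if len(good) else float("nan"),
            sd_CV=float(good["CV"].std(ddof=1)) if len(good) > 1 else float("nan"),
            n_records=int(len(cell)),
            n_excluded=int(cell["excluded"].sum()),
        ))
    return pd.DataFrame(rows, columns=["k", "n", "median_CV", "sd_CV", "n_records", "n_excluded"])
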