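"""Case-study model families for effective-dimension audits.

Three families illustrate how complexity added at successive upgrade stages
moves a model's effective dimensions and output uncertainty:

* a four-stage radionuclide transport chain (waste -> buffer -> geosphere ->
  biosphere) in the style of the PSACOIN Level 0 benchmark;
* a three-stage irrigation chain (reference evapotranspiration -> crop
  evapotranspiration -> water withdrawal) whose reference-ET equation can be
  left structurally uncertain via a trigger parameter;
* three nested SIR(S) epidemic ODE models with waning immunity and
  increasingly detailed vaccination structure.

The chain and SIRS parameterizations shipped here are synthetic templates:
they reproduce the structure of the benchmark families (stage layout, number
of uncertain inputs, trigger mechanism, compartment lists) with plausible
marginals, and are meant to be overwritten with a transcribed specification
when auditing the actual benchmark models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .effective_dimension import effective_dimensions
from .errors import ChainSpecError, IntegrationError, NearZeroMeanError
from .estimators import coefficient_of_variation, estimate_indices
from .sampling import MarginalSpec, SampleDesign, apply_marginals, build_design, split_outputs

__all__ = [
    "Compartment",
    "ChainSpec",
    "TriggerSpec",
    "SirsVariantSpec",
    "run_chain",
    "trigger_select",
    "integrate_sirs",
    "audit_chain",
    "audit_sirs",
    "audit_upgrades",
    "irrigation_chain",
    "psacoin_chain",
    "default_sirs_spec",
    "SIRS_VARIANTS",
]


# ---------------------------------------------------------------------------
# Compartmental chains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Compartment:
    """One chain stage: a deterministic map from consumed quantities (uncertain
    inputs, constants, upstream compartment outputs) to a scalar output."""

    name: str
    func: Callable[[Mapping[str, np.ndarray]], np.ndarray]
    consumes: tuple[str, ...]


@dataclass
class ChainSpec:
    """An ordered causal chain of compartments.

    ``inputs`` maps uncertain input names to their marginals (column order of
    the sampling design); every declared input must be consumed by at least
    one compartment, and a compartment may only consume declared inputs,
    constants, or upstream compartment outputs.
    """

    name: str
    inputs: dict[str, MarginalSpec]
    compartments: list[Compartment]
    constants: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.inputs) | set(self.constants)
        consumed: set[str] = set()
        for comp in self.compartments:
            for name in comp.consumes:
                if name not in known:
                    raise ChainSpecError(
                        f"compartment {comp.name!r} consumes undeclared quantity {name!r}"
                    )
                consumed.add(name)
            known.add(comp.name)
        unused = set(self.inputs) - consumed
        if unused:
            raise ChainSpecError(f"declared inputs never consumed: {sorted(unused)}")

    @property
    def k(self) -> int:
        return len(self.inputs)

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(self.inputs)

    @property
    def marginals(self) -> list[MarginalSpec]:
        return list(self.inputs.values())


def run_chain(chain: ChainSpec, design: SampleDesign | np.ndarray) -> dict[str, np.ndarray]:
    """Evaluate every compartment row-wise; returns one output vector per
    compartment (over the design's concatenated matrices, in canonical order,
    when a :class:`SampleDesign` is passed)."""
    if isinstance(design, SampleDesign):
        if not design.transformed:
            raise ChainSpecError("design must be transformed by the chain's marginals first")
        if design.k != chain.k:
            raise ChainSpecError(f"design has k={design.k} columns but chain declares {chain.k} inputs")
        X = design.stacked()
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        if X.shape[1] != chain.k:
            raise ChainSpecError(f"rows have {X.shape[1]} columns but chain declares {chain.k} inputs")
    env: dict[str, np.ndarray] = {name: X[:, j] for j, name in enumerate(chain.input_names)}
    for name, value in chain.constants.items():
        env[name] = np.full(X.shape[0], float(value))
    outputs: dict[str, np.ndarray] = {}
    for comp in chain.compartments:
        y = np.asarray(comp.func(env), dtype=float)
        env[comp.name] = y
        outputs[comp.name] = y
    return outputs


# ---------------------------------------------------------------------------
# Structural-uncertainty trigger
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriggerSpec:
    """An uncertain input on [0, 1) that selects among alternative equations.

    ``weights`` are option probabilities; selection partitions [0, 1) into
    half-open intervals by cumulative weight.
    """

    options: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.options) < 2:
            raise ChainSpecError("a trigger needs at least two options")
        w = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.options) or np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ChainSpecError("trigger weights must be positive and sum to 1")

    @property
    def cut_points(self) -> np.ndarray:
        return np.cumsum(self.weights)


def trigger_select(value, trig: TriggerSpec):
    """Map trigger values in [0, 1) to 0-based option indices.

    Intervals are half-open [low, high): a value exactly at a cut point
    selects the next option.  Vectorized over ``value``.
    """
    v = np.asarray(value, dtype=float)
    if np.any(v < 0.0) or np.any(v >= 1.0):
        raise ValueError("trigger values must lie in [0, 1)")
    idx = np.searchsorted(trig.cut_points, v, side="right")
    idx = np.minimum(idx, len(trig.options) - 1)
    return idx if idx.ndim else int(idx)


# ---------------------------------------------------------------------------
# Irrigation chain template (synthetic)
# ---------------------------------------------------------------------------

_GAMMA = 0.067       # psychrometric constant, kPa/degC
_ALPHA_PT = 1.74     # Priestley-Taylor coefficient, advective-condition value


def _slope_svp(t: np.ndarray) -> np.ndarray:
    """Slope of the saturation vapour pressure curve at air temperature t (degC)."""
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return 4098.0 * es / (t + 237.3) ** 2


def _et0_penman_monteith(env) -> np.ndarray:
    d = _slope_svp(env["tmean"])
    num = 0.408 * d * env["rn"] + _GAMMA * (900.0 / (env["tmean"] + 273.0)) * env["u2"] * env["vpd"]
    return num / (d + _GAMMA * (1.0 + 0.34 * env["u2"]))


def _et0_priestley_taylor(env) -> np.ndarray:
    d = _slope_svp(env["tmean"])
    return _ALPHA_PT * d / (d + _GAMMA) * 0.408 * env["rn"]


IRRIGATION_TRIGGER = TriggerSpec(options=("penman-monteith", "priestley-taylor"), weights=(0.5, 0.5))


def irrigation_chain(et0_mode: str = "uncertain") -> ChainSpec:
    """Synthetic irrigation water-withdrawal chain template.

    Three compartments: reference evapotranspiration ET0 (mm/day; computed by
    either a Penman-Monteith-type or a Priestley-Taylor-type template
    equation, the two known to disagree substantially), crop
    evapotranspiration ETc = Kc*ET0, and withdrawal = 10*ETc*area/efficiency
    (m^3/day).  ``et0_mode`` is "penman-monteith", "priestley-taylor", or
    "uncertain" (a trigger input picks the equation per simulation).
    """
    if et0_mode not in ("penman-monteith", "priestley-taylor", "uncertain"):
        raise ValueError(f"unknown et0_mode {et0_mode!r}")
    weather = {
        "tmean": MarginalSpec("uniform", {"low": 15.0, "high": 25.0}),   # degC
        "rn": MarginalSpec("uniform", {"low": 10.0, "high": 18.0}),      # MJ m-2 day-1
        "u2": MarginalSpec("uniform", {"low": 0.5, "high": 3.0}),        # m/s
        "vpd": MarginalSpec("uniform", {"low": 0.4, "high": 1.6}),       # kPa
    }
    downstream = {
        "kc": MarginalSpec("uniform", {"low": 0.9, "high": 1.3}),
        "area": MarginalSpec("uniform", {"low": 50.0, "high": 150.0}),   # ha
        "eff": MarginalSpec("uniform", {"low": 0.4, "high": 0.8}),
    }

    if et0_mode == "uncertain":
        inputs = dict(
            weather,
            trigger=MarginalSpec("uniform", {"low": 0.0, "high": 1.0}),
            **downstream,
        )

        def et0(env):
            choice = trigger_select(np.clip(env["trigger"], 0.0, np.nextafter(1.0, 0.0)), IRRIGATION_TRIGGER)
            return np.where(choice == 0, _et0_penman_monteith(env), _et0_priestley_taylor(env))

        et0_consumes = ("tmean", "rn", "u2", "vpd", "trigger")
    elif et0_mode == "penman-monteith":
        et0 = _et0_penman_monteith
        et0_consumes = ("tmean", "rn", "u2", "vpd")
        inputs = dict(weather, **downstream)
    else:  # priestley-taylor uses only temperature and radiation
        et0 = _et0_priestley_taylor
        et0_consumes = ("tmean", "rn")
        inputs = dict(
            {name: weather[name] for name in ("tmean", "rn")}, **downstream
        )

    compartments = [
        Compartment("et0", et0, et0_consumes),
        Compartment("etc", lambda env: env["kc"] * env["et0"], ("kc", "et0")),
        Compartment(
            "withdrawal",
            lambda env: 10.0 * env["etc"] * env["area"] / env["eff"],
            ("etc", "area", "eff"),
        ),
    ]
    return ChainSpec(name=f"irrigation[{et0_mode}]", inputs=inputs, compartments=compartments)


# ---------------------------------------------------------------------------
# Radionuclide transport chain template (synthetic)
# ---------------------------------------------------------------------------

def psacoin_chain() -> ChainSpec:
    """Synthetic four-stage radionuclide transport chain template.

    Mirrors the PSACOIN Level 0 layout — waste, buffer, geosphere, biosphere,
    with 10 uncertain inputs and a set of physical constants — but the
    marginals and constants are placeholder values, not the benchmark's
    specification; replace them with transcribed values to audit the actual
    benchmark.  The waste stage deliberately has a single uncertain input.
    """
    inputs = {
        "leach": MarginalSpec("lognormal", {"mu": math.log(1e-3), "sigma": 0.5}),  # 1/yr
        "t_buf": MarginalSpec("uniform", {"low": 50.0, "high": 500.0}),            # yr
        "kd_buf": MarginalSpec("lognormal", {"mu": math.log(10.0), "sigma": 0.8}),
        "velocity": MarginalSpec("lognormal", {"mu": math.log(5.0), "sigma": 0.7}),  # m/yr
        "length": MarginalSpec("uniform", {"low": 100.0, "high": 1000.0}),           # m
        "retard": MarginalSpec("lognormal", {"mu": math.log(50.0), "sigma": 0.9}),
        "disp": MarginalSpec("uniform", {"low": 0.1, "high": 10.0}),
        "dilution": MarginalSpec("lognormal", {"mu": math.log(1e6), "sigma": 1.0}),  # m^3/yr
        "ing_rate": MarginalSpec("uniform", {"low": 0.4, "high": 1.1}),              # m^3/yr
        "dcf": MarginalSpec("lognormal", {"mu": math.log(5e-8), "sigma": 0.6}),      # Sv/Bq
    }
    constants = {
        "inventory": 1e12,   # Bq
        "lam": 1e-4,         # decay constant, 1/yr
        "rho_b": 1.5,        # buffer bulk density
    }
    compartments = [
        Compartment("waste", lambda e: e["inventory"] * e["leach"], ("inventory", "leach")),
        Compartment(
            "buffer",
            lambda e: e["waste"] * np.exp(-e["lam"] * e["t_buf"]) / (1.0 + e["kd_buf"] * e["rho_b"]),
            ("waste", "lam", "t_buf", "kd_buf", "rho_b"),
        ),
        Compartment(
            "geosphere",
            lambda e: e["buffer"]
            * np.exp(-e["lam"] * e["length"] * e["retard"] / e["velocity"])
            / (1.0 + e["disp"]),
            ("buffer", "lam", "length", "retard", "velocity", "disp"),
        ),
        Compartment(
            "biosphere",
            lambda e: e["geosphere"] * e["ing_rate"] * e["dcf"] / e["dilution"],
            ("geosphere", "ing_rate", "dcf", "dilution"),
        ),
    ]
    return ChainSpec(name="psacoin-template", inputs=inputs, compartments=compartments, constants=constants)


# ---------------------------------------------------------------------------
# SIR(S) variants
# ---------------------------------------------------------------------------

SIRS_VARIANTS = ("SIR(S)", "SIR(S-V)", "SIR(S-E)")

_STATE_NAMES = {
    "SIR(S)": ("S_P", "I_P", "R", "S_S", "I_S"),
    "SIR(S-V)": ("S_P", "I_P", "R", "S_S", "I_S", "V"),
    "SIR(S-E)": (
        "S_P", "I_P", "R", "S_S", "I_S",
        "V1", "V2", "I_V", "S_S1", "S_S2", "I_S1", "I_S2",
    ),
}

_RATE_NAMES = {
    "SIR(S)": ("beta", "gamma", "delta", "eps", "alpha"),
    "SIR(S-V)": ("beta", "gamma", "delta", "eps", "alpha", "nu", "delta_v", "eps_v"),
    "SIR(S-E)": (
        "beta", "gamma", "delta", "eps", "alpha",
        "nu1", "nu2", "delta1", "delta2", "eps_v1", "eps_v2",
    ),
}


@dataclass
class SirsVariantSpec:
    """One of the three nested SIR(S)-family ODE models (fractions of a closed
    population; no demography, so total population is conserved).

    Shared states: fully susceptible S_P, primary infection I_P, recovered R,
    waned-immunity susceptible S_S, secondary infection I_S (transmits at the
    reduced rate alpha).  SIR(S-V) adds one vaccinated compartment V with
    waning and breakthrough infection; SIR(S-E) splits vaccination into one-
    and two-dose immunity (V1, V2), their waned classes (S_S1, S_S2) and the
    corresponding infections (I_V, I_S1, I_S2).
    """

    variant: str
    params: dict[str, MarginalSpec]
    t_grid: np.ndarray
    y0: np.ndarray
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if self.variant not in SIRS_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {SIRS_VARIANTS}")
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.y0 = np.asarray(self.y0, dtype=float)
        if np.any(np.diff(self.t_grid) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.y0 < 0):
            raise ValueError("initial state must be non-negative")
        if abs(self.y0.sum() - 1.0) > 1e-9:
            raise ValueError("initial state fractions must sum to 1")
        if tuple(self.params) != _RATE_NAMES[self.variant]:
            raise ValueError(f"variant {self.variant} requires rates {_RATE_NAMES[self.variant]}")

    @property
    def state_names(self) -> tuple[str, ...]:
        return _STATE_NAMES[self.variant]

    @property
    def rate_names(self) -> tuple[str, ...]:
        return _RATE_NAMES[self.variant]


def _rhs_sirs(t, y, p):
    S_P, I_P, R, S_S, I_S = y
    lam = p["beta"] * (I_P + p["alpha"] * I_S)
    return [
        -S_P * lam,
        S_P * lam - p["gamma"] * I_P,
        p["gamma"] * (I_P + I_S) - p["delta"] * R,
        p["delta"] * R - p["eps"] * S_S * lam,
        p["eps"] * S_S * lam - p["gamma"] * I_S,
    ]


def _rhs_sirs_v(t, y, p):
    S_P, I_P, R, S_S, I_S, V = y
    lam = p["beta"] * (I_P + p["alpha"] * I_S)
    return [
        -S_P * lam - p["nu"] * S_P,
        S_P * lam - p["gamma"] * I_P,
        p["gamma"] * (I_P + I_S) - p["delta"] * R,
        p["delta"] * R + p["delta_v"] * V - p["eps"] * S_S * lam - p["nu"] * S_S,
        (p["eps"] * S_S + p["eps_v"] * V) * lam - p["gamma"] * I_S,
        p["nu"] * (S_P + S_S) - p["delta_v"] * V - p["eps_v"] * V * lam,
    ]


def _rhs_sirs_e(t, y, p):
    S_P, I_P, R, S_S, I_S, V1, V2, I_V, S_S1, S_S2, I_S1, I_S2 = y
    lam = p["beta"] * (I_P + p["alpha"] * (I_S + I_V + I_S1 + I_S2))
    return [
        -S_P * lam - p["nu1"] * S_P,
        S_P * lam - p["gamma"] * I_P,
        p["gamma"] * (I_P + I_S + I_V + I_S1 + I_S2) - p["delta"] * R,
        p["delta"] * R - p["eps"] * S_S * lam - p["nu1"] * S_S,
        p["eps"] * S_S * lam - p["gamma"] * I_S,
        p["nu1"] * (S_P + S_S) - p["nu2"] * V1 - p["delta1"] * V1 - p["eps_v1"] * V1 * lam,
        p["nu2"] * V1 - p["delta2"] * V2 - p["eps_v2"] * V2 * lam,
        (p["eps_v1"] * V1 + p["eps_v2"] * V2) * lam - p["gamma"] * I_V,
        p["delta1"] * V1 - p["eps"] * S_S1 * lam,
        p["delta2"] * V2 - p["eps"] * S_S2 * lam,
        p["eps"] * S_S1 * lam - p["gamma"] * I_S1,
        p["eps"] * S_S2 * lam - p["gamma"] * I_S2,
    ]


_RHS = {"SIR(S)": _rhs_sirs, "SIR(S-V)": _rhs_sirs_v, "SIR(S-E)": _rhs_sirs_e}


def default_sirs_spec(variant: str, t_max: float = 200.0, n_times: int = 101) -> SirsVariantSpec:
    """Synthetic template marginals for the given variant (rates per day).

    Broad uniforms around epidemiologically plausible SARS-CoV-2-era values:
    transmission beta, recovery gamma ~ 1/(7..14 d), immunity waning delta
    ~ 1/(90..365 d), relative susceptibility after waning eps, relative
    infectiousness of non-primary infections alpha, plus vaccination uptake,
    vaccinal waning and breakthrough-susceptibility rates in the extended
    variants.
    """
    U = lambda lo, hi: MarginalSpec("uniform", {"low": lo, "high": hi})  # noqa: E731
    common = {
        "beta": U(0.2, 0.5),
        "gamma": U(1.0 / 14.0, 1.0 / 7.0),
        "delta": U(1.0 / 365.0, 1.0 / 90.0),
        "eps": U(0.5, 1.0),
        "alpha": U(0.3, 0.8),
    }
    if variant == "SIR(S)":
        params = dict(common)
    elif variant == "SIR(S-V)":
        params = dict(common, nu=U(0.001, 0.01), delta_v=U(1.0 / 365.0, 1.0 / 180.0), eps_v=U(0.1, 0.5))
    elif variant == "SIR(S-E)":
        params = dict(
            common,
            nu1=U(0.001, 0.01), nu2=U(0.01, 0.05),
            delta1=U(1.0 / 180.0, 1.0 / 90.0), delta2=U(1.0 / 730.0, 1.0 / 365.0),
            eps_v1=U(0.3, 0.7), eps_v2=U(0.05, 0.3),
        )
    else:
        raise ValueError(f"unknown variant {variant!r}")
    n_states = len(_STATE_NAMES[variant])
    y0 = np.zeros(n_states)
    y0[0] = 1.0 - 1e-3   # S_P
    y0[1] = 1e-3         # seed infection in I_P
    return SirsVariantSpec(
        variant=variant, params=params, t_grid=np.linspace(0.0, t_max, n_times), y0=y0
    )


def integrate_sirs(spec: SirsVariantSpec, params: Mapping[str, float]) -> np.ndarray:
    """Solve the variant's ODE system; returns states on the time grid,
    shape (len(t_grid), n_states)."""
    missing = [r for r in spec.rate_names if r not in params]
    if missing:
        raise ValueError(f"missing rate parameters: {missing}")
    p = {r: float(params[r]) for r in spec.rate_names}
    if any(v < 0 for v in p.values()):
        raise ValueError("rate parameters must be non-negative")
    sol = solve_ivp(
        _RHS[spec.variant], (spec.t_grid[0], spec.t_grid[-1]), spec.y0,
        t_eval=spec.t_grid, args=(p,), method="LSODA",
        rtol=spec.rtol, atol=spec.atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed for {spec.variant}: {sol.message}")
    traj = sol.y.T
    # Integration tolerances can leave tiny negative excursions; they are
    # numerical, not dynamical, so clip within the solver tolerance only.
    if np.any(traj < -1e-7):
        raise IntegrationError(f"negative state beyond solver tolerance in {spec.variant}")
    return np.clip(traj, 0.0, None)


# ---------------------------------------------------------------------------
# Audits
# ---------------------------------------------------------------------------

_AUDIT_COLUMNS = [
    "model_id", "compartment", "time", "k", "k_t", "k_s",
    "sum_S1", "sum_S2", "sum_S3", "CV", "p", "q", "N",
]


def _audit_row(model_id, compartment, time, k, indices, dims, cv, p, q, N) -> dict:
    orders = indices.available_orders()
    return dict(
        model_id=model_id, compartment=compartment, time=time, k=k,
        k_t=dims.k_t, k_s=dims.k_s.label,
        sum_S1=indices.sum_by_order(1),
        sum_S2=indices.sum_by_order(2) if 2 in orders else np.nan,
        sum_S3=indices.sum_by_order(3) if 3 in orders else np.nan,
        CV=cv, p=p, q=q, N=N,
    )


def audit_chain(
    chain: ChainSpec,
    N: int = 2 ** 12,
    subset_orders: Sequence[int] = (2, 3),
    p: float = 0.99,
    q: float = 0.05,
    scramble_seed: int | None = None,
) -> pd.DataFrame:
    """Per-compartment (k_t, k_s, order-wise sums, CV) audit table."""
    subset_orders = tuple(o for o in subset_orders if o <= chain.k)
    design = apply_marginals(
        build_design(N, chain.k, subset_orders=subset_orders, scramble_seed=scramble_seed,
                     subset_sides="both"),
        chain.marginals,
    )
    outputs = run_chain(chain, design)
    rows = []
    for comp in chain.compartments:
        split = split_outputs(design, outputs[comp.name])
        indices = estimate_indices(design, outputs=split)
        dims = effective_dimensions(indices, p=p, q=q)
        pooled = np.concatenate([split["yA"], split["yB"]])
        try:
            cv = coefficient_of_variation(pooled)
        except NearZeroMeanError:
            cv = float("nan")
        rows.append(_audit_row(chain.name, comp.name, np.nan, chain.k, indices, dims, cv, p, q, N))
    return pd.DataFrame(rows, columns=_AUDIT_COLUMNS)


def audit_sirs(
    spec: SirsVariantSpec,
    N: int = 2 ** 7,
    time_points: Sequence[float] | None = None,
    subset_orders: Sequence[int] = (2, 3),
    p: float = 0.99,
    q: float = 0.05,
    scramble_seed: int | None = None,
) -> pd.DataFrame:
    """Per-(compartment, time) audit of a SIR(S) variant.

    Each design row triggers one ODE solve; the audited output is each state's
    value at each requested time point (default: five evenly spaced points of
    the spec's grid).  Summaries over time (mean k_t etc.) can be taken from
    the returned table.
    """
    k = len(spec.rate_names)
    subset_orders = tuple(o for o in subset_orders if o <= k)
    design = apply_marginals(
        build_design(N, k, subset_orders=subset_orders, scramble_seed=scramble_seed,
                     subset_sides="both"),
        [spec.params[r] for r in spec.rate_names],
    )
    grid = spec.t_grid
    if time_points is None:
        time_points = grid[np.linspace(0, grid.size - 1, 5).astype(int)][1:]
    t_idx = [int(np.argmin(np.abs(grid - t))) for t in time_points]

    X = design.stacked()
    trajs = np.empty((X.shape[0], len(t_idx), len(spec.state_names)))
    for r in range(X.shape[0]):
        params = dict(zip(spec.rate_names, X[r]))
        trajs[r] = integrate_sirs(spec, params)[t_idx]

    rows = []
    for s, state in enumerate(spec.state_names):
        for j, ti in enumerate(t_idx):
            split = split_outputs(design, trajs[:, j, s])
            try:
                indices = estimate_indices(design, outputs=split)
                dims = effective_dimensions(indices, p=p, q=q)
            except Exception:
                continue  # state still (near) empty at this time
            pooled = np.concatenate([split["yA"], split["yB"]])
            try:
                cv = coefficient_of_variation(pooled)
            except NearZeroMeanError:
                cv = float("nan")
            rows.append(_audit_row(spec.variant, state, float(grid[ti]), k, indices, dims, cv, p, q, N))
    return pd.DataFrame(rows, columns=_AUDIT_COLUMNS)


def audit_upgrades(family: str, **kwargs) -> pd.DataFrame:
    """Audit a whole model family across its upgrade stages.

    ``family`` is "psacoin", "irrigation" (all three reference-ET modes) or
    "sirs" (all three variants); keyword arguments are forwarded to the
    underlying audit.
    """
    if family == "psacoin":
        return audit_chain(psacoin_chain(), **kwargs)
    if family == "irrigation":
        tables = [
            audit_chain(irrigation_chain(mode), **kwargs)
            for mode in ("penman-monteith", "priestley-taylor", "uncertain")
        ]
        return pd.concat(tables, ignore_index=True)
    if family == "sirs":
        tables = [audit_sirs(default_sirs_spec(v), **kwargs) for v in SIRS_VARIANTS]
        return pd.concat(tables, ignore_index=True)
    raise ValueError(f"unknown family {family!r}; expected psacoin, irrigation or sirs")
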