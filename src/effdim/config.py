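"""Run configuration: YAML schema, validation, resolution."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .sampling import MarginalSpec

__all__ = ["RunConfig", "load_config", "parse_marginal"]

_EXPERIMENTS = {"g-random", "metamodel", "audit-chain", "audit-sirs"}
_KNOWN_KEYS = {
    "experiment", "N", "seed", "n_sims", "k_range", "k_fixed", "n_grid", "reps",
    "mode", "p", "q", "family", "chain", "variant", "marginals", "output_dir",
    "subset_orders", "estimate_dims", "cv_rel_floor",
}


def parse_marginal(obj: dict) -> MarginalSpec:
    """Build a MarginalSpec from a mapping like {kind: uniform, low: 0, high: 1}."""
    if "kind" not in obj:
        raise ConfigError(f"marginal declaration missing 'kind': {obj!r}")
    params = {k: v for k, v in obj.items() if k != "kind"}
    try:
        return MarginalSpec(obj["kind"], params)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


@dataclass
class RunConfig:
    """Validated settings for one experiment or audit run."""

    experiment: str
    seed: int
    N: int = 2 ** 10
    n_sims: int = 0
    k_range: tuple[int, ...] = ()
    k_fixed: int = 15
    n_grid: tuple[int, ...] = ()
    reps: int = 30
    mode: str = "fixed-k-vary-n"
    p: float = 0.99
    q: float = 0.05
    family: str = "psacoin"
    variant: str = "SIR(S)"
    subset_orders: tuple[int, ...] = (2, 3)
    estimate_dims: bool = False
    output_dir: Path = Path("effdim-run")
    raw: dict = field(default_factory=dict)

    def resolved(self) -> dict:
        """Snapshot sufficient to re-run bit-identically."""
        out = {
            "experiment": self.experiment, "seed": self.seed, "N": self.N,
            "p": self.p, "q": self.q, "output_dir": str(self.output_dir),
        }
        if self.experiment == "g-random":
            out.update(n_sims=self.n_sims, k_range=list(self.k_range))
        elif self.experiment == "metamodel":
            out.update(mode=self.mode, reps=self.reps, k_fixed=self.k_fixed,
                       k_range=list(self.k_range), n_grid=list(self.n_grid),
                       estimate_dims=self.estimate_dims)
        elif self.experiment == "audit-chain":
            out.update(family=self.family, subset_orders=list(self.subset_orders))
        elif self.experiment == "audit-sirs":
            out.update(variant=self.variant, subset_orders=list(self.subset_orders))
        return out


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigError` listing every offending key; a seed is
    mandatory for every run (all runs here are stochastic or QMC-seeded).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    problems = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
    exp = raw.get("experiment")
    if exp not in _EXPERIMENTS:
        problems.append(f"experiment must be one of {sorted(_EXPERIMENTS)}, got {exp!r}")
    if "seed" not in raw:
        problems.append("missing mandatory key 'seed' (stochastic run)")
    elif not isinstance(raw["seed"], int):
        problems.append(f"seed must be an integer, got {raw['seed']!r}")
    p = raw.get("p", 0.99)
    if not (0.0 < p < 1.0):
        problems.append(f"p must lie in (0,1), got {p}")
    q = raw.get("q", 0.05)
    if not (0.0 <= q < 1.0):
        problems.append(f"q must lie in [0,1), got {q}")
    if exp == "g-random":
        if not raw.get("k_range"):
            problems.append("g-random requires a non-empty k_range")
        if not isinstance(raw.get("n_sims", 0), int) or raw.get("n_sims", 0) < 0:
            problems.append("n_sims must be a non-negative integer")
    if exp == "metamodel":
        mode = raw.get("mode", "fixed-k-vary-n")
        if mode not in ("fixed-k-vary-n", "vary-k-random-n"):
            problems.append(f"unknown metamodel mode {mode!r}")
        elif mode == "fixed-k-vary-n" and not raw.get("n_grid"):
            problems.append("fixed-k-vary-n requires a non-empty n_grid")
        elif mode == "vary-k-random-n" and not raw.get("k_range"):
            problems.append("vary-k-random-n requires a non-empty k_range")
    if exp == "audit-chain" and raw.get("family", "psacoin") not in ("psacoin", "irrigation"):
        problems.append(f"unknown chain family {raw.get('family')!r}")
    if exp == "audit-sirs" and raw.get("variant", "SIR(S)") not in ("SIR(S)", "SIR(S-V)", "SIR(S-E)"):
        problems.append(f"unknown SIRS variant {raw.get('variant')!r}")
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))

    return RunConfig(
        experiment=exp,
        seed=int(raw["seed"]),
        N=int(raw.get("N", 2 ** 10)),
        n_sims=int(raw.get("n_sims", 0)),
        k_range=tuple(raw.get("k_range", ())),
        k_fixed=int(raw.get("k_fixed", 15)),
        n_grid=tuple(raw.get("n_grid", ())),
        reps=int(raw.get("reps", 30)),
        mode=raw.get("mode", "fixed-k-vary-n"),
        p=float(p),
        q=float(q),
        family=raw.get("family", "psacoin"),
        variant=raw.get("variant", "SIR(S)"),
        subset_orders=tuple(raw.get("subset_orders", (2, 3))),
        estimate_dims=bool(raw.get("estimate_dims", False)),
        output_dir=Path(raw.get("output_dir", "effdim-run")),
        raw=raw,
    )
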