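"""Replicated invasion experiments: sweeps, tallies and exact binomial CIs.

Each experiment sweeps one variable over a grid while holding everything
else at its defaults.  At every grid point, ``n_instances`` independent
replicate chains are run -- draw a pool, enrich it to a resident community
(regenerating collapsed instances from fresh child seeds), draw an invader,
run the assay -- and the four outcome categories are tallied with
Clopper--Pearson confidence intervals.

Seeding: replicate ``i`` at grid point ``g`` of experiment ``name`` under
root seed ``s`` uses ``numpy.random.SeedSequence((s, crc32(name), g, i,
attempt))``, so any replicate can be reproduced in isolation and results
are independent of execution order.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .config import ConfigurationError, CycleConfig, GeneratorConfig, ResourceConfig, snapshot
from .assembly import enrich
from .invasion import OUTCOMES, InvasionResult, Outcome, run_assay
from .network import ablate_invader, generate_invader, generate_network

__all__ = [
    "clopper_pearson",
    "ExperimentSpec",
    "OutcomeTable",
    "make_experiment",
    "builtin_experiments",
    "sweep",
    "summarize",
    "propagule_grid",
    "ablation_label",
]

MAX_REGENERATION_ATTEMPTS = 1000


def clopper_pearson(k: int, n: int, level: float = 0.8) -> tuple[float, float]:
    """Exact (Clopper--Pearson) binomial confidence interval for k successes in n trials.

    Endpoints are Beta-distribution quantiles,

        low  = BetaInv((1-level)/2; k, n-k+1)        (0 when k = 0)
        high = BetaInv(1-(1-level)/2; k+1, n-k)      (1 when k = n).
    """
    if n <= 0:
        raise ConfigurationError("n must be positive")
    if not 0 <= k <= n:
        raise ConfigurationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < level < 1:
        raise ConfigurationError("level must lie in (0, 1)")
    a = (1.0 - level) / 2.0
    low = 0.0 if k == 0 else float(beta_dist.ppf(a, k, n - k + 1))
    high = 1.0 if k == n else float(beta_dist.ppf(1.0 - a, k + 1, n - k))
    return low, high


def propagule_grid(n_points: int = 20, low: float = 1.0e-4, high: float = 0.99) -> np.ndarray:
    """The standard propagule-size grid: log-spaced from 1e-4 to 0.99."""
    return np.logspace(np.log10(low), np.log10(high), n_points)


def ablation_label(flags) -> str:
    """Compact label for an (production, consumption, influence)-removed triple."""
    p, c, i = flags
    removed = [name for name, f in (("production", p), ("consumption", c), ("influence", i)) if f]
    return "intact" if not removed else "no_" + "+".join(removed)


@dataclass(frozen=True)
class ExperimentSpec:
    """One sweep: a named variable, its grid, and the fixed background."""

    name: str
    variable: str
    grid: tuple
    generator: GeneratorConfig = GeneratorConfig()
    cycle: CycleConfig = CycleConfig()
    resource: ResourceConfig = ResourceConfig()
    model: str = "basic"
    r0_ratio: float = 1.5
    propagule_fraction: float = 0.003
    ablation: tuple[bool, bool, bool] = (False, False, False)
    n_instances: int = 1000
    ci_level: float = 0.8

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", tuple(self.grid))
        if not self.grid:
            raise ConfigurationError("grid must be non-empty")
        if self.variable not in _VARIABLES:
            raise ConfigurationError(
                f"unknown swept variable {self.variable!r}; known: {sorted(_VARIABLES)}"
            )
        if self.model not in ("basic", "resource"):
            raise ConfigurationError(f"unknown model variant: {self.model!r}")
        if self.n_instances < 1:
            raise ConfigurationError("n_instances must be >= 1")
        if self.variable in ("propagule_fraction", "r0_ratio", "resource_supply",
                             "production_scale", "consumption_scale"):
            if any(float(v) <= 0 for v in self.grid):
                raise ConfigurationError("grid values must be positive")


@dataclass
class _Condition:
    """The fully resolved parameters of one grid point."""

    generator: GeneratorConfig
    invader_generator: GeneratorConfig
    resource: ResourceConfig
    model: str
    r0_ratio: float
    propagule_fraction: float
    ablation: tuple[bool, bool, bool]
    production_scale: float = 1.0
    consumption_scale: float = 1.0


def _resolve_condition(spec: ExperimentSpec, value) -> _Condition:
    cond = _Condition(
        generator=spec.generator,
        invader_generator=spec.generator,
        resource=spec.resource,
        model=spec.model,
        r0_ratio=spec.r0_ratio,
        propagule_fraction=spec.propagule_fraction,
        ablation=tuple(spec.ablation),
    )
    var = spec.variable
    if var == "propagule_fraction":
        cond.propagule_fraction = float(value)
    elif var == "r0_ratio":
        cond.r0_ratio = float(value)
    elif var == "f_fac_inv":
        cond.invader_generator = dataclasses.replace(
            spec.generator, f_facilitation_invader=float(value)
        )
    elif var == "f_fac":
        cond.generator = dataclasses.replace(spec.generator, f_facilitation=float(value))
        cond.invader_generator = cond.generator
    elif var == "ablation":
        cond.ablation = tuple(bool(v) for v in value)
    elif var == "q_influence_inv":
        cond.invader_generator = dataclasses.replace(spec.generator, q_influence=float(value))
    elif var == "q_production_inv":
        cond.invader_generator = dataclasses.replace(spec.generator, q_production=float(value))
    elif var == "production_scale":
        cond.production_scale = float(value)
    elif var == "consumption_scale":
        cond.consumption_scale = float(value)
    elif var == "resource_supply":
        cond.resource = dataclasses.replace(spec.resource, supply=float(value))
    else:  # pragma: no cover - guarded by ExperimentSpec validation
        raise ConfigurationError(f"unknown swept variable: {var!r}")
    return cond


_VARIABLES = {
    "propagule_fraction",
    "r0_ratio",
    "f_fac_inv",
    "f_fac",
    "ablation",
    "q_influence_inv",
    "q_production_inv",
    "production_scale",
    "consumption_scale",
    "resource_supply",
}


def _experiment_id(name: str) -> int:
    return zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF


def run_replicate(
    spec: ExperimentSpec,
    value,
    root_seed: int,
    grid_index: int,
    replicate: int,
) -> tuple[InvasionResult, int]:
    """Run one replicate chain; returns the result and the number of
    collapsed communities regenerated before a viable one was found."""
    cond = _resolve_condition(spec, value)
    exp_id = _experiment_id(spec.name)
    rc = None
    net = None
    inv_ss = None
    for attempt in range(MAX_REGENERATION_ATTEMPTS):
        ss = np.random.SeedSequence((int(root_seed), exp_id, grid_index, replicate, attempt))
        net_ss, inv_ss = ss.spawn(2)
        net = generate_network(cond.generator, np.random.default_rng(net_ss), cond.resource)
        rc, _ = enrich(net, spec.cycle, cond.model, cond.resource)
        if rc.richness > 0:
            break
    else:  # pragma: no cover - would need 1000 consecutive collapses
        raise RuntimeError("exceeded community regeneration budget")
    inv = generate_invader(
        net, cond.invader_generator, cond.r0_ratio, np.random.default_rng(inv_ss), cond.resource
    )
    if cond.production_scale != 1.0 or cond.consumption_scale != 1.0:
        inv = dataclasses.replace(
            inv,
            production_rate=inv.production_rate * cond.production_scale,
            consumption_rate=inv.consumption_rate * cond.consumption_scale,
        )
    if any(cond.ablation):
        inv = ablate_invader(inv, *cond.ablation)
    seed_tag = int(
        np.random.SeedSequence((int(root_seed), exp_id, grid_index, replicate)).generate_state(1)[0]
        % (2**31)
    )
    result = run_assay(
        rc, inv, cond.propagule_fraction, spec.cycle, cond.model, cond.resource,
        seed=seed_tag,
    )
    return result, attempt


@dataclass
class OutcomeTable:
    """Outcome counts, frequencies and CIs per grid point of one experiment."""

    name: str
    variable: str
    grid: list
    counts: dict                      # outcome value -> np.ndarray over grid
    n_instances: int
    ci_level: float
    root_seed: int
    regenerations: np.ndarray
    config: dict = field(default_factory=dict)
    mean_invader_fraction: np.ndarray | None = None
    mean_pre_richness: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = {k: np.asarray(v, dtype=int) for k, v in self.counts.items()}
        self.regenerations = np.asarray(self.regenerations, dtype=int)
        self.validate()

    def validate(self) -> None:
        totals = sum(self.counts.values())
        if not np.all(totals == self.n_instances):
            raise ConfigurationError("outcome counts must sum to n_instances at every grid point")

    def frequency(self, outcome) -> np.ndarray:
        key = outcome.value if isinstance(outcome, Outcome) else str(outcome)
        return self.counts[key] / self.n_instances

    def confidence_interval(self, outcome) -> tuple[np.ndarray, np.ndarray]:
        key = outcome.value if isinstance(outcome, Outcome) else str(outcome)
        bounds = [clopper_pearson(int(k), self.n_instances, self.ci_level) for k in self.counts[key]]
        low, high = zip(*bounds)
        return np.asarray(low), np.asarray(high)

    def grid_labels(self) -> list[str]:
        if self.variable == "ablation":
            return [ablation_label(v) for v in self.grid]
        return [repr(float(v)) for v in self.grid]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: one row per (grid point, outcome)."""
        rows = []
        labels = self.grid_labels()
        for g, label in enumerate(labels):
            for out in OUTCOMES:
                k = int(self.counts[out.value][g])
                low, high = clopper_pearson(k, self.n_instances, self.ci_level)
                rows.append(
                    {
                        "experiment": self.name,
                        "variable": self.variable,
                        "grid_value": label,
                        "outcome": out.value,
                        "count": k,
                        "n": self.n_instances,
                        "frequency": k / self.n_instances,
                        "ci_low": low,
                        "ci_high": high,
                        "ci_level": self.ci_level,
                        "regenerations": int(self.regenerations[g]),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def config_json(self) -> str:
        return json.dumps(
            {
                "experiment": self.name,
                "variable": self.variable,
                "grid": self.grid_labels(),
                "n_instances": self.n_instances,
                "ci_level": self.ci_level,
                "root_seed": self.root_seed,
                **self.config,
            }
        )


def sweep(spec: ExperimentSpec, root_seed: int = 0, progress: bool = False) -> OutcomeTable:
    """Run the full experiment and tally outcomes per grid point."""
    counts = {out.value: np.zeros(len(spec.grid), dtype=int) for out in OUTCOMES}
    regen = np.zeros(len(spec.grid), dtype=int)
    inv_frac = np.zeros(len(spec.grid))
    pre_rich = np.zeros(len(spec.grid))
    iterator = enumerate(spec.grid)
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic

        iterator = tqdm(list(iterator), desc=spec.name)  # pragma: no cover
    for g, value in iterator:
        for i in range(spec.n_instances):
            result, attempts = run_replicate(spec, value, root_seed, g, i)
            counts[result.outcome.value][g] += 1
            regen[g] += attempts
            inv_frac[g] += result.invader_final_fraction
            pre_rich[g] += result.pre_richness
    return OutcomeTable(
        name=spec.name,
        variable=spec.variable,
        grid=list(spec.grid),
        counts=counts,
        n_instances=spec.n_instances,
        ci_level=spec.ci_level,
        root_seed=root_seed,
        regenerations=regen,
        config=snapshot(spec.generator, spec.cycle, spec.resource)
        | {"model": spec.model, "r0_ratio": spec.r0_ratio,
           "propagule_fraction": spec.propagule_fraction},
        mean_invader_fraction=inv_frac / spec.n_instances,
        mean_pre_richness=pre_rich / spec.n_instances,
    )


def summarize(*tables: OutcomeTable) -> pd.DataFrame:
    """Merge outcome tables into one tidy long-format dataset."""
    if not tables:
        raise ConfigurationError("summarize needs at least one table")
    return pd.concat([t.to_frame() for t in tables], ignore_index=True)


def plot_outcomes(table: OutcomeTable, path=None, ax=None):
    """Stacked outcome-frequency bands over the sweep grid (optional)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(table.grid))
    bottom = np.zeros(len(table.grid))
    for out in OUTCOMES:
        f = table.frequency(out)
        ax.bar(x, f, bottom=bottom, label=out.value)
        bottom += f
    ax.set_xticks(x)
    ax.set_xticklabels(table.grid_labels(), rotation=45, ha="right")
    ax.set_xlabel(table.variable)
    ax.set_ylabel("outcome frequency")
    ax.set_title(table.name)
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
    return ax


# ---------------------------------------------------------------------------
# Built-in experiment battery.

def _default_presets() -> dict:
    gen = GeneratorConfig()
    inhibitory = dataclasses.replace(gen, f_facilitation_invader=0.1)
    facgrid = tuple(np.round(np.linspace(0.1, 0.9, 9), 3))
    return {
        "propagule": dict(
            variable="propagule_fraction",
            grid=tuple(propagule_grid()),
            generator=inhibitory,
            n_instances=1000,
        ),
        "invader_growth": dict(
            variable="r0_ratio",
            grid=tuple(np.round(np.linspace(0.5, 2.0, 7), 3)),
            generator=inhibitory,
            n_instances=1000,
        ),
        "invader_facilitation": dict(
            variable="f_fac_inv",
            grid=facgrid,
            generator=gen,
            n_instances=1000,
        ),
        "resident_facilitation": dict(
            variable="f_fac",
            grid=facgrid,
            generator=inhibitory,
            n_instances=1000,
        ),
        "ablation": dict(
            variable="ablation",
            grid=tuple(product((False, True), repeat=3)),
            generator=inhibitory,
            n_instances=10000,
        ),
        "invader_influence_connectivity": dict(
            variable="q_influence_inv",
            grid=facgrid,
            generator=inhibitory,
            n_instances=1000,
        ),
        "invader_production_connectivity": dict(
            variable="q_production_inv",
            grid=facgrid,
            generator=inhibitory,
            n_instances=1000,
        ),
        "invader_production_rate": dict(
            variable="production_scale",
            grid=(0.25, 0.5, 1.0, 2.0, 4.0),
            generator=inhibitory,
            n_instances=1000,
        ),
        "invader_consumption_rate": dict(
            variable="consumption_scale",
            grid=(0.25, 0.5, 1.0, 2.0, 4.0),
            generator=inhibitory,
            n_instances=1000,
        ),
        "resource_amount": dict(
            variable="resource_supply",
            grid=tuple(np.logspace(5, 7, 5)),
            generator=inhibitory,
            model="resource",
            n_instances=1000,
        ),
    }


def builtin_experiments() -> list[str]:
    """Names of the built-in sweep presets."""
    return sorted(_default_presets())


def make_experiment(name: str, **overrides) -> ExperimentSpec:
    """Instantiate a built-in sweep preset, optionally overriding fields.

    Any :class:`ExperimentSpec` field can be overridden, most usefully
    ``n_instances`` (reduced replicate counts for quick runs), ``grid``,
    ``model`` and ``generator``.
    """
    presets = _default_presets()
    if name not in presets:
        raise ConfigurationError(f"unknown experiment {name!r}; known: {sorted(presets)}")
    kwargs = dict(presets[name])
    kwargs.update(overrides)
    return ExperimentSpec(name=name, **kwargs)
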