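"""Parameter containers for the simulator.

Units
-----
Concentrations are handled internally in fmole/ml.  Saturation constants
that are conventionally quoted in nM are converted with

    1 nM == 1000 fmole/ml,

which closes the dimensions of the mediator balance: a production rate in
fmole per cell per hour multiplied by a density in cells/ml yields
fmole/ml/hr directly.  Rates are per hour, cell densities are cells/ml.

Three containers cover the three layers of the model:

* :class:`GeneratorConfig` -- distributions and connectivities from which
  random species pools and invaders are drawn.
* :class:`CycleConfig` -- the batch growth--dilution protocol (inoculum,
  dilution threshold, extinction threshold, target generations).
* :class:`ResourceConfig` -- the single limiting resource used by the
  explicit resource-competition variant of the model.

All containers are frozen dataclasses; derive variants with
:func:`dataclasses.replace`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

NM_TO_FMOL_PER_ML = 1000.0


class ConfigurationError(ValueError):
    """Raised when a parameter container is internally inconsistent."""


def _check_probability(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")


def _check_range(name: str, rng: tuple[float, float], *, nonneg: bool = True) -> None:
    try:
        lo, hi = rng
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{name} must be a (low, high) pair") from exc
    if lo > hi:
        raise ConfigurationError(f"{name} is inverted: {rng!r}")
    if nonneg and lo < 0:
        raise ConfigurationError(f"{name} must be non-negative: {rng!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Distributions defining a random species pool and its mediators.

    Parameters
    ----------
    n_species, n_mediators
        Pool size (species) and number of chemical mediators.
    basal_rate_range
        Uniform range for the basal net growth rate ``r_i0`` (hr^-1), the
        growth rate a species realises in the absence of any interaction.
    influence_amplitude_range
        Uniform range for the magnitude of a mediator's saturating influence
        on a species' growth rate (hr^-1); the sign is facilitative with
        probability ``f_facilitation``.
    production_rate_range, consumption_rate_range
        Uniform ranges for per-cell mediator production and uptake rates
        (fmole cell^-1 hr^-1).
    saturation_range_nM
        Uniform range (nM) for the shared half-saturation constant used by
        both the uptake and the growth-influence terms.
    q_production
        Probability that a given species produces a given mediator.
    q_influence
        Probability that a given mediator influences (and is therefore also
        consumed by) a given species.
    f_facilitation
        Probability that an existing influence link is positive for
        resident-resident links.
    f_facilitation_invader
        Same, for mediator links onto an invader.
    """

    n_species: int = 20
    n_mediators: int = 10
    basal_rate_range: tuple[float, float] = (0.08, 0.12)
    influence_amplitude_range: tuple[float, float] = (0.0, 0.2)
    production_rate_range: tuple[float, float] = (0.05, 0.15)
    consumption_rate_range: tuple[float, float] = (0.25, 0.75)
    saturation_range_nM: tuple[float, float] = (50.0, 150.0)
    q_production: float = 0.3
    q_influence: float = 0.3
    f_facilitation: float = 0.5
    f_facilitation_invader: float = 0.5

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_mediators < 0:
            raise ConfigurationError("need n_species >= 1 and n_mediators >= 0")
        for name in (
            "basal_rate_range",
            "influence_amplitude_range",
            "production_rate_range",
            "consumption_rate_range",
            "saturation_range_nM",
        ):
            value = tuple(float(x) for x in getattr(self, name))
            object.__setattr__(self, name, value)
            _check_range(name, value)
        if self.saturation_range_nM[0] <= 0:
            raise ConfigurationError("saturation_range_nM must be strictly positive")
        for name in ("q_production", "q_influence", "f_facilitation", "f_facilitation_invader"):
            _check_probability(name, getattr(self, name))

    @property
    def saturation_range(self) -> tuple[float, float]:
        """Half-saturation range converted to fmole/ml."""
        lo, hi = self.saturation_range_nM
        return (lo * NM_TO_FMOL_PER_ML, hi * NM_TO_FMOL_PER_ML)


@dataclass(frozen=True)
class CycleConfig:
    """Batch growth--dilution protocol.

    A community grows from ``inoculum_density`` until its total density
    reaches ``dilution_threshold`` (or, in the resource variant, until
    ``max_cycle_hours`` have elapsed), is diluted back to the inoculum
    density, and any species falling below ``extinction_threshold`` after a
    dilution is removed permanently.  The run ends once the cumulative
    number of doublings of total density reaches ``target_generations``.
    """

    inoculum_density: float = 1.0e4      # cells/ml
    dilution_threshold: float = 1.0e7    # cells/ml
    extinction_threshold: float = 0.1    # cells/ml
    target_generations: float = 200.0
    timestep_divisor: float = 10.0       # steps per shortest doubling time
    max_cycle_hours: float = 80.0        # resource variant only
    stall_factor: float = 10.0           # guard multiplier for stalled cycles

    def __post_init__(self) -> None:
        if not 0 < self.inoculum_density < self.dilution_threshold:
            raise ConfigurationError("need 0 < inoculum_density < dilution_threshold")
        if self.extinction_threshold <= 0:
            raise ConfigurationError("extinction_threshold must be positive")
        if self.target_generations <= 0 or self.timestep_divisor <= 0:
            raise ConfigurationError("target_generations and timestep_divisor must be positive")
        if self.max_cycle_hours <= 0 or self.stall_factor <= 0:
            raise ConfigurationError("max_cycle_hours and stall_factor must be positive")


@dataclass(frozen=True)
class ResourceConfig:
    """Single limiting resource for the explicit-competition model variant.

    ``supply`` is the fresh-medium concentration the resource is reset to at
    every dilution.  Per-species half-saturation constants and per-cell
    consumption coefficients are drawn uniformly from the given ranges when
    a network is generated.
    """

    supply: float = 1.0e6                                  # fmole/ml
    saturation_range: tuple[float, float] = (5.0e5, 1.5e6)  # fmole/ml
    consumption_range: tuple[float, float] = (5.0, 15.0)    # fmole per cell

    def __post_init__(self) -> None:
        if self.supply <= 0:
            raise ConfigurationError("resource supply must be positive")
        _check_range("saturation_range", tuple(self.saturation_range))
        _check_range("consumption_range", tuple(self.consumption_range))
        if self.saturation_range[0] <= 0:
            raise ConfigurationError("resource saturation_range must be strictly positive")


# ---------------------------------------------------------------------------
# Flat config files.  Keys follow the conventional parameter names of the
# batch-culture literature (n_c, n_m, q_p, q_c, f_fac, ...).

_GENERATOR_KEYS = {
    "n_c": "n_species",
    "n_m": "n_mediators",
    "r_0": "basal_rate_range",
    "r_ij": "influence_amplitude_range",
    "beta_ij": "production_rate_range",
    "alpha_ij": "consumption_rate_range",
    "k_ij": "saturation_range_nM",
    "q_p": "q_production",
    "q_c": "q_influence",
    "f_fac": "f_facilitation",
    "f_fac_inv": "f_facilitation_invader",
}

_CYCLE_KEYS = {
    "n_inoc": "inoculum_density",
    "n_dil": "dilution_threshold",
    "n_ext": "extinction_threshold",
    "n_gen": "target_generations",
    "dt_divisor": "timestep_divisor",
    "max_cycle_hours": "max_cycle_hours",
}

_RESOURCE_KEYS = {
    "r0_resource": "supply",
    "k_r": "saturation_range",
    "alpha_r": "consumption_range",
}

_RANGE_FIELDS = {
    "basal_rate_range",
    "influence_amplitude_range",
    "production_rate_range",
    "consumption_rate_range",
    "saturation_range_nM",
    "saturation_range",
    "consumption_range",
}


def load_config(path) -> tuple[GeneratorConfig, CycleConfig, ResourceConfig]:
    """Read a flat YAML parameter file.

    Unknown keys raise :class:`ConfigurationError`; omitted keys keep their
    defaults.  Range-valued keys take a two-element ``[low, high]`` list.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")
    gen_kwargs: dict = {}
    cyc_kwargs: dict = {}
    res_kwargs: dict = {}
    for key, value in raw.items():
        if key in _GENERATOR_KEYS:
            field, target = _GENERATOR_KEYS[key], gen_kwargs
        elif key in _CYCLE_KEYS:
            field, target = _CYCLE_KEYS[key], cyc_kwargs
        elif key in _RESOURCE_KEYS:
            field, target = _RESOURCE_KEYS[key], res_kwargs
        else:
            raise ConfigurationError(f"unknown config key: {key!r}")
        if field in _RANGE_FIELDS:
            value = tuple(float(v) for v in value)
        target[field] = value
    return (
        GeneratorConfig(**gen_kwargs),
        CycleConfig(**cyc_kwargs),
        ResourceConfig(**res_kwargs),
    )


def dump_config(gen: GeneratorConfig, cycle: CycleConfig, resource: ResourceConfig, path) -> None:
    """Write a flat YAML parameter file (inverse of :func:`load_config`)."""
    out: dict = {}
    for key, field in _GENERATOR_KEYS.items():
        out[key] = _plain(getattr(gen, field))
    for key, field in _CYCLE_KEYS.items():
        out[key] = _plain(getattr(cycle, field))
    for key, field in _RESOURCE_KEYS.items():
        out[key] = _plain(getattr(resource, field))
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def _plain(value):
    if isinstance(value, tuple):
        return [float(v) for v in value]
    return value


def snapshot(gen: GeneratorConfig, cycle: CycleConfig, resource: ResourceConfig) -> dict:
    """A JSON-serialisable snapshot of a full parameter set."""
    return {
        "generator": dataclasses.asdict(gen),
        "cycle": dataclasses.asdict(cycle),
        "resource": dataclasses.asdict(resource),
    }
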