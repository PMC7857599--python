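"""Random chemically-mediated interaction networks.

A species pool is described by which mediators each species produces, which
mediators influence (and are taken up by) each species, and the rate
constants attached to those links.  Networks are drawn from independent
binomial link models: each production link exists with probability ``q_p``
and each influence link with probability ``q_c``; rate magnitudes are
uniform within their configured ranges and the sign of an influence link is
facilitative with probability ``f_fac``.

Consumption topology follows influence topology: a species takes up exactly
the mediators whose concentration modulates its growth rate, with uptake
rates drawn independently of the influence amplitudes.  Only the influence
matrix carries signs; production and consumption rates are non-negative.

Everything is seed-controlled through :func:`numpy.random.default_rng`; a
fixed seed and configuration reproduces a network byte-for-byte after JSON
serialisation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError, GeneratorConfig, ResourceConfig

NETWORK_SCHEMA = "medinvade.network/1"
INVADER_SCHEMA = "medinvade.invader/1"

__all__ = [
    "InteractionNetwork",
    "InvaderSpec",
    "generate_network",
    "generate_invader",
    "ablate_invader",
    "attach_invader",
    "invader_from_species",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _arr(x, dtype=float) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(x, dtype=dtype))


@dataclass
class InteractionNetwork:
    """All rate and adjacency matrices defining a species pool.

    Attributes
    ----------
    basal_rate : (n_species,) float
        Net growth rate absent any interaction, hr^-1.
    influence_rate : (n_species, n_mediators) float
        Signed amplitude of each mediator's saturating effect on each
        species' growth rate, hr^-1; zero where no link.
    production_rate : (n_mediators, n_species) float
        Per-cell mediator production rates, fmole cell^-1 hr^-1.
    consumption_rate : (n_mediators, n_species) float
        Per-cell saturating uptake rates, fmole cell^-1 hr^-1.
    saturation : (n_species, n_mediators) float
        Shared half-saturation constant for uptake and growth influence,
        fmole/ml.  The uptake term indexed (mediator i, species j) reads
        this matrix transposed.
    influence_link, production_link : bool
        Adjacency underlying the rate matrices.  A nonzero rate implies the
        link bit is set; a set bit with a zero rate is legal (it happens
        when an amplitude draws exactly zero or a rate has been ablated).
    resource_saturation, resource_consumption : (n_species,) float
        Per-species half-saturation (fmole/ml) and per-cell consumption
        coefficient for the single limiting resource; ignored by the basic
        model variant.
    """

    basal_rate: np.ndarray
    influence_rate: np.ndarray
    production_rate: np.ndarray
    consumption_rate: np.ndarray
    saturation: np.ndarray
    influence_link: np.ndarray
    production_link: np.ndarray
    resource_saturation: np.ndarray
    resource_consumption: np.ndarray

    def __post_init__(self) -> None:
        self.basal_rate = _arr(self.basal_rate)
        self.influence_rate = _arr(self.influence_rate)
        self.production_rate = _arr(self.production_rate)
        self.consumption_rate = _arr(self.consumption_rate)
        self.saturation = _arr(self.saturation)
        self.influence_link = _arr(self.influence_link, bool)
        self.production_link = _arr(self.production_link, bool)
        self.resource_saturation = _arr(self.resource_saturation)
        self.resource_consumption = _arr(self.resource_consumption)
        self.validate()

    @property
    def n_species(self) -> int:
        return self.basal_rate.shape[0]

    @property
    def n_mediators(self) -> int:
        return self.influence_rate.shape[1]

    def validate(self) -> None:
        n_s, n_m = self.influence_rate.shape
        if self.basal_rate.shape != (n_s,):
            raise ConfigurationError("basal_rate shape mismatch")
        for name, shape in (
            ("production_rate", (n_m, n_s)),
            ("consumption_rate", (n_m, n_s)),
            ("saturation", (n_s, n_m)),
            ("influence_link", (n_s, n_m)),
            ("production_link", (n_m, n_s)),
        ):
            if getattr(self, name).shape != shape:
                raise ConfigurationError(f"{name} shape mismatch: want {shape}")
        for name in ("resource_saturation", "resource_consumption"):
            if getattr(self, name).shape != (n_s,):
                raise ConfigurationError(f"{name} shape mismatch")
        if (self.production_rate < 0).any() or (self.consumption_rate < 0).any():
            raise ConfigurationError("production/consumption rates must be >= 0")
        if (self.saturation <= 0).any():
            raise ConfigurationError("saturation constants must be > 0")
        if ((self.influence_rate != 0) & ~self.influence_link).any():
            raise ConfigurationError("nonzero influence rate off-link")
        if ((self.production_rate != 0) & ~self.production_link).any():
            raise ConfigurationError("nonzero production rate off-link")
        if ((self.consumption_rate != 0) & ~self.influence_link.T).any():
            raise ConfigurationError("nonzero consumption rate off influence link")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_rates(
        cls,
        basal_rate,
        influence_rate,
        production_rate,
        consumption_rate=None,
        saturation=1.0e5,
        resource_saturation=1.0e6,
        resource_consumption=10.0,
    ) -> "InteractionNetwork":
        """Build a network directly from rate matrices (links inferred).

        Convenient for hand-built communities: adjacency is derived from the
        nonzero pattern of the rates, ``saturation`` may be a scalar, and
        consumption defaults to zero on the influence links.
        """
        influence_rate = _arr(influence_rate)
        n_s, n_m = influence_rate.shape
        production_rate = _arr(production_rate)
        if consumption_rate is None:
            consumption_rate = np.zeros((n_m, n_s))
        consumption_rate = _arr(consumption_rate)
        saturation = np.broadcast_to(_arr(saturation), (n_s, n_m)).copy()
        influence_link = (influence_rate != 0) | (consumption_rate != 0).T
        return cls(
            basal_rate=_arr(basal_rate),
            influence_rate=influence_rate,
            production_rate=production_rate,
            consumption_rate=consumption_rate,
            saturation=saturation,
            influence_link=influence_link,
            production_link=production_rate != 0,
            resource_saturation=np.broadcast_to(_arr(resource_saturation), (n_s,)).copy(),
            resource_consumption=np.broadcast_to(_arr(resource_consumption), (n_s,)).copy(),
        )

    def subset(self, indices) -> "InteractionNetwork":
        """The sub-network restricted to the given species (all mediators kept)."""
        idx = np.asarray(indices, dtype=int)
        return InteractionNetwork(
            basal_rate=self.basal_rate[idx],
            influence_rate=self.influence_rate[idx],
            production_rate=self.production_rate[:, idx],
            consumption_rate=self.consumption_rate[:, idx],
            saturation=self.saturation[idx],
            influence_link=self.influence_link[idx],
            production_link=self.production_link[:, idx],
            resource_saturation=self.resource_saturation[idx],
            resource_consumption=self.resource_consumption[idx],
        )

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": NETWORK_SCHEMA,
            "n_species": self.n_species,
            "n_mediators": self.n_mediators,
            "basal_rate": self.basal_rate.tolist(),
            "influence_rate": self.influence_rate.tolist(),
            "production_rate": self.production_rate.tolist(),
            "consumption_rate": self.consumption_rate.tolist(),
            "saturation": self.saturation.tolist(),
            "influence_link": self.influence_link.astype(int).tolist(),
            "production_link": self.production_link.astype(int).tolist(),
            "resource_saturation": self.resource_saturation.tolist(),
            "resource_consumption": self.resource_consumption.tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "InteractionNetwork":
        if data.get("schema") != NETWORK_SCHEMA:
            raise ConfigurationError(f"unexpected network schema: {data.get('schema')!r}")
        kwargs = {f.name: data[f.name] for f in dataclasses.fields(cls)}
        return cls(**kwargs)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "InteractionNetwork":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                data = json.loads(text)
            else:
                with open(text, "r", encoding="utf-8") as fh:
                    data = json.load(fh)
        return cls.from_dict(data)


@dataclass
class InvaderSpec:
    """One invader's rates and links over an existing mediator set.

    The invader shares the resident network's mediators (it introduces no
    new chemicals).  Ablation flags zero the *effective* rates used by the
    dynamics while leaving the stored rates and adjacency untouched, so the
    eight keep/remove combinations of production, consumption and mediator
    influence are all reachable from one drawn invader.
    """

    basal_rate: float
    influence_rate: np.ndarray
    production_rate: np.ndarray
    consumption_rate: np.ndarray
    saturation: np.ndarray
    influence_link: np.ndarray
    production_link: np.ndarray
    resource_saturation: float = 1.0e6
    resource_consumption: float = 10.0
    production_removed: bool = False
    consumption_removed: bool = False
    influence_removed: bool = False

    def __post_init__(self) -> None:
        self.influence_rate = _arr(self.influence_rate)
        self.production_rate = _arr(self.production_rate)
        self.consumption_rate = _arr(self.consumption_rate)
        self.saturation = _arr(self.saturation)
        self.influence_link = _arr(self.influence_link, bool)
        self.production_link = _arr(self.production_link, bool)
        n_m = self.influence_rate.shape[0]
        for name in ("production_rate", "consumption_rate", "saturation", "influence_link", "production_link"):
            if getattr(self, name).shape != (n_m,):
                raise ConfigurationError(f"invader {name} shape mismatch")
        if (self.saturation <= 0).any():
            raise ConfigurationError("invader saturation constants must be > 0")

    @property
    def n_mediators(self) -> int:
        return self.influence_rate.shape[0]

    @property
    def effective_influence(self) -> np.ndarray:
        return np.zeros_like(self.influence_rate) if self.influence_removed else self.influence_rate

    @property
    def effective_production(self) -> np.ndarray:
        return np.zeros_like(self.production_rate) if self.production_removed else self.production_rate

    @property
    def effective_consumption(self) -> np.ndarray:
        return np.zeros_like(self.consumption_rate) if self.consumption_removed else self.consumption_rate

    def to_dict(self) -> dict:
        return {
            "schema": INVADER_SCHEMA,
            "basal_rate": float(self.basal_rate),
            "influence_rate": self.influence_rate.tolist(),
            "production_rate": self.production_rate.tolist(),
            "consumption_rate": self.consumption_rate.tolist(),
            "saturation": self.saturation.tolist(),
            "influence_link": self.influence_link.astype(int).tolist(),
            "production_link": self.production_link.astype(int).tolist(),
            "resource_saturation": float(self.resource_saturation),
            "resource_consumption": float(self.resource_consumption),
            "production_removed": self.production_removed,
            "consumption_removed": self.consumption_removed,
            "influence_removed": self.influence_removed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "InvaderSpec":
        if data.get("schema") != INVADER_SCHEMA:
            raise ConfigurationError(f"unexpected invader schema: {data.get('schema')!r}")
        kwargs = {f.name: data[f.name] for f in dataclasses.fields(cls)}
        return cls(**kwargs)


def generate_network(
    cfg: GeneratorConfig,
    seed=None,
    resource_cfg: ResourceConfig | None = None,
) -> InteractionNetwork:
    """Draw a random species pool.

    The draw order is fixed (production links, influence links, basal rates,
    influence amplitudes and signs, production rates, consumption rates,
    saturations, resource traits) and every uniform matrix is drawn densely
    before masking, so the stream of random numbers -- and therefore the
    network -- depends only on ``cfg`` and ``seed``.
    """
    rcfg = resource_cfg or ResourceConfig()
    rng = _as_rng(seed)
    n_s, n_m = cfg.n_species, cfg.n_mediators

    production_link = rng.random((n_m, n_s)) < cfg.q_production
    influence_link = rng.random((n_s, n_m)) < cfg.q_influence
    basal = rng.uniform(*cfg.basal_rate_range, size=n_s)
    amplitude = rng.uniform(*cfg.influence_amplitude_range, size=(n_s, n_m))
    sign = np.where(rng.random((n_s, n_m)) < cfg.f_facilitation, 1.0, -1.0)
    influence = np.where(influence_link, amplitude * sign, 0.0)
    production = np.where(production_link, rng.uniform(*cfg.production_rate_range, size=(n_m, n_s)), 0.0)
    consumption = np.where(influence_link.T, rng.uniform(*cfg.consumption_rate_range, size=(n_m, n_s)), 0.0)
    saturation = rng.uniform(*cfg.saturation_range, size=(n_s, n_m))
    k_r = rng.uniform(*rcfg.saturation_range, size=n_s)
    alpha_r = rng.uniform(*rcfg.consumption_range, size=n_s)

    return InteractionNetwork(
        basal_rate=basal,
        influence_rate=influence,
        production_rate=production,
        consumption_rate=consumption,
        saturation=saturation,
        influence_link=influence_link,
        production_link=production_link,
        resource_saturation=k_r,
        resource_consumption=alpha_r,
    )


def generate_invader(
    net: InteractionNetwork,
    cfg: GeneratorConfig,
    r0_ratio: float = 1.5,
    seed=None,
    resource_cfg: ResourceConfig | None = None,
) -> InvaderSpec:
    """Draw an invader over the mediator set of ``net``.

    The basal rate is drawn from the resident basal-rate distribution and
    scaled by ``r0_ratio``, so a ratio of 1.5 gives the invader a 50 %
    average advantage while preserving resident-scale variability.  Links
    use the same connectivities as the residents but influence signs are
    positive with probability ``cfg.f_facilitation_invader``.
    """
    if r0_ratio <= 0:
        raise ConfigurationError(f"r0_ratio must be positive, got {r0_ratio!r}")
    rcfg = resource_cfg or ResourceConfig()
    rng = _as_rng(seed)
    n_m = net.n_mediators

    production_link = rng.random(n_m) < cfg.q_production
    influence_link = rng.random(n_m) < cfg.q_influence
    basal = rng.uniform(*cfg.basal_rate_range) * r0_ratio
    amplitude = rng.uniform(*cfg.influence_amplitude_range, size=n_m)
    sign = np.where(rng.random(n_m) < cfg.f_facilitation_invader, 1.0, -1.0)
    influence = np.where(influence_link, amplitude * sign, 0.0)
    production = np.where(production_link, rng.uniform(*cfg.production_rate_range, size=n_m), 0.0)
    consumption = np.where(influence_link, rng.uniform(*cfg.consumption_rate_range, size=n_m), 0.0)
    saturation = rng.uniform(*cfg.saturation_range, size=n_m)
    k_r = rng.uniform(*rcfg.saturation_range)
    alpha_r = rng.uniform(*rcfg.consumption_range)

    return InvaderSpec(
        basal_rate=basal,
        influence_rate=influence,
        production_rate=production,
        consumption_rate=consumption,
        saturation=saturation,
        influence_link=influence_link,
        production_link=production_link,
        resource_saturation=k_r,
        resource_consumption=alpha_r,
    )


def ablate_invader(
    inv: InvaderSpec,
    remove_production: bool = False,
    remove_consumption: bool = False,
    remove_influence: bool = False,
) -> InvaderSpec:
    """A copy of ``inv`` with the named interaction channels switched off.

    Flags accumulate (ablating an already-ablated invader keeps earlier
    removals).  Stored rates and adjacency are unchanged; only the
    ``effective_*`` views seen by the dynamics are zeroed.
    """
    return dataclasses.replace(
        inv,
        production_removed=inv.production_removed or remove_production,
        consumption_removed=inv.consumption_removed or remove_consumption,
        influence_removed=inv.influence_removed or remove_influence,
    )


def invader_from_species(net: InteractionNetwork, index: int) -> InvaderSpec:
    """An invader that is a parameter-for-parameter copy of resident ``index``."""
    return InvaderSpec(
        basal_rate=float(net.basal_rate[index]),
        influence_rate=net.influence_rate[index].copy(),
        production_rate=net.production_rate[:, index].copy(),
        consumption_rate=net.consumption_rate[:, index].copy(),
        saturation=net.saturation[index].copy(),
        influence_link=net.influence_link[index].copy(),
        production_link=net.production_link[:, index].copy(),
        resource_saturation=float(net.resource_saturation[index]),
        resource_consumption=float(net.resource_consumption[index]),
    )


def attach_invader(net: InteractionNetwork, inv: InvaderSpec) -> InteractionNetwork:
    """The combined network with the invader appended as the last species.

    Effective (post-ablation) invader rates enter the dynamics; link bits
    keep the original bookkeeping.
    """
    if inv.n_mediators != net.n_mediators:
        raise ConfigurationError("invader and network mediator counts differ")
    return InteractionNetwork(
        basal_rate=np.append(net.basal_rate, inv.basal_rate),
        influence_rate=np.vstack([net.influence_rate, inv.effective_influence]),
        production_rate=np.hstack([net.production_rate, inv.effective_production[:, None]]),
        consumption_rate=np.hstack([net.consumption_rate, inv.effective_consumption[:, None]]),
        saturation=np.vstack([net.saturation, inv.saturation]),
        influence_link=np.vstack([net.influence_link, inv.influence_link]),
        production_link=np.hstack([net.production_link, inv.production_link[:, None]]),
        resource_saturation=np.append(net.resource_saturation, inv.resource_saturation),
        resource_consumption=np.append(net.resource_consumption, inv.resource_consumption),
    )
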