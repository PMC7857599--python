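"""Enrichment of stable resident communities.

A random pool (by default 20 species coupled through 10 mediators) is
inoculated in equal proportions and carried through growth--dilution cycles
for 200 generations of total community growth.  Species that remain above
the extinction threshold at harvest constitute the resident community;
stability is operationalised as having survived the full enrichment, with
:func:`check_stability` available as an optional stricter filter.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, CycleConfig, ResourceConfig
from .dynamics import CommunityState, CycleLog, run_cycles
from .network import InteractionNetwork

COMMUNITY_SCHEMA = "medinvade.community/1"

__all__ = ["ResidentCommunity", "enrich", "check_stability"]


@dataclass
class ResidentCommunity:
    """A stable assembled community harvested at the end of enrichment.

    ``survivors`` indexes into the parent pool ``network``; the harvest
    state (densities, mediator concentrations, leftover resource) is taken
    pre-dilution at the final cycle end.  ``collapsed`` marks instances
    where nothing survived (or growth stalled); these carry richness 0 and
    are excluded from invasion assays.
    """

    network: InteractionNetwork
    survivors: np.ndarray
    harvest_density: np.ndarray
    harvest_mediators: np.ndarray
    harvest_resource: float | None = None
    generations: float = 0.0
    collapsed: bool = False

    def __post_init__(self) -> None:
        self.survivors = np.asarray(self.survivors, dtype=int)
        self.harvest_density = np.asarray(self.harvest_density, dtype=float)
        self.harvest_mediators = np.asarray(self.harvest_mediators, dtype=float)
        if self.harvest_density.shape != self.survivors.shape:
            raise ConfigurationError("harvest_density must align with survivors")

    @property
    def richness(self) -> int:
        return int(self.survivors.size)

    @property
    def fractions(self) -> np.ndarray:
        total = self.harvest_density.sum()
        if total <= 0:
            return np.zeros_like(self.harvest_density)
        return self.harvest_density / total

    def subnetwork(self) -> InteractionNetwork:
        return self.network.subset(self.survivors)

    def to_dict(self) -> dict:
        return {
            "schema": COMMUNITY_SCHEMA,
            "network": self.network.to_dict(),
            "survivors": self.survivors.tolist(),
            "harvest_density": self.harvest_density.tolist(),
            "harvest_mediators": self.harvest_mediators.tolist(),
            "harvest_resource": self.harvest_resource,
            "generations": self.generations,
            "collapsed": self.collapsed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ResidentCommunity":
        if data.get("schema") != COMMUNITY_SCHEMA:
            raise ConfigurationError(f"unexpected community schema: {data.get('schema')!r}")
        return cls(
            network=InteractionNetwork.from_dict(data["network"]),
            survivors=data["survivors"],
            harvest_density=data["harvest_density"],
            harvest_mediators=data["harvest_mediators"],
            harvest_resource=data["harvest_resource"],
            generations=data["generations"],
            collapsed=data["collapsed"],
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ResidentCommunity":
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


def enrich(
    net: InteractionNetwork,
    cycle_cfg: CycleConfig | None = None,
    model: str = "basic",
    resource_cfg: ResourceConfig | None = None,
    until_stable: bool = True,
    max_passes: int = 5,
) -> tuple[ResidentCommunity, CycleLog]:
    """Assemble a resident community from the pool ``net``.

    The inoculum density is split equally among the pool members, mediator
    concentrations start at zero (fresh medium), and the dynamics run to
    the generation target.  Survivors are the species above the extinction
    threshold at harvest.

    With ``until_stable`` (the default) the enrichment repeats further
    generation-target passes -- re-inoculating the harvest into fresh
    medium each time, exactly as an invasion assay later will -- until one
    pass completes with unchanged richness.  The harvest returned is then
    the state *entering* that verifying pass, so any richness loss seen
    when the community is subsequently re-simulated (with or without an
    invader) cannot be residual membership sorting: its own invader-free
    continuation has been observed to keep every member.  Species with
    small growth-rate deficits decline too slowly to cross the extinction
    threshold within a single pass, which otherwise confounds assays that
    attribute richness loss to an invader.  Communities still sorting
    after ``max_passes`` passes are flagged as collapsed.
    ``until_stable=False`` gives the raw single-pass harvest.
    """
    cfg = cycle_cfg or CycleConfig()
    rcfg = resource_cfg or ResourceConfig()
    n = net.n_species
    state0 = CommunityState(
        species_density=np.full(n, cfg.inoculum_density / n),
        mediator_conc=np.zeros(net.n_mediators),
        resource=rcfg.supply if model == "resource" else None,
    )
    final, log = run_cycles(state0, net, cfg, model=model, fresh_resource=rcfg.supply)
    generations = final.cumulative_generations
    richness = int((final.species_density > cfg.extinction_threshold).sum())
    stable = not until_stable
    passes = 1
    while not stable and passes < max_passes and richness > 0 and not (log.stalled or log.collapsed):
        total = final.total_density
        factor = min(1.0, cfg.inoculum_density / total) if total > 0 else 0.0
        S = final.species_density * factor
        S[S < cfg.extinction_threshold] = 0.0
        state0 = CommunityState(
            species_density=S,
            mediator_conc=final.mediator_conc * factor,
            resource=rcfg.supply if model == "resource" else None,
        )
        candidate = final  # harvest candidate: the state entering this pass
        final, log = run_cycles(state0, net, cfg, model=model, fresh_resource=rcfg.supply)
        generations += final.cumulative_generations
        passes += 1
        new_richness = int((final.species_density > cfg.extinction_threshold).sum())
        if new_richness == richness and not (log.stalled or log.collapsed):
            stable = True
            final = candidate  # keep the verified pre-continuation harvest
        else:
            richness = new_richness

    survivors = np.flatnonzero(final.species_density > cfg.extinction_threshold)
    collapsed = bool(
        log.stalled or log.collapsed or survivors.size == 0 or (until_stable and not stable)
    )
    if collapsed:
        survivors = np.empty(0, dtype=int)
    rc = ResidentCommunity(
        network=net,
        survivors=survivors,
        harvest_density=final.species_density[survivors],
        harvest_mediators=final.mediator_conc.copy(),
        harvest_resource=final.resource,
        generations=generations,
        collapsed=collapsed,
    )
    return rc, log


def check_stability(
    rc: ResidentCommunity,
    extra_generations: float = 50.0,
    drift_tolerance: float = 0.01,
    cycle_cfg: CycleConfig | None = None,
    model: str = "basic",
    resource_cfg: ResourceConfig | None = None,
) -> tuple[bool, float]:
    """Continue a harvested community and test for compositional drift.

    The community is re-inoculated from its harvest fractions into fresh
    medium and run for ``extra_generations`` further generations.  It is
    judged stable when no species is lost and each species' end-of-cycle
    fraction moves by less than ``drift_tolerance`` (absolute) across the
    final three cycles.  Returns ``(stable, max_drift)``.
    """
    if rc.richness == 0:
        raise ConfigurationError("cannot check stability of a collapsed community")
    cfg = cycle_cfg or CycleConfig()
    rcfg = resource_cfg or ResourceConfig()
    run_cfg = dataclasses.replace(cfg, target_generations=extra_generations)
    subnet = rc.subnetwork()
    factor = cfg.inoculum_density / rc.harvest_density.sum()
    state0 = CommunityState(
        species_density=rc.fractions * cfg.inoculum_density,
        mediator_conc=rc.harvest_mediators * min(1.0, factor),
        resource=rcfg.supply if model == "resource" else None,
    )
    final, log = run_cycles(
        state0, subnet, run_cfg, model=model,
        fresh_resource=rcfg.supply, record_compositions=True,
    )
    survivors = (final.species_density > cfg.extinction_threshold).sum()
    if log.stalled or log.collapsed or survivors < rc.richness:
        return False, float("inf")
    tail = log.compositions[-3:]
    drift = 0.0
    for a, b in zip(tail[:-1], tail[1:]):
        drift = max(drift, float(np.abs(b - a).max()))
    return drift < drift_tolerance, drift
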