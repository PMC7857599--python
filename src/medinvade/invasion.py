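"""The in silico invasion assay.

An invader is added at a chosen propagule fraction to a freshly
re-inoculated resident community, the coupled system is run for a further
200 generations, and the outcome is classified on the 2x2 of invader
persistence x resident richness maintenance:

* resistance    -- invader extinct, all residents maintained;
* augmentation  -- invader maintained, all residents maintained;
* displacement  -- invader maintained, at least one resident lost;
* disruption    -- invader extinct, at least one resident lost.

Persistence uses the same criterion for invader and residents: final
density above the extinction threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .config import ConfigurationError, CycleConfig, ResourceConfig
from .dynamics import CommunityState, CycleLog, run_cycles
from .assembly import ResidentCommunity
from .network import InteractionNetwork, InvaderSpec, attach_invader

__all__ = ["Outcome", "InvasionResult", "introduce", "classify", "run_assay"]


class Outcome(str, Enum):
    RESISTANCE = "resistance"
    AUGMENTATION = "augmentation"
    DISPLACEMENT = "displacement"
    DISRUPTION = "disruption"


OUTCOMES = (Outcome.RESISTANCE, Outcome.AUGMENTATION, Outcome.DISPLACEMENT, Outcome.DISRUPTION)


@dataclass
class InvasionResult:
    outcome: Outcome
    invader_final_fraction: float
    pre_richness: int
    post_richness: int
    propagule_fraction: float
    sub_detectable: bool = False
    stalled: bool = False
    generations: float = 0.0
    seed: int | None = None

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome.value,
            "invader_final_fraction": self.invader_final_fraction,
            "pre_richness": self.pre_richness,
            "post_richness": self.post_richness,
            "propagule_fraction": self.propagule_fraction,
            "sub_detectable": self.sub_detectable,
            "stalled": self.stalled,
            "seed": self.seed,
        }


def introduce(
    rc: ResidentCommunity,
    inv: InvaderSpec,
    propagule_fraction: float,
    cycle_cfg: CycleConfig | None = None,
    resource_cfg: ResourceConfig | None = None,
) -> tuple[CommunityState, InteractionNetwork, bool]:
    """Re-inoculate the residents and add the invader.

    Residents return to the inoculum density in their harvest proportions;
    the invader is added on top at ``propagule_fraction`` of that density
    (propagule size is measured relative to the resident total).  Mediators
    carry over from harvest, diluted by the re-inoculation factor; the
    resource (when configured) is reset to fresh supply.

    Returns the combined state (invader last), the combined network, and a
    flag marking sub-detectable propagules whose starting density is
    already below the extinction threshold.
    """
    if propagule_fraction <= 0:
        raise ConfigurationError("propagule_fraction must be positive")
    if rc.richness == 0:
        raise ConfigurationError("cannot invade a collapsed community")
    cfg = cycle_cfg or CycleConfig()
    combined = attach_invader(rc.subnetwork(), inv)
    factor = min(1.0, cfg.inoculum_density / rc.harvest_density.sum())
    invader_density = propagule_fraction * cfg.inoculum_density
    state = CommunityState(
        species_density=np.append(rc.fractions * cfg.inoculum_density, invader_density),
        mediator_conc=rc.harvest_mediators * factor,
        resource=resource_cfg.supply if resource_cfg is not None else None,
    )
    sub_detectable = invader_density < cfg.extinction_threshold
    return state, combined, sub_detectable


def classify(
    pre_richness: int,
    final_state: CommunityState,
    invader_index: int = -1,
    extinction_threshold: float = 0.1,
) -> Outcome:
    """Map the final state onto the four invasion outcomes.

    The invader persisted iff its final density exceeds the extinction
    threshold; resident richness is maintained iff every pre-invasion
    survivor still does.  Exactly one category applies to every completed
    assay.
    """
    densities = final_state.species_density
    invader_alive = bool(densities[invader_index] > extinction_threshold)
    residents = np.delete(densities, invader_index % densities.size)
    maintained = int((residents > extinction_threshold).sum()) == pre_richness
    if invader_alive:
        return Outcome.AUGMENTATION if maintained else Outcome.DISPLACEMENT
    return Outcome.RESISTANCE if maintained else Outcome.DISRUPTION


def run_assay(
    rc: ResidentCommunity,
    inv: InvaderSpec,
    propagule_fraction: float = 0.003,
    cycle_cfg: CycleConfig | None = None,
    model: str = "basic",
    resource_cfg: ResourceConfig | None = None,
    seed: int | None = None,
) -> InvasionResult:
    """introduce -> run for the generation target -> classify.

    ``seed`` is metadata recorded in the result; the assay itself is
    deterministic given the community and invader.
    """
    cfg = cycle_cfg or CycleConfig()
    rcfg = resource_cfg or ResourceConfig()
    use_resource = model == "resource"
    state0, combined, sub_detectable = introduce(
        rc, inv, propagule_fraction, cfg, rcfg if use_resource else None
    )
    final, log = run_cycles(
        state0, combined, cfg, model=model,
        fresh_resource=rcfg.supply if use_resource else None,
    )
    total = final.total_density
    invader_fraction = float(final.species_density[-1] / total) if total > 0 else 0.0
    post_richness = int((final.species_density[:-1] > cfg.extinction_threshold).sum())
    outcome = classify(rc.richness, final, -1, cfg.extinction_threshold)
    return InvasionResult(
        outcome=outcome,
        invader_final_fraction=invader_fraction,
        pre_richness=rc.richness,
        post_richness=post_richness,
        propagule_fraction=propagule_fraction,
        sub_detectable=sub_detectable,
        stalled=bool(log.stalled or log.collapsed),
        generations=final.cumulative_generations,
        seed=seed,
    )
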