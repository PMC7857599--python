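"""Shared fixtures: small pools, hand-built two-species motifs."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from medinvade import (
    CommunityState,
    CycleConfig,
    GeneratorConfig,
    InteractionNetwork,
    InvaderSpec,
    ResourceConfig,
    enrich,
)


@pytest.fixture
def gen_cfg() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture
def small_cfg() -> GeneratorConfig:
    return dataclasses.replace(GeneratorConfig(), n_species=3, n_mediators=2)


@pytest.fixture
def cycle_cfg() -> CycleConfig:
    return CycleConfig()


@pytest.fixture
def resource_cfg() -> ResourceConfig:
    return ResourceConfig()


def single_species_net(r0: float = 0.1, n_mediators: int = 1, beta: float = 0.0) -> InteractionNetwork:
    """One species, optionally producing mediator 0, no influences."""
    production = np.zeros((n_mediators, 1))
    if beta:
        production[0, 0] = beta
    return InteractionNetwork.from_rates(
        basal_rate=[r0],
        influence_rate=np.zeros((1, n_mediators)),
        production_rate=production,
    )


def plain_two_species(r_a: float = 0.12, r_b: float = 0.08) -> InteractionNetwork:
    """Two non-interacting species (pure exponential competition)."""
    return InteractionNetwork.from_rates(
        basal_rate=[r_a, r_b],
        influence_rate=np.zeros((2, 1)),
        production_rate=np.zeros((1, 2)),
    )


def mutual_inhibition_invader(
    basal: float = 0.1, beta: float = 0.1, amplitude: float = 0.08, K: float = 1.0e5
):
    """A resident/invader pair in which each poisons the other.

    The resident (species 0) produces mediator 0, which inhibits the
    invader; the invader produces mediator 1, which inhibits the resident.
    Basal rates are equal and the inhibition amplitude is below the basal
    rate so neither partner can drive total growth negative.
    """
    net = InteractionNetwork.from_rates(
        basal_rate=[basal],
        influence_rate=np.array([[0.0, -amplitude]]),
        production_rate=np.array([[beta], [0.0]]),
        saturation=K,
    )
    inv = InvaderSpec(
        basal_rate=basal,
        influence_rate=np.array([-amplitude, 0.0]),
        production_rate=np.array([0.0, beta]),
        consumption_rate=np.zeros(2),
        saturation=np.full(2, K),
        influence_link=np.array([True, False]),
        production_link=np.array([False, True]),
    )
    return net, inv


def commensal_invader(
    basal_resident: float = 0.1,
    basal_invader: float = 0.08,
    beta: float = 0.1,
    amplitude: float = 0.15,
    K: float = 1.0e5,
):
    """A resident that feeds an otherwise slower invader.

    The resident produces mediator 0 which facilitates the invader; the
    invader's basal rate alone is below the resident's, so its persistence
    depends entirely on the commensal boost.
    """
    net = InteractionNetwork.from_rates(
        basal_rate=[basal_resident],
        influence_rate=np.zeros((1, 1)),
        production_rate=np.array([[beta]]),
        saturation=K,
    )
    inv = InvaderSpec(
        basal_rate=basal_invader,
        influence_rate=np.array([amplitude]),
        production_rate=np.zeros(1),
        consumption_rate=np.zeros(1),
        saturation=np.array([K]),
        influence_link=np.array([True]),
        production_link=np.array([False]),
    )
    return net, inv


@pytest.fixture
def single_resident_community(cycle_cfg):
    """An enriched single-species resident community (trivially stable)."""
    net = single_species_net(r0=0.1, n_mediators=2, beta=0.1)
    rc, _ = enrich(net, cycle_cfg)
    return rc
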