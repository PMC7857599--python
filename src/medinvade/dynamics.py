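"""Batch growth--dilution dynamics of mediator-coupled communities.

The state couples species densities ``S_i`` (cells/ml) to mediator
concentrations ``C_i`` (fmole/ml).  Mediators are produced at constant
per-cell rates and taken up with saturating (Monod-type) kinetics; each
mediator modulates the growth rate of the species it links to with a signed
saturating term sharing the same half-saturation constant:

    dC_i/dt = sum_j [ beta_ij - alpha_ij * C_i / (C_i + K_ji) ] * S_j
    dS_i/dt = [ r_i0 + sum_j r_ij * C_j / (C_j + K_ij) ] * S_i

The resource variant multiplies every species' growth-rate bracket by
``R / (R + K_R,i)`` for a single shared resource ``R`` that is consumed in
proportion to realised growth and replenished at every dilution.

Integration is explicit forward Euler with a time step at least
``timestep_divisor`` times smaller than the shortest achievable doubling
time (a conservative bound from basal rates plus all facilitative
amplitudes).  Cultures grow from the inoculum density to the dilution
threshold (or, with the resource variant, for at most ``max_cycle_hours``),
are diluted back into fresh medium, and accrue generations as doublings of
total density until the generation target is met.  Species falling below
the extinction threshold after a dilution are removed permanently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .config import ConfigurationError, CycleConfig
from .network import InteractionNetwork, InvaderSpec, attach_invader

LN2 = math.log(2.0)

__all__ = [
    "CommunityState",
    "CycleLog",
    "CycleConfig",
    "derivatives",
    "derivatives_resource",
    "choose_timestep",
    "advance_cycle",
    "run_cycles",
]


@dataclass
class CommunityState:
    """Species densities + mediator concentrations (+ resource) at a time point."""

    species_density: np.ndarray          # cells/ml
    mediator_conc: np.ndarray            # fmole/ml
    resource: float | None = None        # fmole/ml; None in the basic model
    elapsed_time: float = 0.0            # hr
    cumulative_generations: float = 0.0  # doublings of total density

    def __post_init__(self) -> None:
        self.species_density = np.ascontiguousarray(self.species_density, dtype=float)
        self.mediator_conc = np.ascontiguousarray(self.mediator_conc, dtype=float)
        if (self.species_density < 0).any() or (self.mediator_conc < 0).any():
            raise ConfigurationError("densities and concentrations must be non-negative")

    @property
    def total_density(self) -> float:
        return float(self.species_density.sum())

    def copy(self) -> "CommunityState":
        return CommunityState(
            self.species_density.copy(),
            self.mediator_conc.copy(),
            self.resource,
            self.elapsed_time,
            self.cumulative_generations,
        )


@dataclass
class CycleLog:
    """Per-run event log: dilutions, extinctions, clamping, stall flags."""

    n_cycles: int = 0
    dilution_times: list = field(default_factory=list)       # hr, at each dilution
    cycle_generations: list = field(default_factory=list)    # log2 fold change per cycle
    end_totals: list = field(default_factory=list)           # cells/ml at each cycle end
    extinctions: list = field(default_factory=list)          # (cycle index, species index)
    clamped_steps: int = 0
    total_steps: int = 0
    stalled: bool = False
    collapsed: bool = False
    compositions: list = field(default_factory=list)         # end-of-cycle fractions (opt-in)

    def events(self) -> list[dict]:
        """The log flattened to JSON-lines-ready event dicts."""
        out: list[dict] = []
        for k, t in enumerate(self.dilution_times):
            out.append({"event": "dilution", "cycle": k, "time_hr": t})
        for cycle, species in self.extinctions:
            out.append({"event": "extinction", "cycle": cycle, "species": int(species)})
        if self.clamped_steps:
            out.append({"event": "clamp", "steps": self.clamped_steps})
        if self.stalled:
            out.append({"event": "stalled"})
        if self.collapsed:
            out.append({"event": "collapsed"})
        return out


def _resolve(net: InteractionNetwork, invader: InvaderSpec | None) -> InteractionNetwork:
    return net if invader is None else attach_invader(net, invader)


def derivatives(
    state: CommunityState,
    net: InteractionNetwork,
    invader: InvaderSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Right-hand side of the basic model: ``(dS/dt, dC/dt)``.

    If ``invader`` is given it is attached as the last species and
    ``state`` must already carry its density.
    """
    net = _resolve(net, invader)
    S = state.species_density
    C = state.mediator_conc
    if S.shape[0] != net.n_species or C.shape[0] != net.n_mediators:
        raise ConfigurationError("state dimensions do not match network")
    sat = C[None, :] / (C[None, :] + net.saturation)        # (n_s, n_m)
    growth = net.basal_rate + (net.influence_rate * sat).sum(axis=1)
    dS = growth * S
    dC = ((net.production_rate - net.consumption_rate * sat.T) * S[None, :]).sum(axis=1)
    return dS, dC


def derivatives_resource(
    state: CommunityState,
    net: InteractionNetwork,
    invader: InvaderSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Right-hand side of the resource variant: ``(dS/dt, dC/dt, dR/dt)``.

    The growth bracket of each species is scaled by ``R/(R+K_R,i)`` and the
    resource is consumed in proportion to realised growth; mediator
    dynamics are unchanged.  ``state.resource`` must be set.
    """
    if state.resource is None:
        raise ConfigurationError("resource model requires state.resource")
    net = _resolve(net, invader)
    S = state.species_density
    C = state.mediator_conc
    if S.shape[0] != net.n_species or C.shape[0] != net.n_mediators:
        raise ConfigurationError("state dimensions do not match network")
    R = float(state.resource)
    sat = C[None, :] / (C[None, :] + net.saturation)
    bracket = net.basal_rate + (net.influence_rate * sat).sum(axis=1)
    factor = R / (R + net.resource_saturation)
    growth = factor * bracket
    dS = growth * S
    dC = ((net.production_rate - net.consumption_rate * sat.T) * S[None, :]).sum(axis=1)
    dR = -float((net.resource_consumption * growth * S).sum())
    return dS, dC, dR


def choose_timestep(
    net: InteractionNetwork,
    invader: InvaderSpec | None = None,
    divisor: float = 10.0,
) -> float:
    """Euler step: shortest achievable doubling time over ``divisor``.

    The maximum achievable growth rate is bounded by each species' basal
    rate plus the sum of its facilitative influence amplitudes (saturating
    terms never exceed their amplitude), so

        dt = (ln 2 / max_i [r_i0 + sum_j max(r_ij, 0)]) / divisor.
    """
    if divisor <= 0:
        raise ConfigurationError("divisor must be positive")
    net = _resolve(net, invader)
    max_rate = float((net.basal_rate + np.clip(net.influence_rate, 0.0, None).sum(axis=1)).max())
    if max_rate <= 0:
        raise ConfigurationError("no species can achieve positive growth; timestep undefined")
    return LN2 / max_rate / divisor


@njit(cache=False)
def _euler_advance(S, C, r0, rinf, K, beta, alpha, use_resource, R, K_R, alpha_R,
                   dt, n_dil, max_steps):  # pragma: no cover - exercised via wrappers
    n_s = S.shape[0]
    n_m = C.shape[0]
    dC = np.empty(n_m)
    g = np.empty(n_s)
    steps = 0
    clamps = 0
    reached = False
    while steps < max_steps:
        for m in range(n_m):
            acc = 0.0
            for j in range(n_s):
                s = S[j]
                if s > 0.0:
                    acc += (beta[m, j] - alpha[m, j] * C[m] / (C[m] + K[j, m])) * s
            dC[m] = acc
        for i in range(n_s):
            gi = r0[i]
            for m in range(n_m):
                rij = rinf[i, m]
                if rij != 0.0:
                    gi += rij * C[m] / (C[m] + K[i, m])
            if use_resource:
                gi *= R / (R + K_R[i])
            g[i] = gi
        dR = 0.0
        total = 0.0
        for i in range(n_s):
            if use_resource:
                dR -= alpha_R[i] * g[i] * S[i]
            S[i] += dt * g[i] * S[i]
            if S[i] < 0.0:
                S[i] = 0.0
                clamps += 1
            total += S[i]
        for m in range(n_m):
            C[m] += dt * dC[m]
            if C[m] < 0.0:
                C[m] = 0.0
                clamps += 1
        if use_resource:
            R += dt * dR
            if R < 0.0:
                R = 0.0
                clamps += 1
        steps += 1
        if total >= n_dil:
            reached = True
            break
    return steps, clamps, R, reached


def _kernel_args(net: InteractionNetwork):
    return (
        np.ascontiguousarray(net.basal_rate),
        np.ascontiguousarray(net.influence_rate),
        np.ascontiguousarray(net.saturation),
        np.ascontiguousarray(net.production_rate),
        np.ascontiguousarray(net.consumption_rate),
    )


def _stall_cap(net: InteractionNetwork, cfg: CycleConfig, dt: float) -> int:
    # Flag a cycle as stalled when mean growth is slower than the slowest
    # basal rate divided by stall_factor (i.e. ~10x slower than the slowest
    # possible interaction-free culture).
    guard_rate = max(float(net.basal_rate.min()), 1.0e-3) / cfg.stall_factor
    span = math.log(cfg.dilution_threshold / cfg.inoculum_density)
    return int(math.ceil(span / (guard_rate * dt)))


def advance_cycle(
    state: CommunityState,
    net: InteractionNetwork,
    cycle_cfg: CycleConfig | None = None,
    model: str = "basic",
    invader: InvaderSpec | None = None,
    dt: float | None = None,
    max_steps: int | None = None,
) -> tuple[CommunityState, int, bool]:
    """Euler-step one growth interval; no dilution is applied.

    Advances until total density reaches the dilution threshold, the
    step budget runs out (``max_steps``; defaults to the stall guard for
    the basic model and to the 80-hour cap for the resource variant), or
    ``max_steps`` explicit steps were taken.  Returns the new state, the
    number of steps taken, and whether the threshold was reached.
    """
    cfg = cycle_cfg or CycleConfig()
    if model not in ("basic", "resource"):
        raise ConfigurationError(f"unknown model variant: {model!r}")
    net = _resolve(net, invader)
    use_resource = model == "resource"
    if use_resource and state.resource is None:
        raise ConfigurationError("resource model requires state.resource")
    if dt is None:
        dt = choose_timestep(net, divisor=cfg.timestep_divisor)
    if max_steps is None:
        if use_resource:
            max_steps = int(math.ceil(cfg.max_cycle_hours / dt))
        else:
            max_steps = _stall_cap(net, cfg, dt)
    S = state.species_density.copy()
    C = state.mediator_conc.copy()
    r0, rinf, K, beta, alpha = _kernel_args(net)
    R = float(state.resource) if use_resource else 0.0
    steps, clamps, R, reached = _euler_advance(
        S, C, r0, rinf, K, beta, alpha, use_resource, R,
        np.ascontiguousarray(net.resource_saturation),
        np.ascontiguousarray(net.resource_consumption),
        dt, cfg.dilution_threshold, max_steps,
    )
    new = CommunityState(
        S, C, R if use_resource else None,
        state.elapsed_time + steps * dt,
        state.cumulative_generations,
    )
    new._clamps = clamps  # type: ignore[attr-defined]
    return new, steps, bool(reached)


def run_cycles(
    state0: CommunityState,
    net: InteractionNetwork,
    cycle_cfg: CycleConfig | None = None,
    model: str = "basic",
    invader: InvaderSpec | None = None,
    dt: float | None = None,
    fresh_resource: float | None = None,
    record_compositions: bool = False,
) -> tuple[CommunityState, CycleLog]:
    """Integrate through growth--dilution cycles to the generation target.

    Each cycle grows until the dilution threshold (resource variant: or the
    80-hour cap), accrues ``log2(end/start)`` generations, then dilutes all
    species and mediators by ``inoculum/total`` (never concentrating) and
    resets the resource to ``fresh_resource`` (default: the starting
    resource level).  Species below the extinction threshold after a
    dilution are zeroed permanently.  The run returns at the first cycle
    end where cumulative generations reach the target -- the harvest state
    is therefore pre-dilution, at the dilution threshold in the basic
    model.

    A basic-model cycle that fails to reach the threshold within the stall
    guard (mean growth ~``stall_factor`` times slower than the slowest
    basal rate) ends the run with ``log.stalled``; losing every species
    ends it with ``log.collapsed``.
    """
    cfg = cycle_cfg or CycleConfig()
    if model not in ("basic", "resource"):
        raise ConfigurationError(f"unknown model variant: {model!r}")
    net = _resolve(net, invader)
    use_resource = model == "resource"
    if use_resource and state0.resource is None:
        raise ConfigurationError("resource model requires state.resource")
    if dt is None:
        dt = choose_timestep(net, divisor=cfg.timestep_divisor)
    if use_resource:
        max_steps = int(math.ceil(cfg.max_cycle_hours / dt))
        if fresh_resource is None:
            fresh_resource = float(state0.resource)
    else:
        max_steps = _stall_cap(net, cfg, dt)
    max_cycles = int(math.ceil(cfg.stall_factor * cfg.target_generations))

    S = state0.species_density.copy()
    C = state0.mediator_conc.copy()
    R = float(state0.resource) if use_resource else 0.0
    t = state0.elapsed_time
    gens = state0.cumulative_generations
    log = CycleLog()
    r0, rinf, K, beta, alpha = _kernel_args(net)
    k_r = np.ascontiguousarray(net.resource_saturation)
    a_r = np.ascontiguousarray(net.resource_consumption)

    while gens < cfg.target_generations:
        start_total = float(S.sum())
        if start_total <= 0.0:
            log.collapsed = True
            break
        steps, clamps, R, reached = _euler_advance(
            S, C, r0, rinf, K, beta, alpha, use_resource, R, k_r, a_r,
            dt, cfg.dilution_threshold, max_steps,
        )
        t += steps * dt
        log.total_steps += steps
        log.clamped_steps += clamps
        end_total = float(S.sum())
        if end_total <= 0.0:
            log.collapsed = True
            break
        if not reached and not use_resource:
            log.stalled = True
            break
        fold = math.log2(end_total / start_total)
        gens += fold
        log.cycle_generations.append(fold)
        log.end_totals.append(end_total)
        if record_compositions:
            log.compositions.append(S / end_total)
        cycle_index = log.n_cycles
        log.n_cycles += 1
        if gens >= cfg.target_generations:
            break
        if log.n_cycles >= max_cycles:
            log.stalled = True
            break
        # dilution into fresh medium
        factor = min(1.0, cfg.inoculum_density / end_total)
        S *= factor
        C *= factor
        if use_resource:
            R = fresh_resource
        log.dilution_times.append(t)
        dead = np.flatnonzero((S > 0.0) & (S < cfg.extinction_threshold))
        for idx in dead:
            S[idx] = 0.0
            log.extinctions.append((cycle_index, int(idx)))

    final = CommunityState(S, C, R if use_resource else None, t, gens)
    return final, log
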