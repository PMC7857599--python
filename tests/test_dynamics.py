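"""Derivatives, time-step rule, Euler kernel, and the growth--dilution protocol."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medinvade import (
    CommunityState,
    ConfigurationError,
    CycleConfig,
    GeneratorConfig,
    InteractionNetwork,
    advance_cycle,
    choose_timestep,
    derivatives,
    derivatives_resource,
    generate_network,
    run_cycles,
)
from conftest import plain_two_species, single_species_net
from oracles import naive_derivatives

LN2 = math.log(2.0)


class TestDerivatives:
    def test_isolated_species_grows_at_basal_rate(self):
        net = single_species_net(r0=0.1)
        state = CommunityState([1.0e4], [0.0])
        dS, dC = derivatives(state, net)
        assert dS[0] == pytest.approx(1.0e3)
        assert dC[0] == 0.0

    def test_pure_producer_mediator_accumulation(self):
        net = single_species_net(r0=0.1, beta=0.1)
        state = CommunityState([1.0e4], [0.0])
        _, dC = derivatives(state, net)
        assert dC[0] == pytest.approx(1.0e3)

    def test_saturation_limits(self):
        # at C >> K the uptake term approaches alpha*S and the growth
        # influence approaches its full amplitude
        net = InteractionNetwork.from_rates(
            basal_rate=[0.1],
            influence_rate=np.array([[0.15]]),
            production_rate=np.zeros((1, 1)),
            consumption_rate=np.array([[0.5]]),
            saturation=1.0e5,
        )
        state = CommunityState([1.0e4], [1.0e12])
        dS, dC = derivatives(state, net)
        assert dS[0] == pytest.approx((0.1 + 0.15) * 1.0e4, rel=1e-6)
        assert dC[0] == pytest.approx(-0.5 * 1.0e4, rel=1e-6)

    def test_matches_naive_double_loop_oracle(self, small_cfg):
        rng = np.random.default_rng(0)
        for seed in range(10):
            net = generate_network(small_cfg, seed=seed)
            state = CommunityState(rng.uniform(1e2, 1e6, 3), rng.uniform(0, 2e5, 2))
            dS, dC = derivatives(state, net)
            eS, eC = naive_derivatives(state.species_density, state.mediator_conc, net)
            np.testing.assert_allclose(dS, eS, rtol=1e-12)
            np.testing.assert_allclose(dC, eC, rtol=1e-12)

    def test_dimension_mismatch_rejected(self, small_cfg):
        net = generate_network(small_cfg, seed=0)
        with pytest.raises(ConfigurationError):
            derivatives(CommunityState([1.0, 1.0], [0.0, 0.0]), net)


class TestResourceDerivatives:
    @pytest.fixture
    def net(self):
        return single_species_net(r0=0.1)

    def test_no_resource_halts_growth_and_consumption(self, net):
        state = CommunityState([1.0e4], [0.0], resource=0.0)
        dS, dC, dR = derivatives_resource(state, net)
        assert dS[0] == 0.0 and dR == 0.0

    def test_abundant_resource_recovers_basic_model(self, small_cfg):
        net = generate_network(small_cfg, seed=1)
        state = CommunityState([1e4, 2e4, 3e4], [1e4, 5e4], resource=1.0e15)
        dS_b, dC_b = derivatives(state, net)
        dS_r, dC_r, _ = derivatives_resource(state, net)
        np.testing.assert_allclose(dS_r, dS_b, rtol=1e-6)
        np.testing.assert_allclose(dC_r, dC_b, rtol=1e-12)

    def test_single_species_closed_form(self, net):
        # dR/dt = -alpha_R * (R/(R+K_R)) * r0 * S
        R, K_R, alpha_R = 5.0e5, 1.0e6, 10.0
        net.resource_saturation[:] = K_R
        net.resource_consumption[:] = alpha_R
        state = CommunityState([1.0e4], [0.0], resource=R)
        dS, _, dR = derivatives_resource(state, net)
        factor = R / (R + K_R)
        assert dS[0] == pytest.approx(factor * 0.1 * 1e4, rel=1e-12)
        assert dR == pytest.approx(-alpha_R * factor * 0.1 * 1e4, rel=1e-12)

    def test_missing_resource_is_structural_error(self, net):
        with pytest.raises(ConfigurationError):
            derivatives_resource(CommunityState([1.0e4], [0.0]), net)


class TestChooseTimestep:
    def test_matches_doubling_time_rule(self):
        net = single_species_net(r0=0.12)
        assert choose_timestep(net) == pytest.approx(LN2 / 0.12 / 10, rel=1e-12)
        assert choose_timestep(net) == pytest.approx(0.5776, rel=1e-3)

    def test_facilitative_links_tighten_the_step(self):
        net = InteractionNetwork.from_rates(
            basal_rate=[0.1, 0.1],
            influence_rate=np.array([[0.2, 0.0], [-0.2, 0.1]]),
            production_rate=np.zeros((2, 2)),
        )
        # species 0 can reach 0.1+0.2, species 1 only 0.1+0.1 (inhibition ignored)
        assert choose_timestep(net) == pytest.approx(LN2 / 0.3 / 10, rel=1e-12)

    def test_divisor_scales_inversely(self):
        net = single_species_net()
        assert choose_timestep(net, divisor=1000) == pytest.approx(
            choose_timestep(net, divisor=10) / 100, rel=1e-12
        )


class TestEulerKernel:
    def test_kernel_reproduces_explicit_numpy_stepping(self, small_cfg):
        net = generate_network(small_cfg, seed=2)
        dt = choose_timestep(net)
        state = CommunityState(np.array([3e3, 3e3, 4e3]), np.zeros(2))
        stepped, n, reached = advance_cycle(
            state, net, CycleConfig(), dt=dt, max_steps=50
        )
        assert n == 50 and not reached
        S = state.species_density.copy()
        C = state.mediator_conc.copy()
        for _ in range(50):
            dS, dC = derivatives(CommunityState(S, C), net)
            S = np.maximum(S + dt * dS, 0.0)
            C = np.maximum(C + dt * dC, 0.0)
        np.testing.assert_allclose(stepped.species_density, S, rtol=1e-12)
        np.testing.assert_allclose(stepped.mediator_conc, C, rtol=1e-12)


class TestRunCycles:
    def test_single_species_cycle_matches_exponential_closed_form(self):
        # one cycle from 1e4 to 1e7 at r0=0.1: continuous time ln(1000)/0.1
        # = 69.1 hr; Euler's per-step growth log(1+r dt) shifts that by a
        # known O(dt) bias
        net = single_species_net(r0=0.1)
        dt = choose_timestep(net)
        state = CommunityState([1.0e4], [0.0])
        out, steps, reached = advance_cycle(state, net, CycleConfig(), dt=dt)
        assert reached
        euler_rate = math.log(1 + 0.1 * dt) / dt
        expected_hours = math.log(1000.0) / euler_rate
        assert steps * dt == pytest.approx(expected_hours, abs=dt)
        assert math.log(1000.0) / 0.1 == pytest.approx(69.1, abs=0.1)
        assert steps * dt == pytest.approx(69.1, rel=0.05)

    def test_generation_accounting_and_cycle_count(self):
        net = single_species_net(r0=0.1)
        state = CommunityState([1.0e4], [0.0])
        final, log = run_cycles(state, net)
        # each 1000-fold cycle contributes ~log2(1000) = 9.966 generations
        assert log.cycle_generations[0] == pytest.approx(math.log2(1000.0), abs=0.1)
        assert log.n_cycles in (20, 21)
        assert final.cumulative_generations >= 200.0
        # exact identity: the per-cycle log2 folds sum to the cumulative count
        assert sum(log.cycle_generations) == pytest.approx(
            final.cumulative_generations, abs=1e-9
        )

    def test_dilution_factor_and_mediator_carryover(self):
        net = single_species_net(r0=0.1, beta=0.1)
        cfg = CycleConfig(target_generations=15.0)
        state = CommunityState([1.0e4], [0.0])
        final, log = run_cycles(state, net, cfg)
        assert log.n_cycles == 2
        # after the first dilution the culture restarted at ~1e4, so the
        # second cycle also shows a ~1000-fold climb
        assert log.end_totals[1] == pytest.approx(log.end_totals[0], rel=0.1)

    def test_species_below_extinction_threshold_removed_permanently(self):
        net = plain_two_species(r_a=0.1, r_b=0.1)
        state = CommunityState([1.0e4, 0.05], [0.0])
        final, log = run_cycles(state, net, CycleConfig(target_generations=40.0))
        # the rare species grows by ~1000x within the cycle but is diluted
        # back below 0.1 cells/ml, at which point it is zeroed
        assert final.species_density[1] == 0.0
        assert (0, 1) in log.extinctions

    def test_dilution_overshoot_is_bounded_by_one_step(self):
        net = single_species_net(r0=0.12)
        state = CommunityState([1.0e4], [0.0])
        final, log = run_cycles(state, net, CycleConfig(target_generations=50.0))
        dt = choose_timestep(net)
        assert max(log.end_totals) <= 1.0e7 * (1 + 0.12 * dt)

    def test_self_poisoning_culture_flags_stalled(self):
        # a species producing a strong self-inhibitor stops growing long
        # before the dilution threshold
        net = InteractionNetwork.from_rates(
            basal_rate=[0.1],
            influence_rate=np.array([[-0.2]]),
            production_rate=np.array([[0.5]]),
            saturation=100.0,
        )
        state = CommunityState([1.0e4], [0.0])
        final, log = run_cycles(state, net)
        assert log.stalled
        assert final.cumulative_generations < 200.0

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_state_never_negative(self, seed):
        cfg = GeneratorConfig(n_species=4, n_mediators=3)
        net = generate_network(cfg, seed=seed)
        state = CommunityState(np.full(4, 2.5e3), np.zeros(3))
        final, log = run_cycles(state, net, CycleConfig(target_generations=25.0))
        assert (final.species_density >= 0).all()
        assert (final.mediator_conc >= 0).all()


class TestResourceRunCycles:
    def test_resource_limited_cycle_ends_at_time_cap(self):
        # R0=1e6 at alpha_R=10 supports only ~1e5 cells/ml, so the culture
        # cannot reach 1e7 and the 80-hour cap triggers the dilution
        net = single_species_net(r0=0.1)
        net.resource_saturation[:] = 1.0e6
        net.resource_consumption[:] = 10.0
        state = CommunityState([1.0e4], [0.0], resource=1.0e6)
        out, steps, reached = advance_cycle(state, net, CycleConfig(), model="resource")
        assert not reached
        dt = choose_timestep(net)
        assert steps == math.ceil(80.0 / dt)
        assert out.total_density < 2.0e5

    def test_resource_conservation_within_one_cycle(self):
        # with no mediators dR = -alpha_R dS holds step by step, so the
        # depletion equals alpha_R times the density gain to round-off
        net = single_species_net(r0=0.1)
        net.resource_saturation[:] = 1.0e6
        net.resource_consumption[:] = 10.0
        state = CommunityState([1.0e4], [0.0], resource=1.0e6)
        out, _, _ = advance_cycle(state, net, CycleConfig(), model="resource")
        consumed = 1.0e6 - out.resource
        gained = out.total_density - 1.0e4
        assert consumed == pytest.approx(10.0 * gained, rel=1e-9)

    def test_resource_reset_at_dilution_allows_repeated_growth(self):
        net = single_species_net(r0=0.1)
        net.resource_saturation[:] = 1.0e6
        net.resource_consumption[:] = 10.0
        state = CommunityState([1.0e4], [0.0], resource=1.0e6)
        final, log = run_cycles(
            state, net, CycleConfig(target_generations=10.0), model="resource"
        )
        assert log.n_cycles >= 2
        # every cycle achieves a similar fold because the resource is fresh
        folds = log.cycle_generations
        assert max(folds) - min(folds) < 0.5 * max(folds)

    def test_missing_resource_state_rejected(self):
        net = single_species_net()
        with pytest.raises(ConfigurationError):
            run_cycles(CommunityState([1e4], [0.0]), net, model="resource")
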