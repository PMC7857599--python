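"""Random pool and invader generation: determinism, topology, signs, ablation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medinvade import (
    ConfigurationError,
    GeneratorConfig,
    InteractionNetwork,
    InvaderSpec,
    ablate_invader,
    attach_invader,
    generate_invader,
    generate_network,
    invader_from_species,
)


class TestGenerateNetwork:
    def test_identical_seed_gives_byte_identical_serialization(self, gen_cfg):
        a = generate_network(gen_cfg, seed=42)
        b = generate_network(gen_cfg, seed=42)
        assert a.to_json() == b.to_json()
        c = generate_network(gen_cfg, seed=43)
        assert a.to_json() != c.to_json()

    def test_roundtrip_through_json(self, gen_cfg, tmp_path):
        net = generate_network(gen_cfg, seed=7)
        path = tmp_path / "net.json"
        net.to_json(path)
        back = InteractionNetwork.from_json(path)
        assert back.to_json() == net.to_json()

    def test_zero_connectivity_gives_empty_matrices(self, gen_cfg):
        cfg = dataclasses.replace(gen_cfg, q_production=0.0, q_influence=0.0)
        net = generate_network(cfg, seed=0)
        assert not net.production_rate.any()
        assert not net.influence_rate.any()
        assert not net.consumption_rate.any()

    def test_full_facilitation_makes_all_influences_positive(self, gen_cfg):
        cfg = dataclasses.replace(gen_cfg, f_facilitation=1.0, q_influence=1.0)
        net = generate_network(cfg, seed=3)
        assert (net.influence_rate > 0).all()

    def test_link_counts_match_binomial_expectation(self, gen_cfg):
        # production links ~ Binomial(200, 0.3): mean 60, sd 6.48; the mean
        # over 300 pools has SE ~0.37, so a 4-sigma band is (58.5, 61.5)
        counts = [generate_network(gen_cfg, seed=s).production_link.sum() for s in range(300)]
        assert abs(np.mean(counts) - 60.0) < 1.5

    def test_sign_fraction_converges_to_f_facilitation(self, gen_cfg):
        pos = tot = 0
        for s in range(200):
            net = generate_network(gen_cfg, seed=s)
            nz = net.influence_rate[net.influence_rate != 0]
            pos += (nz > 0).sum()
            tot += nz.size
        frac = pos / tot  # ~12000 draws: 4-sigma band around 0.5 is +-0.018
        assert abs(frac - 0.5) < 0.02

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        q_p=st.floats(0.0, 1.0),
        q_c=st.floats(0.0, 1.0),
        f_fac=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_structural_invariants_hold_for_any_connectivity(self, q_p, q_c, f_fac, seed):
        cfg = GeneratorConfig(
            n_species=6, n_mediators=4, q_production=q_p, q_influence=q_c, f_facilitation=f_fac
        )
        net = generate_network(cfg, seed=seed)
        lo_b, hi_b = cfg.production_rate_range
        lo_a, hi_a = cfg.consumption_rate_range
        lo_r, hi_r = cfg.influence_amplitude_range
        on = net.production_link
        assert ((net.production_rate[on] >= lo_b) & (net.production_rate[on] <= hi_b)).all()
        assert not net.production_rate[~on].any()
        on = net.influence_link
        mag = np.abs(net.influence_rate[on])
        assert ((mag >= lo_r) & (mag <= hi_r)).all()
        assert not net.influence_rate[~on].any()
        # consumption topology follows influence topology
        on_t = net.influence_link.T
        assert ((net.consumption_rate[on_t] >= lo_a) & (net.consumption_rate[on_t] <= hi_a)).all()
        assert not net.consumption_rate[~on_t].any()
        assert (net.saturation > 0).all()

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(q_production=1.2)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(basal_rate_range=(0.12, 0.08))
        with pytest.raises(ConfigurationError):
            GeneratorConfig(saturation_range_nM=(0.0, 100.0))


class TestGenerateInvader:
    def test_basal_rate_scales_with_advantage_ratio(self, gen_cfg):
        net = generate_network(gen_cfg, seed=0)
        rates = [generate_invader(net, gen_cfg, 1.5, seed=s).basal_rate for s in range(200)]
        assert min(rates) >= 0.12 and max(rates) <= 0.18

    def test_nonpositive_ratio_rejected(self, gen_cfg):
        net = generate_network(gen_cfg, seed=0)
        with pytest.raises(ConfigurationError):
            generate_invader(net, gen_cfg, 0.0, seed=1)

    def test_mostly_inhibitory_invader_sign_fraction(self, gen_cfg):
        cfg = dataclasses.replace(gen_cfg, f_facilitation_invader=0.1)
        net = generate_network(cfg, seed=0)
        pos = tot = 0
        for s in range(500):
            inv = generate_invader(net, cfg, 1.5, seed=s)
            nz = inv.influence_rate[inv.influence_rate != 0]
            pos += (nz > 0).sum()
            tot += nz.size
        assert abs(pos / tot - 0.1) < 0.05

    def test_full_connectivity_all_inhibitory(self, gen_cfg):
        cfg = dataclasses.replace(gen_cfg, q_influence=1.0, f_facilitation_invader=0.0)
        net = generate_network(cfg, seed=0)
        inv = generate_invader(net, cfg, 1.5, seed=1)
        assert (inv.influence_rate < 0).all()

    def test_copy_of_resident_matches_resident(self, gen_cfg):
        net = generate_network(gen_cfg, seed=5)
        inv = invader_from_species(net, 3)
        assert inv.basal_rate == net.basal_rate[3]
        assert (inv.influence_rate == net.influence_rate[3]).all()
        assert (inv.production_rate == net.production_rate[:, 3]).all()
        combined = attach_invader(net, inv)
        assert combined.n_species == net.n_species + 1
        assert (combined.influence_rate[-1] == net.influence_rate[3]).all()


class TestAblation:
    @pytest.fixture
    def invader(self, gen_cfg):
        net = generate_network(gen_cfg, seed=0)
        return generate_invader(net, gen_cfg, 1.5, seed=11)

    def test_no_flags_is_identity(self, invader):
        same = ablate_invader(invader)
        assert (same.effective_influence == invader.influence_rate).all()
        assert (same.effective_production == invader.production_rate).all()
        assert (same.effective_consumption == invader.consumption_rate).all()

    def test_each_flag_zeroes_its_channel_only(self, invader):
        cases = {
            "production": ablate_invader(invader, remove_production=True),
            "consumption": ablate_invader(invader, remove_consumption=True),
            "influence": ablate_invader(invader, remove_influence=True),
        }
        assert not cases["production"].effective_production.any()
        assert (cases["production"].effective_consumption == invader.consumption_rate).all()
        assert not cases["consumption"].effective_consumption.any()
        assert (cases["consumption"].effective_influence == invader.influence_rate).all()
        assert not cases["influence"].effective_influence.any()
        assert (cases["influence"].effective_production == invader.production_rate).all()

    def test_stored_rates_and_links_untouched(self, invader):
        gone = ablate_invader(invader, True, True, True)
        assert (gone.production_rate == invader.production_rate).all()
        assert (gone.influence_link == invader.influence_link).all()
        assert not gone.effective_production.any()
        assert not gone.effective_consumption.any()
        assert not gone.effective_influence.any()

    def test_flags_accumulate(self, invader):
        step1 = ablate_invader(invader, remove_production=True)
        step2 = ablate_invader(step1, remove_influence=True)
        assert step2.production_removed and step2.influence_removed
        assert not step2.consumption_removed
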