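import math

import numpy as np
import pytest

import ruralfv as rf
from ruralfv.community import (
    Agent,
    Community,
    FoodOutlet,
    community_from_csv,
    community_to_csv,
    outlet_ratio,
    sample_demographics,
    set_nearest_fv_distances,
)
from ruralfv.errors import ConfigError, DomainError, NoFVSourceError


class TestAgentCount:
    def test_rural_full_scale(self, rural_community):
        # 1503.4 persons/sq-mile x 3.43 sq-miles
        assert len(rural_community.agents) == 5157

    def test_urban_full_scale_count(self):
        cfg = rf.urban_ca().replace(subsample_factor=1.0)
        assert cfg.n_agents == 137122

    def test_subsampling(self, rural_config):
        assert rural_config.replace(subsample_factor=0.1).n_agents == 516

    def test_zero_density_warns_and_is_empty(self, rural_config):
        cfg = rural_config.replace(pop_density=0.0)
        with pytest.warns(UserWarning, match="zero agents"):
            com = rf.build_community(cfg, seed=0)
        assert com.agents == []
        assert len(com.outlets) == 10


class TestDemographics:
    @pytest.mark.parametrize(
        "extract, expected",
        [
            (lambda d: d[1] == "female", 0.50),
            (lambda d: d[2] == "below_hs", 1 - 0.664),
            (lambda d: d[2] == "bachelor_plus", 0.08),
            (lambda d: d[0] == "18_65", 0.547),
        ],
    )
    def test_marginal_recovery(self, rural_config, extract, expected):
        n = 50_000
        rng = np.random.default_rng(5)
        draws = sample_demographics(rural_config, n, rng)
        share = sum(extract(d) for d in draws) / n
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(share - expected) < 3 * se

    def test_empty(self, rural_config):
        assert sample_demographics(rural_config, 0, np.random.default_rng(0)) == []

    def test_inconsistent_marginals_rejected(self, rural_config):
        with pytest.raises(ConfigError):
            rural_config.replace(pct_bachelors_or_higher=0.9)

    def test_age_remainder_split(self, rural_config):
        rng = np.random.default_rng(1)
        draws = sample_demographics(rural_config, 50_000, rng)
        under = sum(d[0] == "under18" for d in draws)
        over = sum(d[0] == "over65" for d in draws)
        # remainder 45.3% split 0.6 : 0.4
        assert under / (under + over) == pytest.approx(0.6, abs=0.02)


def _community_with_counts(n_lim, n_full, n_super, n_fv):
    outlets = []
    oid = 0
    for t, n in (
        ("limited_service", n_lim),
        ("full_service", n_full),
        ("supermarket", n_super),
        ("fv_market", n_fv),
    ):
        for _ in range(n):
            outlets.append(
                FoodOutlet(oid, t, (0.0, 0.0), t in ("supermarket", "fv_market"), 1.0)
            )
            oid += 1
    cfg = rf.rural_tx().replace(
        n_limited_service=n_lim, n_full_service=n_full,
        n_supermarkets=n_super, n_fv_markets=n_fv,
    )
    return Community(config=cfg, agents=[], outlets=outlets, rng_seed=0)


class TestOutletRatio:
    def test_rural_worked_example(self, rural_community):
        ratio = outlet_ratio(rural_community)
        assert ratio.rounded == 2
        assert ratio.exact == pytest.approx(7 / 3)

    def test_urban_worked_example(self):
        com = _community_with_counts(87, 26, 2, 14)
        ratio = outlet_ratio(com)
        assert ratio.rounded == 7
        assert ratio.exact == pytest.approx(113 / 16)

    def test_no_unhealthy(self):
        assert outlet_ratio(_community_with_counts(0, 0, 3, 0)).rounded == 0

    def test_no_healthy_raises(self):
        with pytest.raises(NoFVSourceError):
            outlet_ratio(_community_with_counts(2, 2, 0, 0))

    def test_brute_force_recount(self):
        """Ratio matches a direct healthy/unhealthy recount on random counts."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_lim, n_full, n_super, n_fv = rng.integers(0, 20, size=4)
            if n_super + n_fv == 0:
                continue
            com = _community_with_counts(int(n_lim), int(n_full), int(n_super), int(n_fv))
            healthy = sum(o.outlet_type in ("supermarket", "fv_market") for o in com.outlets)
            unhealthy = len(com.outlets) - healthy
            expected = unhealthy / healthy
            ratio = outlet_ratio(com)
            assert ratio.exact == pytest.approx(expected)
            assert ratio.rounded == int(math.ceil(expected - 0.5))


class TestDistances:
    def test_fixed_mode_sets_everyone(self, small_community):
        set_nearest_fv_distances(small_community, mode="fixed", fixed_value=5.0)
        assert all(a.nearest_fv_distance == 5.0 for a in small_community.agents)

    def test_fixed_mode_requires_value(self, small_community):
        with pytest.raises(DomainError):
            set_nearest_fv_distances(small_community, mode="fixed", fixed_value=None)

    def test_geometric_scaling_linearity(self, small_config):
        com1 = rf.build_community(small_config, seed=3, distance_mode="geometric")
        com2 = rf.build_community(
            small_config.replace(distance_scale=10.0), seed=3, distance_mode="geometric"
        )
        d1 = np.array([a.nearest_fv_distance for a in com1.agents])
        d2 = np.array([a.nearest_fv_distance for a in com2.agents])
        np.testing.assert_allclose(d2, 2 * d1, rtol=1e-12)

    def test_geometric_values(self, small_config):
        com = rf.build_community(small_config, seed=3, distance_mode="geometric")
        healthy_pos = np.array([o.position for o in com.healthy_outlets()])
        agent = com.agents[0]
        expected = small_config.distance_scale * np.min(
            np.hypot(*(healthy_pos - np.array(agent.position)).T)
        )
        assert agent.nearest_fv_distance == pytest.approx(expected, rel=1e-9)

    def test_colocated_agent_distance_zero(self, small_config):
        com = rf.build_community(small_config, seed=3, distance_mode="geometric")
        target = com.healthy_outlets()[0]
        com.agents[0].position = target.position
        set_nearest_fv_distances(com, mode="geometric")
        assert com.agents[0].nearest_fv_distance == 0.0

    def test_no_fv_source_raises(self, rural_config):
        cfg = rural_config.replace(n_supermarkets=0, n_fv_markets=0, subsample_factor=0.02)
        with pytest.raises(NoFVSourceError):
            rf.build_community(cfg, seed=0)


class TestBuildInvariants:
    def test_positions_inside_square(self, small_community):
        side = small_community.side
        for a in small_community.agents:
            assert 0 <= a.position[0] <= side and 0 <= a.position[1] <= side

    def test_peers_symmetric_no_self(self, small_community):
        peers = {a.id: set(a.peers) for a in small_community.agents}
        for i, ps in peers.items():
            assert i not in ps
            for j in ps:
                assert i in peers[j]

    def test_random_peer_mode(self, small_config):
        com = rf.build_community(small_config, seed=3, peer_mode="random")
        peers = {a.id: set(a.peers) for a in com.agents}
        assert any(peers.values())
        for i, ps in peers.items():
            assert i not in ps

    def test_outlet_counts_match_config(self, small_community):
        cfg = small_community.config
        by_type = {t: len(small_community.outlets_of_type(t)) for t in
                   ("limited_service", "full_service", "supermarket", "fv_market")}
        assert by_type == {
            "limited_service": cfg.n_limited_service,
            "full_service": cfg.n_full_service,
            "supermarket": cfg.n_supermarkets,
            "fv_market": cfg.n_fv_markets,
        }

    def test_healthy_flag_consistency(self):
        with pytest.raises(ConfigError):
            FoodOutlet(0, "supermarket", (0, 0), healthy=False, price_level=1.0)

    def test_invalid_config_rejected(self, rural_config):
        with pytest.raises(ConfigError):
            rural_config.replace(land_area=0.0)
        with pytest.raises(ConfigError):
            rural_config.replace(distance_scale=-1.0)
        with pytest.raises(ConfigError):
            rf.build_community(rural_config, seed=-1)


class TestSerialization:
    def test_determinism_byte_identical(self, small_config):
        a = community_to_csv(rf.build_community(small_config, seed=7))
        b = community_to_csv(rf.build_community(small_config, seed=7))
        assert a == b

    def test_seed_changes_output(self, small_config):
        a = community_to_csv(rf.build_community(small_config, seed=7))
        b = community_to_csv(rf.build_community(small_config, seed=8))
        assert a != b

    def test_round_trip(self, small_community, small_config):
        agents_csv, outlets_csv = community_to_csv(small_community)
        back = community_from_csv(agents_csv, outlets_csv, small_config, seed=7)
        assert community_to_csv(back) == (agents_csv, outlets_csv)
        a0, b0 = small_community.agents[0], back.agents[0]
        assert a0 == b0
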