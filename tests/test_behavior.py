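import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ruralfv as rf
from ruralfv.behavior import (
    ALTERNATIVES,
    BehaviorParams,
    access_score,
    choice_probabilities,
    choice_probability_matrix,
    compute_weights,
    draw_daily_servings,
    tilt_pmf,
    update_health_belief,
)
from ruralfv.community import Agent
from ruralfv.errors import ConfigError, DomainError


def _agent(education="hs", belief=0.5, d_fv=5.0, d_lim=2.0, d_full=2.0, ps=1.0):
    return Agent(
        id=0, position=(0.5, 0.5), age_group="18_65", sex="female",
        education=education, health_belief=belief, price_sensitivity=ps,
        nearest_fv_distance=d_fv, nearest_limited_distance=d_lim,
        nearest_full_distance=d_full,
    )


class TestWeights:
    def test_low_education_price_boost(self):
        params = BehaviorParams(price_weight_boost_low_edu=1.0,
                                health_weight_boost_belief=1.0)
        w = compute_weights(_agent(education="below_hs", belief=0.0), params)
        assert w == pytest.approx((0.2, 0.4, 0.2, 0.2))

    def test_no_modifier_uniform(self):
        params = BehaviorParams(price_weight_boost_low_edu=7.0,
                                health_weight_boost_belief=3.0)
        w = compute_weights(_agent(education="bachelor_plus", belief=0.0), params)
        assert w == pytest.approx((0.25, 0.25, 0.25, 0.25))

    def test_price_weight_ordering_by_education(self, params):
        low = compute_weights(_agent(education="below_hs", belief=0.3), params)
        high = compute_weights(_agent(education="bachelor_plus", belief=0.3), params)
        assert low.price > high.price

    def test_belief_raises_health_weight(self, params):
        strong = compute_weights(_agent(belief=1.0), params)
        weak = compute_weights(_agent(belief=0.0), params)
        assert strong.health > weak.health

    def test_normalized(self, params):
        w = compute_weights(_agent(education="below_hs", belief=0.8), params)
        assert sum(w) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_base_weights_rejected(self):
        with pytest.raises(ConfigError):
            BehaviorParams(w_taste_base=0, w_price_base=0, w_access_base=0,
                           w_health_base=0)


class TestAccessScore:
    def test_midpoint_is_half(self):
        params = BehaviorParams(kappa=1.7, delta=2.8)
        assert access_score(2.8, params) == pytest.approx(0.5)

    def test_closed_form_at_zero(self):
        params = BehaviorParams(kappa=1.0, delta=3.25)
        # 1 / (1 + e^-3.25)
        assert access_score(0.0, params) == pytest.approx(0.9627, abs=5e-5)

    def test_strictly_decreasing(self, params):
        grid = np.linspace(0, 12, 60)
        scores = access_score(grid, params)
        assert np.all(np.diff(scores) < 0)

    def test_vanishes_at_infinity(self, params):
        assert access_score(1e6, params) < 1e-12

    def test_negative_distance_rejected(self, params):
        with pytest.raises(DomainError):
            access_score(-0.1, params)

    def test_hard_threshold_variant(self):
        params = BehaviorParams(hard_threshold_access=True, delta=5.0)
        assert access_score(4.9, params) == 1.0
        assert access_score(5.1, params) == 0.0


class TestChoiceProbabilities:
    def test_symmetric_attributes_give_uniform(self, small_community):
        params = BehaviorParams(
            w_access_base=0.0,
            attr_taste=(0.5, 0.5, 0.5, 0.5),
            attr_price=(0.5, 0.5, 0.5, 0.5),
            attr_health=(0.5, 0.5, 0.5, 0.5),
        )
        p = choice_probabilities(_agent(), small_community, params)
        assert p == pytest.approx([0.25] * 4, abs=1e-12)

    def test_zero_temperature_limit_selects_argmax(self, small_community):
        params = BehaviorParams(choice_temperature=1e-3)
        agent = _agent(belief=1.0, d_fv=0.0, d_lim=50.0, d_full=50.0)
        p = choice_probabilities(agent, small_community, params)
        assert p[ALTERNATIVES.index("fv_source")] > 0.999

    def test_monotone_in_fv_distance(self, small_community, params):
        """P(fv_source) rises as the FV outlet gets closer, on a grid."""
        grid = np.arange(0.0, 10.5, 0.5)
        probs = [
            choice_probabilities(_agent(d_fv=d), small_community, params)[0]
            for d in grid
        ]
        assert np.all(np.diff(probs) < 0)

    def test_softmax_brute_force_oracle(self, small_community):
        """Probabilities match a direct exp/normalize computation to 1e-12."""
        params = BehaviorParams()
        for agent in (
            _agent(), _agent(education="below_hs", belief=0.9, d_fv=1.0),
            _agent(education="bachelor_plus", belief=0.1, d_fv=9.0, ps=0.7),
        ):
            w = compute_weights(agent, params)
            taste = np.array(params.attr_taste)
            price = np.array(params.attr_price)
            health = np.array(params.attr_health)
            access = np.array([
                access_score(agent.nearest_fv_distance, params),
                access_score(agent.nearest_limited_distance, params),
                access_score(agent.nearest_full_distance, params),
                1.0,
            ])
            u = (w.taste * taste - w.price * agent.price_sensitivity * price
                 + w.access * access + w.health * health)
            expected = np.exp(u / params.choice_temperature)
            expected /= expected.sum()
            got = choice_probabilities(agent, small_community, params)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_absent_alternative_gets_zero(self, small_config):
        cfg = small_config.replace(n_limited_service=0, subsample_factor=0.02)
        com = rf.build_community(cfg, seed=1)
        p = choice_probabilities(_agent(), com, BehaviorParams())
        assert p[ALTERNATIVES.index("limited_service")] == 0.0
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matrix_agrees_with_scalar(self, small_community, params):
        mat = choice_probability_matrix(small_community, params)
        for i in (0, 17, 101):
            agent = small_community.agents[i]
            np.testing.assert_allclose(
                mat[i], choice_probabilities(agent, small_community, params),
                atol=1e-12,
            )

    @given(
        kappa=st.floats(0.2, 4.0),
        delta=st.floats(0.0, 6.0),
        temp=st.floats(0.05, 3.0),
        wa=st.floats(0.0, 3.0),
        belief=st.floats(0.0, 1.0),
        d_fv=st.floats(0.0, 30.0),
        edu=st.sampled_from(["below_hs", "hs", "bachelor_plus"]),
    )
    def test_probabilities_normalize(self, kappa, delta, temp, wa, belief, d_fv, edu,
                                     small_community):
        params = BehaviorParams(kappa=kappa, delta=delta, choice_temperature=temp,
                                w_access_base=wa)
        p = choice_probabilities(
            _agent(education=edu, belief=belief, d_fv=d_fv), small_community, params
        )
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)


class TestServings:
    def test_degenerate_pmf(self):
        pmf = (0.0, 0.0, 0.0, 1.0, 0.0, 0.0)
        params = BehaviorParams(servings_pmf_healthy=pmf)
        rng = np.random.default_rng(0)
        assert all(
            draw_daily_servings("fv_source", params, rng) == 3 for _ in range(20)
        )

    def test_tail_mass_statistic(self, params):
        """Empirical P(servings >= 2) matches the pmf tail over many draws."""
        rng = np.random.default_rng(12)
        n = 100_000
        pmf = np.array(params.servings_pmf_healthy)
        draws = rng.choice(6, size=n, p=pmf)  # oracle: direct pmf sampling
        tail = pmf[2:].sum()
        se = math.sqrt(tail * (1 - tail) / n)
        engine_draws = np.array([
            draw_daily_servings("fv_source", params, np.random.default_rng(i))
            for i in range(3000)
        ])
        assert abs((draws >= 2).mean() - tail) < 3 * se
        se2 = math.sqrt(tail * (1 - tail) / len(engine_draws))
        assert abs((engine_draws >= 2).mean() - tail) < 3 * se2

    def test_invalid_choice_rejected(self, params):
        with pytest.raises(DomainError):
            draw_daily_servings("gas_station", params, np.random.default_rng(0))

    def test_unnormalized_pmf_rejected(self):
        with pytest.raises(ConfigError):
            BehaviorParams(servings_pmf_home=(0.5, 0.5, 0.5, 0, 0, 0))


class TestTiltPmf:
    def test_identity_at_one(self, params):
        np.testing.assert_allclose(
            tilt_pmf(params.servings_pmf_healthy, 1.0), params.servings_pmf_healthy
        )

    def test_tail_mass_scales(self, params):
        pmf = np.array(params.servings_pmf_unhealthy)
        out = tilt_pmf(pmf, 1.5)
        assert out[2:].sum() == pytest.approx(1.5 * pmf[2:].sum())
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out >= 0)

    def test_clipped_to_valid_distribution(self, params):
        out = tilt_pmf(params.servings_pmf_healthy, 50.0)
        assert out[2:].sum() == pytest.approx(0.995)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)


class TestBeliefUpdate:
    def test_zero_influencability_is_identity(self):
        agent = _agent(belief=0.37)
        assert update_health_belief(agent, [0.0, 1.0, 0.9], 0.0) == 0.37

    def test_convex_combination(self):
        agent = _agent(belief=0.4)
        assert update_health_belief(agent, [0.8], 0.5) == pytest.approx(0.6)

    def test_no_peers_unchanged(self):
        agent = _agent(belief=0.42)
        assert update_health_belief(agent, [], 0.9) == 0.42

    def test_sigma_out_of_range(self):
        with pytest.raises(DomainError):
            update_health_belief(_agent(), [0.5], 1.5)

    def test_repeated_updates_with_zero_sigma_invariant(self):
        agent = _agent(belief=0.25)
        for _ in range(50):
            agent.health_belief = update_health_belief(agent, [1.0] * 8, 0.0)
        assert agent.health_belief == 0.25
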