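"""Agent decision model: weights, access decay, outlet choice, servings.

Each simulated day an agent picks one food source among four alternatives —
the nearest fruit/vegetable source (supermarket or FV market), a
limited-service (fast-food) restaurant, a full-service restaurant, or eating
at home — via a linear-utility multinomial logit. The utility of an
alternative is a weighted sum of four attributes: taste, price (scaled by
the agent's price sensitivity, which proxies income through education),
accessibility, and healthiness. Attribute weights vary by demographics:
low-education agents up-weight price, and agents with a strong health
belief up-weight healthiness.

Accessibility decays with driving distance through a logistic curve
``1 / (1 + exp(kappa * (d - delta)))``: ``delta`` is the distance (miles)
at which an outlet is half as accessible as one next door, and ``kappa``
controls how sharply reachability falls off around it. A hard-threshold
variant (reachable iff within the accessibility radius) is retained behind
a flag; the logistic is the default because it produces a smooth response
curve under distance interventions.

The chosen source determines the distribution of fruit-and-vegetable
servings eaten that day (0-5): FV sources draw from a produce-rich
distribution, restaurants from a produce-poor one, home from an
intermediate one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import yaml

from .community import Agent, Community
from .errors import ConfigError, DomainError

__all__ = [
    "ALTERNATIVES",
    "BehaviorParams",
    "WeightVector",
    "compute_weights",
    "access_score",
    "choice_probabilities",
    "choice_probability_matrix",
    "draw_daily_servings",
    "update_health_belief",
    "tilt_pmf",
]

#: Choice alternatives, in fixed order (probability vectors follow it).
ALTERNATIVES = ("fv_source", "limited_service", "full_service", "home")

_N_ALT = len(ALTERNATIVES)
_SERVINGS = np.arange(6)

# Per-alternative attribute defaults (order = ALTERNATIVES).
# The FV price attribute is the mean of the fresh-vegetable (0.72) and
# fresh-fruit (2.71) price indices, rescaled by the larger index so all
# price attributes share a [0, 1] scale.
_TASTE = (0.5, 0.9, 0.8, 0.4)
_PRICE = ((0.72 + 2.71) / 2.0 / 2.71, 0.5, 0.9, 0.3)
_HEALTH = (1.0, 0.0, 0.2, 0.5)


def _pmf(values: Sequence[float]) -> tuple[float, ...]:
    return tuple(float(v) for v in values)


@dataclass
class BehaviorParams:
    """Tunable parameters of the decision model.

    The five calibration degrees of freedom are ``kappa``, ``delta``,
    ``w_access_base``, ``p_belief`` and ``servings_tail_tilt``; everything
    else is frozen at its default during calibration.
    """

    w_taste_base: float = 1.0
    w_price_base: float = 1.0
    w_access_base: float = 1.0
    w_health_base: float = 1.0
    price_weight_boost_low_edu: float = 1.0
    health_weight_boost_belief: float = 1.0
    kappa: float = 1.2          # access decay steepness, per mile
    delta: float = 3.25         # access decay midpoint, miles
    choice_temperature: float = 0.35
    servings_pmf_healthy: tuple[float, ...] = _pmf((0.02, 0.08, 0.30, 0.35, 0.15, 0.10))
    servings_pmf_unhealthy: tuple[float, ...] = _pmf((0.35, 0.35, 0.20, 0.07, 0.02, 0.01))
    servings_pmf_home: tuple[float, ...] = _pmf((0.15, 0.25, 0.30, 0.20, 0.07, 0.03))
    p_shop_today: float = 1.0
    p_belief: float = 0.5       # share of agents with a strong health belief
    servings_tail_tilt: float = 1.0
    hard_threshold_access: bool = False
    attr_taste: tuple[float, ...] = _TASTE
    attr_price: tuple[float, ...] = _PRICE
    attr_health: tuple[float, ...] = _HEALTH

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("servings_pmf_healthy", "servings_pmf_unhealthy", "servings_pmf_home"):
            pmf = np.asarray(getattr(self, name), dtype=float)
            if pmf.shape != (6,):
                raise ConfigError(f"{name} must have 6 entries (servings 0..5)")
            if (pmf < 0).any():
                raise ConfigError(f"{name} has negative entries")
            if abs(pmf.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name} sums to {pmf.sum()!r}, not 1")
        if self.kappa <= 0:
            raise ConfigError(f"kappa={self.kappa} must be > 0")
        if self.delta < 0:
            raise ConfigError(f"delta={self.delta} must be >= 0")
        if self.choice_temperature <= 0:
            raise ConfigError("choice_temperature must be > 0")
        if not 0.0 <= self.p_shop_today <= 1.0:
            raise ConfigError("p_shop_today must lie in [0, 1]")
        if not 0.0 <= self.p_belief <= 1.0:
            raise ConfigError("p_belief must lie in [0, 1]")
        if self.servings_tail_tilt <= 0:
            raise ConfigError("servings_tail_tilt must be > 0")
        for name in (
            "w_taste_base", "w_price_base", "w_access_base", "w_health_base",
            "price_weight_boost_low_edu", "health_weight_boost_belief",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if (
            self.w_taste_base == self.w_price_base == self.w_access_base
            == self.w_health_base == 0.0
        ):
            raise ConfigError("all base weights are zero")

    def replace(self, **changes) -> "BehaviorParams":
        return dataclasses.replace(self, **changes)

    def effective_pmfs(self) -> np.ndarray:
        """(3, 6) servings pmfs [healthy, unhealthy, home] after tail tilt.

        ``servings_tail_tilt`` multiplies the healthy pmf's mass on >=2
        servings and divides the unhealthy pmf's; head masses absorb the
        complement. Tail masses are clipped to [0.005, 0.995] so the result
        is always a valid distribution.
        """
        out = np.vstack(
            [
                tilt_pmf(self.servings_pmf_healthy, self.servings_tail_tilt),
                tilt_pmf(self.servings_pmf_unhealthy, 1.0 / self.servings_tail_tilt),
                np.asarray(self.servings_pmf_home, dtype=float),
            ]
        )
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in list(d.items()):
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "BehaviorParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown behavior keys: {sorted(unknown)}")
        coerced = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        }
        return cls(**coerced)

    @classmethod
    def from_yaml(cls, path) -> "BehaviorParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            return cls()
        if "behavior" in raw and isinstance(raw["behavior"], dict):
            raw = raw["behavior"]
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"behavior": self.to_dict()}, fh, sort_keys=False)


def tilt_pmf(pmf: Sequence[float], factor: float) -> np.ndarray:
    """Rescale the mass a servings pmf puts on the >=2 tail by ``factor``.

    The tail entries are scaled proportionally to reach the new tail mass
    and the 0/1 entries absorb the complement; the new tail mass is clipped
    to [0.005, 0.995].
    """
    p = np.asarray(pmf, dtype=float)
    tail = p[2:].sum()
    if tail <= 0.0 or tail >= 1.0:
        return p.copy()
    new_tail = float(np.clip(tail * factor, 0.005, 0.995))
    out = np.empty_like(p)
    out[:2] = p[:2] * (1.0 - new_tail) / (1.0 - tail)
    out[2:] = p[2:] * new_tail / tail
    return out


class WeightVector(NamedTuple):
    """Normalized attribute weights (sum to 1)."""

    taste: float
    price: float
    access: float
    health: float


def compute_weights(agent: Agent, params: BehaviorParams) -> WeightVector:
    """Attribute weights for one agent, normalized to sum 1.

    Low education multiplies the price weight by
    ``1 + price_weight_boost_low_edu``; the health weight is multiplied by
    ``1 + health_weight_boost_belief * belief``.
    """
    w_price = params.w_price_base
    if agent.education == "below_hs":
        w_price *= 1.0 + params.price_weight_boost_low_edu
    w_health = params.w_health_base * (
        1.0 + params.health_weight_boost_belief * agent.health_belief
    )
    raw = np.array([params.w_taste_base, w_price, params.w_access_base, w_health])
    total = raw.sum()
    if total <= 0:
        raise ConfigError("weight vector degenerate: all raw weights zero")
    w = raw / total
    return WeightVector(*map(float, w))


def access_score(
    distance: float | np.ndarray, params: BehaviorParams
) -> float | np.ndarray:
    """Accessibility in (0, 1) as a function of driving distance (miles).

    Logistic decay ``1 / (1 + exp(kappa * (d - delta)))`` by default;
    with ``hard_threshold_access`` a step function at ``delta``.
    """
    d = np.asarray(distance, dtype=float)
    if (d < 0).any():
        raise DomainError("distance must be >= 0")
    if params.hard_threshold_access:
        score = np.where(d <= params.delta, 1.0, 0.0)
    else:
        with np.errstate(over="ignore"):
            score = 1.0 / (1.0 + np.exp(params.kappa * (d - params.delta)))
    if np.isscalar(distance) or np.ndim(distance) == 0:
        return float(score)
    return score


@dataclass
class AgentStatics:
    """Per-agent arrays that never change during a run (hot-path cache)."""

    n: int
    low_edu: np.ndarray
    price_sensitivity: np.ndarray
    d_lim: np.ndarray
    d_full: np.ndarray
    belief_quantile: np.ndarray
    fv_distance: np.ndarray
    health_belief: np.ndarray

    @classmethod
    def from_community(cls, community: Community) -> "AgentStatics":
        agents = community.agents
        return cls(
            n=len(agents),
            low_edu=np.array([a.education == "below_hs" for a in agents]),
            price_sensitivity=np.array([a.price_sensitivity for a in agents]),
            d_lim=np.minimum(
                np.array([a.nearest_limited_distance for a in agents]), 1e6
            ),
            d_full=np.minimum(
                np.array([a.nearest_full_distance for a in agents]), 1e6
            ),
            belief_quantile=np.array([a.belief_quantile for a in agents]),
            fv_distance=np.array([a.nearest_fv_distance for a in agents]),
            health_belief=np.array([a.health_belief for a in agents]),
        )


def _presence_mask(community: Community) -> np.ndarray:
    cfg = community.config
    return np.array(
        [
            cfg.n_supermarkets + cfg.n_fv_markets > 0,
            cfg.n_limited_service > 0,
            cfg.n_full_service > 0,
            True,  # home is always available
        ]
    )


def _utilities(
    weights: np.ndarray,
    price_sensitivity: np.ndarray,
    access: np.ndarray,
    params: BehaviorParams,
) -> np.ndarray:
    """(n, 4) utilities from (n, 4) weights and access attributes."""
    taste = np.asarray(params.attr_taste)
    price = np.asarray(params.attr_price)
    health = np.asarray(params.attr_health)
    u = (
        weights[:, [0]] * taste[None, :]
        - weights[:, [1]] * price_sensitivity[:, None] * price[None, :]
        + weights[:, [2]] * access
        + weights[:, [3]] * health[None, :]
    )
    return u


def _softmax_masked(utilities: np.ndarray, mask: np.ndarray, temperature: float) -> np.ndarray:
    z = utilities / temperature
    z = np.where(mask[None, :], z, -np.inf)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def choice_probability_matrix(
    community: Community,
    params: BehaviorParams,
    *,
    beliefs: np.ndarray | None = None,
    fv_distances: np.ndarray | None = None,
    statics: AgentStatics | None = None,
) -> np.ndarray:
    """(n_agents, 4) choice probabilities for the whole community.

    ``beliefs`` / ``fv_distances`` override the stored agent fields (used by
    the engine when beliefs evolve or a scenario changes distances);
    ``statics`` lets callers reuse the extracted per-agent arrays.
    """
    if not community.agents:
        raise DomainError("empty community")
    if statics is None:
        statics = AgentStatics.from_community(community)
    n = statics.n
    if beliefs is None:
        beliefs = statics.health_belief
    if fv_distances is None:
        fv_distances = statics.fv_distance
    low_edu = statics.low_edu
    ps = statics.price_sensitivity

    w_price = params.w_price_base * np.where(
        low_edu, 1.0 + params.price_weight_boost_low_edu, 1.0
    )
    w_health = params.w_health_base * (
        1.0 + params.health_weight_boost_belief * beliefs
    )
    raw = np.column_stack(
        [
            np.full(n, params.w_taste_base),
            w_price,
            np.full(n, params.w_access_base),
            w_health,
        ]
    )
    totals = raw.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ConfigError("degenerate weight vector for some agent")
    weights = raw / totals

    access = np.column_stack(
        [
            access_score(fv_distances, params),
            access_score(statics.d_lim, params),
            access_score(statics.d_full, params),
            np.ones(n),
        ]
    )
    u = _utilities(weights, ps, access, params)
    return _softmax_masked(u, _presence_mask(community), params.choice_temperature)


def choice_probabilities(
    agent: Agent, community: Community, params: BehaviorParams
) -> np.ndarray:
    """Probability vector over ``ALTERNATIVES`` for one agent.

    Alternatives whose outlet type is absent from the community get
    probability 0 and the remainder renormalizes (softmax over the
    present set).
    """
    if not community.agents:
        raise DomainError("empty community")
    w = compute_weights(agent, params)
    access = np.array(
        [
            access_score(agent.nearest_fv_distance, params),
            access_score(min(agent.nearest_limited_distance, 1e6), params),
            access_score(min(agent.nearest_full_distance, 1e6), params),
            1.0,
        ]
    )
    u = _utilities(
        np.array([w]), np.array([agent.price_sensitivity]), access[None, :], params
    )
    return _softmax_masked(u, _presence_mask(community), params.choice_temperature)[0]


_CHOICE_TO_PMF = {"fv_source": 0, "limited_service": 1, "full_service": 1, "home": 2}


def draw_daily_servings(
    choice: str, params: BehaviorParams, rng: np.random.Generator
) -> int:
    """Draw the day's FV servings (0-5) given the chosen food source."""
    if choice not in _CHOICE_TO_PMF:
        raise DomainError(f"unknown choice {choice!r}")
    pmf = params.effective_pmfs()[_CHOICE_TO_PMF[choice]]
    return int(rng.choice(_SERVINGS, p=pmf))


def update_health_belief(
    agent: Agent, peer_beliefs: Sequence[float], sigma: float
) -> float:
    """Convex peer-averaging belief update, clamped to [0, 1].

    ``sigma`` is the social influencability index; with sigma = 0 (the
    published setting for both communities) beliefs never move.
    """
    if not 0.0 <= sigma <= 1.0:
        raise DomainError(f"sigma={sigma} outside [0, 1]")
    if len(peer_beliefs) == 0 or sigma == 0.0:
        return float(agent.health_belief)
    new = (1.0 - sigma) * agent.health_belief + sigma * float(np.mean(peer_beliefs))
    return float(np.clip(new, 0.0, 1.0))
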