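"""Synthetic community construction: agents, outlets, layout, peer network.

Agents are placed uniformly on the square of side ``sqrt(land_area)``
(map-miles); demographics are independent categorical draws from the
configured marginals. Food outlets are placed uniformly on the same square,
with counts taken exactly from the configuration. An outlet is *healthy*
(sells fresh produce) iff it is a supermarket or a fruit-and-vegetable
market; limited-service (fast-food) and full-service restaurants are
unhealthy.

Driving distances are Euclidean map distances multiplied by the
community's ``distance_scale`` (a stand-in for road-network routing). The
distance to the nearest FV source can alternatively be pinned to a fixed
value for every agent, which is how the policy scenario sweep parameterizes
"effective driving distance".

The peer network defaults to k-nearest spatial neighbors, symmetrized; an
Erdos-Renyi option with matching expected degree is available since the
underlying social topology is unobserved.
"""

from __future__ import annotations

import dataclasses
import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import CommunityConfig
from .errors import ConfigError, DomainError, NoFVSourceError

__all__ = [
    "Agent",
    "FoodOutlet",
    "Community",
    "OutletRatio",
    "build_community",
    "sample_demographics",
    "outlet_ratio",
    "set_nearest_fv_distances",
    "community_to_csv",
    "community_from_csv",
]

AGE_GROUPS = ("under18", "18_65", "over65")
SEXES = ("female", "male")
EDUCATION_LEVELS = ("below_hs", "hs", "bachelor_plus")
OUTLET_TYPES = ("limited_service", "full_service", "supermarket", "fv_market")
HEALTHY_TYPES = frozenset({"supermarket", "fv_market"})

#: Under-18 : over-65 split of the population share not aged 18-65
#: (typical rural age pyramid; only the 18-65 share is observed).
DEFAULT_AGE_REMAINDER_SPLIT = (0.6, 0.4)

#: Health beliefs are seeded from a two-point distribution: a share
#: ``p_belief`` of agents strongly prefers healthy foods (belief 0.8),
#: the rest weakly (belief 0.2).
BELIEF_HIGH = 0.8
BELIEF_LOW = 0.2
DEFAULT_P_BELIEF = 0.5


@dataclass
class Agent:
    """One simulated resident."""

    id: int
    position: tuple[float, float]
    age_group: str
    sex: str
    education: str
    health_belief: float
    price_sensitivity: float
    peers: list[int] = field(default_factory=list)
    nearest_fv_distance: float = 0.0
    nearest_limited_distance: float = math.inf
    nearest_full_distance: float = math.inf
    belief_quantile: float = 0.5
    servings_log: list[int] = field(default_factory=list)


@dataclass
class FoodOutlet:
    """One food source."""

    id: int
    outlet_type: str
    position: tuple[float, float]
    healthy: bool
    price_level: float

    def __post_init__(self) -> None:
        if self.healthy != (self.outlet_type in HEALTHY_TYPES):
            raise ConfigError(
                f"outlet {self.id}: healthy={self.healthy} inconsistent with "
                f"type {self.outlet_type!r}"
            )


@dataclass
class Community:
    """A built community: configuration, agents, and outlets."""

    config: CommunityConfig
    agents: list[Agent]
    outlets: list[FoodOutlet]
    rng_seed: int

    @property
    def side(self) -> float:
        return math.sqrt(self.config.land_area)

    def healthy_outlets(self) -> list[FoodOutlet]:
        return [o for o in self.outlets if o.healthy]

    def outlets_of_type(self, outlet_type: str) -> list[FoodOutlet]:
        return [o for o in self.outlets if o.outlet_type == outlet_type]


def sample_demographics(
    config: CommunityConfig,
    n: int,
    rng: np.random.Generator,
    age_remainder_split: tuple[float, float] = DEFAULT_AGE_REMAINDER_SPLIT,
) -> list[tuple[str, str, str]]:
    """Draw ``n`` independent (age_group, sex, education) triples.

    Education follows the nested marginals: P(bachelor_plus) is the
    bachelors-or-higher share, P(hs) the high-school-or-higher share minus
    it, and P(below_hs) the complement. The unobserved non-working-age
    share is split between under-18 and over-65 by ``age_remainder_split``.
    """
    if n < 0:
        raise DomainError(f"n={n} must be >= 0")
    if config.pct_bachelors_or_higher > config.pct_hs_or_higher:
        raise ConfigError("bachelors-or-higher marginal exceeds HS-or-higher")
    if n == 0:
        return []
    u, o = age_remainder_split
    if u < 0 or o < 0 or not math.isclose(u + o, 1.0, abs_tol=1e-9):
        raise ConfigError(f"age_remainder_split {age_remainder_split} must sum to 1")
    remainder = 1.0 - config.pct_age_18_65
    p_age = np.array([remainder * u, config.pct_age_18_65, remainder * o])
    p_sex = np.array([config.pct_female, 1.0 - config.pct_female])
    p_edu = np.array(
        [
            1.0 - config.pct_hs_or_higher,
            config.pct_hs_or_higher - config.pct_bachelors_or_higher,
            config.pct_bachelors_or_higher,
        ]
    )
    ages = rng.choice(len(AGE_GROUPS), size=n, p=p_age)
    sexes = rng.choice(len(SEXES), size=n, p=p_sex)
    edus = rng.choice(len(EDUCATION_LEVELS), size=n, p=p_edu)
    return [
        (AGE_GROUPS[a], SEXES[s], EDUCATION_LEVELS[e])
        for a, s, e in zip(ages, sexes, edus)
    ]


#: Education proxies income; lower attainment implies higher sensitivity to
#: food prices in the choice utility.
PRICE_SENSITIVITY = {"below_hs": 1.5, "hs": 1.0, "bachelor_plus": 0.7}


def _knn_peers(positions: np.ndarray, k: int) -> list[list[int]]:
    n = len(positions)
    if n <= 1:
        return [[] for _ in range(n)]
    k_eff = min(k, n - 1)
    tree = cKDTree(positions)
    _, idx = tree.query(positions, k=k_eff + 1)
    idx = np.atleast_2d(idx)
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in idx[i]:
            if j != i:
                neighbors[i].add(int(j))
    # symmetrize: peer relation is mutual
    for i in range(n):
        for j in neighbors[i]:
            neighbors[j].add(i)
    return [sorted(s) for s in neighbors]


def _random_peers(n: int, k: int, rng: np.random.Generator) -> list[list[int]]:
    if n <= 1:
        return [[] for _ in range(n)]
    p = min(1.0, k / max(n - 1, 1))
    g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return [sorted(g.neighbors(i)) for i in range(n)]


def build_community(
    config: CommunityConfig,
    seed: int,
    *,
    peer_k: int = 8,
    peer_mode: Literal["knn", "random"] = "knn",
    distance_mode: Literal["fixed", "geometric"] = "fixed",
    p_belief: float = DEFAULT_P_BELIEF,
    require_fv_source: bool = True,
    age_remainder_split: tuple[float, float] = DEFAULT_AGE_REMAINDER_SPLIT,
) -> Community:
    """Build the synthetic community from the configured marginals.

    ``distance_mode="fixed"`` pins every agent's nearest-FV driving distance
    to ``config.baseline_nearest_fv_distance`` (the scenario-sweep
    parameterization); ``"geometric"`` computes it from the spatial layout.
    """
    config.validate()
    if seed < 0 or int(seed) != seed:
        raise ConfigError(f"seed={seed!r} must be a non-negative integer")
    if not 0.0 <= p_belief <= 1.0:
        raise ConfigError(f"p_belief={p_belief} must lie in [0, 1]")
    if require_fv_source and config.n_healthy_outlets == 0:
        raise NoFVSourceError(
            f"community {config.name!r} has no supermarket or FV market: "
            "agents would have no fruit/vegetable source"
        )
    rng = np.random.default_rng(seed)
    side = math.sqrt(config.land_area)
    n = config.n_agents
    if n == 0:
        warnings.warn(
            f"community {config.name!r} has zero agents "
            f"(pop_density={config.pop_density}, subsample={config.subsample_factor})",
            stacklevel=2,
        )

    # outlets first so the draw count per entity class is stable
    outlet_counts = {
        "limited_service": config.n_limited_service,
        "full_service": config.n_full_service,
        "supermarket": config.n_supermarkets,
        "fv_market": config.n_fv_markets,
    }
    price_by_type = {
        "limited_service": 0.5,
        "full_service": 0.9,
        "supermarket": config.veg_price_index,
        "fv_market": config.fruit_price_index,
    }
    outlets: list[FoodOutlet] = []
    oid = 0
    for outlet_type in OUTLET_TYPES:
        for _ in range(outlet_counts[outlet_type]):
            pos = tuple(rng.uniform(0.0, side, size=2))
            outlets.append(
                FoodOutlet(
                    id=oid,
                    outlet_type=outlet_type,
                    position=(float(pos[0]), float(pos[1])),
                    healthy=outlet_type in HEALTHY_TYPES,
                    price_level=price_by_type[outlet_type],
                )
            )
            oid += 1

    positions = rng.uniform(0.0, side, size=(n, 2))
    demographics = sample_demographics(config, n, rng, age_remainder_split)
    belief_q = rng.uniform(size=n)

    if peer_mode == "knn":
        peers = _knn_peers(positions, peer_k)
    elif peer_mode == "random":
        peers = _random_peers(n, peer_k, rng)
    else:
        raise ConfigError(f"unknown peer_mode {peer_mode!r}")

    agents: list[Agent] = []
    for i in range(n):
        age, sex, edu = demographics[i]
        agents.append(
            Agent(
                id=i,
                position=(float(positions[i, 0]), float(positions[i, 1])),
                age_group=age,
                sex=sex,
                education=edu,
                health_belief=BELIEF_HIGH if belief_q[i] < p_belief else BELIEF_LOW,
                price_sensitivity=PRICE_SENSITIVITY[edu],
                peers=peers[i],
                belief_quantile=float(belief_q[i]),
            )
        )

    community = Community(config=config, agents=agents, outlets=outlets, rng_seed=seed)
    _set_unhealthy_distances(community)
    if distance_mode == "geometric":
        set_nearest_fv_distances(community, mode="geometric")
    else:
        set_nearest_fv_distances(
            community, mode="fixed", fixed_value=config.baseline_nearest_fv_distance
        )
    return community


def _nearest_distance(
    agent_positions: np.ndarray, outlet_positions: Sequence[tuple[float, float]]
) -> np.ndarray:
    if len(outlet_positions) == 0:
        return np.full(len(agent_positions), np.inf)
    tree = cKDTree(np.asarray(outlet_positions))
    dist, _ = tree.query(agent_positions)
    return np.atleast_1d(dist)


def _set_unhealthy_distances(community: Community) -> None:
    """Driving distance to nearest limited- and full-service restaurant.

    These enter the access attribute of the corresponding choice
    alternatives and are unaffected by FV-access interventions.
    """
    if not community.agents:
        return
    pos = np.array([a.position for a in community.agents])
    scale = community.config.distance_scale
    d_lim = _nearest_distance(
        pos, [o.position for o in community.outlets_of_type("limited_service")]
    )
    d_full = _nearest_distance(
        pos, [o.position for o in community.outlets_of_type("full_service")]
    )
    for i, agent in enumerate(community.agents):
        agent.nearest_limited_distance = float(d_lim[i] * scale)
        agent.nearest_full_distance = float(d_full[i] * scale)


def set_nearest_fv_distances(
    community: Community,
    mode: Literal["geometric", "fixed"] = "geometric",
    fixed_value: float | None = None,
) -> Community:
    """Set every agent's driving distance to the nearest FV source (in place).

    ``geometric``: distance_scale x Euclidean map distance to the nearest
    healthy outlet. ``fixed``: the same ``fixed_value`` for every agent.
    """
    if mode == "fixed":
        if fixed_value is None or fixed_value < 0:
            raise DomainError(f"fixed mode requires fixed_value >= 0, got {fixed_value!r}")
        for agent in community.agents:
            agent.nearest_fv_distance = float(fixed_value)
        return community
    if mode != "geometric":
        raise DomainError(f"unknown distance mode {mode!r}")
    healthy = community.healthy_outlets()
    if not healthy:
        raise NoFVSourceError("no healthy outlet: cannot compute FV distances")
    if not community.agents:
        return community
    pos = np.array([a.position for a in community.agents])
    dist = _nearest_distance(pos, [o.position for o in healthy])
    scale = community.config.distance_scale
    for i, agent in enumerate(community.agents):
        agent.nearest_fv_distance = float(dist[i] * scale)
    return community


class OutletRatio(NamedTuple):
    rounded: int
    exact: float


def outlet_ratio(community: Community) -> OutletRatio:
    """Unhealthy-to-healthy outlet ratio, rounded half-down to an integer.

    Healthy outlets are supermarkets and FV markets; unhealthy outlets are
    limited- and full-service restaurants. Rounding is half-down so that the
    published worked examples (2.33 -> 2, 7.06 -> 7) reproduce; plain
    round-half-even gives the same integers for those inputs.
    """
    n_healthy = sum(1 for o in community.outlets if o.healthy)
    n_unhealthy = sum(1 for o in community.outlets if not o.healthy)
    if n_healthy == 0:
        raise NoFVSourceError(
            "outlet ratio undefined: community has zero healthy outlets"
        )
    exact = n_unhealthy / n_healthy
    return OutletRatio(rounded=int(math.ceil(exact - 0.5)), exact=exact)


# ---------------------------------------------------------------------------
# serialization

_AGENT_COLUMNS = [
    "id", "x", "y", "age_group", "sex", "education", "belief",
    "belief_quantile", "price_sensitivity", "nearest_fv_distance",
    "nearest_limited_distance", "nearest_full_distance", "peers",
]
_OUTLET_COLUMNS = ["id", "type", "x", "y", "healthy", "price_level"]


def community_to_csv(community: Community) -> tuple[str, str]:
    """Serialize to two CSV documents: (agents, outlets).

    Deterministic for a fixed community (used by the reproducibility
    contract: same config and seed give byte-identical output).
    """
    agents = pd.DataFrame(
        {
            "id": [a.id for a in community.agents],
            "x": [repr(a.position[0]) for a in community.agents],
            "y": [repr(a.position[1]) for a in community.agents],
            "age_group": [a.age_group for a in community.agents],
            "sex": [a.sex for a in community.agents],
            "education": [a.education for a in community.agents],
            "belief": [repr(a.health_belief) for a in community.agents],
            "belief_quantile": [repr(a.belief_quantile) for a in community.agents],
            "price_sensitivity": [repr(a.price_sensitivity) for a in community.agents],
            "nearest_fv_distance": [repr(a.nearest_fv_distance) for a in community.agents],
            "nearest_limited_distance": [
                repr(a.nearest_limited_distance) for a in community.agents
            ],
            "nearest_full_distance": [
                repr(a.nearest_full_distance) for a in community.agents
            ],
            "peers": [";".join(map(str, a.peers)) for a in community.agents],
        },
        columns=_AGENT_COLUMNS,
    )
    outlets = pd.DataFrame(
        {
            "id": [o.id for o in community.outlets],
            "type": [o.outlet_type for o in community.outlets],
            "x": [repr(o.position[0]) for o in community.outlets],
            "y": [repr(o.position[1]) for o in community.outlets],
            "healthy": [o.healthy for o in community.outlets],
            "price_level": [repr(o.price_level) for o in community.outlets],
        },
        columns=_OUTLET_COLUMNS,
    )
    return (
        agents.to_csv(index=False, lineterminator="\n"),
        outlets.to_csv(index=False, lineterminator="\n"),
    )


def community_from_csv(
    agents_csv: str | Path, outlets_csv: str | Path, config: CommunityConfig, seed: int
) -> Community:
    """Rebuild a community from its two CSV documents (round-trip of
    :func:`community_to_csv`)."""

    def _read(src):
        if isinstance(src, Path) or (isinstance(src, str) and "\n" not in src):
            return pd.read_csv(src, float_precision="round_trip")
        return pd.read_csv(io.StringIO(src), float_precision="round_trip")

    adf = _read(agents_csv)
    odf = _read(outlets_csv)
    agents = [
        Agent(
            id=int(r.id),
            position=(float(r.x), float(r.y)),
            age_group=r.age_group,
            sex=r.sex,
            education=r.education,
            health_belief=float(r.belief),
            price_sensitivity=float(r.price_sensitivity),
            peers=[int(p) for p in str(r.peers).split(";") if p != "" and p != "nan"],
            nearest_fv_distance=float(r.nearest_fv_distance),
            nearest_limited_distance=float(r.nearest_limited_distance),
            nearest_full_distance=float(r.nearest_full_distance),
            belief_quantile=float(r.belief_quantile),
        )
        for r in adf.itertuples()
    ]
    outlets = [
        FoodOutlet(
            id=int(r.id),
            outlet_type=r.type,
            position=(float(r.x), float(r.y)),
            healthy=bool(r.healthy),
            price_level=float(r.price_level),
        )
        for r in odf.itertuples()
    ]
    return Community(config=config, agents=agents, outlets=outlets, rng_seed=seed)


def copy_community(community: Community) -> Community:
    """Deep copy (agents and outlets are mutable dataclasses)."""
    agents = [
        dataclasses.replace(a, peers=list(a.peers), servings_log=list(a.servings_log))
        for a in community.agents
    ]
    outlets = [dataclasses.replace(o) for o in community.outlets]
    return Community(
        config=community.config,
        agents=agents,
        outlets=outlets,
        rng_seed=community.rng_seed,
    )
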