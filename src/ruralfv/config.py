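"""Community configuration: demographic marginals and food-environment constants.

A :class:`CommunityConfig` bundles everything needed to synthesize one
community: land area and population density (which fix the agent count),
demographic marginals (age, sex, education), outlet counts by type, the
accessibility radius, the map-to-real distance scale, produce price indices,
and the social influencability index that gates peer effects on health
beliefs.

Two presets ship with the package: a low-density west-Texas rural community
(``rural_tx``) and the high-density California urban community the behavior
model was originally developed for (``urban_ca``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = [
    "CommunityConfig",
    "rural_tx",
    "urban_ca",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class CommunityConfig:
    """Marginals and environment constants for one community.

    Proportions are in [0, 1]. ``land_area`` is in square map-miles and
    ``pop_density`` in persons per square map-mile, so the agent count is
    ``round(pop_density * land_area * subsample_factor)``. Distances are
    converted from map-miles to real driving miles by ``distance_scale``.
    """

    name: str
    land_area: float
    pop_density: float
    pct_age_18_65: float
    pct_female: float
    pct_hs_or_higher: float
    pct_bachelors_or_higher: float
    n_limited_service: int
    n_full_service: int
    n_supermarkets: int
    n_fv_markets: int
    accessibility_radius: float
    distance_scale: float
    veg_price_index: float
    fruit_price_index: float
    social_influencability: float
    baseline_nearest_fv_distance: float
    subsample_factor: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ConfigError` if any invariant is violated."""
        props = {
            "pct_age_18_65": self.pct_age_18_65,
            "pct_female": self.pct_female,
            "pct_hs_or_higher": self.pct_hs_or_higher,
            "pct_bachelors_or_higher": self.pct_bachelors_or_higher,
            "social_influencability": self.social_influencability,
        }
        for key, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{key}={value!r} must lie in [0, 1]")
        if self.pct_bachelors_or_higher > self.pct_hs_or_higher:
            raise ConfigError(
                "pct_bachelors_or_higher exceeds pct_hs_or_higher: "
                f"{self.pct_bachelors_or_higher} > {self.pct_hs_or_higher}"
            )
        counts = {
            "n_limited_service": self.n_limited_service,
            "n_full_service": self.n_full_service,
            "n_supermarkets": self.n_supermarkets,
            "n_fv_markets": self.n_fv_markets,
        }
        for key, value in counts.items():
            if value < 0 or int(value) != value:
                raise ConfigError(f"{key}={value!r} must be a non-negative integer")
        if self.land_area <= 0:
            raise ConfigError(f"land_area={self.land_area!r} must be > 0")
        if self.pop_density < 0:
            raise ConfigError(f"pop_density={self.pop_density!r} must be >= 0")
        if self.distance_scale <= 0:
            raise ConfigError(f"distance_scale={self.distance_scale!r} must be > 0")
        if not 0.0 < self.subsample_factor <= 1.0:
            raise ConfigError(
                f"subsample_factor={self.subsample_factor!r} must lie in (0, 1]"
            )
        if self.baseline_nearest_fv_distance < 0:
            raise ConfigError("baseline_nearest_fv_distance must be >= 0")

    @property
    def n_agents(self) -> int:
        """Agent count implied by density, area, and subsampling."""
        return int(round(self.pop_density * self.land_area * self.subsample_factor))

    @property
    def n_healthy_outlets(self) -> int:
        return self.n_supermarkets + self.n_fv_markets

    @property
    def n_unhealthy_outlets(self) -> int:
        return self.n_limited_service + self.n_full_service

    def replace(self, **changes) -> "CommunityConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _coerce(raw: dict) -> CommunityConfig:
    known = {f.name for f in dataclasses.fields(CommunityConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    missing = known - set(raw) - {"subsample_factor"}
    if missing:
        raise ConfigError(f"missing config keys: {sorted(missing)}")
    try:
        return CommunityConfig(**raw)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> CommunityConfig:
    """Load a community configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    return _coerce(raw)


def save_config(config: CommunityConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def _builtin(name: str) -> CommunityConfig:
    source = resources.files("ruralfv.data").joinpath(f"{name}.yaml")
    raw = yaml.safe_load(source.read_text())
    return _coerce(raw)


def rural_tx() -> CommunityConfig:
    """The west-Texas rural community preset (5,157 residents at full scale)."""
    return _builtin("rural_tx")


def urban_ca() -> CommunityConfig:
    """The California urban community preset.

    Ships with ``subsample_factor=0.05`` because the full population
    (~137k agents) is beyond interactive scale; outcome statistics are
    proportions and therefore scale-free.

    Note: the published education marginals for this community list
    bachelors-or-higher above high-school-or-higher, which is impossible
    for nested attainment categories; the preset stores the two values in
    the only consistent order (HS-or-higher 61.2%, bachelors 27.9%).
    """
    return _builtin("urban_ca")
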