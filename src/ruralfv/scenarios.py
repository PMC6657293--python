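"""Distance-reduction interventions, the response curve, and marginal effects.

A policy scenario shortens every agent's driving distance to the nearest
FV source by ``delta_miles`` (clamped at zero), standing in for bringing FV
retailers closer or densifying them. Sweeping a grid of reductions yields
the response curve: population percentage meeting the 2-servings threshold
as a function of effective driving distance. Marginal effects are the
per-step changes along that curve; their argmax locates the distance band
where an access intervention buys the most consumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import BehaviorParams
from .community import Community, copy_community
from .engine import SimulationResult, SimulationSpec, run_simulation
from .errors import DomainError

__all__ = [
    "Scenario",
    "CurvePoint",
    "ResponseCurve",
    "MarginalEffectTable",
    "apply_distance_reduction",
    "sweep",
    "marginal_effects",
    "add_outlet",
    "DEFAULT_GRID",
]

#: Default sweep: reductions of 0 to 5 miles in half-mile steps.
DEFAULT_GRID = tuple(np.round(np.arange(0.0, 5.0001, 0.5), 10))


@dataclass(frozen=True)
class Scenario:
    """A distance-reduction intervention."""

    delta_miles: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.delta_miles < 0:
            raise DomainError(f"delta_miles={self.delta_miles} must be >= 0")


@dataclass(frozen=True)
class CurvePoint:
    delta: float
    effective_distance: float
    pct: float
    sd_pct: float
    pct_relative_change: float


@dataclass
class ResponseCurve:
    """(effective distance, outcome) pairs, sorted by decreasing distance."""

    points: list[CurvePoint]
    baseline_pct: float
    relative: bool = True
    results: list[SimulationResult] = field(default_factory=list, repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta": [p.delta for p in self.points],
                "effective_distance_miles": [p.effective_distance for p in self.points],
                "mean_pct": [p.pct for p in self.points],
                "sd_pct": [p.sd_pct for p in self.points],
                "relative_change_pct": [p.pct_relative_change for p in self.points],
            }
        )

    def plot(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.to_dataframe()
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(df.effective_distance_miles, df.mean_pct, marker="o")
        ax.invert_xaxis()
        ax.set_xlabel("Effective driving distance to nearest FV source (miles)")
        ax.set_ylabel("Population with ≥2 FV servings/day (%)")
        ax.set_title("Response curve")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclass
class MarginalEffectTable:
    """Per-step changes of the response curve over consecutive grid points."""

    steps: list[tuple[float, float, float]]  # (from_distance, to_distance, pct change)
    argmax_step: tuple[float, float]
    degenerate: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["from_distance", "to_distance", "pct_change"]
        )


def apply_distance_reduction(community: Community, scenario: Scenario) -> Community:
    """Return a copy with every nearest-FV distance reduced by the scenario.

    Distances clamp at zero; no other field changes.
    """
    if scenario.delta_miles < 0:
        raise DomainError("negative distance reduction")
    out = copy_community(community)
    for agent in out.agents:
        agent.nearest_fv_distance = max(0.0, agent.nearest_fv_distance - scenario.delta_miles)
    return out


def sweep(
    community: Community,
    params: BehaviorParams,
    spec: SimulationSpec,
    grid: Sequence[float] = DEFAULT_GRID,
    *,
    relative: bool = True,
    strict: bool = False,
) -> ResponseCurve:
    """Run one simulation per distance reduction and build the response curve.

    ``relative=True`` reports changes as percent of the baseline outcome
    (100 x (pct - baseline) / baseline); ``relative=False`` reports
    percentage-point differences. Each grid point re-simulates from an
    independently reset copy of the baseline community with the same
    replicate seeds (common random numbers across grid points).
    """
    deltas = sorted(float(d) for d in grid)
    if not deltas:
        raise DomainError("empty scenario grid")
    if any(d < 0 for d in deltas):
        raise DomainError("grid deltas must be >= 0")
    if deltas[0] != 0.0:
        raise DomainError("grid must include delta 0 (the baseline)")

    from .behavior import AgentStatics

    statics = AgentStatics.from_community(community)
    points: list[CurvePoint] = []
    results: list[SimulationResult] = []
    baseline_pct = None
    for delta in deltas:
        # same effect as apply_distance_reduction, without copying the
        # community per grid point
        fv = np.maximum(0.0, statics.fv_distance - delta)
        result = run_simulation(
            community, params, spec, strict=strict, fv_distances=fv, statics=statics
        )
        if baseline_pct is None:
            baseline_pct = result.mean_pct
        if relative:
            change = (
                100.0 * (result.mean_pct - baseline_pct) / baseline_pct
                if baseline_pct != 0
                else float("nan")
            )
        else:
            change = result.mean_pct - baseline_pct
        points.append(
            CurvePoint(
                delta=delta,
                effective_distance=result.mean_fv_distance,
                pct=result.mean_pct,
                sd_pct=result.sd_pct,
                pct_relative_change=change,
            )
        )
        results.append(result)
    # sorted by decreasing effective distance = increasing delta
    return ResponseCurve(
        points=points, baseline_pct=float(baseline_pct), relative=relative,
        results=results,
    )


def marginal_effects(curve: ResponseCurve) -> MarginalEffectTable:
    """Per-step outcome changes and the location of the largest one.

    Steps run from larger to smaller effective distance; ties in the
    argmax break toward the larger distance. A flat curve is flagged
    degenerate.
    """
    if len(curve.points) < 2:
        raise DomainError("need at least 2 curve points for marginal effects")
    pts = sorted(curve.points, key=lambda p: -p.effective_distance)
    steps = [
        (a.effective_distance, b.effective_distance, b.pct - a.pct)
        for a, b in zip(pts[:-1], pts[1:])
    ]
    changes = np.array([s[2] for s in steps])
    degenerate = bool(np.allclose(changes, 0.0))
    best = int(np.argmax(changes))  # first occurrence = larger distance on ties
    return MarginalEffectTable(
        steps=steps,
        argmax_step=(steps[best][0], steps[best][1]),
        degenerate=degenerate,
    )


def add_outlet(
    community: Community, outlet_type: str, position: tuple[float, float]
) -> Community:
    """Exploratory variant: add one outlet and recompute geometric distances.

    Secondary to :func:`apply_distance_reduction`; useful for siting
    questions rather than the distance-parameterized response curve.
    """
    from .community import (
        HEALTHY_TYPES, FoodOutlet, set_nearest_fv_distances, _set_unhealthy_distances,
    )

    out = copy_community(community)
    cfg = out.config
    price = {
        "limited_service": 0.5,
        "full_service": 0.9,
        "supermarket": cfg.veg_price_index,
        "fv_market": cfg.fruit_price_index,
    }[outlet_type]
    out.outlets.append(
        FoodOutlet(
            id=max((o.id for o in out.outlets), default=-1) + 1,
            outlet_type=outlet_type,
            position=position,
            healthy=outlet_type in HEALTHY_TYPES,
            price_level=price,
        )
    )
    counts = {
        "limited_service": "n_limited_service",
        "full_service": "n_full_service",
        "supermarket": "n_supermarkets",
        "fv_market": "n_fv_markets",
    }
    field_name = counts[outlet_type]
    out.config = cfg.replace(**{field_name: getattr(cfg, field_name) + 1})
    _set_unhealthy_distances(out)
    set_nearest_fv_distances(out, mode="geometric")
    return out
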