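"""Anchor calibration of the behavior model and baseline validation.

The emergent population statistic (percent of agents meeting the
2-servings threshold) is anchored to three published values — the baseline
level and the relative changes under one-mile and five-mile reductions in
driving distance — plus the location of the largest marginal step of the
response curve. Five parameters are free: the access-decay steepness
``kappa`` and midpoint ``delta``, the access weight ``w_access_base``, the
share ``p_belief`` of agents with a strong health belief, and a single
multiplicative tilt between the healthy and unhealthy servings tail
masses. Three anchors cannot identify more than a handful of parameters;
the contract is reproduction of the anchored response curve, not point
identification.

The search is derivative-free: a deterministic space-filling screen on the
anchor residuals, followed by compass (pattern) search on the full loss,
which adds a hinge penalty whenever a marginal step other than the target
one comes within a margin of the largest. Every evaluation re-simulates
with the same replicate seeds (common random numbers), so the loss surface
— and therefore the fitted parameters — are deterministic given the
simulation spec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import yaml

from .behavior import BehaviorParams
from .community import Community
from .engine import SimulationSpec
from .errors import ConfigError, DomainError
from .scenarios import DEFAULT_GRID, ResponseCurve, marginal_effects, sweep

__all__ = [
    "Anchor",
    "AnchorSet",
    "CalibrationResult",
    "calibrate",
    "validate_baseline",
    "DEFAULT_BOUNDS",
    "FREE_PARAMETERS",
    "ROBUST_PEAK_MARGIN_PP",
]


class Anchor(NamedTuple):
    delta_miles: float
    target_value: float
    #: "baseline_pct" (the delta-0 level), "relative_change_pct" (percent of
    #: baseline), or "pct" (absolute percent at any delta)
    target_type: str
    #: Residual weight in the squared loss. The shipped anchor set weights
    #: each anchor by the inverse square of its reproduction tolerance, so
    #: tighter anchors pull harder.
    weight: float = 1.0


@dataclass(frozen=True)
class AnchorSet:
    """Published targets the calibration drives the model toward."""

    anchors: tuple[Anchor, ...]
    peak_step: tuple[float, float]  # (from_distance, to_distance), miles

    def __post_init__(self) -> None:
        baselines = [a for a in self.anchors if a.target_type == "baseline_pct"]
        if len(baselines) != 1 or baselines[0].delta_miles != 0.0:
            raise ConfigError("anchor set needs exactly one baseline anchor at delta 0")
        for a in self.anchors:
            if a.target_type not in ("baseline_pct", "relative_change_pct", "pct"):
                raise ConfigError(f"unknown target_type {a.target_type!r}")

    @property
    def baseline(self) -> Anchor:
        return next(a for a in self.anchors if a.target_type == "baseline_pct")

    @classmethod
    def from_yaml(cls, path) -> "AnchorSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        anchors = tuple(
            Anchor(
                float(a["delta_miles"]),
                float(a["target_value"]),
                a["target_type"],
                float(a.get("weight", 1.0)),
            )
            for a in raw["anchors"]
        )
        return cls(anchors=anchors, peak_step=tuple(float(x) for x in raw["peak_step"]))


#: Calibrated degrees of freedom and their bounds.
FREE_PARAMETERS = ("kappa", "delta", "w_access_base", "p_belief", "servings_tail_tilt")
DEFAULT_BOUNDS = {
    "kappa": (0.5, 2.5),
    "delta": (2.0, 4.5),       # keeps the peak marginal step reachable near 3.25
    "w_access_base": (0.3, 3.0),
    "p_belief": (0.05, 0.95),
    "servings_tail_tilt": (0.6, 1.1),
}

_PEAK_PENALTY_WEIGHT = 80.0
#: With a positive ``peak_margin_pp`` the convergence check demands this
#: fraction of the requested margin, leaving the optimizer a cushion.
_PEAK_CONV_FRACTION = 0.6
_ANCHOR_TOL_PP = 1.5
#: Margin used when calibrating to the published anchors: large enough
#: that the fitted peak location survives re-simulation noise.
ROBUST_PEAK_MARGIN_PP = 0.45


@dataclass
class CalibrationResult:
    fitted: dict[str, float]
    params: BehaviorParams
    loss: float
    n_evaluations: int
    converged: bool
    achieved: list[tuple[Anchor, float]]
    curve: ResponseCurve | None = None
    peak_ok: bool = field(default=False)
    message: str = ""

    @property
    def achieved_baseline(self) -> float:
        for anchor, value in self.achieved:
            if anchor.target_type == "baseline_pct":
                return value
        raise DomainError("calibration result has no baseline anchor")

    def to_dict(self) -> dict:
        return {
            "fitted": self.fitted,
            "loss": self.loss,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "peak_ok": self.peak_ok,
            "message": self.message,
            "achieved": [
                {
                    "delta_miles": a.delta_miles,
                    "target_type": a.target_type,
                    "target_value": a.target_value,
                    "simulated_value": v,
                }
                for a, v in self.achieved
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _curve_value(curve: ResponseCurve, anchor: Anchor) -> float:
    for p in curve.points:
        if abs(p.delta - anchor.delta_miles) < 1e-9:
            if anchor.target_type == "relative_change_pct":
                return p.pct_relative_change
            return p.pct  # baseline_pct and absolute pct anchors
    raise DomainError(f"curve has no point at delta {anchor.delta_miles}")


def _peak_penalty(
    curve: ResponseCurve, peak_step: tuple[float, float], margin_pp: float = 0.0
) -> tuple[float, bool, float]:
    """Hinge penalty pushing the largest marginal step onto ``peak_step``.

    Only steps of the same width as the target step are compared (a coarse
    search grid may contain wider spans). Returns (penalty, peak_ok,
    margin): peak_ok means the recorded argmax sits on the target step,
    margin is the gap (pp) between the target step and the runner-up.
    """
    table = marginal_effects(curve)
    width = abs(peak_step[0] - peak_step[1])
    target_change = None
    others = []
    for frm, to, change in table.steps:
        if abs(frm - peak_step[0]) < 1e-6 and abs(to - peak_step[1]) < 1e-6:
            target_change = change
        elif abs(abs(frm - to) - width) < 1e-6:
            others.append(change)
    if target_change is None:
        raise ConfigError(f"sweep grid does not contain the peak step {peak_step}")
    ok = (
        abs(table.argmax_step[0] - peak_step[0]) < 1e-6
        and abs(table.argmax_step[1] - peak_step[1]) < 1e-6
        and not table.degenerate
    )
    violations = [
        max(0.0, other - (target_change - margin_pp)) for other in others
    ]
    penalty = _PEAK_PENALTY_WEIGHT * float(np.sum(np.square(violations)))
    if target_change <= 0:
        penalty += _PEAK_PENALTY_WEIGHT * (1.0 + target_change**2)
    margin = target_change - max(others) if others else float("inf")
    return penalty, ok, margin


def _anchor_loss(
    curve: ResponseCurve, anchors: AnchorSet
) -> tuple[float, list[tuple[Anchor, float]]]:
    """Weighted squared residuals plus the achieved value per anchor.

    Each residual is taken on its anchor's own scale (percentage points
    for the baseline, relative points for the scenario changes), so the
    loss optimizes exactly the quantities the anchors state.
    """
    loss = 0.0
    achieved = []
    for anchor in anchors.anchors:
        value = _curve_value(curve, anchor)
        loss += anchor.weight * (value - anchor.target_value) ** 2
        achieved.append((anchor, value))
    return loss, achieved


def _apply_theta(params0: BehaviorParams, theta: np.ndarray) -> BehaviorParams:
    return params0.replace(**{k: float(v) for k, v in zip(FREE_PARAMETERS, theta)})


def _screen_design(
    bounds: np.ndarray, n: int, seed: int
) -> np.ndarray:
    """Deterministic Latin-hypercube screen over the box."""
    rng = np.random.default_rng(seed)
    d = bounds.shape[0]
    u = np.empty((n, d))
    for j in range(d):
        u[:, j] = (rng.permutation(n) + rng.uniform(size=n)) / n
    return bounds[:, 0] + u * (bounds[:, 1] - bounds[:, 0])


def calibrate(
    community: Community,
    params0: BehaviorParams,
    anchors: AnchorSet,
    spec: SimulationSpec,
    budget: int = 140,
    *,
    bounds: dict[str, tuple[float, float]] | None = None,
    grid: Sequence[float] = DEFAULT_GRID,
    n_screen: int = 30,
    peak_margin_pp: float = 0.0,
) -> CalibrationResult:
    """Fit the five free parameters to the anchor set.

    ``budget`` caps the number of loss evaluations across both stages.
    The incumbent loss is non-increasing, and the whole procedure is a
    deterministic function of (community, params0, anchors, spec).

    ``peak_margin_pp`` > 0 additionally requires the target marginal step
    to beat every other step by that many percentage points (through the
    hinge penalty, with convergence demanding a fraction of it), which
    makes the fitted peak location robust to re-simulation noise.
    """
    if budget < 1:
        raise DomainError("budget must be >= 1")
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    box = np.array([bnds[k] for k in FREE_PARAMETERS], dtype=float)
    if (box[:, 0] >= box[:, 1]).any():
        raise ConfigError(f"infeasible bounds: {bnds}")

    anchor_deltas = sorted({a.delta_miles for a in anchors.anchors} | {0.0})
    full_grid = sorted(set(float(g) for g in grid) | set(anchor_deltas))
    # the pattern search monitors the marginal steps around the target peak
    # on a reduced grid; the winning parameters get one full-grid pass
    width = abs(anchors.peak_step[0] - anchors.peak_step[1])
    lo = min(anchors.peak_step) - 2 * width
    base_dist = float(np.mean([a.nearest_fv_distance for a in community.agents]))
    search_grid = sorted(
        set(anchor_deltas)
        | {d for d in full_grid if lo - 1e-9 <= base_dist - d <= base_dist + 1e-9}
    )
    evals = {"n": 0}
    cache: dict[tuple, tuple] = {}

    def evaluate(theta: np.ndarray, *, mode: str) -> tuple:
        key = (tuple(np.round(theta, 10)), mode)
        if key in cache:
            return cache[key]
        if evals["n"] >= budget and mode != "full":
            return None
        evals["n"] += 1
        params = _apply_theta(params0, theta)
        grid_used = {
            "anchors": anchor_deltas,
            "search": search_grid,
            "full": full_grid,
        }[mode]
        curve = sweep(community, params, spec, grid=grid_used)
        loss, achieved = _anchor_loss(curve, anchors)
        peak_ok, margin = False, -np.inf
        if mode != "anchors":
            penalty, peak_ok, margin = _peak_penalty(
                curve, anchors.peak_step, peak_margin_pp
            )
            loss += penalty
        out = (loss, achieved, curve, peak_ok, margin)
        cache[key] = out
        return out

    def is_converged(res) -> bool:
        _, achieved, _, peak_ok, margin = res
        return (
            peak_ok
            and margin >= _PEAK_CONV_FRACTION * peak_margin_pp
            and all(abs(v - a.target_value) <= _ANCHOR_TOL_PP for a, v in achieved)
        )

    theta0 = np.clip(
        np.array([getattr(params0, k) for k in FREE_PARAMETERS], dtype=float),
        box[:, 0], box[:, 1],
    )
    best_theta = theta0
    best = evaluate(theta0, mode="search")

    # fixed point: starting parameters already satisfy everything
    if best is not None and is_converged(best):
        final = evaluate(best_theta, mode="full")
        if is_converged(final):
            return _result(
                best_theta, params0, final, evals["n"], anchors, True,
                "starting parameters satisfied the anchors",
            )

    # stage A: space-filling screen on the anchor residuals alone
    n_screen_eff = min(n_screen, max(0, budget - evals["n"] - 20))
    screened: list[tuple[float, np.ndarray]] = []
    if n_screen_eff > 0:
        # a fixed quasi-random design: the screen is a deterministic coarse
        # grid over the box, identical for every simulation seed
        design = _screen_design(box, n_screen_eff, seed=20406080)
        for theta in design:
            res = evaluate(theta, mode="anchors")
            if res is None:
                break
            screened.append((res[0], theta))
    screened.sort(key=lambda t: t[0])

    # compass search with opportunistic acceptance; ``mode`` selects the
    # surface (anchor residuals alone, or with the peak penalty)
    def compass(theta, incumbent, mode, stop_at=None, initial_step=0.2):
        steps = initial_step * (box[:, 1] - box[:, 0])
        min_steps = 0.002 * (box[:, 1] - box[:, 0])
        while evals["n"] < budget and (stop_at is None or evals["n"] < stop_at):
            improved = False
            for j in range(len(FREE_PARAMETERS)):
                for direction in (+1.0, -1.0):
                    trial = theta.copy()
                    trial[j] = np.clip(
                        trial[j] + direction * steps[j], box[j, 0], box[j, 1]
                    )
                    if np.allclose(trial, theta):
                        continue
                    res = evaluate(trial, mode=mode)
                    if res is None:
                        return theta, incumbent
                    if incumbent is None or res[0] < incumbent[0]:
                        theta, incumbent = trial, res
                        improved = True
                        # greedy line extension along the winning direction
                        while True:
                            ext = theta.copy()
                            ext[j] = np.clip(
                                ext[j] + direction * steps[j], box[j, 0], box[j, 1]
                            )
                            if np.allclose(ext, theta):
                                break
                            res = evaluate(ext, mode=mode)
                            if res is None or res[0] >= incumbent[0]:
                                break
                            theta, incumbent = ext, res
                        break  # poll the next coordinate from the new point
            if (
                mode != "anchors"
                and incumbent is not None
                and is_converged(incumbent)
                and not improved
            ):
                break
            if not improved:
                steps *= 0.6
                if (steps < min_steps).all():
                    break
        return theta, incumbent

    # Two complementary descents share the remaining budget; the better
    # endpoint wins. (a) Direct: descend the full search loss from the
    # screen leader — effective when the feasible peak region shapes the
    # solution. (b) Anchors-first fallback: descend the penalty-free anchor
    # surface, then polish with the peak penalty switched on — effective
    # when penalty cliffs would trap a direct descent.
    remaining = budget - evals["n"]
    starts = [theta for _, theta in screened[:2]]
    starts.append(theta0)  # the shipped defaults are a curated start

    # (a) direct descents on the full search loss via Nelder-Mead, which
    # follows the diagonal valleys that coordinate-wise polling cannot
    from scipy.optimize import minimize

    tracker = {"best": best, "theta": best_theta}

    def search_objective(x):
        theta = np.clip(x, box[:, 0], box[:, 1])
        res = evaluate(theta, mode="search")
        if res is None:
            return float("inf")
        if tracker["best"] is None or res[0] < tracker["best"][0]:
            tracker["best"], tracker["theta"] = res, theta
        return res[0]

    for start in starts:
        allowance = budget - evals["n"]
        if allowance <= 10 and tracker["best"] is not None:
            break
        minimize(
            search_objective, start, method="Nelder-Mead", bounds=box,
            options={
                "maxfev": max(10, min(allowance, int(0.3 * remaining))),
                "xatol": 1e-3, "fatol": 1e-3,
            },
        )
        if tracker["best"] is not None and is_converged(tracker["best"]):
            break
    best, best_theta = tracker["best"], tracker["theta"]

    # (b) anchors-first fallback
    if (best is None or not is_converged(best)) and budget - evals["n"] > 10:
        start = starts[0] if screened else theta0
        inc = evaluate(start, mode="anchors")
        if inc is not None:
            th_a, _ = compass(
                start.copy(), inc, "anchors",
                stop_at=evals["n"] + max(10, int(0.6 * (budget - evals["n"]))),
            )
            inc_a = evaluate(th_a, mode="search")
            if inc_a is not None:
                if best is None or inc_a[0] < best[0]:
                    best, best_theta = inc_a, th_a
                th_a, inc_a = compass(
                    th_a.copy(), inc_a, "search", initial_step=0.08
                )
                if inc_a is not None and (best is None or inc_a[0] < best[0]):
                    best, best_theta = inc_a, th_a

    # final polish: restart the simplex around the incumbent
    if best is not None and budget - evals["n"] > 5:
        tracker["best"], tracker["theta"] = best, best_theta
        minimize(
            search_objective, best_theta, method="Nelder-Mead", bounds=box,
            options={"maxfev": budget - evals["n"], "xatol": 1e-4, "fatol": 1e-4},
        )
        best, best_theta = tracker["best"], tracker["theta"]

    if best is None:  # budget exhausted before any search evaluation
        params = _apply_theta(params0, best_theta)
        return CalibrationResult(
            fitted={k: float(v) for k, v in zip(FREE_PARAMETERS, best_theta)},
            params=params, loss=float("inf"), n_evaluations=evals["n"],
            converged=False, achieved=[], curve=None,
            message="budget exhausted before any evaluation completed",
        )
    # final verification on the full grid (one extra sweep)
    final = evaluate(best_theta, mode="full")
    converged = is_converged(final)
    message = "converged" if converged else "budget exhausted without convergence"
    return _result(best_theta, params0, final, evals["n"], anchors, converged, message)


def _result(theta, params0, best, n_evals, anchors, converged, message) -> CalibrationResult:
    loss, achieved, curve, peak_ok, _margin = best
    return CalibrationResult(
        fitted={k: float(v) for k, v in zip(FREE_PARAMETERS, theta)},
        params=_apply_theta(params0, theta),
        loss=float(loss),
        n_evaluations=n_evals,
        converged=converged,
        achieved=achieved,
        curve=curve,
        peak_ok=peak_ok,
        message=message,
    )


def validate_baseline(
    result: CalibrationResult, observed_pct: float, tolerance_pp: float = 1.0
) -> tuple[bool, dict]:
    """Compare the calibrated baseline against an externally observed figure.

    Returns (within tolerance, report with both values and the gap).
    """
    achieved = result.achieved_baseline
    gap = abs(achieved - observed_pct)
    ok = gap <= tolerance_pp
    report = {
        "simulated_baseline_pct": achieved,
        "observed_pct": observed_pct,
        "gap_pp": gap,
        "tolerance_pp": tolerance_pp,
        "within_tolerance": ok,
    }
    return ok, report
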