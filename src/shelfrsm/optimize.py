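"""Maximize the fitted shelf-life surface over the admissible factor box.

Packaging is an ordered categorical factor: the optimizer enumerates
its admissible levels and never interpolates between them, even though
the model carries packaging on a numeric code.  Within each packaging
level the response is a one-dimensional quadratic in the coded rate,
maximized analytically (interior vertex when the quadratic coefficient
is negative and the vertex lies in bounds, otherwise the better
endpoint) and cross-checked against a dense grid scan.

A Derringer-style linear desirability ramp maps the achieved response
onto [0, 1] for goal reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import FactorSpec, code_value, decode_value
from .model import QuadraticModel

__all__ = [
    "GoalSpec",
    "OptimizationResult",
    "optimize_response",
    "desirability",
    "surface_grid",
]


@dataclass
class GoalSpec:
    """Optimization goal: response direction and the admissible factor box.

    ``packaging_levels`` restricts the enumerated categorical levels
    (default: all fitted levels); ``rate_bounds`` is the closed actual-
    unit interval searched (default: the fitted level range).
    """

    response_goal: str = "maximize"
    packaging_levels: tuple | None = None
    rate_bounds: tuple | None = None

    def __post_init__(self) -> None:
        if self.response_goal not in ("maximize", "minimize"):
            raise ValueError(f"unknown response goal {self.response_goal!r}")
        if self.rate_bounds is not None:
            lo, hi = self.rate_bounds
            if not lo < hi:
                raise ValueError("rate bounds must satisfy lo < hi")
        if self.packaging_levels is not None and not self.packaging_levels:
            raise ValueError("empty packaging level set")


@dataclass
class OptimizationResult:
    packaging: str
    rate: float
    predicted: float
    desirability: float
    trace: str


def desirability(value: float, goal: str, low: float, high: float) -> float:
    """Linear desirability ramp on [low, high].

    For ``maximize``: 0 at or below ``low``, 1 at or above ``high``,
    linear between; mirrored for ``minimize``.
    """
    if low >= high:
        raise ValueError("desirability needs low < high")
    t = (value - low) / (high - low)
    t = min(max(t, 0.0), 1.0)
    if goal == "maximize":
        return t
    if goal == "minimize":
        return 1.0 - t
    raise ValueError(f"unknown goal {goal!r}")


def _rate_spec(model: QuadraticModel) -> FactorSpec:
    for f in model.factors:
        if not f.is_categorical:
            return f
    raise ValueError("model has no continuous rate factor")


def _packaging_spec(model: QuadraticModel) -> FactorSpec:
    for f in model.factors:
        if f.is_categorical:
            return f
    raise ValueError("model has no categorical packaging factor")


def _quadratic_in_rate(model: QuadraticModel, pkg_coded: float):
    """Coefficients (c, b, a) of the response as a quadratic in coded rate."""
    pkg = _packaging_spec(model).name
    rate = _rate_spec(model).name
    c = (
        model.beta0
        + model.beta_linear[pkg] * pkg_coded
        + model.beta_quadratic[pkg] * pkg_coded**2
    )
    key = (pkg, rate) if (pkg, rate) in model.beta_interaction else (rate, pkg)
    b = model.beta_linear[rate] + model.beta_interaction[key] * pkg_coded
    a = model.beta_quadratic[rate]
    return c, b, a


def _extremum_1d(c, b, a, lo, hi, maximize=True):
    """Closed-form extremum of a*t^2 + b*t + c over [lo, hi]."""
    cands = [lo, hi]
    if a != 0.0:
        vertex = -b / (2.0 * a)
        vertex_is_max = a < 0.0
        if lo <= vertex <= hi and vertex_is_max == maximize:
            cands.append(vertex)
    vals = [a * t * t + b * t + c for t in cands]
    idx = int(np.argmax(vals)) if maximize else int(np.argmin(vals))
    return cands[idx], vals[idx]


def optimize_response(
    model: QuadraticModel,
    goals: GoalSpec | None = None,
    grid_step: float = 0.001,
) -> OptimizationResult:
    """Find the packaging level and residue rate optimizing the surface.

    The analytic per-level optimum is verified against a grid scan with
    actual-unit step ``grid_step``; a discrepancy beyond one grid step
    raises, since it would indicate an algebra error.  Ties between
    packaging levels are broken toward the level whose desirability
    integral over the rate interval is larger.
    """
    goals = goals or GoalSpec()
    pkg_spec = _packaging_spec(model)
    rate_spec = _rate_spec(model)
    maximize = goals.response_goal == "maximize"

    levels = goals.packaging_levels or pkg_spec.actual_levels
    unknown = set(levels) - set(pkg_spec.actual_levels)
    if unknown:
        raise ValueError(f"packaging levels outside the fitted set: {sorted(unknown)}")

    rlevels = rate_spec.numeric_levels
    lo_a, hi_a = (
        goals.rate_bounds
        if goals.rate_bounds is not None
        else (float(rlevels.min()), float(rlevels.max()))
    )
    if lo_a < rlevels.min() or hi_a > rlevels.max():
        raise ValueError("rate bounds extend beyond the fitted level range")
    lo_c = code_value(lo_a, rate_spec)
    hi_c = code_value(hi_a, rate_spec)

    # desirability ramp spans the surface over a probe grid of the box
    probe = np.linspace(lo_c, hi_c, 201)
    probe_vals = []
    per_level = {}
    trace_lines = []
    for lev in levels:
        pc = code_value(lev, pkg_spec)
        c, b, a = _quadratic_in_rate(model, pc)
        t_star, v_star = _extremum_1d(c, b, a, lo_c, hi_c, maximize)
        per_level[lev] = (t_star, v_star)
        probe_vals.append(a * probe**2 + b * probe + c)
        kind = (
            "interior vertex"
            if lo_c < t_star < hi_c
            else "interval endpoint"
        )
        trace_lines.append(
            f"{lev}: coded-rate optimum {t_star:.4f} ({kind}), "
            f"predicted {v_star:.4f}"
        )
    probe_vals = np.concatenate(probe_vals)
    low, high = float(probe_vals.min()), float(probe_vals.max())

    sign = 1.0 if maximize else -1.0
    best_val = max(sign * v for _, v in per_level.values())
    tied = [
        lev for lev, (_, v) in per_level.items()
        if abs(sign * v - best_val) < 1e-12
    ]
    if len(tied) > 1:
        # integral of the desirability ramp over the rate interval
        def ramp_integral(lev):
            pc = code_value(lev, pkg_spec)
            c, b, a = _quadratic_in_rate(model, pc)
            vals = a * probe**2 + b * probe + c
            if high == low:
                return 0.0
            return float(
                np.trapezoid(
                    np.clip(sign * (vals - low) / (high - low), 0, 1), probe
                )
            )

        tied.sort(key=ramp_integral, reverse=True)
        trace_lines.append(
            f"tie between {tied} broken by desirability integral -> {tied[0]}"
        )
    best_level = tied[0]
    t_star, v_star = per_level[best_level]
    rate_star = decode_value(t_star, rate_spec)

    # dense-grid verification in actual units
    n_grid = max(int(round((hi_a - lo_a) / grid_step)) + 1, 2)
    grid_a = np.linspace(lo_a, hi_a, n_grid)
    grid_c = np.array([code_value(v, rate_spec) for v in grid_a])
    grid_best = -np.inf if maximize else np.inf
    for lev in levels:
        pc = code_value(lev, pkg_spec)
        c, b, a = _quadratic_in_rate(model, pc)
        vals = a * grid_c**2 + b * grid_c + c
        ext = vals.max() if maximize else vals.min()
        grid_best = max(grid_best, ext) if maximize else min(grid_best, ext)
    if sign * (grid_best - v_star) > 1e-6 + abs(
        _grid_gap(model, best_level, t_star, grid_step, rate_spec, pkg_spec)
    ):
        raise RuntimeError(
            f"grid scan found {grid_best:.6f} better than analytic "
            f"{v_star:.6f}"
        )
    trace_lines.append(
        f"grid scan (step {grid_step} rate units) agrees within one step"
    )

    if high == low:
        des = 1.0
    else:
        des = desirability(
            v_star, goals.response_goal, low, high
        )
    return OptimizationResult(
        packaging=best_level,
        rate=round(float(rate_star), 3),
        predicted=float(v_star),
        desirability=des,
        trace="; ".join(trace_lines),
    )


def _grid_gap(model, level, t_star, grid_step, rate_spec, pkg_spec):
    # bound on how much the quadratic can change over one grid step
    pc = code_value(level, pkg_spec)
    c, b, a = _quadratic_in_rate(model, pc)
    span = rate_spec.numeric_levels.max() - rate_spec.numeric_levels.min()
    step_coded = 2.0 * grid_step / span if span else grid_step
    return (abs(b) + 2 * abs(a)) * step_coded


def surface_grid(
    model: QuadraticModel,
    rate_steps: int = 51,
    packaging_levels: tuple | None = None,
) -> pd.DataFrame:
    """Rectangular (packaging level x rate) grid of predicted responses.

    Backs surface plots; values equal ``model.predict`` pointwise.
    """
    if rate_steps < 2:
        raise ValueError("rate_steps must be at least 2")
    pkg_spec = _packaging_spec(model)
    rate_spec = _rate_spec(model)
    levels = packaging_levels or pkg_spec.actual_levels
    rlevels = rate_spec.numeric_levels
    rates = np.linspace(rlevels.min(), rlevels.max(), rate_steps)
    rows = []
    for lev in levels:
        pc = code_value(lev, pkg_spec)
        for r in rates:
            rows.append(
                {
                    "packaging": lev,
                    "packaging_code": pc,
                    "rate": float(r),
                    "predicted_days": model.predict(
                        {pkg_spec.name: lev, rate_spec.name: float(r)}
                    ),
                }
            )
    return pd.DataFrame(rows)
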