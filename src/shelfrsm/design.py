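"""Experimental factors and the replicated two-factor shelf-life design.

The experiment varies two factors over three levels each:

* ``packaging`` -- an ordered categorical factor with levels ``NONE``
  (no packaging), ``PBP`` (vented polyethylene plastic bag) and ``VBP``
  (polypropylene vacuum bag);
* ``rate`` -- the fraction of agro-industrial residue (olive pruning
  residue, spent coffee grounds, or their combination) mixed into the
  wheat-straw growing substrate.

The layout is a replicated 3x3 grid: nine distinct factor combinations,
with the (no packaging, rate 0) control point run five times.  The five
replicates supply four degrees of freedom of pure error for the
lack-of-fit test.

Factors are fitted on a dimensionless coded scale.  Under *level*
coding the three ordered levels map onto (-1, 0, +1); under *range*
coding a continuous value ``v`` maps to ``(v - midrange) / halfrange``.
For a factor whose middle level is not the midrange of its extremes
(e.g. rates 0 / 0.3 / 0.7) the two schemes differ, but only through the
interaction column of the quadratic model -- every statistic that does
not isolate the interaction term is invariant to the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FactorSpec",
    "DesignRun",
    "DesignMatrix",
    "code_value",
    "decode_value",
    "shelf_life_design",
    "replicate_groups",
    "RESIDUE_SCHEMES",
    "PACKAGING_LEVELS",
]

#: Packaging levels in the canonical coding order (lexicographic by label,
#: the ordering convention of mainstream DoE software for categoric
#: factors).  Coding order matters only for the interaction column.
PACKAGING_LEVELS: tuple[str, ...] = ("NONE", "PBP", "VBP")

#: Residue-rate levels per mixing scheme (fraction of substrate volume).
RESIDUE_SCHEMES: dict[str, tuple[float, float, float]] = {
    "OLPR": (0.0, 0.3, 0.7),
    "SCG": (0.0, 0.3, 0.7),
    "OLPR_SCG": (0.0, 0.17, 0.33),
}


class UnknownLevelError(ValueError):
    """A categorical setting is not one of the factor's levels."""


class CodingRangeError(ValueError):
    """A continuous setting lies outside the factor's level range."""


@dataclass(frozen=True)
class FactorSpec:
    """A three-level experimental factor with its coding scheme.

    Parameters
    ----------
    name
        Factor name used in run settings and model terms.
    kind
        ``"ordinal_categorical"`` (levels are labels with a fixed order)
        or ``"continuous"`` (levels are numeric settings).
    actual_levels
        The three distinct levels in coding order; the level-coding map
        sends them to -1, 0, +1 respectively.
    coding
        ``"level"`` or ``"range"``.  Categorical factors are always
        level-coded regardless of this field.
    """

    name: str
    kind: str
    actual_levels: tuple
    coding: str = "level"

    def __post_init__(self) -> None:
        if self.kind not in ("ordinal_categorical", "continuous"):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if self.coding not in ("level", "range"):
            raise ValueError(f"unknown coding {self.coding!r}")
        if len(self.actual_levels) != 3 or len(set(self.actual_levels)) != 3:
            raise ValueError(
                f"factor {self.name!r} needs exactly 3 distinct levels, "
                f"got {self.actual_levels!r}"
            )

    @property
    def is_categorical(self) -> bool:
        return self.kind == "ordinal_categorical"

    @property
    def numeric_levels(self) -> np.ndarray:
        """Actual levels as floats (continuous factors only)."""
        if self.is_categorical:
            raise TypeError(f"factor {self.name!r} is categorical")
        return np.asarray(self.actual_levels, dtype=float)

    def with_coding(self, coding: str) -> "FactorSpec":
        return replace(self, coding=coding)


def code_value(value, spec: FactorSpec) -> float:
    """Map an actual factor setting to its coded (dimensionless) value.

    Level coding sends the three ordered levels to -1/0/+1; for a
    continuous factor, intermediate settings are interpolated linearly
    between adjacent levels, so the coded axis is a monotone, piecewise
    linear transform of the actual axis.  Range coding is the affine map
    ``(value - midrange) / halfrange`` over the level extremes.
    """
    if spec.is_categorical or spec.coding == "level":
        if spec.is_categorical:
            try:
                idx = spec.actual_levels.index(value)
            except ValueError:
                raise UnknownLevelError(
                    f"{value!r} is not a level of {spec.name!r}; "
                    f"expected one of {spec.actual_levels!r}"
                ) from None
            return float(idx - 1)
        levels = spec.numeric_levels
        v = float(value)
        if not (levels.min() <= v <= levels.max()):
            raise CodingRangeError(
                f"{spec.name}={v} outside level range "
                f"[{levels.min()}, {levels.max()}]"
            )
        return float(np.interp(v, levels, [-1.0, 0.0, 1.0]))
    levels = spec.numeric_levels
    lo, hi = levels.min(), levels.max()
    v = float(value)
    if not (lo <= v <= hi):
        raise CodingRangeError(
            f"{spec.name}={v} outside level range [{lo}, {hi}]"
        )
    mid = (lo + hi) / 2.0
    half = (hi - lo) / 2.0
    return (v - mid) / half


def decode_value(coded: float, spec: FactorSpec):
    """Inverse of :func:`code_value`.

    Categorical factors only decode exactly at -1, 0, +1.
    """
    if spec.is_categorical:
        mapping = {-1.0: 0, 0.0: 1, 1.0: 2}
        key = float(coded)
        if key not in mapping:
            raise UnknownLevelError(
                f"coded value {coded} does not name a level of {spec.name!r}"
            )
        return spec.actual_levels[mapping[key]]
    if spec.coding == "level":
        levels = spec.numeric_levels
        return float(np.interp(coded, [-1.0, 0.0, 1.0], levels))
    levels = spec.numeric_levels
    lo, hi = levels.min(), levels.max()
    return float((lo + hi) / 2.0 + coded * (hi - lo) / 2.0)


@dataclass
class DesignRun:
    """One experimental run: factor settings and an optional response."""

    run_id: int
    settings: dict
    response: float | None = None

    def __post_init__(self) -> None:
        if self.run_id <= 0:
            raise ValueError("run_id must be a positive integer")
        if self.response is not None and self.response < 0:
            raise ValueError(
                f"run {self.run_id}: response must be nonnegative, "
                f"got {self.response}"
            )


@dataclass
class DesignMatrix:
    """A designed experiment: factors, runs, and the response name."""

    factors: list[FactorSpec]
    runs: list[DesignRun]
    response_name: str = "shelf_life_days"

    def __post_init__(self) -> None:
        names = {f.name for f in self.factors}
        for run in self.runs:
            missing = names - set(run.settings)
            if missing:
                raise ValueError(
                    f"run {run.run_id} lacks settings for {sorted(missing)}"
                )

    def factor(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def responses(self) -> np.ndarray:
        ys = [r.response for r in self.runs]
        if any(y is None for y in ys):
            raise ValueError("design has runs without measured responses")
        return np.asarray(ys, dtype=float)

    def coded_settings(self) -> np.ndarray:
        """(n_runs, n_factors) array of coded factor settings."""
        return np.array(
            [
                [code_value(r.settings[f.name], f) for f in self.factors]
                for r in self.runs
            ]
        )

    def with_responses(self, values: Sequence[float]) -> "DesignMatrix":
        if len(values) != len(self.runs):
            raise ValueError("one response per run required")
        runs = [
            DesignRun(r.run_id, dict(r.settings), float(v))
            for r, v in zip(self.runs, values)
        ]
        return DesignMatrix(list(self.factors), runs, self.response_name)


def shelf_life_design(
    residue_scheme: str = "OLPR",
    rate_coding: str = "level",
    response_name: str = "shelf_life_days",
) -> DesignMatrix:
    """Build the 13-run packaging x residue-rate layout (no responses).

    Nine distinct points cover the full 3x3 grid; the unpacked,
    zero-residue control is replicated five times (runs 1 and 10-13),
    giving pure-error df = 4.
    """
    if residue_scheme not in RESIDUE_SCHEMES:
        raise ValueError(
            f"unknown residue scheme {residue_scheme!r}; "
            f"expected one of {sorted(RESIDUE_SCHEMES)}"
        )
    rates = RESIDUE_SCHEMES[residue_scheme]
    packaging = FactorSpec("packaging", "ordinal_categorical", PACKAGING_LEVELS)
    rate = FactorSpec("rate", "continuous", rates, coding=rate_coding)
    grid = [
        ("NONE", rates[0]),
        ("NONE", rates[1]),
        ("NONE", rates[2]),
        ("PBP", rates[0]),
        ("PBP", rates[1]),
        ("PBP", rates[2]),
        ("VBP", rates[0]),
        ("VBP", rates[1]),
        ("VBP", rates[2]),
        ("NONE", rates[0]),
        ("NONE", rates[0]),
        ("NONE", rates[0]),
        ("NONE", rates[0]),
    ]
    runs = [
        DesignRun(i, {"packaging": p, "rate": r})
        for i, (p, r) in enumerate(grid, start=1)
    ]
    return DesignMatrix([packaging, rate], runs, response_name)


def replicate_groups(design: DesignMatrix) -> list[list[int]]:
    """Partition run ids into groups sharing identical factor settings.

    Singleton groups are kept; group order follows first appearance.
    """
    if not design.runs:
        raise ValueError("empty design")
    seen: dict[tuple, list[int]] = {}
    for run in design.runs:
        key = tuple(run.settings[f.name] for f in design.factors)
        seen.setdefault(key, []).append(run.run_id)
    return list(seen.values())
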