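"""Synthetic data generators mirroring the structure of the real tables.

Three generators cover the three data streams the analysis consumes:

* ``simulate_design`` -- responses on a design layout: a known
  quadratic surface evaluated at each run's coded settings plus
  i.i.d. Gaussian noise.  The default noise level (0.16 days) matches
  the replicate-to-replicate scatter of the shipped shelf-life data
  (pure-error mean square ~ 0.025 days^2).
* ``simulate_tmc`` -- log-CFU storage trajectories: a linear growth
  trend with Gaussian noise, projected onto non-decreasing sequences
  by a cumulative maximum (noise first, projection second, so runs of
  equal values appear, as in the real tables) and rounded to one
  decimal.  Defaults (intercept 3.0, slope 1.0 log units/day) mimic an
  unpacked sample at ambient temperature.
* ``simulate_quality`` -- weight decaying geometrically, firmness
  decaying linearly with a floor at the scale minimum, and veil counts
  opening progressively.

All randomness flows through one explicitly seeded generator; no
global random state is touched.  Identical configuration and seed give
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DesignMatrix
from .model import QuadraticModel, model_matrix
from .quality import QualityRecord
from .tmc import TMCSeries

__all__ = ["SyntheticConfig", "simulate_design", "simulate_tmc", "simulate_quality"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic data generators.

    Attributes
    ----------
    true_beta
        Coefficients of the generating quadratic surface in fit order
        (b0, b1, b2, b12, b11, b22) on the coded scale, in days.
    noise_sd
        Standard deviation of the response noise, days.
    seed
        Seed for the single pseudo-random generator.
    tmc_intercept, tmc_slope, tmc_noise_sd
        Day-0 level, daily increase and noise of the log-CFU trend
        (log10 CFU/g, per day).
    w0, daily_loss_fraction
        Initial weight (g) and per-day fractional weight loss.
    firmness0, firmness_decay
        Initial firmness score and its daily linear decay (floored at 1).
    veils_total
        Partial-veil count per sample.
    """

    true_beta: tuple = (3.0, 2.0, 0.5, 0.2, 1.5, -1.0)
    noise_sd: float = 0.16
    seed: int = 0
    tmc_intercept: float = 3.0
    tmc_slope: float = 1.0
    tmc_noise_sd: float = 0.15
    w0: float = 200.0
    daily_loss_fraction: float = 0.03
    firmness0: float = 9.0
    firmness_decay: float = 1.35
    veils_total: int = 10

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.tmc_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if self.tmc_slope < 0:
            raise ValueError("TMC daily increase must be nonnegative")
        if not 0.0 <= self.daily_loss_fraction < 1.0:
            raise ValueError("daily loss fraction must lie in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_design(
    config: SyntheticConfig,
    layout: DesignMatrix,
    rng: np.random.Generator | None = None,
) -> DesignMatrix:
    """Attach surface-plus-noise responses to a design layout."""
    rng = rng if rng is not None else config.rng()
    A = model_matrix(layout.coded_settings())
    beta = np.asarray(config.true_beta, dtype=float)
    if beta.shape != (A.shape[1],):
        raise ValueError(
            f"true_beta must have {A.shape[1]} coefficients, got {beta.shape[0]}"
        )
    y = A @ beta + rng.normal(0.0, config.noise_sd, size=A.shape[0])
    return layout.with_responses(np.clip(y, 0.0, None))


def simulate_tmc(
    config: SyntheticConfig,
    days: list[int],
    packaging: str = "NONE",
    substrate_code: str = "SYN",
    temperature: str = "ambient",
    rng: np.random.Generator | None = None,
) -> TMCSeries:
    """Generate one monotone log-CFU trajectory over the given days."""
    d = np.asarray(days, dtype=float)
    if d.ndim != 1 or len(d) == 0 or np.any(np.diff(d) <= 0):
        raise ValueError("days must be a non-empty strictly increasing list")
    rng = rng if rng is not None else config.rng()
    trend = config.tmc_intercept + config.tmc_slope * d
    noisy = trend + rng.normal(0.0, config.tmc_noise_sd, size=len(d))
    mono = np.maximum.accumulate(np.clip(noisy, 0.0, None))
    values = np.round(mono, 1)
    # rounding can break ties downward by half a unit in the last place
    values = np.maximum.accumulate(values)
    return TMCSeries(
        packaging=packaging,
        substrate_code=substrate_code,
        temperature=temperature,
        days=tuple(int(v) for v in days),
        values=tuple(float(v) for v in values),
    )


def simulate_quality(
    config: SyntheticConfig,
    days: list[int],
    rng: np.random.Generator | None = None,
) -> list[QualityRecord]:
    """Generate a deteriorating quality series over the given days."""
    rng = rng if rng is not None else config.rng()
    records = []
    open_count = 0
    for day in days:
        wt = config.w0 * (1.0 - config.daily_loss_fraction) ** day
        firmness = max(config.firmness0 - config.firmness_decay * day, 1.0)
        remaining = config.veils_total - open_count
        if remaining > 0 and day > 0:
            open_count += int(rng.binomial(remaining, 0.25))
        records.append(
            QualityRecord(
                day=int(day),
                weight_initial=config.w0,
                weight_t=wt,
                firmness=firmness,
                veils_total=config.veils_total,
                veils_open=open_count,
            )
        )
    return records
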