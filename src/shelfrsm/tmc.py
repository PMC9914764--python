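"""Total microbial count (TMC) classification and consumability windows.

TMC is the total aerobic plate count of a sample, reported as
log10 CFU/g.  Counts are classified into four contamination bands:

    LOW        < 5.0
    MEDIUM     5.0 - 6.5   (inclusive both ends)
    HIGH       > 6.5, <= 8.05
    VERY_HIGH  > 8.05

The published band definitions leave gaps between bands (5.0-5.1 and
8.0-8.1 are quoted to one decimal); the edges used here close those
gaps so that every one-decimal reading classifies uniquely.  5.0 counts
as MEDIUM -- the assignment under which the band membership of every
stored observation matches the summary fractions reported alongside the
data -- and the upper HIGH edge sits at the 8.0/8.1 midpoint, so 8.1
reads as VERY_HIGH.

A sample is considered consumable while its TMC stays at or below
8.1 log CFU/g; :func:`consumability_window` reports the last storage
day before a series first exceeds that threshold.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContaminationLevel",
    "TMCSeries",
    "classify",
    "log_transform",
    "level_summary",
    "consumability_window",
    "CONSUMABILITY_THRESHOLD",
]

#: log10 CFU/g above which a sample is ranked unfavorable for consumption.
CONSUMABILITY_THRESHOLD = 8.1

_LOW_EDGE = 5.0     # < edge -> LOW; the edge itself is MEDIUM
_MEDIUM_EDGE = 6.5  # inclusive upper MEDIUM bound
_HIGH_EDGE = 8.05   # midpoint of the quoted 8.0 / 8.1 band gap


class ContaminationLevel(enum.IntEnum):
    """Ordered contamination bands on the log10 CFU/g scale."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2
    VERY_HIGH = 3


def classify(tmc: float) -> ContaminationLevel:
    """Assign a log10 CFU/g reading to its contamination band."""
    if tmc < 0:
        raise ValueError(f"TMC must be nonnegative, got {tmc}")
    if not math.isfinite(tmc):
        raise ValueError("TMC must be finite")
    if tmc < _LOW_EDGE:
        return ContaminationLevel.LOW
    if tmc <= _MEDIUM_EDGE:
        return ContaminationLevel.MEDIUM
    if tmc <= _HIGH_EDGE:
        return ContaminationLevel.HIGH
    return ContaminationLevel.VERY_HIGH


def log_transform(cfu: float) -> float:
    """Convert a raw CFU/g count to log10 CFU/g."""
    if cfu <= 0:
        raise ValueError(f"CFU count must be positive, got {cfu}")
    return math.log10(cfu)


@dataclass
class TMCSeries:
    """One storage trajectory: log10 CFU/g per day for one sample group."""

    packaging: str
    substrate_code: str
    temperature: str
    days: tuple
    values: tuple

    def __post_init__(self) -> None:
        if len(self.days) != len(self.values):
            raise ValueError("days and values must align")
        if not self.days:
            raise ValueError("empty series")
        d = np.asarray(self.days)
        if np.any(np.diff(d) <= 0):
            raise ValueError("days must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TMC values must be finite")

    def value_at(self, day: int) -> float:
        try:
            return self.values[self.days.index(day)]
        except ValueError:
            raise KeyError(
                f"day {day} absent from series "
                f"({self.packaging}/{self.substrate_code})"
            ) from None

    @property
    def label(self) -> str:
        return f"{self.packaging}/{self.substrate_code}/{self.temperature}"


def series_from_frame(frame: pd.DataFrame) -> list[TMCSeries]:
    """Build series from a long-format table.

    Expected columns: packaging, substrate_code, temperature, day,
    log_cfu_g.
    """
    required = {"packaging", "substrate_code", "temperature", "day", "log_cfu_g"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"TMC table lacks columns {sorted(missing)}")
    out = []
    keys = ["packaging", "substrate_code", "temperature"]
    for (pkg, code, temp), grp in frame.groupby(keys, sort=False):
        grp = grp.sort_values("day")
        out.append(
            TMCSeries(
                packaging=pkg,
                substrate_code=code,
                temperature=temp,
                days=tuple(int(d) for d in grp["day"]),
                values=tuple(float(v) for v in grp["log_cfu_g"]),
            )
        )
    return out


def level_summary(
    series: Iterable[TMCSeries],
    day: int,
    packaging: Sequence[str] | None = None,
) -> dict:
    """Band counts, fractions and the value range on one storage day.

    Parameters
    ----------
    series
        The series to summarize.
    day
        Storage day; must be observed in every selected series.
    packaging
        Optional packaging filter (e.g. ``("PBP", "VBP")`` for packed
        samples only).

    Returns a dict with ``n``, per-band ``counts`` and ``fractions``
    (summing to 1), and the ``(min, max)`` TMC ``range`` of the
    selected values.
    """
    selected = [
        s for s in series if packaging is None or s.packaging in packaging
    ]
    if not selected:
        raise ValueError("no series match the packaging filter")
    values = [s.value_at(day) for s in selected]
    counts = {lev: 0 for lev in ContaminationLevel}
    for v in values:
        counts[classify(v)] += 1
    n = len(values)
    return {
        "n": n,
        "day": day,
        "counts": {lev.name: c for lev, c in counts.items()},
        "fractions": {lev.name: c / n for lev, c in counts.items()},
        "range": (min(values), max(values)),
    }


def consumability_window(
    series: TMCSeries, threshold: float = CONSUMABILITY_THRESHOLD
) -> int | None:
    """Last observed day on which the series has stayed at or below threshold.

    Scans observations in day order and returns the day of the last
    observation before the threshold is first exceeded; ``None`` if the
    series starts above it.
    """
    last = None
    for day, value in zip(series.days, series.values):
        if value > threshold:
            break
        last = day
    return last
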