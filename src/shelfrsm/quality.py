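"""Physicochemical quality metrics and consumer-acceptability rules.

Weight loss and veil opening are the two computed metrics:

    weight loss (%)  = 100 * (W0 - Wt) / W0
    veil opening (%) = 100 * (Vt - Vf) / Vt

where W0/Wt are the initial and current weights and Vt/Vf the total
and open partial-veil counts.  Note the veil formula, taken verbatim
from its published form, is the percentage of veils remaining *closed*
(it reads 100 % when no veil is open); because the surrounding
acceptability rule treats values at or above 70 % as deterioration --
the reading that matches the rest of the quality narrative -- each
record also exposes ``veil_opened_pct``, the complementary
``100 * Vf / Vt``, and carries a ``veil_metric_convention`` flag naming
which convention a value follows.

Acceptability (field rules of thumb for fresh mushrooms):

* weight loss of at most 5 % of the harvest weight;
* instrumented firmness score of at least 3.0 on the 1-9 scale
  (below 3.0 the mushroom is soft and unmarketable);
* veil metric below 70 %.

Protein (Kjeldahl nitrogen x 4.38) and carbohydrate (anthrone assay)
contents are carried as measured percentages of fresh weight; the
assays themselves are upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "QualityRecord",
    "weight_loss",
    "veil_opening",
    "veil_opened_fraction",
    "acceptability",
    "WEIGHT_LOSS_LIMIT_PCT",
    "FIRMNESS_FLOOR",
    "VEIL_OPENING_LIMIT_PCT",
]

WEIGHT_LOSS_LIMIT_PCT = 5.0   # inclusive: "around 5 %" reads as <= 5.0
FIRMNESS_FLOOR = 3.0          # inclusive: >= 3.0 is acceptable
VEIL_OPENING_LIMIT_PCT = 70.0  # exclusive: 70 % marks deterioration


def weight_loss(w0: float, wt: float) -> float:
    """Percent weight lost since harvest: 100 * (W0 - Wt) / W0."""
    if w0 <= 0:
        raise ValueError("initial weight must be positive")
    if wt <= 0:
        raise ValueError("current weight must be positive")
    if wt > w0:
        raise ValueError(
            f"current weight {wt} exceeds initial weight {w0}; "
            "mass gain is not modelled"
        )
    return 100.0 * (w0 - wt) / w0


def veil_opening(vt: int, vf: int) -> float:
    """Veil metric as published: 100 * (Vt - Vf) / Vt.

    ``vt`` is the total number of partial veils and ``vf`` the number
    that have opened.  As written this is the percentage of veils still
    closed; see the module docstring for the convention flag.
    """
    if vt < 1:
        raise ValueError("total veil count must be at least 1")
    if not 0 <= vf <= vt:
        raise ValueError(f"open veil count {vf} outside [0, {vt}]")
    return 100.0 * (vt - vf) / vt


def veil_opened_fraction(vt: int, vf: int) -> float:
    """Complementary metric: percentage of veils that have opened."""
    return 100.0 - veil_opening(vt, vf)


@dataclass
class QualityRecord:
    """Quality observations for one sample group on one storage day."""

    day: int
    weight_initial: float
    weight_t: float
    firmness: float
    veils_total: int
    veils_open: int
    protein_pct: float = 0.0
    carb_pct: float = 0.0
    #: which convention the veil metric below follows
    veil_metric_convention: str = "closed_fraction"

    def __post_init__(self) -> None:
        if not 0 < self.weight_t <= self.weight_initial:
            raise ValueError(
                f"day {self.day}: weight must satisfy 0 < Wt <= W0 "
                f"(got W0={self.weight_initial}, Wt={self.weight_t})"
            )
        if not 1.0 <= self.firmness <= 9.0:
            raise ValueError(
                f"day {self.day}: firmness {self.firmness} outside the 1-9 scale"
            )
        if not 0 <= self.veils_open <= self.veils_total:
            raise ValueError(f"day {self.day}: invalid veil counts")
        for name in ("protein_pct", "carb_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"day {self.day}: {name}={v} outside [0, 100]")

    @property
    def weight_loss_pct(self) -> float:
        return weight_loss(self.weight_initial, self.weight_t)

    @property
    def veil_metric_pct(self) -> float:
        return veil_opening(self.veils_total, self.veils_open)

    @property
    def veil_opened_pct(self) -> float:
        return veil_opened_fraction(self.veils_total, self.veils_open)


def acceptability(record: QualityRecord) -> dict:
    """Apply the consumer-acceptability rules to one record.

    Returns flags ``weight_ok`` (loss <= 5 %), ``firmness_ok``
    (score >= 3.0), ``veil_ok`` (veil metric < 70 %) and their
    conjunction ``overall``.
    """
    weight_ok = record.weight_loss_pct <= WEIGHT_LOSS_LIMIT_PCT
    firmness_ok = record.firmness >= FIRMNESS_FLOOR
    veil_ok = record.veil_metric_pct < VEIL_OPENING_LIMIT_PCT
    return {
        "weight_ok": weight_ok,
        "firmness_ok": firmness_ok,
        "veil_ok": veil_ok,
        "overall": weight_ok and firmness_ok and veil_ok,
    }
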