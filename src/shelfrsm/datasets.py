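"""Bundled example dataset: a packaging x substrate shelf-life experiment.

The package ships the measured tables of a published storage experiment
on fresh *Pleurotus ostreatus* (oyster mushroom):

* six 13-run designed-experiment tables -- shelf-life in days for
  mushrooms grown on wheat straw blended with olive pruning residue
  (OLPR), spent coffee grounds (SCG), or both (OLPR_SCG), stored at
  ambient temperature (~20 C) or at 4 C under three packaging
  conditions;
* two total-microbial-count tables -- log10 CFU/g trajectories for 27
  packaging x substrate groups per storage temperature.

See ``data/NOTES.md`` for transcription notes.  File checksums are
pinned in the test suite; edits to a transcribed table fail the suite
until the notes are updated.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .design import DesignMatrix, shelf_life_design
from .tmc import TMCSeries, series_from_frame

__all__ = [
    "load_shelf_life",
    "load_tmc",
    "load_tmc_frame",
    "fixture_checksums",
    "TEMPERATURES",
]

TEMPERATURES = ("ambient", "cold_4C")


def _data_path(name: str):
    return resources.files("shelfrsm.data").joinpath(name)


def load_shelf_life(
    residue_scheme: str = "OLPR",
    temperature: str = "ambient",
    rate_coding: str = "level",
) -> DesignMatrix:
    """Load one measured 13-run shelf-life design.

    Parameters
    ----------
    residue_scheme
        ``"OLPR"``, ``"SCG"`` or ``"OLPR_SCG"``.
    temperature
        ``"ambient"`` or ``"cold_4C"``.
    rate_coding
        Coding scheme for the residue-rate factor.
    """
    if temperature not in TEMPERATURES:
        raise ValueError(f"unknown temperature {temperature!r}")
    name = f"shelf_life_{temperature}_{residue_scheme}.csv"
    frame = pd.read_csv(_data_path(name))
    layout = shelf_life_design(residue_scheme, rate_coding=rate_coding)
    frame = frame.sort_values("run_id")
    return layout.with_responses(frame["response_days"].to_numpy())


def load_tmc_frame(temperature: str = "ambient") -> pd.DataFrame:
    """Long-format TMC table: packaging, substrate_code, temperature, day, log_cfu_g."""
    if temperature not in TEMPERATURES:
        raise ValueError(f"unknown temperature {temperature!r}")
    return pd.read_csv(_data_path(f"tmc_{temperature}.csv"))


def load_tmc(temperature: str = "ambient") -> list[TMCSeries]:
    """TMC trajectories as typed series (27 per temperature)."""
    return series_from_frame(load_tmc_frame(temperature))


def fixture_checksums() -> dict[str, str]:
    """SHA-256 of every bundled CSV, keyed by file name."""
    out = {}
    for entry in sorted(
        resources.files("shelfrsm.data").iterdir(), key=lambda e: e.name
    ):
        if entry.name.endswith(".csv"):
            out[entry.name] = hashlib.sha256(entry.read_bytes()).hexdigest()
    return out
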