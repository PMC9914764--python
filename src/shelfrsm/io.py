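"""CSV/JSON readers and writers, the pipeline driver, and contrasts.

CSV is the tabular interchange format (UTF-8, comma separator, dot
decimal); models and reports round-trip through JSON.  The pipeline
driver runs fit -> ANOVA -> optimization -> TMC summary for one
response selection and writes a self-describing bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anova import AnovaReport, anova_table
from .datasets import fixture_checksums, load_shelf_life, load_tmc
from .design import (
    DesignMatrix,
    DesignRun,
    PACKAGING_LEVELS,
    shelf_life_design,
)
from .model import QuadraticModel, fit_quadratic
from .optimize import GoalSpec, optimize_response
from .tmc import ContaminationLevel, level_summary

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "read_design_csv",
    "write_design_csv",
    "run_full_pipeline",
    "shelf_life_gain",
]

DESIGN_COLUMNS = ("run_id", "packaging", "rate", "response_days")


class SchemaError(ValueError):
    """An input file does not match its expected schema."""


def read_design_csv(path, rate_coding: str = "level") -> DesignMatrix:
    """Read a design table (run_id, packaging, rate, response_days).

    Malformed rows are reported with their line numbers; the factor
    specs are inferred from the three distinct rate levels present.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = set(DESIGN_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    problems = []
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        if row["packaging"] not in PACKAGING_LEVELS:
            problems.append(
                f"line {line}: unknown packaging {row['packaging']!r}"
            )
        if not np.isfinite(pd.to_numeric(row["response_days"], errors="coerce")):
            problems.append(f"line {line}: non-numeric response")
        if not np.isfinite(pd.to_numeric(row["rate"], errors="coerce")):
            problems.append(f"line {line}: non-numeric rate")
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    rates = sorted(frame["rate"].astype(float).unique())
    if len(rates) != 3:
        raise SchemaError(
            f"{path}: expected 3 distinct rate levels, found {len(rates)}"
        )
    from .design import FactorSpec

    packaging = FactorSpec("packaging", "ordinal_categorical", PACKAGING_LEVELS)
    rate = FactorSpec("rate", "continuous", tuple(rates), coding=rate_coding)
    runs = [
        DesignRun(
            int(row["run_id"]),
            {"packaging": row["packaging"], "rate": float(row["rate"])},
            float(row["response_days"]),
        )
        for _, row in frame.iterrows()
    ]
    return DesignMatrix([packaging, rate], runs)


def write_design_csv(design: DesignMatrix, path) -> None:
    rows = [
        {
            "run_id": r.run_id,
            "packaging": r.settings["packaging"],
            "rate": r.settings["rate"],
            "response_days": r.response,
        }
        for r in design.runs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """One end-to-end analysis: which response, coding, goals, output."""

    residue_scheme: str = "OLPR"
    temperature: str = "ambient"
    design_csv: str | None = None  # bundled dataset when None
    rate_coding: str = "level"
    goal: str = "maximize"
    rate_bounds: tuple | None = None
    output_dir: str | None = None
    include_tmc: bool = True


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Fit, diagnose and optimize one response; optionally summarize TMC.

    Returns the report bundle as a dict; if ``config.output_dir`` is
    set, also writes model JSON, ANOVA CSV, optimization JSON and the
    TMC summary CSV there.  Deterministic given inputs.
    """
    if config.design_csv is not None:
        design = read_design_csv(config.design_csv, config.rate_coding)
    else:
        design = load_shelf_life(
            config.residue_scheme, config.temperature, config.rate_coding
        )
    try:
        fit = fit_quadratic(design)
        report = anova_table(design, fit)
        result = optimize_response(
            fit.model,
            GoalSpec(response_goal=config.goal, rate_bounds=config.rate_bounds),
        )
    except Exception as exc:
        raise RuntimeError(f"model stage failed: {exc}") from exc

    bundle = {
        "provenance": {
            "software": f"shelfrsm {__version__}",
            "residue_scheme": config.residue_scheme,
            "temperature": config.temperature,
            "rate_coding": config.rate_coding,
            "fixture_checksums": fixture_checksums(),
        },
        "model": fit.model.to_dict(),
        "anova": report.to_dict(),
        "optimization": {
            "packaging": result.packaging,
            "rate": result.rate,
            "predicted_days": result.predicted,
            "desirability": result.desirability,
            "trace": result.trace,
        },
    }
    if config.include_tmc:
        series = load_tmc(config.temperature)
        days = sorted({d for s in series for d in s.days})
        tmc_rows = []
        for day in days:
            summary = level_summary(series, day)
            row = {"day": day, "n": summary["n"]}
            row.update(
                {f"frac_{k.lower()}": v for k, v in summary["fractions"].items()}
            )
            row["tmc_min"], row["tmc_max"] = summary["range"]
            tmc_rows.append(row)
        bundle["tmc_summary"] = tmc_rows

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        fit.model.to_json(out / "model.json")
        report.to_csv(out / "anova.csv")
        with open(out / "optimization.json", "w") as fh:
            json.dump(bundle["optimization"], fh, indent=2)
        if config.include_tmc:
            pd.DataFrame(bundle["tmc_summary"]).to_csv(
                out / "tmc_summary.csv", index=False
            )
        with open(out / "bundle.json", "w") as fh:
            json.dump(bundle, fh, indent=2)
    return bundle


def shelf_life_gain(
    design: DesignMatrix,
    reference_settings: dict,
    comparison_settings: list[dict],
) -> list[float]:
    """Measured response differences: each comparison run minus the reference.

    The reference is the mean of all runs at ``reference_settings``;
    every comparison setting contributes one difference per matching
    run.  Missing settings raise with the offending settings named.
    """

    def runs_at(settings):
        found = [
            r
            for r in design.runs
            if all(r.settings[k] == v for k, v in settings.items())
        ]
        if not found:
            raise ValueError(f"no runs at settings {settings!r}")
        return found

    ref = float(np.mean([r.response for r in runs_at(reference_settings)]))
    gains = []
    for settings in comparison_settings:
        for r in runs_at(settings):
            gains.append(round(float(r.response) - ref, 10))
    return gains
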