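"""ANOVA diagnostics for the fitted response surface.

Produces the full diagnostic table for a quadratic fit on a replicated
design: per-term partial (Type III) F tests, the overall model test,
the lack-of-fit / pure-error decomposition of the residual, the R^2
family (ordinary, adjusted, predicted), PRESS and adequate precision.

Partial sums of squares answer "what does this term add on top of all
the others": SS_term = SS_residual(model without the term) -
SS_residual(full model).  Sequential (Type I) sums of squares are
available behind a flag for comparison; the two coincide only when the
term's column is orthogonal to the rest of the model.

Per-term rows for the linear and interaction terms depend on the coded
basis (notably on how categorical levels are assigned numeric codes);
the model, residual, lack-of-fit, pure-error, R^2 and PRESS rows do
not.  Reports therefore carry the coding in their metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix, replicate_groups
from .model import FitResult, model_matrix, term_names

__all__ = [
    "AnovaReport",
    "anova_table",
    "lack_of_fit",
    "press",
    "r2_family",
    "adequate_precision",
    "format_p",
]


def format_p(p: float) -> str:
    """Render a p-value to 4 decimals, with '<0.0001' below that."""
    if p < 0.0001:
        return "<0.0001"
    return f"{p:.4f}"


@dataclass
class AnovaRow:
    term: str
    sum_sq: float
    dof: int
    mean_sq: float | None = None
    F: float | None = None
    p: float | None = None


@dataclass
class AnovaReport:
    """Full diagnostic table plus summary statistics."""

    rows: list[AnovaRow]
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    adeq_precision: float
    coding: str
    flags: list[str] = field(default_factory=list)

    def row(self, term: str) -> AnovaRow:
        for r in self.rows:
            if r.term == term:
                return r
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": r.term,
                    "sum_sq": r.sum_sq,
                    "df": r.dof,
                    "mean_sq": r.mean_sq,
                    "F": r.F,
                    "p": format_p(r.p) if r.p is not None else "",
                }
                for r in self.rows
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "coding": self.coding,
            "rows": [
                {
                    "term": r.term,
                    "sum_sq": r.sum_sq,
                    "df": r.dof,
                    "mean_sq": r.mean_sq,
                    "F": r.F,
                    "p": r.p,
                }
                for r in self.rows
            ],
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "pred_r2": self.pred_r2,
            "press": self.press,
            "adeq_precision": self.adeq_precision,
            "flags": self.flags,
        }


def _ols_ss(A: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ beta
    return float(r @ r)


def lack_of_fit(design: DesignMatrix, fit: FitResult):
    """Split the residual SS into lack-of-fit and pure-error parts.

    Pure error is the within-group scatter of replicated runs and does
    not depend on the model; lack of fit is what remains of the
    residual.  Returns two dicts, ``(lof, pure)``, with keys
    ``sum_sq/dof/mean_sq`` plus ``F/p`` on the lack-of-fit side.
    """
    groups = replicate_groups(design)
    id_to_y = {r.run_id: r.response for r in design.runs}
    ss_pure = 0.0
    dof_pure = 0
    for g in groups:
        if len(g) < 2:
            continue
        ys = np.array([id_to_y[i] for i in g], dtype=float)
        ss_pure += float(((ys - ys.mean()) ** 2).sum())
        dof_pure += len(g) - 1
    if dof_pure == 0:
        raise ValueError(
            "no replicated runs: pure error has 0 df, lack of fit undefined"
        )
    ss_res = fit.residual_ss
    dof_res = fit.model.residual_dof
    ss_lof = max(ss_res - ss_pure, 0.0)
    dof_lof = dof_res - dof_pure
    ms_pure = ss_pure / dof_pure
    ms_lof = ss_lof / dof_lof if dof_lof > 0 else np.nan
    if ms_pure == 0.0:
        F = np.inf
        p = 0.0
    else:
        F = ms_lof / ms_pure
        p = float(stats.f.sf(F, dof_lof, dof_pure))
    lof = {"sum_sq": ss_lof, "dof": dof_lof, "mean_sq": ms_lof, "F": F, "p": p}
    pure = {"sum_sq": ss_pure, "dof": dof_pure, "mean_sq": ms_pure}
    return lof, pure


def press(design: DesignMatrix, fit: FitResult) -> float:
    """Prediction error sum of squares via the leverage shortcut.

    PRESS = sum_i (e_i / (1 - h_ii))^2 equals the sum of squared
    leave-one-out prediction errors for a linear least-squares fit.
    """
    h = fit.leverages
    if np.any(h >= 1.0 - 1e-12):
        worst = int(np.argmax(h)) + 1
        raise ValueError(
            f"leverage of run {worst} is 1: the point determines its own "
            "fit and cannot be cross-validated"
        )
    return float(np.sum((fit.residuals / (1.0 - h)) ** 2))


def r2_family(ss_res: float, ss_tot: float, dof_res: int, dof_tot: int,
              press_value: float) -> tuple[float, float, float]:
    """Ordinary, adjusted and predicted R^2."""
    if ss_tot <= 0.0:
        raise ValueError("total SS is zero: R^2 undefined for a constant response")
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (ss_res / dof_res) / (ss_tot / dof_tot)
    pred = 1.0 - press_value / ss_tot
    return r2, adj, pred


def adequate_precision(fit: FitResult) -> float:
    """Signal-to-noise ratio of the fitted surface over the design points.

    (max fitted - min fitted) / sqrt(p * MS_residual / n); values above
    about 4 indicate the model discriminates between settings.
    """
    n = len(fit.fitted)
    p = fit.model.n_terms
    ms_res = fit.residual_ss / fit.model.residual_dof
    rng = float(fit.fitted.max() - fit.fitted.min())
    if ms_res == 0.0:
        return np.inf
    return rng / np.sqrt(p * ms_res / n)


def anova_table(
    design: DesignMatrix, fit: FitResult, ss_type: str = "partial"
) -> AnovaReport:
    """Assemble the full diagnostic report for a fitted design.

    Parameters
    ----------
    ss_type
        ``"partial"`` (Type III, the default: each term tested against
        the full model containing all others) or ``"sequential"``
        (Type I, terms entered in model order).
    """
    if ss_type not in ("partial", "sequential"):
        raise ValueError(f"unknown ss_type {ss_type!r}")
    y = design.responses
    coded = design.coded_settings()
    A = model_matrix(coded)
    n, p = A.shape
    names = term_names(design.factors)

    ss_res = fit.residual_ss
    dof_res = fit.model.residual_dof
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_model = ss_tot - ss_res
    dof_model = p - 1
    ms_model = ss_model / dof_model
    flags = []
    if ss_res == 0.0 or dof_res == 0:
        ms_res = 0.0
        F_model = np.inf
        p_model = 0.0
        flags.append("zero residual mean square: F reported as infinite")
    else:
        ms_res = ss_res / dof_res
        F_model = ms_model / ms_res
        p_model = float(stats.f.sf(F_model, dof_model, dof_res))

    rows = [
        AnovaRow("Model", ss_model, dof_model, ms_model, F_model, p_model)
    ]
    # per-term single-df tests
    if ss_type == "partial":
        for j in range(1, p):
            Aj = np.delete(A, j, axis=1)
            ss_term = _ols_ss(Aj, y) - ss_res
            _add_term_row(rows, names[j], ss_term, ms_res, dof_res)
    else:
        prev = _ols_ss(A[:, :1], y)
        for j in range(1, p):
            cur = _ols_ss(A[:, : j + 1], y)
            _add_term_row(rows, names[j], prev - cur, ms_res, dof_res)
            prev = cur

    rows.append(AnovaRow("Residual", ss_res, dof_res, ms_res if dof_res else None))
    has_replicates = any(len(g) > 1 for g in replicate_groups(design))
    if has_replicates:
        lof, pure = lack_of_fit(design, fit)
        rows.append(
            AnovaRow("LackOfFit", lof["sum_sq"], lof["dof"], lof["mean_sq"],
                     lof["F"], lof["p"])
        )
        rows.append(AnovaRow("PureError", pure["sum_sq"], pure["dof"], pure["mean_sq"]))
    else:
        flags.append("no replicated runs: lack-of-fit rows omitted")
    rows.append(AnovaRow("Total", ss_tot, n - 1))

    press_value = press(design, fit)
    r2, adj, pred = r2_family(ss_res, ss_tot, dof_res, n - 1, press_value)
    coding = "; ".join(
        f"{f.name}: {f.coding} coding of {f.actual_levels}" for f in design.factors
    )
    return AnovaReport(
        rows=rows,
        r2=r2,
        adj_r2=adj,
        pred_r2=pred,
        press=press_value,
        adeq_precision=adequate_precision(fit),
        coding=coding,
        flags=flags,
    )


def _add_term_row(rows, name, ss_term, ms_res, dof_res):
    ss_term = max(ss_term, 0.0)
    if ms_res == 0.0:
        F = np.inf
        pv = 0.0
    else:
        F = ss_term / ms_res
        pv = float(stats.f.sf(F, 1, dof_res))
    rows.append(AnovaRow(name, ss_term, 1, ss_term, F, pv))
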