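"""Second-order response-surface model fitted by ordinary least squares.

For two factors the model is

    y = b0 + b1*x1 + b2*x2 + b12*x1*x2 + b11*x1^2 + b22*x2^2

in coded units, giving p = 6 coefficients.  The fit is solved through a
QR factorization of the model matrix; leverages are the squared row
norms of the thin-Q factor.

The span of {1, x1, x1^2} over a three-level factor contains every
function of that factor, so fitted values, residuals and leverages are
invariant to how the three packaging levels are assigned to -1/0/+1 --
with the single exception of the interaction column x1*x2, which does
change with the assignment.  This package codes packaging levels in
lexicographic label order (NONE, PBP, VBP -> -1, 0, +1), the ordering
convention that standard design-of-experiments software applies to
categoric factors, so model summaries computed here line up with output
from such software.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix, FactorSpec, code_value

__all__ = [
    "QuadraticModel",
    "FitResult",
    "SingularDesignError",
    "ExtrapolationWarning",
    "fit_quadratic",
    "coefficients_report",
    "model_matrix",
]


class SingularDesignError(np.linalg.LinAlgError):
    """The model columns are collinear; names the offending columns."""


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the fitted factor range."""


def term_names(factors: list[FactorSpec]) -> list[str]:
    """Model term names in fit order: intercept, linear, interactions, quadratics."""
    k = len(factors)
    names = ["intercept"] + [f.name for f in factors]
    for i in range(k):
        for j in range(i + 1, k):
            names.append(f"{factors[i].name}:{factors[j].name}")
    names += [f"{f.name}^2" for f in factors]
    return names


def model_matrix(coded: np.ndarray) -> np.ndarray:
    """Quadratic model matrix from (n, k) coded settings."""
    coded = np.asarray(coded, dtype=float)
    n, k = coded.shape
    cols = [np.ones(n)]
    cols.extend(coded[:, i] for i in range(k))
    for i in range(k):
        for j in range(i + 1, k):
            cols.append(coded[:, i] * coded[:, j])
    cols.extend(coded[:, i] ** 2 for i in range(k))
    return np.column_stack(cols)


@dataclass
class QuadraticModel:
    """Fitted second-order polynomial with its coding metadata.

    Coefficients are stored on the coded scale.  ``predict`` accepts
    settings in actual units and codes them through the factor specs
    captured at fit time.
    """

    beta0: float
    beta_linear: dict
    beta_quadratic: dict
    beta_interaction: dict
    factors: list[FactorSpec]
    residual_dof: int
    response_name: str = "shelf_life_days"

    @property
    def n_terms(self) -> int:
        k = len(self.factors)
        return 1 + 2 * k + k * (k - 1) // 2

    def coefficient_vector(self) -> np.ndarray:
        k = len(self.factors)
        beta = [self.beta0]
        beta += [self.beta_linear[f.name] for f in self.factors]
        for i in range(k):
            for j in range(i + 1, k):
                key = (self.factors[i].name, self.factors[j].name)
                beta.append(self.beta_interaction[key])
        beta += [self.beta_quadratic[f.name] for f in self.factors]
        return np.asarray(beta)

    def predict_coded(self, coded: np.ndarray) -> np.ndarray:
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        return model_matrix(coded) @ self.coefficient_vector()

    def predict(self, settings: dict) -> float:
        """Evaluate the surface at actual-unit factor settings.

        Continuous settings between the fitted levels are mapped onto
        the coded axis by the factor's coding transform; values outside
        the fitted range raise :class:`ExtrapolationWarning` and are
        evaluated anyway.  Categorical settings must be fitted levels.
        """
        coded = []
        for f in self.factors:
            v = settings[f.name]
            if not f.is_categorical:
                levels = f.numeric_levels
                if not (levels.min() <= float(v) <= levels.max()):
                    warnings.warn(
                        f"{f.name}={v} outside fitted range "
                        f"[{levels.min()}, {levels.max()}]",
                        ExtrapolationWarning,
                        stacklevel=2,
                    )
                    # extend the end segment of the coding map linearly
                    lv, cv = levels, np.array([-1.0, 0.0, 1.0])
                    if float(v) < lv[0]:
                        slope = (cv[1] - cv[0]) / (lv[1] - lv[0])
                        coded.append(cv[0] + (float(v) - lv[0]) * slope)
                    else:
                        slope = (cv[2] - cv[1]) / (lv[2] - lv[1])
                        coded.append(cv[2] + (float(v) - lv[2]) * slope)
                    continue
            coded.append(code_value(v, f))
        return float(self.predict_coded(np.asarray(coded)[None, :])[0])

    # -- JSON round trip ------------------------------------------------
    def to_dict(self) -> dict:
        k = len(self.factors)
        short = {1: "b1", 2: "b2"}
        coeffs = {"b0": self.beta0}
        for i, f in enumerate(self.factors, start=1):
            coeffs[f"b{i}"] = self.beta_linear[f.name]
        for i in range(k):
            for j in range(i + 1, k):
                key = (self.factors[i].name, self.factors[j].name)
                coeffs[f"b{i + 1}{j + 1}"] = self.beta_interaction[key]
        for i, f in enumerate(self.factors, start=1):
            coeffs[f"b{i}{i}"] = self.beta_quadratic[f.name]
        return {
            "response": self.response_name,
            "coding": [
                {
                    "name": f.name,
                    "kind": f.kind,
                    "actual_levels": list(f.actual_levels),
                    "coding": f.coding,
                }
                for f in self.factors
            ],
            "coefficients": coeffs,
            "residual_dof": self.residual_dof,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticModel":
        factors = [
            FactorSpec(
                f["name"], f["kind"], tuple(f["actual_levels"]), f["coding"]
            )
            for f in d["coding"]
        ]
        k = len(factors)
        c = d["coefficients"]
        lin = {f.name: c[f"b{i}"] for i, f in enumerate(factors, start=1)}
        quad = {f.name: c[f"b{i}{i}"] for i, f in enumerate(factors, start=1)}
        inter = {}
        for i in range(k):
            for j in range(i + 1, k):
                inter[(factors[i].name, factors[j].name)] = c[f"b{i + 1}{j + 1}"]
        return cls(
            beta0=c["b0"],
            beta_linear=lin,
            beta_quadratic=quad,
            beta_interaction=inter,
            factors=factors,
            residual_dof=d["residual_dof"],
            response_name=d["response"],
        )

    @classmethod
    def from_json(cls, path) -> "QuadraticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FitResult:
    """A fitted model plus per-run diagnostics."""

    model: QuadraticModel
    design: DesignMatrix
    fitted: np.ndarray
    residuals: np.ndarray
    leverages: np.ndarray

    @property
    def residual_ss(self) -> float:
        return float(self.residuals @ self.residuals)


def fit_quadratic(design: DesignMatrix) -> FitResult:
    """Fit the full quadratic surface to a measured design by OLS.

    Raises
    ------
    SingularDesignError
        If the six model columns are rank deficient; the error message
        names the collinear columns.
    ValueError
        If fewer runs than ``p + 1`` carry responses.
    """
    y = design.responses
    coded = design.coded_settings()
    A = model_matrix(coded)
    n, p = A.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} measured runs, have {n}")
    names = term_names(design.factors)
    Q, R = np.linalg.qr(A)
    diag = np.abs(np.diag(R))
    tol = max(A.shape) * np.finfo(float).eps * diag.max()
    bad = [names[i] for i in np.nonzero(diag < tol)[0]]
    if bad:
        raise SingularDesignError(
            f"design matrix is singular; collinear columns: {bad}"
        )
    beta = np.linalg.solve(R, Q.T @ y)
    fitted = A @ beta
    leverages = np.sum(Q**2, axis=1)

    k = len(design.factors)
    lin = {f.name: float(beta[1 + i]) for i, f in enumerate(design.factors)}
    inter = {}
    idx = 1 + k
    for i in range(k):
        for j in range(i + 1, k):
            inter[(design.factors[i].name, design.factors[j].name)] = float(
                beta[idx]
            )
            idx += 1
    quad = {
        f.name: float(beta[idx + i]) for i, f in enumerate(design.factors)
    }
    model = QuadraticModel(
        beta0=float(beta[0]),
        beta_linear=lin,
        beta_quadratic=quad,
        beta_interaction=inter,
        factors=list(design.factors),
        residual_dof=n - p,
        response_name=design.response_name,
    )
    return FitResult(model, design, fitted, y - fitted, leverages)


def coefficients_report(model: QuadraticModel) -> pd.DataFrame:
    """Ordered coefficient table on the coded basis.

    The ``basis`` column records each factor's coding so the convention
    the coefficients refer to travels with the table.
    """
    rows = [("intercept", model.beta0, "1")]
    for f in model.factors:
        basis = f"{f.coding} coding of {f.actual_levels}"
        rows.append((f.name, model.beta_linear[f.name], basis))
    for (a, b), v in model.beta_interaction.items():
        rows.append((f"{a}:{b}", v, "product of coded axes"))
    for f in model.factors:
        rows.append((f"{f.name}^2", model.beta_quadratic[f.name], "coded axis squared"))
    return pd.DataFrame(rows, columns=["term", "coefficient", "coded_basis"])
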