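"""Multi-linear QSAR models, activity-unit conversion and the frozen
published arginase-I equation.

pIC50 is the negative decadic logarithm of IC50 in molar units, so for
IC50 given in nanomolar: pIC50 = 9 - log10(IC50/nM).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr as scipy_qr

from .descriptors import DescriptorMatrix


def pic50_from_ic50(ic50_nM: float | np.ndarray) -> float | np.ndarray:
    """Convert IC50 in nM to pIC50 (molar scale)."""
    arr = np.asarray(ic50_nM, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("IC50 must be positive")
    out = 9.0 - np.log10(arr)
    return float(out) if np.isscalar(ic50_nM) else out


def ic50_from_pic50(pic50: float | np.ndarray) -> float | np.ndarray:
    """Inverse conversion: pIC50 back to IC50 in nM."""
    arr = np.asarray(pic50, dtype=float)
    out = 10.0 ** (9.0 - arr)
    return float(out) if np.isscalar(pic50) else out


def read_activity_csv(path: str | Path, unit: str = "nM") -> pd.Series:
    """Read a compound-id/activity table; accepts a ``pIC50`` column or
    an ``IC50`` column in the configured unit (default nM)."""
    df = pd.read_csv(path)
    id_col = df.columns[0]
    df = df.set_index(id_col)
    cols = {c.lower(): c for c in df.columns}
    if "pic50" in cols:
        return df[cols["pic50"]].astype(float)
    for key in ("ic50_nm", "ic50"):
        if key in cols:
            vals = df[cols[key]].astype(float)
            if unit == "nM":
                return pd.Series(pic50_from_ic50(vals.to_numpy()), index=df.index)
            if unit == "M":
                return -np.log10(vals)
            raise ValueError(f"unknown unit {unit!r}")
    raise ValueError("activity table needs a pIC50 or IC50 column")


@dataclass
class LinearModel:
    """An ordinary multi-linear model: pIC50 = intercept + beta . x."""

    descriptor_names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    coef_uncertainties: np.ndarray | None = None
    intercept_uncertainty: float | None = None
    n_train: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.descriptor_names = tuple(self.descriptor_names)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.descriptor_names),):
            raise ValueError("one coefficient per descriptor name required")
        if not np.all(np.isfinite(self.coefficients)) or not math.isfinite(
            self.intercept
        ):
            raise ValueError("model coefficients must be finite")
        if self.coef_uncertainties is not None:
            self.coef_uncertainties = np.asarray(self.coef_uncertainties, dtype=float)

    @property
    def p(self) -> int:
        return len(self.descriptor_names)

    def predict(self, x) -> np.ndarray | float:
        """Predict pIC50 for a descriptor vector, matrix or DataFrame.

        Named inputs (DataFrame / Series / dict / DescriptorMatrix) are
        aligned by descriptor name; a missing descriptor is an error.
        """
        scalar = False
        if isinstance(x, DescriptorMatrix):
            x = x.data
        if isinstance(x, pd.DataFrame):
            missing = [n for n in self.descriptor_names if n not in x.columns]
            if missing:
                raise KeyError(f"missing descriptors: {missing}")
            arr = x[list(self.descriptor_names)].to_numpy(dtype=float)
        elif isinstance(x, (pd.Series, Mapping)):
            missing = [n for n in self.descriptor_names if n not in x]
            if missing:
                raise KeyError(f"missing descriptors: {missing}")
            arr = np.array([float(x[n]) for n in self.descriptor_names])[None, :]
            scalar = True
        else:
            arr = np.asarray(x, dtype=float)
            if arr.ndim == 1:
                arr = arr[None, :]
                scalar = True
            if arr.shape[1] != self.p:
                raise ValueError(
                    f"expected {self.p} descriptors, got {arr.shape[1]}"
                )
        out = self.intercept + arr @ self.coefficients
        return float(out[0]) if scalar else out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "descriptor_names": list(self.descriptor_names),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "coef_uncertainties": (
                None
                if self.coef_uncertainties is None
                else self.coef_uncertainties.tolist()
            ),
            "intercept_uncertainty": self.intercept_uncertainty,
            "n_train": self.n_train,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LinearModel":
        text = (
            Path(source).read_text()
            if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists())
            else str(source)
        )
        d = json.loads(text)
        return cls(
            descriptor_names=tuple(d["descriptor_names"]),
            coefficients=np.array(d["coefficients"]),
            intercept=d["intercept"],
            coef_uncertainties=(
                None
                if d.get("coef_uncertainties") is None
                else np.array(d["coef_uncertainties"])
            ),
            intercept_uncertainty=d.get("intercept_uncertainty"),
            n_train=d.get("n_train"),
            provenance=d.get("provenance", ""),
        )


#: The published six-descriptor arginase-I inhibition equation.
PUBLISHED_ARGINASE_MODEL = LinearModel(
    descriptor_names=(
        "rsa",
        "com_lipohyd_3A",
        "fringNdon3B",
        "fsp2OC9B",
        "fHringC2B",
        "fringCC3B",
    ),
    coefficients=np.array([19.791, 0.344, 0.905, 0.402, -0.375, -0.567]),
    intercept=-7.008,
    coef_uncertainties=np.array([3.496, 0.067, 0.125, 0.16, 0.069, 0.205]),
    intercept_uncertainty=2.115,
    n_train=119,
    provenance="published arginase-I GA-MLR equation",
)


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def fit_ols(
    X: DescriptorMatrix | pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray | None = None,
    *,
    compute_se: bool = False,
) -> LinearModel:
    """Ordinary least squares with intercept.

    ``X`` may be a DescriptorMatrix carrying its own activity, a
    DataFrame, or a bare array (then names are x1..xp).  Rank-deficient
    designs raise, naming the columns involved in the collinearity.
    """
    if isinstance(X, DescriptorMatrix):
        if y is None:
            if X.activity is None:
                raise ValueError("no activity available to fit against")
            y = X.activity
        names = tuple(X.descriptor_names)
        arr = X.values
    elif isinstance(X, pd.DataFrame):
        names = tuple(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = tuple(f"x{i+1}" for i in range(arr.shape[1]))
    if y is None:
        raise ValueError("y required")
    yv = np.asarray(y, dtype=float)
    n, p = arr.shape
    if n <= p + 1:
        raise ValueError(f"need more rows ({n}) than descriptors + 1 ({p + 1})")
    D = _design(arr)
    if np.linalg.matrix_rank(D) < p + 1:
        raise ValueError(
            "rank-deficient design; collinear columns: "
            f"{_collinear_columns(arr, names)}"
        )
    beta, *_ = np.linalg.lstsq(D, yv, rcond=None)
    model = LinearModel(
        descriptor_names=names,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        n_train=n,
    )
    if compute_se:
        resid = yv - D @ beta
        s2 = float(resid @ resid) / (n - p - 1)
        cov = s2 * np.linalg.inv(D.T @ D)
        se = np.sqrt(np.diag(cov))
        model.intercept_uncertainty = float(se[0])
        model.coef_uncertainties = se[1:]
    return model


def _collinear_columns(arr: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns past the numerical rank in a pivoted QR of the design."""
    D = _design(arr)
    _, r, piv = scipy_qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(D.shape) * np.finfo(float).eps
    rank = int(np.count_nonzero(diag > tol))
    dependent = [piv[k] for k in range(rank, D.shape[1])]
    labels = ["<intercept>"] + list(names)
    return sorted(labels[k] for k in dependent)


def predict(model: LinearModel, x) -> np.ndarray | float:
    """Functional alias for :meth:`LinearModel.predict`."""
    return model.predict(x)
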