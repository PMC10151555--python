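"""Model validation battery and leverage-based applicability domain.

Covers the statistics conventionally reported for GA-MLR QSAR models:
training fit (R², adjusted R², RMSE, MAE, CCC, s, F, Friedman LOF),
leave-one-out and leave-many-out cross-validation, Y-scrambling,
external-set predictivity (Q²F1/F2/F3, CCC, the Golbraikh-Tropsha
through-origin diagnostics and Roy's r²m family), and Williams-plot
quantities (hat leverage, standardized residuals, the h* = 3(p+1)/n
warning threshold).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .ga import quik_filter
from .model import LinearModel, fit_ols


# ---------------------------------------------------------------------------
# Report containers


@dataclass
class SplitAssignment:
    training_ids: list[str]
    prediction_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        if set(self.training_ids) & set(self.prediction_ids):
            raise ValueError("training and prediction sets overlap")


@dataclass
class InternalValidationReport:
    n: int
    p: int
    r2: float
    r2_adj: float
    lof: float
    rmse_tr: float
    mae_tr: float
    rss_tr: float
    ccc_tr: float
    s: float
    f_stat: float
    q2_loo: float
    rmse_cv: float
    mae_cv: float
    press_cv: float
    ccc_cv: float
    q2_lmo: float | None
    kxx: float
    delta_k: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExternalValidationReport:
    n_ext: int
    rmse_ext: float
    mae_ext: float
    press_ext: float
    r2_ext: float
    q2_f1: float
    q2_f2: float
    q2_f3: float
    ccc_ext: float
    r2m_average: float
    r2m_delta: float
    k: float
    k_prime: float
    r2o: float
    r2o_prime: float
    regression_angle_deg: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class YScramblingReport:
    iterations: int
    r2_mean: float
    q2_mean: float
    rmse_mean: float
    r2_values: np.ndarray
    q2_values: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "r2_mean": self.r2_mean,
            "q2_mean": self.q2_mean,
            "rmse_mean": self.rmse_mean,
            "seed": self.seed,
        }


@dataclass
class LeverageReport:
    ids: list[str]
    leverages: np.ndarray
    h_star: float
    std_residuals: np.ndarray | None
    in_domain: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"leverage": self.leverages}, index=self.ids)
        if self.std_residuals is not None:
            df["std_residual"] = self.std_residuals
        df["in_domain"] = self.in_domain
        df["h_star"] = self.h_star
        return df


# ---------------------------------------------------------------------------
# Helpers


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    mx, my = xv.mean(), yv.mean()
    sx2 = float(np.mean((xv - mx) ** 2))
    sy2 = float(np.mean((yv - my) ** 2))
    sxy = float(np.mean((xv - mx) * (yv - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        return 1.0
    return 2.0 * sxy / denom


def _xy(model: LinearModel, X, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(X, DescriptorMatrix):
        arr = X.subset(model.descriptor_names).values
    elif isinstance(X, pd.DataFrame):
        arr = X[list(model.descriptor_names)].to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    yhat = np.asarray(model.predict(arr), dtype=float)
    return arr, yv, yhat


def _hat_diag_and_resid(arr: np.ndarray, yv: np.ndarray):
    D = np.column_stack([np.ones(len(arr)), arr])
    q, _ = np.linalg.qr(D)
    h = np.einsum("ij,ij->i", q, q)
    yhat = q @ (q.T @ yv)
    return h, yv - yhat


# ---------------------------------------------------------------------------
# Operations


def random_split(
    ids: Sequence[str], fraction: float = 0.8, seed: int = 0
) -> SplitAssignment:
    """Random train/prediction split; train size = round(n * fraction)."""
    ids = list(ids)
    if len(ids) < 5:
        raise ValueError("need at least 5 compounds to split")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(len(ids) * fraction))
    train = sorted(ids[i] for i in order[:n_train])
    pred = sorted(ids[i] for i in order[n_train:])
    if not pred:
        warnings.warn("fraction leaves an empty prediction set", stacklevel=2)
    return SplitAssignment(training_ids=train, prediction_ids=pred, seed=seed)


def internal_stats(
    model: LinearModel,
    X_train,
    y_train,
    *,
    lof_d: float = 0.5,
    lmo_fraction: float = 0.3,
    lmo_repeats: int = 1000,
    lmo_seed: int = 0,
    compute_lmo: bool = True,
) -> InternalValidationReport:
    """Training-set and cross-validated statistics for a fitted model."""
    arr, yv, yhat = _xy(model, X_train, y_train)
    n, p = arr.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    resid = yv - yhat
    rss = float(resid @ resid)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - rss / tss
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    rmse = float(np.sqrt(rss / n))
    mae = float(np.mean(np.abs(resid)))
    s = float(np.sqrt(rss / (n - p - 1)))
    f_stat = (r2 / p) / ((1.0 - r2) / (n - p - 1)) if r2 < 1 else np.inf
    # Friedman lack-of-fit with smoothing parameter d
    lof = (rss / n) / (1.0 - (p + 1 + lof_d * p) / n) ** 2
    h, fit_resid = _hat_diag_and_resid(arr, yv)
    press_resid = fit_resid / (1.0 - h)
    press = float(press_resid @ press_resid)
    q2_loo = 1.0 - press / tss
    y_loo = yv - press_resid
    quik = quik_filter(arr, yv)
    q2_lmo = (
        lmo_cv(
            arr,
            yv,
            leave_fraction=lmo_fraction,
            repeats=lmo_repeats,
            seed=lmo_seed,
        )
        if compute_lmo
        else None
    )
    return InternalValidationReport(
        n=n,
        p=p,
        r2=r2,
        r2_adj=r2_adj,
        lof=float(lof),
        rmse_tr=rmse,
        mae_tr=mae,
        rss_tr=rss,
        ccc_tr=lin_ccc(yv, yhat),
        s=s,
        f_stat=float(f_stat),
        q2_loo=float(q2_loo),
        rmse_cv=float(np.sqrt(press / n)),
        mae_cv=float(np.mean(np.abs(press_resid))),
        press_cv=press,
        ccc_cv=lin_ccc(yv, y_loo),
        q2_lmo=q2_lmo,
        kxx=quik.kxx,
        delta_k=quik.delta,
    )


def lmo_cv(
    X,
    y,
    subset_names: Sequence[str] | None = None,
    leave_fraction: float = 0.3,
    repeats: int = 1000,
    seed: int = 0,
) -> float:
    """Leave-many-out Q²: mean over random left-out groups of
    1 - PRESS/TSS, with TSS taken about the training-fold mean."""
    if not 0 < leave_fraction <= 0.5:
        raise ValueError("leave_fraction must lie in (0, 0.5]")
    if isinstance(X, DescriptorMatrix):
        X = X.data
    if isinstance(X, pd.DataFrame):
        if subset_names is not None:
            X = X[list(subset_names)]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = arr.shape
    n_out = max(1, int(round(n * leave_fraction)))
    if n - n_out <= p + 1:
        raise ValueError("left-in group too small to fit the model")
    rng = np.random.default_rng(seed)
    q2s = np.empty(repeats)
    for rep in range(repeats):
        out = rng.choice(n, size=n_out, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[out] = False
        D_in = np.column_stack([np.ones(mask.sum()), arr[mask]])
        beta, *_ = np.linalg.lstsq(D_in, yv[mask], rcond=None)
        pred = np.column_stack([np.ones(n_out), arr[out]]) @ beta
        press = float(np.sum((yv[out] - pred) ** 2))
        tss = float(np.sum((yv[out] - yv[mask].mean()) ** 2))
        q2s[rep] = 1.0 - press / tss if tss > 0 else np.nan
    return float(np.nanmean(q2s))


def y_scramble(
    X,
    y,
    subset_names: Sequence[str] | None = None,
    iterations: int = 2000,
    seed: int = 0,
    *,
    permute: bool = True,
) -> YScramblingReport:
    """Y-randomization: refit against permuted activities.

    The design is fixed across iterations, so fitted values and LOO
    residuals come from one precomputed orthogonal basis; each
    iteration records training R², Q²LOO and RMSE of the scrambled
    model.  ``permute=False`` is a degenerate mode (identity
    permutation) used to verify the bookkeeping.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if isinstance(X, DescriptorMatrix):
        X = X.data
    if isinstance(X, pd.DataFrame):
        if subset_names is not None:
            X = X[list(subset_names)]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    rng = np.random.default_rng(seed)
    perms = np.empty((iterations, n), dtype=int)
    for i in range(iterations):
        perms[i] = rng.permutation(n) if permute else np.arange(n)
    Y = yv[perms.T]  # n x iterations
    D = np.column_stack([np.ones(n), arr])
    q, _ = np.linalg.qr(D)
    h = np.einsum("ij,ij->i", q, q)
    fitted = q @ (q.T @ Y)
    resid = Y - fitted
    rss = np.sum(resid**2, axis=0)
    tss = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    r2 = 1.0 - rss / tss
    press = np.sum((resid / (1.0 - h)[:, None]) ** 2, axis=0)
    q2 = 1.0 - press / tss
    rmse = np.sqrt(rss / n)
    return YScramblingReport(
        iterations=iterations,
        r2_mean=float(r2.mean()),
        q2_mean=float(q2.mean()),
        rmse_mean=float(rmse.mean()),
        r2_values=r2,
        q2_values=q2,
        seed=seed,
    )


def external_stats(
    model: LinearModel, X_ext, y_ext, y_train
) -> ExternalValidationReport:
    """External-set predictivity statistics.

    ``y_train`` (the training activities) supplies the reference mean
    for Q²F1 and the per-observation training variance for Q²F3.
    """
    arr, yv, yhat = _xy(model, X_ext, y_ext)
    n_ext = len(yv)
    if n_ext < 3:
        raise ValueError("need at least 3 external compounds")
    ytr = np.asarray(y_train, dtype=float)
    resid = yv - yhat
    press = float(resid @ resid)
    rmse = float(np.sqrt(press / n_ext))
    mae = float(np.mean(np.abs(resid)))
    q2_f1 = 1.0 - press / float(np.sum((yv - ytr.mean()) ** 2))
    q2_f2 = 1.0 - press / float(np.sum((yv - yv.mean()) ** 2))
    tss_train = float(np.sum((ytr - ytr.mean()) ** 2))
    q2_f3 = 1.0 - (press / n_ext) / (tss_train / len(ytr))
    # squared Pearson correlation between observed and predicted
    if np.std(yhat) == 0 or np.std(yv) == 0:
        r2_ext = 0.0
    else:
        r2_ext = float(np.corrcoef(yv, yhat)[0, 1] ** 2)

    # Golbraikh-Tropsha through-origin diagnostics, both orientations
    k = float(np.sum(yv * yhat) / np.sum(yhat**2))
    k_prime = float(np.sum(yv * yhat) / np.sum(yv**2))
    tss_obs = float(np.sum((yv - yv.mean()) ** 2))
    tss_pred = float(np.sum((yhat - yhat.mean()) ** 2))
    # degenerate (zero-variance) blocks: through-origin R² taken as 0
    r2o = (
        1.0 - float(np.sum((yv - k * yhat) ** 2)) / tss_obs if tss_obs > 0 else 0.0
    )
    r2o_prime = (
        1.0 - float(np.sum((yhat - k_prime * yv) ** 2)) / tss_pred
        if tss_pred > 0
        else 0.0
    )
    r2m = r2_ext * (1.0 - np.sqrt(max(r2_ext - r2o, 0.0)))
    r2m_prime = r2_ext * (1.0 - np.sqrt(max(r2_ext - r2o_prime, 0.0)))
    r2m_average = float((r2m + r2m_prime) / 2.0)
    r2m_delta = float(abs(r2m - r2m_prime))
    # OLS slope of predicted on experimental; angle relative to y = x
    slope = float(
        np.sum((yv - yv.mean()) * (yhat - yhat.mean())) / np.sum((yv - yv.mean()) ** 2)
    )
    angle = float(np.degrees(np.arctan(slope)) - 45.0)
    return ExternalValidationReport(
        n_ext=n_ext,
        rmse_ext=rmse,
        mae_ext=mae,
        press_ext=press,
        r2_ext=r2_ext,
        q2_f1=float(q2_f1),
        q2_f2=float(q2_f2),
        q2_f3=float(q2_f3),
        ccc_ext=lin_ccc(yv, yhat),
        r2m_average=r2m_average,
        r2m_delta=r2m_delta,
        k=k,
        k_prime=k_prime,
        r2o=float(r2o),
        r2o_prime=float(r2o_prime),
        regression_angle_deg=angle,
    )


def leverage_analysis(
    model: LinearModel,
    X_train,
    X_query=None,
    residuals=None,
    *,
    query_ids: Sequence[str] | None = None,
    std_resid_cutoff: float = 3.0,
) -> LeverageReport:
    """Hat leverages and applicability-domain flags.

    h_i = x_i (XᵀX)⁻¹ x_iᵀ with an intercept column; the warning
    threshold is h* = 3(p+1)/n_train.  When residuals for the query
    block are supplied, standardized residuals (residual / s, with s
    the training standard error) join the domain criterion
    |std residual| <= ``std_resid_cutoff``.
    """
    if isinstance(X_train, DescriptorMatrix):
        train_arr = X_train.subset(model.descriptor_names).values
        train_ids = X_train.compound_ids
    elif isinstance(X_train, pd.DataFrame):
        train_arr = X_train[list(model.descriptor_names)].to_numpy(dtype=float)
        train_ids = [str(i) for i in X_train.index]
    else:
        train_arr = np.asarray(X_train, dtype=float)
        train_ids = [str(i) for i in range(len(train_arr))]
    n_train, p = train_arr.shape
    D = np.column_stack([np.ones(n_train), train_arr])
    xtx = D.T @ D
    if np.linalg.matrix_rank(xtx) < p + 1:
        raise ValueError("singular XᵀX in leverage computation")
    xtx_inv = np.linalg.inv(xtx)

    if X_query is None:
        query_arr = train_arr
        ids = list(train_ids)
    else:
        if isinstance(X_query, DescriptorMatrix):
            query_arr = X_query.subset(model.descriptor_names).values
            ids = X_query.compound_ids
        elif isinstance(X_query, pd.DataFrame):
            query_arr = X_query[list(model.descriptor_names)].to_numpy(dtype=float)
            ids = [str(i) for i in X_query.index]
        else:
            query_arr = np.atleast_2d(np.asarray(X_query, dtype=float))
            ids = [str(i) for i in range(len(query_arr))]
    if query_ids is not None:
        ids = list(query_ids)
    Dq = np.column_stack([np.ones(len(query_arr)), query_arr])
    h = np.einsum("ij,jk,ik->i", Dq, xtx_inv, Dq)
    h_star = 3.0 * (p + 1) / n_train
    std_resid = None
    in_domain = h <= h_star
    if residuals is not None:
        res = np.asarray(residuals, dtype=float)
        s = float(np.sqrt(np.sum(res**2) / (len(res) - p - 1)))
        std_resid = res / s
        in_domain = in_domain & (np.abs(std_resid) <= std_resid_cutoff)
    return LeverageReport(
        ids=ids,
        leverages=h,
        h_star=float(h_star),
        std_residuals=std_resid,
        in_domain=in_domain,
    )


def warning_leverage(n_train: int, p: int) -> float:
    """The Williams-plot warning threshold h* = 3(p+1)/n."""
    return 3.0 * (p + 1) / n_train


def save_report(report, path: str | Path) -> None:
    """Serialize any validation report to JSON."""
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))
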