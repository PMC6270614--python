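"""Partial least squares regression and the 3D-QSAR statistics suite.

Single-response NIPALS PLS with leave-one-out cross-validation, component
selection by maximum q2, fit statistics (r2, SEE, F), external validation
(SD, PRESS, predictive r2) and per-field-block contribution fractions.

Scaling follows the CoMFA standard: each column is divided by the pooled
standard deviation of its whole block, so the steric and electrostatic
blocks enter the regression on a common energy scale. Plain mean-centering
is available as ``center_only``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PlsModel",
    "StatsReport",
    "ExternalValidation",
    "RankError",
    "pls_fit",
    "predict",
    "loo_cv",
    "select_ncomp",
    "fit_statistics",
    "model_stats",
    "external_validation",
    "block_contributions",
]


class RankError(ValueError):
    """Requested more latent components than the data can support."""


@dataclass
class PlsModel:
    """Fitted latent-variable regression.

    ``coefficients`` act on raw (uncentered, unscaled) descriptors:
    yhat = y_mean + (x - x_mean) . coefficients.
    """

    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray  # divisor per column (1.0 under center_only)
    y_mean: float
    coefficients: np.ndarray
    weights: np.ndarray  # p x N
    loadings: np.ndarray  # p x N
    y_loadings: np.ndarray  # N
    scores: np.ndarray  # n x N
    scaling: str = "center_only"
    columns: Optional[list] = None
    training_ids: Optional[list] = None


@dataclass
class StatsReport:
    """Everything a model summary table reports."""

    q2_profile: np.ndarray  # per component count 1..max
    sep_profile: np.ndarray
    press_cv_profile: np.ndarray
    n_components: int
    r2: float
    see: float
    f: float
    block_contributions: dict
    external: Optional["ExternalValidation"] = None


@dataclass
class ExternalValidation:
    sd: float
    press: float
    r2_pred: float
    predictions: np.ndarray
    residuals: np.ndarray  # experimental - predicted


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

def _column_scale(
    X: np.ndarray, scaling: str, blocks: Optional[Sequence] = None
) -> np.ndarray:
    if scaling == "center_only":
        return np.ones(X.shape[1])
    if scaling != "comfa_std":
        raise ValueError(f"unknown scaling {scaling!r}")
    scale = np.ones(X.shape[1])
    labels = np.asarray(blocks if blocks is not None else ["all"] * X.shape[1])
    for label in np.unique(labels):
        idx = labels == label
        pooled = np.sqrt(np.mean(X[:, idx].var(axis=0, ddof=0)))
        if pooled > 0:
            scale[idx] = pooled
    return scale


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    scaling: str = "center_only",
    blocks: Optional[Sequence] = None,
    columns: Optional[list] = None,
    training_ids: Optional[list] = None,
) -> PlsModel:
    """NIPALS PLS1.

    Per component: weight = normalised X'y, score = X weight, X/y loadings
    by least squares on the score, then deflation. The final coefficient
    vector is composed back to the original descriptor space.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    max_rank = min(n - 1, p)
    if n_components < 1 or n_components > max_rank:
        raise RankError(
            f"n_components={n_components} exceeds achievable maximum {max_rank}"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    scale = _column_scale(X, scaling, blocks)
    Xd = (X - x_mean) / scale
    yd = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros(n_components)
    T = np.zeros((n, n_components))
    actual = 0
    for k in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break  # residual response exhausted (e.g. constant y)
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p_load = Xd.T @ t / tt
        c = float(yd @ t) / tt
        Xd = Xd - np.outer(t, p_load)
        yd = yd - c * t
        W[:, k], P[:, k], C[k], T[:, k] = w, p_load, c, t
        actual += 1
    W, P, C, T = W[:, :actual], P[:, :actual], C[:actual], T[:, :actual]
    if actual == 0:
        beta_scaled = np.zeros(p)
    else:
        beta_scaled = W @ np.linalg.solve(P.T @ W, C)
    return PlsModel(
        n_components=n_components,
        x_mean=x_mean,
        x_scale=scale,
        y_mean=y_mean,
        coefficients=beta_scaled / scale,
        weights=W,
        loadings=P,
        y_loadings=C,
        scores=T,
        scaling=scaling,
        columns=list(columns) if columns is not None else None,
        training_ids=list(training_ids) if training_ids is not None else None,
    )


def predict(model: PlsModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    return model.y_mean + (X - model.x_mean) @ model.coefficients


# --------------------------------------------------------------------------
# Cross-validation and statistics
# --------------------------------------------------------------------------

def loo_cv(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 10,
    scaling: str = "center_only",
    blocks: Optional[Sequence] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-out cross-validation over component counts 1..max.

    For each left-out sample the model (including centering and scaling) is
    refit on the remaining n-1 rows. q2(N) = 1 - PRESS_cv(N) / SStot with
    SStot about the full-training-set mean; SEP(N) = sqrt(PRESS_cv(N) /
    (n - N - 1)), mirroring the SEE denominator.

    Returns (q2, sep, press_cv) arrays indexed by N-1.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if n < 3:
        raise ValueError("LOO needs at least 3 samples")
    limit = min(n - 2, X.shape[1])
    if max_components > limit:
        warnings.warn(
            f"max_components trimmed from {max_components} to {limit}", stacklevel=2
        )
        max_components = limit
    ss_tot = float(((y - y.mean()) ** 2).sum())
    press = np.zeros(max_components)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        x_mean = Xi.mean(axis=0)
        y_mean = yi.mean()
        scale = _column_scale(Xi, scaling, blocks)
        Xd = (Xi - x_mean) / scale
        yd = yi - y_mean
        x_new = (X[i] - x_mean) / scale
        # one NIPALS pass, accumulating the prediction per component count
        yhat = y_mean
        for k in range(max_components):
            w = Xd.T @ yd
            norm = np.linalg.norm(w)
            if norm < 1e-12:
                press[k:] += (y[i] - yhat) ** 2
                break
            w /= norm
            t = Xd @ w
            tt = float(t @ t)
            if tt < 1e-12:
                press[k:] += (y[i] - yhat) ** 2
                break
            p_load = Xd.T @ t / tt
            c = float(yd @ t) / tt
            t_new = float(x_new @ w)
            yhat = yhat + c * t_new
            x_new = x_new - t_new * p_load
            Xd = Xd - np.outer(t, p_load)
            yd = yd - c * t
            press[k] += (y[i] - yhat) ** 2
    N = np.arange(1, max_components + 1)
    q2 = 1.0 - press / ss_tot
    denom = n - N - 1
    sep = np.sqrt(np.where(denom > 0, press / np.maximum(denom, 1), np.nan))
    return q2, sep, press


def select_ncomp(q2_profile: Sequence[float]) -> int:
    """Optimal component count: smallest N attaining the maximum q2."""
    profile = np.asarray(list(q2_profile), float)
    if profile.size == 0:
        raise ValueError("empty q2 profile")
    return int(np.argmax(profile)) + 1


def fit_statistics(y: np.ndarray, y_pred: np.ndarray, n_components: int) -> tuple[float, float, float]:
    """Non-cross-validated statistics from observed/fitted pairs.

    r2 = 1 - SSres/SStot; SEE = sqrt(SSres / (n - N - 1));
    F = (r2/N) / ((1 - r2)/(n - N - 1)).
    """
    y = np.asarray(y, float)
    y_pred = np.asarray(y_pred, float)
    n = len(y)
    if n <= n_components + 1:
        raise ValueError("need n > N + 1")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ZeroDivisionError("SStot is zero: r2 undefined for constant response")
    ss_res = float(((y - y_pred) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    dof = n - n_components - 1
    see = float(np.sqrt(ss_res / dof))
    f = (r2 / n_components) / ((1.0 - r2) / dof) if r2 < 1.0 else float("inf")
    return r2, see, f


def model_stats(model: PlsModel, X: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(r2, SEE, F) of a fitted model on its training data."""
    return fit_statistics(y, predict(model, X), model.n_components)


def external_validation(
    y_test: np.ndarray, predictions_test: np.ndarray, y_train_mean: float
) -> ExternalValidation:
    """Test-set validation: SD, PRESS and predictive r2.

    SD = sum (y_test - mean of training activities)^2;
    PRESS = sum (y_test - predicted)^2; r2_pred = (SD - PRESS) / SD.
    """
    y_test = np.asarray(y_test, float)
    predictions_test = np.asarray(predictions_test, float)
    if y_test.size == 0:
        raise ValueError("need at least one test compound")
    sd = float(((y_test - y_train_mean) ** 2).sum())
    if sd == 0:
        raise ZeroDivisionError("SD is zero: r2_pred undefined")
    press = float(((y_test - predictions_test) ** 2).sum())
    return ExternalValidation(
        sd=sd,
        press=press,
        r2_pred=(sd - press) / sd,
        predictions=predictions_test,
        residuals=y_test - predictions_test,
    )


def block_contributions(
    model: PlsModel,
    X: np.ndarray,
    columns: Optional[Sequence[tuple[str, int]]] = None,
) -> dict[str, float]:
    """Fraction of |coefficient| x column-stdev mass per field block.

    fraction_b = sum_{j in b} |beta_j| s_j / sum_all |beta_j| s_j, with s_j
    the training-data column standard deviation (population).
    """
    cols = columns if columns is not None else model.columns
    if cols is None:
        raise ValueError("column metadata required")
    s = np.asarray(X, float).std(axis=0, ddof=0)
    mass = np.abs(model.coefficients) * s
    total = mass.sum()
    if total == 0:
        raise ZeroDivisionError("all coefficients are zero: contributions undefined")
    out: dict[str, float] = {}
    for (block, _idx), m in zip(cols, mass):
        out[block] = out.get(block, 0.0) + float(m)
    return {k: v / total for k, v in out.items()}
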