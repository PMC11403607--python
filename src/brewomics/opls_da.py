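"""Two-class OPLS-DA with cross-validated diagnostics and VIP marker selection.

Orthogonal projections to latent structures: variation in X uncorrelated with
the class response y is peeled off into orthogonal components (NIPALS-style),
then a single predictive PLS component is fitted on the filtered X. Model
quality is summarized by R2X / R2Y, cross-validated Q2, an F-test on the
cross-validated residuals (CV-ANOVA), and Hotelling's T2 in score space for
outlier flagging. Per-variable importance (VIP) on the predictive component
drives marker selection.

Class coding: y in {0, 1}; by convention the husked (T) line is 1, so a
positive predictive weight means the variable is elevated in T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold


@dataclass
class ScalingRecord:
    mean: np.ndarray
    scale: np.ndarray          # 1.0 for zero-variance columns
    zero_variance: np.ndarray  # boolean flags


def uv_scale(X: np.ndarray) -> tuple[np.ndarray, ScalingRecord]:
    """Column-wise unit-variance (autoscaling) pretreatment.

    Zero-variance columns are centered only and flagged.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    zero = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    scale = np.where(zero, 1.0, sd)
    Xs = (X - mean) / scale
    Xs[:, zero] = 0.0
    return Xs, ScalingRecord(mean, scale, zero)


def uv_unscale(Xs: np.ndarray, record: ScalingRecord) -> np.ndarray:
    return Xs * record.scale + record.mean


@dataclass
class OPLSModel:
    w: np.ndarray              # predictive weights, unit norm
    p: np.ndarray              # predictive loadings
    q: float                   # predictive y-loading
    t: np.ndarray              # predictive scores (training)
    w_ortho: np.ndarray        # n_ortho x p
    p_ortho: np.ndarray
    t_ortho: np.ndarray        # n x n_ortho
    scaling: ScalingRecord
    y_mean: float
    r2x: float
    r2y: float
    q2: float
    n_ortho: int
    cv_folds: int
    press: float
    ss_y: float
    y: np.ndarray
    y_pred_cv: np.ndarray
    feature_ids: list[str] | None = None

    @property
    def scores(self) -> np.ndarray:
        """Training scores: predictive first, then orthogonal components."""
        if self.n_ortho:
            return np.column_stack([self.t, self.t_ortho])
        return self.t[:, None]


def _fit_core(Xs: np.ndarray, yc: np.ndarray, n_ortho: int):
    """NIPALS OPLS on pre-scaled X and centered y (single response)."""
    w = Xs.T @ yc / (yc @ yc)
    w = w / np.linalg.norm(w)
    Xres = Xs.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_ortho):
        t = Xres @ w
        p = Xres.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break
        w_o = w_o / norm
        t_o = Xres @ w_o
        p_o = Xres.T @ t_o / (t_o @ t_o)
        Xres = Xres - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    t = Xres @ w
    p = Xres.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    return w, p, q, t, np.array(W_o), np.array(P_o), (
        np.column_stack(T_o) if T_o else np.empty((Xs.shape[0], 0))
    )


def _predict_scaled(Xs, w, q, W_o, P_o):
    Xres = Xs.copy()
    for w_o, p_o in zip(W_o, P_o):
        t_o = Xres @ w_o
        Xres = Xres - np.outer(t_o, p_o)
    return (Xres @ w) * q


def predict(model: OPLSModel, X: np.ndarray) -> np.ndarray:
    """Predicted (continuous) class response for new samples."""
    Xs = (np.asarray(X, dtype=float) - model.scaling.mean) / model.scaling.scale
    return _predict_scaled(Xs, model.w, model.q, model.w_ortho, model.p_ortho) + model.y_mean


def _cross_validate(X, y, n_ortho, cv_folds, seed) -> np.ndarray:
    """Out-of-fold predictions with scaling re-estimated inside each fold."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    y_pred = np.empty(len(y), dtype=float)
    for train, test in skf.split(X, y):
        Xs_tr, record = uv_scale(X[train])
        y_mean = y[train].mean()
        w, p, q, t, W_o, P_o, T_o = _fit_core(Xs_tr, y[train] - y_mean, n_ortho)
        Xs_te = (X[test] - record.mean) / record.scale
        y_pred[test] = _predict_scaled(Xs_te, w, q, W_o, P_o) + y_mean
    return y_pred


def fit_opls(
    X: np.ndarray,
    y: Sequence[int],
    n_ortho: int | str = "auto",
    cv_folds: int = 7,
    seed: int = 0,
    feature_ids: Sequence[str] | None = None,
) -> OPLSModel:
    """Fit a 1-predictive-component OPLS-DA model.

    ``n_ortho="auto"`` grows the orthogonal block while Q2 improves by more
    than 0.01, up to 3 components. Q2 = 1 - PRESS/SS from stratified
    ``cv_folds``-fold cross-validation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("y must contain exactly two classes")
    if cv_folds < 2 or cv_folds > len(y):
        raise ValueError("need 2 <= cv_folds <= n_samples")
    counts = [(y == c).sum() for c in classes]
    if min(counts) < cv_folds:
        cv_folds = int(min(counts))
        if cv_folds < 2:
            raise ValueError("too few samples per class for cross-validation")

    ss_y = float(((y - y.mean()) ** 2).sum())

    def q2_for(k: int) -> tuple[float, np.ndarray]:
        y_pred = _cross_validate(X, y, k, cv_folds, seed)
        press = float(((y - y_pred) ** 2).sum())
        return 1.0 - press / ss_y, y_pred

    if n_ortho == "auto":
        best_k = 0
        best_q2, best_pred = q2_for(0)
        for k in range(1, 4):
            q2_k, pred_k = q2_for(k)
            if q2_k > best_q2 + 0.01:
                best_k, best_q2, best_pred = k, q2_k, pred_k
            else:
                break
        n_ortho, q2, y_pred_cv = best_k, best_q2, best_pred
    else:
        n_ortho = int(n_ortho)
        q2, y_pred_cv = q2_for(n_ortho)

    Xs, record = uv_scale(X)
    y_mean = float(y.mean())
    yc = y - y_mean
    w, p, q, t, W_o, P_o, T_o = _fit_core(Xs, yc, n_ortho)
    n_ortho = len(W_o)  # may have stopped early on degenerate structure

    ss_x = float((Xs ** 2).sum())
    explained = float((t @ t) * (p @ p))
    for i in range(n_ortho):
        explained += float((T_o[:, i] @ T_o[:, i]) * (P_o[i] @ P_o[i]))
    r2x = explained / ss_x if ss_x > 0 else 0.0

    y_fit = t * q
    r2y = 1.0 - float(((yc - y_fit) ** 2).sum()) / ss_y

    press = (1.0 - q2) * ss_y
    return OPLSModel(
        w=w, p=p, q=q, t=t,
        w_ortho=W_o, p_ortho=P_o, t_ortho=T_o,
        scaling=record, y_mean=y_mean,
        r2x=r2x, r2y=r2y, q2=q2,
        n_ortho=n_ortho, cv_folds=cv_folds,
        press=press, ss_y=ss_y, y=y, y_pred_cv=y_pred_cv,
        feature_ids=list(feature_ids) if feature_ids is not None else None,
    )


def hotelling_t2(model: OPLSModel, alpha: float = 0.95) -> tuple[np.ndarray, float]:
    """Per-sample Hotelling T2 in score space and the F-based (alpha) limit.

    Samples with T2 above the limit are candidate strong outliers. Uses the
    predictive plus orthogonal scores (predictive only when n_ortho = 0).
    """
    scores = model.scores
    n, k = scores.shape
    if n < k + 1:
        raise ValueError("need more samples than score dimensions")
    centered = scores - scores.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    t2 = np.einsum("ij,jk,ik->i", centered, np.linalg.pinv(cov), centered)
    if alpha >= 1.0:
        return t2, np.inf
    limit = k * (n - 1) / (n - k) * stats.f.ppf(alpha, k, n - k)
    return t2, float(limit)


def hotelling_outliers(model: OPLSModel, alpha: float = 0.95) -> np.ndarray:
    """Boolean outlier flags at the (alpha) Hotelling T2 limit."""
    t2, limit = hotelling_t2(model, alpha)
    return t2 > limit


def fit_opls_robust(
    X: np.ndarray,
    y: Sequence[int],
    alpha: float = 0.95,
    **kwargs,
) -> tuple[OPLSModel, np.ndarray]:
    """Fit, flag Hotelling T2 outliers once, refit without them.

    Single flag-and-refit pass; returns (refitted model, flags on the
    original samples). If flagging would leave a class with fewer than two
    samples, the initial model is returned with no exclusions.
    """
    model = fit_opls(X, y, **kwargs)
    flags = hotelling_outliers(model, alpha)
    if not flags.any():
        return model, flags
    y = np.asarray(y, dtype=float)
    keep = ~flags
    if min((y[keep] == c).sum() for c in np.unique(y)) < 2:
        return model, np.zeros(len(y), dtype=bool)
    refit = fit_opls(X[keep], y[keep], **kwargs)
    return refit, flags


def cv_anova(model: OPLSModel) -> float:
    """CV-ANOVA p-value: F-test of cross-validated residuals vs total variation.

    F = ((SS_tot - PRESS)/d1) / (PRESS/d2) with d1 = model components
    (1 predictive + n_ortho) and d2 = n - 1 - d1 residual degrees of freedom.
    """
    n = len(model.y)
    d1 = 1 + model.n_ortho
    d2 = n - 1 - d1
    if d2 <= 0:
        return 1.0
    press = model.press
    if press <= 0:
        return 0.0
    explained = model.ss_y - press
    if explained <= 0:
        return 1.0
    f_stat = (explained / d1) / (press / d2)
    return float(stats.f.sf(f_stat, d1, d2))


def vip(model: OPLSModel) -> np.ndarray:
    """Variable importance in projection on the predictive component.

    With one predictive component and unit-norm weights this reduces to
    VIP_j = sqrt(p) * |w_j|, so the mean squared VIP is exactly 1.
    """
    n_vars = len(model.w)
    return np.sqrt(n_vars) * np.abs(model.w)


@dataclass
class MarkerSet:
    table: pd.DataFrame  # columns: vip, direction (index: feature ids)
    threshold: float

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)


def select_markers(
    vips: np.ndarray,
    threshold: float,
    model: OPLSModel,
    feature_ids: Sequence[str] | None = None,
) -> MarkerSet:
    """Features with VIP >= threshold, tagged with their direction.

    Direction 'class1' means elevated in the class coded 1 (line T by
    convention), 'class0' the converse.
    """
    ids = list(feature_ids) if feature_ids is not None else (
        model.feature_ids or [f"V{i}" for i in range(len(vips))]
    )
    mask = vips >= threshold
    direction = np.where(model.w >= 0, "class1", "class0")
    table = pd.DataFrame(
        {"vip": vips[mask], "direction": direction[mask]},
        index=[fid for fid, m in zip(ids, mask) if m],
    ).sort_values("vip", ascending=False)
    return MarkerSet(table, threshold)
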