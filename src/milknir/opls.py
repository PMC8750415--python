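"""Orthogonal PLS (OPLS) regression for targeted adulterant quantification.

A single-response OPLS model removes ``n_ortho`` components of structured
X-variation orthogonal to the response before fitting one predictive PLS
component on the deflated matrix (the standard published O-PLS recipe):

1. w = X'y / ||X'y||, t = Xw, p = X't / t't
2. w_o = p − (w'p)·w, normalized; t_o = Xw_o; p_o = X't_o / t_o't_o
3. deflate X ← X − t_o p_o' and repeat for each orthogonal component
4. one predictive component (w, t, p, q) on the deflated matrix.

X rows are preprocessed (SNV) averaged spectra and are mean-centered inside
the model; y is mean-centered, never scaled.  Validation follows the
sample-wise Venetian-blinds scheme: every sample (an SMP with all its
concentration levels) is left out exactly once.  Error metrics use the
study's conventions: RMSEc with denominator N−2 (degrees of freedom lost to
a one-predictive-factor model on centered data) and RMSEcv with denominator N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "OPLS",
    "OPLSResults",
    "rmse_calibration",
    "rmse_cross_validation",
    "venetian_cv",
    "select_opls_size",
]


def rmse_calibration(y_ref: np.ndarray, y_pred: np.ndarray) -> float:
    """Calibration RMSE with denominator N−2."""
    y_ref = np.asarray(y_ref, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_ref.shape != y_pred.shape:
        raise ValueError("reference and prediction lengths differ")
    n = y_ref.size
    if n <= 2:
        raise ValueError("RMSEc needs more than two samples")
    return float(np.sqrt(np.sum((y_ref - y_pred) ** 2) / (n - 2)))


def rmse_cross_validation(y_ref: np.ndarray, y_pred_cv: np.ndarray) -> float:
    """Cross-validation RMSE with denominator N."""
    y_ref = np.asarray(y_ref, dtype=float)
    y_pred_cv = np.asarray(y_pred_cv, dtype=float)
    if y_ref.shape != y_pred_cv.shape:
        raise ValueError("reference and prediction lengths differ")
    if y_ref.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((y_ref - y_pred_cv) ** 2)))


# ---------------------------------------------------------------------------
# Core fit
# ---------------------------------------------------------------------------

def _opls_core(Xc: np.ndarray, yc: np.ndarray, n_ortho: int):
    """O-PLS on centered data; returns predictive and orthogonal parts."""
    X = Xc.copy()
    w_orthos, p_orthos = [], []
    for _ in range(n_ortho):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("X carries no covariance with y")
        w /= nw
        t = X @ w
        p = X.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12 * np.linalg.norm(p):
            raise ValueError("no orthogonal variation left to extract")
        w_o /= n_o
        t_o = X @ w_o
        denom = t_o @ t_o
        if denom == 0:
            raise ValueError("degenerate orthogonal component")
        p_o = X.T @ t_o / denom
        X = X - np.outer(t_o, p_o)
        w_orthos.append(w_o)
        p_orthos.append(p_o)
    w = X.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("X carries no covariance with y")
    w /= nw
    t = X @ w
    tt = t @ t
    if tt == 0:
        raise ValueError("degenerate predictive component")
    p = X.T @ t / tt
    q = (yc @ t) / tt
    return w, p, q, (np.array(w_orthos), np.array(p_orthos))


class OPLS:
    """OPLS model of adulterant concentration on (averaged) spectra.

    Parameters
    ----------
    X : (N, K) array
        Preprocessed averaged spectra (one row per sample × level).
    y : (N,) array
        Reference concentrations (g/100 g).
    groups : sequence, optional
        Sample identifiers for Venetian-blinds cross-validation (each group
        is one SMP with all its levels).
    n_ortho : int
        Number of orthogonal components (total components = n_ortho + 1).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 groups: Optional[Sequence] = None, n_ortho: int = 0):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X rows must match y length")
        if np.unique(self.y).size < 2:
            raise ValueError("y must carry at least two distinct values")
        if n_ortho < 0:
            raise ValueError("n_ortho must be non-negative")
        rank = np.linalg.matrix_rank(self.X - self.X.mean(axis=0))
        if n_ortho >= rank:
            raise ValueError("n_ortho must be below the rank of centered X")
        self.groups = None if groups is None else np.asarray(groups)
        self.n_ortho = int(n_ortho)

    def fit(self, cross_validate: bool = True) -> "OPLSResults":
        x_mean = self.X.mean(axis=0)
        y_mean = self.y.mean()
        Xc = self.X - x_mean
        yc = self.y - y_mean
        w, p, q, (w_o, p_o) = _opls_core(Xc, yc, self.n_ortho)
        res = OPLSResults(model=self, n_ortho=self.n_ortho,
                          x_mean=x_mean, y_mean=y_mean,
                          weights=w, loadings=p, q=q,
                          ortho_weights=w_o, ortho_loadings=p_o)
        res.y_pred_cal = res.predict(self.X)
        res.rmsec = rmse_calibration(self.y, res.y_pred_cal)
        ss_tot = np.sum((self.y - y_mean) ** 2)
        res.r2 = float(1.0 - np.sum((self.y - res.y_pred_cal) ** 2) / ss_tot)
        if cross_validate and self.groups is not None:
            res.y_pred_cv = venetian_cv(self.X, self.y, self.groups, self.n_ortho)
            res.rmsecv = rmse_cross_validation(self.y, res.y_pred_cv)
            res.q2 = float(1.0 - np.sum((self.y - res.y_pred_cv) ** 2) / ss_tot)
        return res


@dataclass
class OPLSResults:
    """Fitted OPLS model: weights, loadings and error diagnostics."""

    model: OPLS
    n_ortho: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    loadings: np.ndarray
    q: float
    ortho_weights: np.ndarray
    ortho_loadings: np.ndarray
    y_pred_cal: Optional[np.ndarray] = None
    y_pred_cv: Optional[np.ndarray] = None
    rmsec: Optional[float] = None
    rmsecv: Optional[float] = None
    r2: Optional[float] = None
    q2: Optional[float] = None

    @property
    def n_components(self) -> int:
        return self.n_ortho + 1

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predictions are linear in X: deflate orthogonal parts, then t·q."""
        X = np.atleast_2d(np.asarray(X, dtype=float)) - self.x_mean
        for w_o, p_o in zip(self.ortho_weights, self.ortho_loadings):
            t_o = X @ w_o
            X = X - np.outer(t_o, p_o)
        t = X @ self.weights
        return t * self.q + self.y_mean

    def ejcr(self, alpha: float = 0.05, use_cv: bool = True):
        """EJCR bias test on this model's predictions (CV by default)."""
        from .merit import ejcr_test

        y_pred = self.y_pred_cv if (use_cv and self.y_pred_cv is not None) \
            else self.y_pred_cal
        return ejcr_test(self.model.y, y_pred, alpha=alpha)

    def lod(self, alpha: float = 0.05, beta: float = 0.05, use_cv: bool = True):
        """Pseudo-univariate detection limit from this model's predictions."""
        from .merit import lod

        y_pred = self.y_pred_cv if (use_cv and self.y_pred_cv is not None) \
            else self.y_pred_cal
        return lod(self.model.y, y_pred, alpha=alpha, beta=beta)

    def to_dict(self) -> dict:
        return {
            "n_ortho": self.n_ortho,
            "n_components": self.n_components,
            "rmsec": self.rmsec,
            "rmsecv": self.rmsecv,
            "r2": self.r2,
            "q2": self.q2,
            "y_mean": self.y_mean,
            "q": self.q,
        }

    def summary(self) -> str:
        fmt = lambda v: "      --" if v is None else f"{v:8.4f}"
        return "\n".join([
            "OPLS regression (1 predictive component)",
            "=" * 44,
            f"orthogonal components    {self.n_ortho}",
            f"total components         {self.n_components}",
            f"RMSEc                    {fmt(self.rmsec)}",
            f"RMSEcv                   {fmt(self.rmsecv)}",
            f"R2 (calibration)         {fmt(self.r2)}",
            f"Q2 (cross-validation)    {fmt(self.q2)}",
        ])

    def plot_fitness(self, ax=None):
        """Predicted-vs-reference plot (cross-validation when available)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.model.y
        y_pred = self.y_pred_cv if self.y_pred_cv is not None else self.y_pred_cal
        ax.scatter(y, y_pred, s=15)
        lims = [min(y.min(), y_pred.min()), max(y.max(), y_pred.max())]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel("reference (g/100 g)")
        ax.set_ylabel("predicted (g/100 g)")
        return ax


# ---------------------------------------------------------------------------
# Cross-validation and size selection
# ---------------------------------------------------------------------------

def venetian_cv(X: np.ndarray, y: np.ndarray, groups: Sequence,
                n_ortho: int) -> np.ndarray:
    """Sample-wise leave-one-group-out predictions.

    Each group (one SMP with all its concentration levels) is removed once;
    the model is refit on the remaining groups and predicts the held-out
    rows.  Fully deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if uniq.size < 2:
        raise ValueError("Venetian-blinds CV needs at least two groups")
    y_cv = np.empty_like(y)
    for g in uniq:
        held = groups == g
        model = OPLS(X[~held], y[~held], n_ortho=n_ortho)
        res = model.fit(cross_validate=False)
        y_cv[held] = res.predict(X[held])
    return y_cv


def select_opls_size(X: np.ndarray, y: np.ndarray, groups: Sequence,
                     max_components: int = 8, stabilization_tol: float = 0.05,
                     gap_limit: float = 0.30) -> Tuple[int, pd.DataFrame, bool]:
    """Choose the total component count from the RMSE curves.

    The chosen size is the smallest total-component count whose RMSEcv lies
    within ``stabilization_tol`` of the minimum of a centered 3-point moving
    average of the RMSEcv curve ("stabilized around its averaged minimum")
    and whose relative gap (RMSEcv − RMSEc)/RMSEc is below ``gap_limit``.
    When no size qualifies, the RMSEcv argmin is returned with a warning
    flag.  Returns (chosen size, curve table, criterion_met).
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    rows = []
    for total in range(1, max_components + 1):
        n_ortho = total - 1
        if n_ortho >= rank:
            break
        model = OPLS(X, y, groups=groups, n_ortho=n_ortho)
        res = model.fit()
        rows.append({"n_components": total, "rmsec": res.rmsec,
                     "rmsecv": res.rmsecv, "r2": res.r2, "q2": res.q2})
    table = pd.DataFrame(rows)
    rmsecv = table.rmsecv.to_numpy()
    # centered 3-point moving average (shorter windows at the ends)
    smooth = np.array([rmsecv[max(0, i - 1): i + 2].mean()
                       for i in range(len(rmsecv))])
    band = smooth.min() * (1.0 + stabilization_tol)
    rel_gap = (table.rmsecv - table.rmsec) / table.rmsec
    ok = (table.rmsecv <= band) & (rel_gap < gap_limit)
    if ok.any():
        chosen = int(table.loc[ok, "n_components"].iloc[0])
        return chosen, table, True
    chosen = int(table.loc[table.rmsecv.idxmin(), "n_components"])
    return chosen, table, False
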