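"""One-class SIMCA: a PCA model of the authentic class with statistical limits.

The authentic-class spectra are mean-centered and Pareto-scaled, a PCA basis
of C components is extracted by SVD, and every sample gets two distances:

* the score distance SD_i = Σ_c (t_ic − t̄_c)²/s²_tc — Hotelling's T², the
  squared Mahalanobis distance inside the score space, compared with the
  F-based limit F(1−α; C, N−C)·C(N−1)/(N−C);
* the normalized orthogonal distance OD_i = (s_i/s0)·ν with
  s_i² = Σ_k e_ik²/(K−C) and s0² = ΣΣ e²/((N−C−C0)(K−C)), compared with
  sqrt(F(1−α; df1, df2)) where df2 = sqrt((N−C−C0)(K−C)) and df1 follows the
  vendor-style observation-degrees-of-freedom formula (see ``od_critical``).

The small-sample correction ν = sqrt(N/(N−C−C0)) is applied to the working
set only, so the training OD² values average exactly one; projected query
samples use ν = 1.  A sample is authentic only if it sits inside both limits.

Model size is chosen by grouped 3-fold cross-validation: the candidate with
the highest predictive cumulative variance (Q²) whose explained-vs-predicted
gap is smallest wins, with ties broken toward fewer components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ScalingRecord, pareto_scale
from .synthetic import SpectraSet

__all__ = [
    "SimcaOCC",
    "SimcaResults",
    "fit_pca",
    "t2_critical",
    "od_critical",
    "select_simca_size",
]


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def fit_pca(X_scaled: np.ndarray, n_components: int) -> Tuple[np.ndarray, np.ndarray]:
    """SVD-based PCA of an already centered/scaled matrix.

    Returns (scores, loadings) with orthonormal loadings; the sign of each
    loading vector is fixed so its largest-magnitude element is positive.
    """
    X = np.asarray(X_scaled, dtype=float)
    n, k = X.shape
    c = int(n_components)
    if c < 1:
        raise ValueError("need at least one component")
    if c >= min(n - 1, k):
        raise ValueError("component count must be < min(N-1, K)")
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    loadings = vt[:c].T
    # deterministic sign convention
    for j in range(c):
        idx = np.argmax(np.abs(loadings[:, j]))
        if loadings[idx, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = X @ loadings
    return scores, loadings


def t2_critical(n: int, n_components: int, alpha: float) -> float:
    """F-based critical score distance: F(1−α; C, N−C)·C(N−1)/(N−C)."""
    n, c = int(n), int(n_components)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n <= c or c < 1:
        raise ValueError("need N > C >= 1 for the T2 limit")
    return stats.f.ppf(1 - alpha, c, n - c) * c * (n - 1) / (n - c)


def od_critical(n: int, n_components: int, n_channels: int, alpha: float,
                c0: int = 1) -> Tuple[float, bool]:
    """Critical normalized orthogonal distance sqrt(F(1−α; df1, df2)).

    df2 = sqrt((N−C−C0)(K−C)).  When K > df2 > 100 the observation degrees
    of freedom follow df1 = (100 + sqrt(K−df2) − C)·N/(N−C−C0); outside that
    regime the uncorrected residual form df1 = (K−C)·N/(N−C−C0) is used and
    the second return value flags the fallback.
    """
    n, c, k = int(n), int(n_components), int(n_channels)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k <= c or n <= c + c0:
        raise ValueError("need K > C and N > C + C0 for the OD limit")
    df2 = np.sqrt((n - c - c0) * (k - c))
    if k > df2 > 100:
        df1 = (100.0 + np.sqrt(k - df2) - c) * n / (n - c - c0)
        fallback = False
    else:
        df1 = (k - c) * n / (n - c - c0)
        fallback = True
    if df1 <= 0 or df2 <= 0:
        raise ValueError("non-positive degrees of freedom")
    return float(np.sqrt(stats.f.ppf(1 - alpha, df1, df2))), fallback


# ---------------------------------------------------------------------------
# Model / results objects
# ---------------------------------------------------------------------------

class SimcaOCC:
    """One-class SIMCA model of an authentic training population.

    Parameters
    ----------
    X : (N, K) array
        Preprocessed (e.g. SNV-treated) absorbance rows of the authentic
        class.  Centering and Pareto scaling happen inside the model.
    alpha : float
        Significance level of both distance limits (default 0.05).
    n_components : int, optional
        Model size; selected by grouped cross-validation when omitted.
    sample_ids : sequence, optional
        Sample labels used to keep all replicates of a sample in one
        cross-validation group.
    """

    def __init__(self, X: np.ndarray, alpha: float = 0.05,
                 n_components: Optional[int] = None,
                 sample_ids: Optional[Sequence] = None,
                 candidate_components: Optional[Sequence[int]] = None,
                 cv_groups: int = 3, seed: int = 0):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(self.X)):
            raise ValueError("training matrix contains non-finite values")
        self.alpha = float(alpha)
        self.n_components = n_components
        self.sample_ids = None if sample_ids is None else np.asarray(sample_ids)
        n, k = self.X.shape
        if candidate_components is None:
            candidate_components = range(1, min(11, n - 2, k))
        self.candidate_components = list(candidate_components)
        self.cv_groups = cv_groups
        self.seed = seed

    def fit(self) -> "SimcaResults":
        n, k = self.X.shape
        size_table = None
        c = self.n_components
        if c is None:
            c, size_table = select_simca_size(
                self.X, self.candidate_components, cv_groups=self.cv_groups,
                seed=self.seed, sample_ids=self.sample_ids)
        c = int(c)
        Xs, record = pareto_scale(self.X)
        scores, loadings = fit_pca(Xs, c)
        score_var = scores.var(axis=0, ddof=1)
        if np.any(score_var <= 0):
            raise ValueError("degenerate component with zero score variance")
        residuals = Xs - scores @ loadings.T
        c0 = 1
        rss_rows = np.sum(residuals ** 2, axis=1)
        s0_sq = rss_rows.sum() / ((n - c - c0) * (k - c))
        nu = float(np.sqrt(n / (n - c - c0)))
        t2_crit = t2_critical(n, c, self.alpha)
        od_crit, od_fallback = od_critical(n, c, k, self.alpha, c0)
        return SimcaResults(
            model=self, n_components=c, loadings=loadings,
            score_mean=scores.mean(axis=0), score_var=score_var,
            scaling=record, s0=float(np.sqrt(s0_sq)), nu=nu, c0=c0,
            n_train=n, n_channels=k, alpha=self.alpha,
            t2_crit=float(t2_crit), od_crit=float(od_crit),
            od_df_fallback=od_fallback, size_table=size_table,
            _train_scores=scores, _train_rss=rss_rows)


@dataclass
class SimcaResults:
    """Fitted one-class SIMCA model with its limits and projection methods."""

    model: SimcaOCC
    n_components: int
    loadings: np.ndarray
    score_mean: np.ndarray
    score_var: np.ndarray
    scaling: ScalingRecord
    s0: float
    nu: float
    c0: int
    n_train: int
    n_channels: int
    alpha: float
    t2_crit: float
    od_crit: float
    od_df_fallback: bool
    size_table: Optional[pd.DataFrame] = None
    _train_scores: Optional[np.ndarray] = None
    _train_rss: Optional[np.ndarray] = None

    # -- distances ---------------------------------------------------------

    def score_distance(self, X: np.ndarray) -> np.ndarray:
        """Hotelling T² of preprocessed rows in the model's score space."""
        scores = self.scaling.apply(X) @ self.loadings
        d = (scores - self.score_mean) ** 2 / self.score_var
        return d.sum(axis=1)

    def orthogonal_distance(self, X: np.ndarray, working_set: bool = False) -> np.ndarray:
        """Normalized residual distance; ν is applied to the working set only."""
        if self.s0 <= 1e-8:  # exact low-rank training data
            raise ValueError("exact-fit model: s0 = 0, OD undefined")
        Xs = self.scaling.apply(X)
        residuals = Xs - (Xs @ self.loadings) @ self.loadings.T
        k, c = self.n_channels, self.n_components
        s_i = np.sqrt(np.sum(residuals ** 2, axis=1) / (k - c))
        od = s_i / self.s0
        return od * self.nu if working_set else od

    @property
    def sd_train(self) -> np.ndarray:
        d = (self._train_scores - self.score_mean) ** 2 / self.score_var
        return d.sum(axis=1)

    @property
    def od_train(self) -> np.ndarray:
        k, c = self.n_channels, self.n_components
        return np.sqrt(self._train_rss / (k - c)) / self.s0 * self.nu

    # -- projection --------------------------------------------------------

    def project(self, queries, meta: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        """Project query spectra; verdict is authentic iff inside both limits.

        ``queries`` is a preprocessed (N, K) matrix or a :class:`SpectraSet`
        whose grid must match the training grid (the caller preprocesses the
        absorbance identically to the training data).
        """
        if isinstance(queries, SpectraSet):
            if queries.absorbance.shape[1] != self.n_channels:
                raise ValueError("query wavelength grid does not match the model")
            X = queries.absorbance
            meta = queries.meta
        else:
            X = np.atleast_2d(np.asarray(queries, dtype=float))
            if X.shape[1] != self.n_channels:
                raise ValueError("query channel count does not match the model")
        sd = self.score_distance(X)
        od = self.orthogonal_distance(X)
        result = pd.DataFrame({
            "sd": sd,
            "od": od,
            "inside_sd": sd <= self.t2_crit,
            "inside_od": od <= self.od_crit,
        })
        result["verdict"] = np.where(result.inside_sd & result.inside_od,
                                     "authentic", "outlying")
        if meta is not None:
            result = pd.concat([meta.reset_index(drop=True), result], axis=1)
        return result

    # -- reporting ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "n_train": self.n_train,
            "n_channels": self.n_channels,
            "alpha": self.alpha,
            "s0": self.s0,
            "nu": self.nu,
            "c0": self.c0,
            "t2_crit": self.t2_crit,
            "od_crit": self.od_crit,
            "od_df_fallback": self.od_df_fallback,
            "score_mean": self.score_mean.tolist(),
            "score_var": self.score_var.tolist(),
            "scaling_mean": self.scaling.mean.tolist(),
            "scaling_scale": self.scaling.scale.tolist(),
        }

    def summary(self) -> str:
        lines = [
            "One-class SIMCA model",
            "=" * 44,
            f"training rows (N)        {self.n_train}",
            f"channels (K)             {self.n_channels}",
            f"components (C)           {self.n_components}",
            f"alpha                    {self.alpha:g}",
            f"pooled residual sd (s0)  {self.s0:.6g}",
            f"nu correction            {self.nu:.4f}",
            f"T2 critical (SD limit)   {self.t2_crit:.4f}",
            f"OD critical              {self.od_crit:.4f}"
            + ("  [fallback df1]" if self.od_df_fallback else ""),
        ]
        if self.size_table is not None:
            lines.append("")
            lines.append(self.size_table.to_string(index=False,
                                                   float_format="%.4f"))
        return "\n".join(lines)

    def plot_distances(self, projection: pd.DataFrame, ax=None, hue: str = None):
        """Score-distance vs orthogonal-distance map with the model limits."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if hue and hue in projection:
            for label, sub in projection.groupby(hue):
                ax.scatter(sub["sd"], sub["od"], s=12, label=str(label))
            ax.legend(fontsize=8)
        else:
            ax.scatter(projection["sd"], projection["od"], s=12)
        ax.axvline(self.t2_crit, color="k", ls="--", lw=1)
        ax.axhline(self.od_crit, color="k", ls="--", lw=1)
        ax.set_xlabel("score distance (T²)")
        ax.set_ylabel("orthogonal distance (normalized)")
        return ax


# ---------------------------------------------------------------------------
# Cross-validated size selection
# ---------------------------------------------------------------------------

def _cv_group_assignment(n: int, n_groups: int, rng: np.random.Generator,
                         sample_ids: Optional[np.ndarray]) -> np.ndarray:
    """Random group labels; all replicates of one sample share a group."""
    if sample_ids is None:
        labels = rng.permutation(n) % n_groups
        return labels
    uniq = pd.unique(sample_ids)
    perm = rng.permutation(len(uniq)) % n_groups
    lookup = dict(zip(uniq, perm))
    return np.array([lookup[s] for s in sample_ids])


def select_simca_size(X: np.ndarray, candidate_components: Sequence[int],
                      cv_groups: int = 3, seed: int = 0,
                      sample_ids: Optional[Sequence] = None,
                      q2_tol: float = 0.01) -> Tuple[int, pd.DataFrame]:
    """Choose the PCA model size by grouped cross-validation.

    For each candidate C the table reports the cumulative explained variance
    R² and the cross-validated predictive variance Q².  Q² uses the held-out
    row PRESS inflated by K/(K−C): projecting independent rows on any C
    directions removes a C/K share of their variance, so without the
    adjustment pure noise would look increasingly "predictable".  The chosen
    C maximizes Q² (within ``q2_tol``) with the smallest R²−Q² gap,
    ties broken toward fewer components.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if n < 6:
        raise ValueError("need at least 6 rows for 3-group cross-validation")
    cands = sorted(int(c) for c in candidate_components)
    cands = [c for c in cands if 1 <= c < min(n - 2, k)]
    if not cands:
        raise ValueError("no feasible candidate component counts")
    rng = np.random.default_rng(seed)
    ids = None if sample_ids is None else np.asarray(sample_ids)
    groups = _cv_group_assignment(n, cv_groups, rng, ids)

    # explained variance from the full-data PCA spectrum
    Xs, _ = pareto_scale(X)
    sv = np.linalg.svd(Xs, compute_uv=False)
    total_ss = np.sum(Xs ** 2)
    r2_cum = np.cumsum(sv ** 2) / total_ss

    press = {c: 0.0 for c in cands}
    ss_held = 0.0
    for g in range(cv_groups):
        train, held = groups != g, groups == g
        if held.sum() == 0 or train.sum() <= max(cands) + 1:
            continue
        Xt, record = pareto_scale(X[train])
        Xh = record.apply(X[held])
        _, _, vt = np.linalg.svd(Xt, full_matrices=False)
        ss_held += np.sum(Xh ** 2)
        for c in cands:
            P = vt[:c].T
            resid = Xh - (Xh @ P) @ P.T
            press[c] += np.sum(resid ** 2) * k / (k - c)
    if ss_held == 0:
        raise ValueError("cross-validation produced no held-out rows")

    table = pd.DataFrame({
        "n_components": cands,
        "r2": [r2_cum[c - 1] for c in cands],
        "q2": [1.0 - press[c] / ss_held for c in cands],
    })
    table["gap"] = table.r2 - table.q2
    q2_max = table.q2.max()
    eligible = table[table.q2 >= q2_max - q2_tol]
    best = eligible.sort_values(["gap", "n_components"]).iloc[0]
    return int(best.n_components), table
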