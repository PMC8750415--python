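"""Post-regression figures of merit: EJCR bias test and pseudo-univariate LoD.

EJCR fits the univariate regression of predicted on reference values and
tests whether the ideal point (intercept 0, slope 1) lies inside the joint
elliptical confidence region

    N(â−a)² + 2·Σy_ref·(â−a)(b̂−b) + Σy_ref²·(b̂−b)² ≤ 2·MSE·F(2, N−2; 1−α)

with MSE the mean squared error of that univariate fit.  The model is
unbiased (at level α) when the ideal point satisfies the inequality.

The detection limit follows the pseudo-univariate approach:

    LoD = Δ(α, β; ν) · RMSEu · sqrt(1 + 1/N + h0) / b̂

with RMSEu the univariate-regression RMSE (denominator N−2), h0 the leverage
at zero concentration (ȳ_ref²/Σ(y_ref−ȳ_ref)²), and Δ(α, β; ν) the
non-centrality parameter of a non-central t distribution with ν = N−2
degrees of freedom; for ν > 100 it converges to the sum of the two Student
quantiles t(1−α; ν) + t(1−β; ν).  LoQ = 3·LoD by convention.  By default the
regression uses cross-validated predictions against reference values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import brentq

from .synthetic import (Composition, DEFAULT_COMPOSITION,
                        NITROGEN_MASS_FRACTION)

__all__ = [
    "EjcrResult",
    "LodResult",
    "ejcr_test",
    "lod",
    "loq",
    "delta_factor",
    "fraud_pct_conversion",
]


@dataclass(frozen=True)
class EjcrResult:
    """Outcome of the elliptical joint confidence region bias test."""

    a_hat: float
    b_hat: float
    mse: float
    f_crit: float
    quadratic_form_at_ideal: float
    unbiased: bool
    alpha: float
    n: int
    sum_y: float = 0.0
    sum_y2: float = 0.0

    def ellipse(self, n_points: int = 200) -> np.ndarray:
        """Boundary points (a, b) of the confidence ellipse, for plotting."""
        m = np.array([[self.n, self.sum_y], [self.sum_y, self.sum_y2]])
        radius = 2.0 * self.mse * self.f_crit
        # unit circle mapped through the inverse Cholesky factor of M/radius
        theta = np.linspace(0.0, 2 * np.pi, n_points)
        circle = np.vstack([np.cos(theta), np.sin(theta)])
        l = np.linalg.cholesky(m / radius)
        pts = np.linalg.solve(l.T, circle)
        return pts.T + np.array([self.a_hat, self.b_hat])

    def summary(self) -> str:
        verdict = "unbiased" if self.unbiased else "BIASED"
        return "\n".join([
            "EJCR bias test (intercept 0, slope 1)",
            "=" * 44,
            f"intercept (a^)       {self.a_hat: .5g}",
            f"slope (b^)           {self.b_hat: .5g}",
            f"MSE                  {self.mse: .5g}",
            f"F(2, N-2; 1-alpha)   {self.f_crit: .5g}",
            f"Q(0,1) vs 2*MSE*F    {self.quadratic_form_at_ideal: .5g} vs "
            f"{2 * self.mse * self.f_crit: .5g}",
            f"verdict              {verdict} (alpha = {self.alpha:g})",
        ])


def ejcr_test(y_ref: np.ndarray, y_pred: np.ndarray,
              alpha: float = 0.05) -> EjcrResult:
    """Joint test of intercept = 0 and slope = 1 on predicted vs reference."""
    y_ref = np.asarray(y_ref, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_ref.shape != y_pred.shape:
        raise ValueError("reference and prediction lengths differ")
    n = y_ref.size
    if n <= 2:
        raise ValueError("EJCR needs more than two samples")
    if np.ptp(y_ref) == 0:
        raise ValueError("constant reference values: regression undefined")
    fit = sm.OLS(y_pred, sm.add_constant(y_ref)).fit()
    a_hat, b_hat = float(fit.params[0]), float(fit.params[1])
    mse = float(fit.ssr / (n - 2))
    f_crit = float(stats.f.ppf(1 - alpha, 2, n - 2))
    da, db = a_hat - 0.0, b_hat - 1.0
    q = (n * da ** 2 + 2 * np.sum(y_ref) * da * db
         + np.sum(y_ref ** 2) * db ** 2)
    # absolute epsilon so an exact fit (q and MSE both ~ machine zero)
    # counts as unbiased
    threshold = 2 * mse * f_crit + 1e-12
    return EjcrResult(a_hat=a_hat, b_hat=b_hat, mse=mse, f_crit=f_crit,
                      quadratic_form_at_ideal=float(q),
                      unbiased=bool(q <= threshold),
                      alpha=alpha, n=n, sum_y=float(np.sum(y_ref)),
                      sum_y2=float(np.sum(y_ref ** 2)))


def delta_factor(alpha: float, beta: float, nu: int) -> float:
    """Δ(α, β; ν): non-centrality of a non-central t detection scheme.

    Δ is the non-centrality parameter δ at which a one-sided level-α t test
    with ν degrees of freedom has power 1−β, i.e. the solution of
    P(T'_ν(δ) ≤ t(1−α; ν)) = β.  For ν > 100 the Student-sum approximation
    t(1−α; ν) + t(1−β; ν) is used.
    """
    if not (0 < alpha < 1 and 0 < beta < 1):
        raise ValueError("alpha and beta must be in (0, 1)")
    if nu < 1:
        raise ValueError("degrees of freedom must be positive")
    t_alpha = stats.t.ppf(1 - alpha, nu)
    t_beta = stats.t.ppf(1 - beta, nu)
    if nu > 100:
        return float(t_alpha + t_beta)
    f = lambda d: stats.nct.cdf(t_alpha, nu, d) - beta
    return float(brentq(f, 1e-9, (t_alpha + t_beta) * 4 + 10))


@dataclass(frozen=True)
class LodResult:
    """Detection/quantification limits with their plug-in components."""

    lod: float
    loq: float
    rmseu: float
    h0: float
    delta: float
    b_hat: float
    n: int
    nu: int
    alpha: float
    beta: float
    lod_fraud_pct: Optional[float] = None
    loq_fraud_pct: Optional[float] = None

    def summary(self) -> str:
        lines = [
            "Pseudo-univariate detection limit",
            "=" * 44,
            f"Delta(alpha, beta; nu)   {self.delta: .4f}",
            f"RMSEu                    {self.rmseu: .5g}",
            f"h0 (zero-conc leverage)  {self.h0: .5g}",
            f"slope (b^)               {self.b_hat: .5g}",
            f"LoD                      {self.lod: .4g} g/100 g",
            f"LoQ = 3 LoD              {self.loq: .4g} g/100 g",
        ]
        if self.lod_fraud_pct is not None:
            lines.append(f"LoD (fraud basis)        {self.lod_fraud_pct: .3g} %")
            lines.append(f"LoQ (fraud basis)        {self.loq_fraud_pct: .3g} %")
        return "\n".join(lines)


def lod(y_ref: np.ndarray, y_pred: np.ndarray, alpha: float = 0.05,
        beta: float = 0.05, b_hat: Optional[float] = None,
        adulterant: Optional[str] = None,
        composition: Composition = DEFAULT_COMPOSITION,
        cornstarch_lactose_factor: float = 0.9) -> LodResult:
    """Pseudo-univariate LoD from a predicted-vs-reference regression.

    ``y_pred`` should normally hold cross-validated predictions.  When
    ``adulterant`` is given, the limits are also expressed on the fraud
    percentage basis (total nitrogen for N-rich adulterants, lactose for
    cornstarch).
    """
    y_ref = np.asarray(y_ref, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = y_ref.size
    if n <= 2:
        raise ValueError("LoD needs more than two samples")
    if np.ptp(y_ref) == 0:
        raise ValueError("constant reference values: regression undefined")
    fit = sm.OLS(y_pred, sm.add_constant(y_ref)).fit()
    slope = float(fit.params[1]) if b_hat is None else float(b_hat)
    if slope == 0:
        raise ValueError("zero slope: LoD undefined")
    rmseu = float(np.sqrt(fit.ssr / (n - 2)))
    y_bar = y_ref.mean()
    h0 = float(y_bar ** 2 / np.sum((y_ref - y_bar) ** 2))
    nu = n - 2
    delta = delta_factor(alpha, beta, nu)
    value = delta * rmseu * np.sqrt(1.0 + 1.0 / n + h0) / abs(slope)
    lod_fraud = loq_fraud = None
    if adulterant is not None:
        lod_fraud = fraud_pct_conversion(value, adulterant, composition,
                                         cornstarch_lactose_factor)
        loq_fraud = 3.0 * lod_fraud
    return LodResult(lod=float(value), loq=float(3.0 * value), rmseu=rmseu,
                     h0=h0, delta=float(delta), b_hat=slope, n=n, nu=nu,
                     alpha=alpha, beta=beta, lod_fraud_pct=lod_fraud,
                     loq_fraud_pct=loq_fraud)


def loq(lod_result: LodResult) -> float:
    """Limit of quantification: 3 × LoD (on the mass basis)."""
    return 3.0 * lod_result.lod


def fraud_pct_conversion(dose_g_per_100g: float, adulterant: str,
                         composition: Composition = DEFAULT_COMPOSITION,
                         cornstarch_lactose_factor: float = 0.9) -> float:
    """Express a dose (g/100 g) as a fraud percentage on its natural basis.

    Inverse of :func:`milknir.synthetic.dose_for_fraud_level`: nitrogen basis
    for the N-rich adulterants, lactose basis for cornstarch.
    """
    if dose_g_per_100g < 0:
        raise ValueError("dose must be non-negative")
    if adulterant in NITROGEN_MASS_FRACTION:
        n_added = dose_g_per_100g * NITROGEN_MASS_FRACTION[adulterant]
        return 100.0 * n_added / composition.total_nitrogen
    if adulterant == "cornstarch":
        return (100.0 * dose_g_per_100g * cornstarch_lactose_factor
                / composition.lactose)
    raise ValueError(f"unknown adulterant basis: {adulterant!r}")
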