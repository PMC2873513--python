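"""Global goodness-of-fit assessment: chi-square test, RMSEA, NFI.

RMSEA is the noncentrality-based per-degree-of-freedom misfit,
``sqrt(max(chi2 - df, 0) / (df (n - 1)))``, with a confidence interval from
inverting the noncentral chi-square distribution in its noncentrality
parameter.  NFI compares the model chi-square with that of the independence
(uncorrelated-variables) baseline, which has the closed form
``chi2_b = -(N - 1) ln(|S| / |diag S|)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2 as chi2_dist
from scipy.stats import ncx2

from .data import CovarianceSummary
from .engine import FittedModel, _check_pd

__all__ = ["FitIndexReport", "rmsea", "baseline_chi_square", "nfi", "fit_report"]


@dataclass
class FitIndexReport:
    chi_square: float
    df: int
    p_value: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    nfi: float
    baseline_chi_square: float
    baseline_df: int
    n: int
    nfi_warning: bool = False  # model fit worse than the independence baseline

    def render(self) -> str:
        lo, hi = self.rmsea_ci
        lo_s = "." if lo == 0.0 else f"{lo:.2f}"
        lines = [
            f"chi2({self.df}) = {self.chi_square:.2f}, p = {self.p_value:.3f}",
            f"RMSEA {self.rmsea:.2f} [{lo_s} ; {hi:.2f}]",
            f"NFI {self.nfi:.3f}",
        ]
        if self.nfi_warning:
            lines.append("warning: model chi-square exceeds the baseline chi-square")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "p_value": self.p_value,
            "rmsea": self.rmsea,
            "rmsea_ci": list(self.rmsea_ci),
            "nfi": self.nfi,
            "baseline_chi_square": self.baseline_chi_square,
            "baseline_df": self.baseline_df,
            "n": self.n,
        }


def _ncp_bound(chi_square: float, df: int, target: float, upper: float) -> float:
    """Noncentrality lambda with ncx2.cdf(chi_square; df, lambda) == target."""

    def f(lam: float) -> float:
        return ncx2.cdf(chi_square, df, lam) - target

    if f(0.0) < 0:  # even lambda = 0 puts too little mass below chi_square
        return 0.0
    hi = max(upper, 1.0)
    while f(hi) > 0:
        hi *= 2
        if hi > 1e8:
            return hi
    return brentq(f, 0.0, hi, xtol=1e-10)


def rmsea(
    chi_square: float, df: int, n: int, ci_level: float = 0.95
) -> tuple[float, float, float]:
    """RMSEA point value and confidence interval ``(point, lower, upper)``.

    The bounds invert the noncentral chi-square CDF for the noncentrality
    parameter at the two tails; an unattainable lower bound is reported as
    0 (rendered "." in text output).
    """
    if df <= 0:
        raise ValueError("RMSEA undefined for saturated model")
    if n <= 1:
        raise ValueError("need n > 1")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    scale = df * (n - 1)
    point = float(np.sqrt(max(chi_square - df, 0.0) / scale))
    alpha = 1 - ci_level
    guess = max(chi_square - df, 1.0)
    lam_lo = _ncp_bound(chi_square, df, 1 - alpha / 2, guess)
    lam_hi = _ncp_bound(chi_square, df, alpha / 2, 3 * guess + 10)
    return point, float(np.sqrt(lam_lo / scale)), float(np.sqrt(lam_hi / scale))


def baseline_chi_square(cov: CovarianceSummary) -> tuple[float, int]:
    """Chi-square and df of the independence model Sigma_b = diag(S)."""
    S = np.asarray(cov.S, dtype=float)
    lndetS = _check_pd(S, "S")
    lndiag = float(np.sum(np.log(np.diag(S))))
    chi = (cov.n - 1) * (lndiag - lndetS)  # = -(N-1) ln(|S|/|diag S|)
    p = S.shape[0]
    return float(max(chi, 0.0)), p * (p - 1) // 2


def nfi(chi_model: float, chi_baseline: float) -> float:
    """Normed fit index (chi2_b - chi2_m) / chi2_b."""
    if chi_baseline <= 0:
        raise ValueError("baseline chi-square must be positive")
    return float((chi_baseline - chi_model) / chi_baseline)


def fit_report(
    fit: FittedModel, cov: CovarianceSummary, *, rmsea_ci_level: float = 0.95
) -> FitIndexReport:
    """Assemble the standard fit-index panel for a fitted model."""
    chi_b, df_b = baseline_chi_square(cov)
    point, lo, hi = rmsea(fit.chi_square, fit.df, fit.n, rmsea_ci_level)
    value = nfi(fit.chi_square, chi_b)
    return FitIndexReport(
        chi_square=fit.chi_square,
        df=fit.df,
        p_value=float(chi2_dist.sf(fit.chi_square, fit.df)),
        rmsea=point,
        rmsea_ci=(lo, hi),
        nfi=value,
        baseline_chi_square=chi_b,
        baseline_df=df_b,
        n=fit.n,
        nfi_warning=fit.chi_square > chi_b,
    )
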