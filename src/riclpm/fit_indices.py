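"""Global fit evaluation: chi-square, RMSEA, CFI, TLI, SRMR.

All indices are deterministic functions of the maximized log-likelihoods
(model, saturated, independence baseline), the sample size and the degrees
of freedom.  Adequacy thresholds follow the common reporting convention:
RMSEA <= 0.05, CFI >= 0.95, TLI >= 0.95, SRMR < 0.08 (note the strict
inequality for SRMR).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq

from .estimation import (
    FitResult,
    _as_stats,
    baseline_loglik,
    saturated_loglik,
)

__all__ = [
    "FitIndexSet",
    "chi_square",
    "rmsea",
    "cfi_tli",
    "srmr",
    "adequacy",
    "compute_fit_indices",
    "ADEQUACY_THRESHOLDS",
]

ADEQUACY_THRESHOLDS = {"rmsea": 0.05, "cfi": 0.95, "tli": 0.95, "srmr": 0.08}


def chi_square(ll_model: float, ll_saturated: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio statistic 2(ll_sat - ll_model) and its p-value."""
    chi2 = 2.0 * (ll_saturated - ll_model)
    if chi2 < -1e-8:
        raise ValueError(
            f"saturated log-likelihood below model log-likelihood (chi2 = {chi2}); "
            "the saturated optimization did not converge"
        )
    chi2 = max(chi2, 0.0)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), p


def rmsea(chi2: float, df: int, n: int, coverage: float = 0.95,
          denominator: str = "n-1") -> tuple[float, tuple[float, float]]:
    """RMSEA point estimate and confidence interval.

    Point estimate sqrt(max(chi2 - df, 0) / (df * (n - 1))); the CI inverts
    the noncentral chi-square distribution in its noncentrality parameter.
    ``denominator`` may be "n-1" (default) or "n"; at large n they agree to
    three decimals.
    """
    if n <= 1:
        raise ValueError("n must exceed 1")
    if df < 1:
        raise ValueError("df must be at least 1")
    scale = df * ((n - 1) if denominator == "n-1" else n)
    point = float(np.sqrt(max(chi2 - df, 0.0) / scale))
    alpha = 1.0 - coverage

    def lam_for(prob: float) -> float:
        # largest lambda with P(X_{df,lam} <= chi2) >= prob is found by root
        f0 = sps.ncx2.cdf(chi2, df, 1e-10) - prob
        if f0 <= 0:
            return 0.0
        hi = max(chi2 * 2, 10.0)
        while sps.ncx2.cdf(chi2, df, hi) > prob:
            hi *= 2
            if hi > 1e8:
                break
        return brentq(lambda lam: sps.ncx2.cdf(chi2, df, lam) - prob, 1e-10, hi, xtol=1e-8)

    lam_lo = lam_for(1.0 - alpha / 2.0)
    lam_hi = lam_for(alpha / 2.0)
    ci = (float(np.sqrt(lam_lo / scale)), float(np.sqrt(lam_hi / scale)))
    return point, ci


def cfi_tli(chi2: float, df: int, chi2_baseline: float, df_baseline: int,
            clamp_tli: bool = False) -> tuple[float, float]:
    """Comparative Fit Index and Tucker-Lewis Index against the baseline.

    CFI floors both noncentrality estimates at zero; TLI is reported
    unclamped unless ``clamp_tli`` (it can exceed 1 for well-fitting models).
    """
    if df_baseline == 0:
        raise ValueError("baseline degrees of freedom must be positive")
    num = max(chi2 - df, 0.0)
    den = max(chi2_baseline - df_baseline, chi2 - df, 0.0)
    cfi = 1.0 if den == 0.0 else 1.0 - num / den
    cfi = float(min(max(cfi, 0.0), 1.0))
    rb = chi2_baseline / df_baseline
    rm = chi2 / df if df > 0 else np.inf
    tli = (rb - rm) / (rb - 1.0)
    if clamp_tli:
        tli = min(tli, 1.0)
    return cfi, float(tli)


def srmr(sample_mean: np.ndarray, sample_cov: np.ndarray,
         implied_mean: np.ndarray, implied_cov: np.ndarray) -> float:
    """Standardized root mean square residual over the lower triangle.

    Residuals are differences of correlation-metric entries,
    s_ij/sqrt(s_ii s_jj) - sigma_ij/sqrt(sigma_ii sigma_jj), including the
    diagonal (whose residuals are zero); mean residuals are excluded.
    Invariant to rescaling any observed variable.
    """
    S = np.asarray(sample_cov, float)
    Sig = np.asarray(implied_cov, float)
    if S.shape != Sig.shape:
        raise ValueError("moment matrices must share a variable order")
    if np.any(np.diag(S) <= 0) or np.any(~np.isfinite(np.diag(S))):
        raise ValueError("sample covariance has a non-positive diagonal")
    ds = np.sqrt(np.diag(S))
    dg = np.sqrt(np.diag(Sig))
    Rs = S / np.outer(ds, ds)
    Ri = Sig / np.outer(dg, dg)
    tril = np.tril_indices(S.shape[0])
    resid = (Rs - Ri)[tril]
    return float(np.sqrt(np.mean(resid ** 2)))


@dataclass
class FitIndexSet:
    """Chi-square and descriptive fit indices with adequacy flags."""

    chi2: float
    df: int
    p_value: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    cfi: float
    tli: float
    srmr: float
    n: int
    chi2_baseline: float = np.nan
    df_baseline: int = 0
    adequate: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=lambda: dict(ADEQUACY_THRESHOLDS))

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2, "df": self.df, "p_value": self.p_value,
            "rmsea": self.rmsea, "rmsea_ci": list(self.rmsea_ci),
            "cfi": self.cfi, "tli": self.tli, "srmr": self.srmr, "n": self.n,
            "chi2_baseline": self.chi2_baseline, "df_baseline": self.df_baseline,
            "adequate": dict(self.adequate), "thresholds": dict(self.thresholds),
        }


def adequacy(indices: FitIndexSet) -> dict:
    """Per-index adequacy flags, honoring the boundary conventions exactly:
    RMSEA and CFI/TLI thresholds are inclusive, the SRMR threshold strict."""
    th = indices.thresholds
    return {
        "rmsea": bool(indices.rmsea <= th["rmsea"]),
        "cfi": bool(indices.cfi >= th["cfi"]),
        "tli": bool(indices.tli >= th["tli"]),
        "srmr": bool(indices.srmr < th["srmr"]),
        "all": bool(indices.rmsea <= th["rmsea"] and indices.cfi >= th["cfi"]
                    and indices.tli >= th["tli"] and indices.srmr < th["srmr"]),
    }


def compute_fit_indices(result: FitResult, panel, coverage: float = 0.95,
                        clamp_tli: bool = False) -> FitIndexSet:
    """Evaluate all indices for a fitted model on its analysis panel.

    The saturated-model FIML estimates serve as the sample moments for SRMR,
    which keeps the index well-defined under missingness.
    """
    stats = _as_stats(panel)
    ll_sat, mu_s, Sigma_s = saturated_loglik(stats)
    ll_base, df_base = baseline_loglik(stats)
    df = result.index.df
    chi2, p = chi_square(result.loglik, ll_sat, df)
    chi2_b, _ = chi_square(ll_base, ll_sat, df_base)
    point, ci = rmsea(chi2, df, stats.n, coverage=coverage)
    cfi, tli = cfi_tli(chi2, df, chi2_b, df_base, clamp_tli=clamp_tli)
    from .model import implied_moments
    mu_i, Sigma_i = implied_moments(result.params)
    s = srmr(mu_s, Sigma_s, mu_i, Sigma_i)
    out = FitIndexSet(chi2=chi2, df=df, p_value=p, rmsea=point, rmsea_ci=ci,
                      cfi=cfi, tli=tli, srmr=s, n=stats.n,
                      chi2_baseline=chi2_b, df_baseline=df_base)
    out.adequate = adequacy(out)
    return out
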