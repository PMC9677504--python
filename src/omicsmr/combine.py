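"""Gene-level combination of per-exposure MR P-values.

A gene is interrogated once per omic exposure (expression, protein,
metabolite, ...), giving m P-values that are generally *dependent*: the
exposures share instruments and often share biology, so the underlying GLS
z-statistics are correlated. The combiners differ in how they handle that
dependence:

* :func:`combine_cauchy` — Cauchy combination (ACAT); valid under arbitrary
  dependence.
* :func:`combine_hmp` — harmonic-mean P-value calibrated against the
  one-sided stable (Landau) law with tail index λ = β = 1; valid under
  arbitrary dependence, slightly more conservative than Cauchy.
* :func:`combine_minp` — minimum P-value taken as the combined P, with no
  multiplicity or dependence correction; anti-conservative, retained only
  for benchmarking.
* :func:`combine_fisher_chisq` — Fisher's −2Σln p against χ²(2m); exact
  under independence, anti-conservative under positive dependence.
* :func:`combine_fisher_gamma` — Fisher's statistic against a
  moment-matched gamma null whose variance is inflated by the Brown/Kost
  polynomial in the pairwise correlations of the GLS z-statistics
  (estimated by :func:`gls_z_correlation` from the LD matrix alone).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate, stats

from .core_data import CombinedResult, LDMatrix, SummaryStats, ValidationError
from .engines import _solve_spd

logger = logging.getLogger("omicsmr")

__all__ = [
    "ZCorrelation",
    "combine_cauchy",
    "combine_hmp",
    "combine_minp",
    "combine_fisher_chisq",
    "combine_fisher_gamma",
    "gls_z_correlation",
    "landau_sf",
]

_EULER_GAMMA = 0.5772156649015329


def _check_pvals(pvals, open_unit: bool = True) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("need a non-empty 1-D array of P-values")
    if open_unit:
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValidationError("P-values must lie strictly in (0, 1)")
    else:
        if np.any(p <= 0) or np.any(p > 1):
            raise ValidationError("P-values must lie in (0, 1]")
    return p


def _check_weights(weights, m: int) -> np.ndarray:
    if weights is None:
        return np.full(m, 1.0 / m)
    w = np.asarray(weights, dtype=float)
    if w.shape != (m,):
        raise ValidationError("weights must match the number of P-values")
    if np.any(w <= 0):
        raise ValidationError("weights must be strictly positive")
    return w


def combine_cauchy(pvals, weights=None) -> CombinedResult:
    """Cauchy combination test (ACAT).

        T = Σ_k w_k tan{(0.5 − p_k) π},
        P = 0.5 − arctan(T / Σw) / π.

    Valid for arbitrarily dependent P-values. For very large T the arctan
    form loses precision and the tail expansion P ≈ (Σw)/(Tπ) is used; for
    p_k below ~1e-16 the tangent overflows and the per-term tail
    w_k/(p_k π) is substituted.
    """
    p = _check_pvals(pvals)
    w = _check_weights(weights, len(p))
    small = p < 1e-16
    terms = np.empty_like(p)
    terms[~small] = w[~small] * np.tan((0.5 - p[~small]) * np.pi)
    terms[small] = w[small] / (p[small] * np.pi)
    t_stat = float(np.sum(terms))
    wsum = float(np.sum(w))
    if t_stat / wsum > 1e15:
        pval = wsum / (t_stat * np.pi)
    else:
        pval = 0.5 - np.arctan(t_stat / wsum) / np.pi
    return CombinedResult(pval=float(min(max(pval, np.nextafter(0, 1)), 1.0)),
                          statistic=t_stat, method="cauchy", weights=w, m=len(p))


def landau_sf(x: float) -> float:
    """Survival function of the standard Landau distribution.

    The one-sided stable law with index α = 1, skewness β = 1 arising as the
    limit of centered means of Pareto(1) variables:

        SF(x) = (1/π) ∫₀^∞ exp(−t ln t − x t) sin(π t) / t dt.

    Matches ``scipy.stats.levy_stable(α=1, β=1, loc=ln(π/2), scale=π/2)``
    (S1 parameterization) but is ~100× faster and stable in the far tail.
    """
    x = float(x)
    if x > 1e120:
        return 1.0 / x  # asymptotic Pareto tail
    if x < -3.0:
        # left tail decays doubly-exponentially; SF(-3) > 0.99991 and the
        # quadrature integrand overflows there
        return 1.0
    def integrand(t):
        return np.exp(-t * np.log(t) - x * t) * np.sin(np.pi * t) / t
    if x > 40:
        # integrand mass concentrates near t = 0; avoid oscillatory roundoff
        val, _ = integrate.quad(integrand, 0, 400.0 / x, limit=200)
    else:
        val, _ = integrate.quad(integrand, 0, np.inf, limit=500)
    return min(max(val / np.pi, 0.0), 1.0)


def combine_hmp(pvals, weights=None) -> CombinedResult:
    """Harmonic-mean P-value with the asymptotically exact stable-law tail.

    With weights normalized to Σw = 1,

        T_HMP = 1 / Σ_k (w_k / p_k),

    and under the null S = 1/T_HMP is asymptotically Landau with location
    ln m + 1 + ψ(1) − ln(2/π) and scale π/2, giving

        P = SF_Landau( S − ln m − (1 − γ) )

    in the standard-Landau coordinates of :func:`landau_sf`.
    """
    p = _check_pvals(pvals)
    m = len(p)
    w = _check_weights(weights, m)
    w = w / w.sum()
    s = float(np.sum(w / p))
    t_hmp = 1.0 / s
    pval = landau_sf(s - np.log(m) - (1.0 - _EULER_GAMMA))
    return CombinedResult(pval=float(min(max(pval, np.nextafter(0, 1)), 1.0)),
                          statistic=t_hmp, method="hmp", weights=w, m=m)


def combine_minp(pvals) -> CombinedResult:
    """Minimum P-value, reported as-is (no dependence or multiplicity
    correction); anti-conservative and kept only for benchmark parity."""
    p = _check_pvals(pvals, open_unit=False)
    m = len(p)
    t_min = float(np.min(p))
    return CombinedResult(pval=t_min, statistic=t_min, method="minp",
                          weights=np.full(m, 1.0 / m), m=m)


def combine_fisher_chisq(pvals) -> CombinedResult:
    """Fisher's combination: T = −2Σ ln p_k against χ²(2m).

    Exact for independent P-values; anti-conservative when they are
    positively dependent.
    """
    p = _check_pvals(pvals, open_unit=False)
    m = len(p)
    t_stat = float(-2.0 * np.sum(np.log(p)))
    pval = float(stats.chi2.sf(t_stat, df=2 * m))
    return CombinedResult(pval=float(min(max(pval, np.nextafter(0, 1)), 1.0)),
                          statistic=t_stat, method="fisher_chisq",
                          weights=np.full(m, 1.0 / m), m=m)


@dataclass
class ZCorrelation:
    """Correlation matrix of per-exposure GLS z-statistics."""

    labels: list[str]
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        m = len(self.labels)
        if self.rho.shape != (m, m):
            raise ValidationError("rho dimension must match labels")
        if np.max(np.abs(self.rho - self.rho.T)) > 1e-8:
            raise ValidationError("rho must be symmetric")
        if np.max(np.abs(np.diag(self.rho) - 1.0)) > 1e-8:
            raise ValidationError("rho diagonal must be 1")
        if np.max(np.abs(self.rho)) > 1.0 + 1e-6:
            raise ValidationError("|rho| must not exceed 1")
        clipped = np.clip(self.rho, -1.0, 1.0)
        if np.max(np.abs(clipped - self.rho)) > 0:
            logger.warning("ZCorrelation: |rho| marginally above 1 clamped to ±1")
        self.rho = (clipped + clipped.T) / 2.0
        np.fill_diagonal(self.rho, 1.0)


def gls_z_correlation(
    qtls: dict[str, SummaryStats],
    gwas: SummaryStats,
    ld: LDMatrix,
) -> ZCorrelation:
    """Correlation of the GLS z-statistics across exposures.

    Each exposure's GLS z-statistic is a linear functional of the GWAS
    z-score vector z_Y, whose covariance is approximated by the LD matrix R
    (first-order: instrument strength high enough that the QTL effect
    vector can be treated as fixed). Writing γ̂_Xk = β̂_Xk / σ̂_Y over
    exposure k's SNP set S_k and

        a_k = R_k⁻¹ γ̂_Xk / √(γ̂_Xkᵀ R_k⁻¹ γ̂_Xk),

    the covariance of two exposures' z-statistics is the sandwich

        cov(z_k1, z_k2) = a_k1ᵀ R[S_k1, S_k2] a_k2,

    needing only the LD submatrix over the two exposures' (clumped) SNP
    sets. Exposures may use different SNP subsets of ``ld``.
    """
    labels = list(qtls)
    m = len(labels)
    if m == 0:
        raise ValidationError("gls_z_correlation: no exposures supplied")
    weights: dict[str, np.ndarray] = {}
    for label in labels:
        qtl = qtls[label]
        sy = gwas.subset(qtl.snp_ids).se
        gamma = qtl.beta / sy
        r_sub = ld.submatrix(qtl.snp_ids).r
        r_inv = _solve_spd(r_sub, f"gls_z_correlation[{label}]", qtl.snp_ids)
        a = r_inv @ gamma
        norm = float(gamma @ a)
        if norm <= 0:
            raise ValidationError(f"gls_z_correlation: degenerate exposure {label}")
        weights[label] = a / np.sqrt(norm)
    rho = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            cross = ld.cross(qtls[labels[i]].snp_ids, qtls[labels[j]].snp_ids)
            rho[i, j] = rho[j, i] = float(weights[labels[i]] @ cross @ weights[labels[j]])
    return ZCorrelation(labels, rho)


def _brown_kost_var_term(rho: float) -> float:
    """Variance contribution c(ρ) of one correlated pair to Fisher's T.

    Cubic polynomial fit of cov(−2 ln p_i, −2 ln p_j) for two-sided
    P-values of bivariate-normal z-scores; applied to |ρ| since two-sided
    tests make the induced dependence symmetric in the sign of ρ. Exact
    anchors: c(0) = 0 and c(1) = 4 (perfect duplication).
    """
    a = abs(rho)
    return 3.263 * a + 0.710 * a ** 2 + 0.027 * a ** 3


def combine_fisher_gamma(pvals, zcorr: ZCorrelation) -> CombinedResult:
    """Fisher's combination with a gamma null adjusted for dependence.

    T = −2Σ ln p_k has null mean E = 2m and, for correlated underlying
    z-statistics, variance V = 4m + 2 Σ_{i<j} c(ρ_ij) with the Brown/Kost
    polynomial c(·). T is compared with the moment-matched gamma law
    (shape E²/V, scale V/E); at ρ ≡ 0 this is exactly χ²(2m).
    """
    p = _check_pvals(pvals, open_unit=False)
    m = len(p)
    if len(zcorr.labels) != m:
        raise ValidationError("zcorr dimension must match the number of P-values")
    t_stat = float(-2.0 * np.sum(np.log(p)))
    e_t = 2.0 * m
    var_t = 4.0 * m
    for i in range(m):
        for j in range(i + 1, m):
            var_t += 2.0 * _brown_kost_var_term(zcorr.rho[i, j])
    shape = e_t ** 2 / var_t
    scale = var_t / e_t
    pval = float(stats.gamma.sf(t_stat, a=shape, scale=scale))
    return CombinedResult(pval=float(min(max(pval, np.nextafter(0, 1)), 1.0)),
                          statistic=t_stat, method="fisher_gamma",
                          weights=np.full(m, 1.0 / m), m=m)
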