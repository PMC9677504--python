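"""Per-exposure Mendelian randomization estimators.

Each engine turns QTL summary statistics (exposure side) and GWAS summary
statistics (outcome side) into a causal-effect estimate with a P-value:

* :func:`ivw` — inverse-variance-weighted estimate, valid for uncorrelated
  instruments; algebraically the GLS estimate with an identity LD matrix.
* :func:`gls` — generalized least squares accounting for residual LD between
  instruments through the unsquared correlation matrix R.
* :func:`smr` / :func:`smr_multi` — single-SNP summary-data MR with the
  second-order chi-squared(1) statistic T = z_Y² z_X² / (z_Y² + z_X²).
* :func:`gsmr` — multi-SNP extension of SMR combining per-SNP Wald ratios
  with a second-order covariance matrix under LD.
* :func:`mvmr` — multivariable MR: a joint m-degree-of-freedom Wald test of
  all exposures' direct effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .core_data import LDMatrix, MRResult, SummaryStats, ValidationError, two_sided_p

logger = logging.getLogger("omicsmr")

__all__ = [
    "DegenerateInstrumentsError",
    "InsufficientInstrumentsError",
    "NearSingularError",
    "MVMRResult",
    "ivw",
    "gls",
    "smr",
    "smr_multi",
    "gsmr",
    "mvmr",
]

#: Reciprocal-condition-number threshold below which covariance matrices are
#: treated as numerically singular.
RCOND_MIN = 1e-10


class DegenerateInstrumentsError(ValidationError):
    """All instrument-exposure effects are zero; the Wald ratio is undefined."""


class InsufficientInstrumentsError(ValidationError):
    """Too few instruments survive filtering for the estimator to run."""


class NearSingularError(ValidationError):
    """A covariance matrix is numerically singular (e.g. duplicate SNPs)."""


def _check_aligned(qtl: SummaryStats, gwas: SummaryStats) -> None:
    if qtl.snp_ids != gwas.snp_ids:
        raise ValidationError(
            "QTL and GWAS summary statistics must cover the same SNPs in the "
            "same order; use SummaryStats.subset to align them"
        )


def _solve_spd(omega: np.ndarray, context: str, snp_ids: Optional[list[str]] = None) -> np.ndarray:
    """Inverse of a symmetric positive-definite matrix with a singularity guard."""
    eigvals = np.linalg.eigvalsh(omega)
    if eigvals[0] <= 0 or eigvals[0] / eigvals[-1] < RCOND_MIN:
        detail = ""
        if snp_ids is not None and len(snp_ids) > 1:
            # name the most collinear pair for the error message
            d = np.sqrt(np.diag(omega))
            corr = omega / np.outer(d, d)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
            detail = f" (most collinear pair: {snp_ids[i]}, {snp_ids[j]}, r={corr[i, j]:.4f})"
        raise NearSingularError(f"{context}: covariance matrix is numerically singular{detail}")
    return np.linalg.inv(omega)


def gls(qtl: SummaryStats, gwas: SummaryStats, ld: LDMatrix) -> MRResult:
    """Generalized least squares causal-effect estimate under LD.

    With Ω = diag(σ̂_Y) R diag(σ̂_Y),

        θ̂ = (β̂_Xᵀ Ω⁻¹ β̂_X)⁻¹ (β̂_Xᵀ Ω⁻¹ β̂_Y),   var(θ̂) = (β̂_Xᵀ Ω⁻¹ β̂_X)⁻¹.

    Reduces exactly to :func:`ivw` when R is the identity.
    """
    _check_aligned(qtl, gwas)
    sub = ld.submatrix(qtl.snp_ids)
    if np.all(qtl.beta == 0):
        raise DegenerateInstrumentsError("gls: all exposure effects are zero")
    sy = gwas.se
    omega = sy[:, None] * sub.r * sy[None, :]
    omega_inv = _solve_spd(omega, "gls", qtl.snp_ids)
    bx, by = qtl.beta, gwas.beta
    denom = float(bx @ omega_inv @ bx)
    theta = float(bx @ omega_inv @ by) / denom
    var = 1.0 / denom
    z = theta / np.sqrt(var)
    return MRResult(
        exposure_label=qtl.trait_label, theta=theta, var_theta=var,
        z=z, pval=float(two_sided_p(np.array(z))), method="gls",
        n_snps_used=len(qtl), snp_ids=list(qtl.snp_ids),
    )


def ivw(qtl: SummaryStats, gwas: SummaryStats) -> MRResult:
    """Inverse-variance-weighted causal-effect estimate (uncorrelated SNPs).

        θ̂ = Σ β̂_Xj β̂_Yj σ̂_Yj⁻² / Σ β̂_Xj² σ̂_Yj⁻²,   var(θ̂) = (Σ β̂_Xj² σ̂_Yj⁻²)⁻¹,

    i.e. the no-intercept weighted-least-squares slope of β̂_Y on β̂_X with
    weights σ̂_Y⁻². Implemented as :func:`gls` with R = I.
    """
    _check_aligned(qtl, gwas)
    res = gls(qtl, gwas, LDMatrix(list(qtl.snp_ids), np.eye(len(qtl))))
    res.method = "ivw"
    return res


def smr(
    z_x: float,
    z_y: float,
    beta_x: Optional[float] = None,
    beta_y: Optional[float] = None,
    exposure_label: str = "",
    snp_id: str = "",
) -> MRResult:
    """Single-SNP summary-data MR test.

        T = z_Y² z_X² / (z_Y² + z_X²)  ~  χ²(1) under the null.

    The Wald-ratio estimate β̂_Y/β̂_X is reported when betas are supplied.
    At z_X = z_Y = 0 the statistic is taken at its limit T = 0 (P = 1).
    """
    z_x, z_y = float(z_x), float(z_y)
    if not (np.isfinite(z_x) and np.isfinite(z_y)):
        raise ValidationError("smr: z-values must be finite")
    denom = z_x ** 2 + z_y ** 2
    t_stat = 0.0 if denom == 0 else (z_x ** 2) * (z_y ** 2) / denom
    pval = float(stats.chi2.sf(t_stat, df=1)) if t_stat > 0 else 1.0
    if beta_x is not None and beta_y is not None and beta_x != 0:
        theta = beta_y / beta_x
        # variance consistent with the reported chi-squared(1) statistic
        var = theta ** 2 / t_stat if t_stat > 0 else 1.0
        theta_out, var_out = theta, var
        z_out = theta / np.sqrt(var)
    else:
        # no effect-size scale available: report the signed sqrt statistic
        z_out = np.sign(z_x * z_y) * np.sqrt(t_stat) if t_stat > 0 else 0.0
        theta_out, var_out = z_out, 1.0
    return MRResult(
        exposure_label=exposure_label, theta=theta_out, var_theta=var_out,
        z=float(z_out), pval=pval, method="smr", n_snps_used=1,
        snp_ids=[snp_id] if snp_id else [],
    )


def smr_multi(
    qtls: dict[str, SummaryStats],
    gwas: SummaryStats,
    mode: str = "singleSNP",
) -> dict[str, list[MRResult]]:
    """SMR across exposures.

    ``singleSNP``: for each exposure, the SNP with the strongest QTL
    (largest |z_X|) is tested. ``allSNPs``: every SNP × exposure pair is
    tested and all results returned, tagged by exposure and SNP.
    """
    if mode not in ("singleSNP", "allSNPs"):
        raise ValidationError(f"smr_multi: unknown mode {mode!r}")
    out: dict[str, list[MRResult]] = {}
    for label, qtl in qtls.items():
        if len(qtl) == 0:  # defensive; SummaryStats forbids empty
            logger.warning("smr_multi: exposure %s has no SNPs, skipped", label)
            continue
        aligned = gwas.subset(qtl.snp_ids)
        if mode == "singleSNP":
            j = int(np.argmax(np.abs(qtl.z)))
            out[label] = [smr(qtl.z[j], aligned.z[j], qtl.beta[j], aligned.beta[j],
                              exposure_label=label, snp_id=qtl.snp_ids[j])]
        else:
            out[label] = [
                smr(qtl.z[j], aligned.z[j], qtl.beta[j], aligned.beta[j],
                    exposure_label=label, snp_id=qtl.snp_ids[j])
                for j in range(len(qtl))
            ]
    return out


def _gsmr_cov(
    bx: np.ndarray, by: np.ndarray,
    vx: np.ndarray, vy: np.ndarray,
    r: np.ndarray,
) -> np.ndarray:
    """Second-order covariance matrix of per-SNP Wald ratios under LD.

    Diagonal:
        var(θ̂_j) = (β̂_Yj²/β̂_Xj²) [ var(β̂_Xj)/β̂_Xj² + var(β̂_Yj)/β̂_Yj²
                                      − var(β̂_Xj)²/β̂_Xj⁴ ]
    Off-diagonal:
        cov(θ̂_i, θ̂_j) = r_ij √(var(β̂_Yi) var(β̂_Yj)) / (β̂_Xi β̂_Xj)
            + (β̂_Yi β̂_Yj)/(β̂_Xi β̂_Xj) [ r_ij √(var(β̂_Xi) var(β̂_Xj))
              / (β̂_Xi β̂_Xj) − var(β̂_Xi) var(β̂_Xj) / (β̂_Xi² β̂_Xj²) ]
    """
    ratio = by / bx
    var_diag = ratio ** 2 * (vx / bx ** 2 + vy / by ** 2 - vx ** 2 / bx ** 4)
    bxo = np.outer(bx, bx)
    term1 = r * np.sqrt(np.outer(vy, vy)) / bxo
    term2 = np.outer(by, by) / bxo * (
        r * np.sqrt(np.outer(vx, vx)) / bxo - np.outer(vx, vx) / bxo ** 2
    )
    cov = term1 + term2
    np.fill_diagonal(cov, var_diag)
    return cov


def gsmr(
    qtl: SummaryStats,
    gwas: SummaryStats,
    ld: LDMatrix,
    r2_filter: float = 0.95,
    chi2_filter: float = 10.0,
    min_snps: int = 10,
) -> MRResult:
    """Generalized summary-data MR over multiple (possibly correlated) SNPs.

    SNPs are filtered to pairwise r² < ``r2_filter`` (greedy in descending
    instrument strength |z_X|) and instrument strength z_X² > ``chi2_filter``;
    the surviving per-SNP Wald ratios are pooled by GLS against their
    second-order covariance matrix V:

        θ̂ = (1ᵀV⁻¹1)⁻¹ 1ᵀV⁻¹ θ̂_snp,  var(θ̂) = (1ᵀV⁻¹1)⁻¹,
        T = θ̂²/var(θ̂)  ~  χ²(1).

    Raises :class:`InsufficientInstrumentsError` when fewer than ``min_snps``
    SNPs survive.
    """
    _check_aligned(qtl, gwas)
    keep = np.flatnonzero(qtl.z ** 2 > chi2_filter)
    # greedy r² pruning, strongest instruments first
    sub_all = ld.submatrix(qtl.snp_ids).r
    order = keep[np.argsort(-np.abs(qtl.z[keep]), kind="stable")]
    chosen: list[int] = []
    for i in order:
        if all(sub_all[i, j] ** 2 < r2_filter for j in chosen):
            chosen.append(int(i))
    chosen.sort()
    if len(chosen) < max(min_snps, 1):
        raise InsufficientInstrumentsError(
            f"gsmr[{qtl.trait_label}]: {len(chosen)} SNP(s) survive filtering "
            f"(min_snps={min_snps})"
        )
    idx = np.array(chosen, dtype=int)
    bx, by = qtl.beta[idx], gwas.beta[idx]
    if np.any(bx == 0) or np.any(by == 0):
        raise DegenerateInstrumentsError("gsmr: zero effect among filtered SNPs")
    vx, vy = qtl.se[idx] ** 2, gwas.se[idx] ** 2
    r_sub = sub_all[np.ix_(idx, idx)]
    cov = _gsmr_cov(bx, by, vx, vy, r_sub)
    snp_ids = [qtl.snp_ids[i] for i in idx]
    cov_inv = _solve_spd(cov, "gsmr", snp_ids)
    ones = np.ones(len(idx))
    denom = float(ones @ cov_inv @ ones)
    theta = float(ones @ cov_inv @ (by / bx)) / denom
    var = 1.0 / denom
    t_stat = theta ** 2 / var
    return MRResult(
        exposure_label=qtl.trait_label, theta=theta, var_theta=var,
        z=theta / np.sqrt(var), pval=float(stats.chi2.sf(t_stat, df=1)),
        method="gsmr", n_snps_used=len(idx), snp_ids=snp_ids,
    )


@dataclass
class MVMRResult:
    """Joint multivariable-MR result: direct effects and an m-df Wald test."""

    exposure_labels: list[str]
    thetas: np.ndarray
    cov_theta: np.ndarray
    joint_stat: float
    df: int
    pval: float
    status: str = "ok"

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=float)
        if self.status == "ok":
            if self.df != len(self.thetas):
                raise ValidationError("df must equal the number of exposures")
            if not (0 < self.pval <= 1):
                raise ValidationError("pval must lie in (0, 1]")


def mvmr(
    qtls: dict[str, SummaryStats],
    gwas: SummaryStats,
    ld: Optional[LDMatrix] = None,
) -> MVMRResult:
    """Multivariable MR: joint test that every exposure's direct effect is 0.

    Fits the no-intercept weighted regression β̂_Y ~ Σ_k θ_k β̂_Xk with
    weights σ̂_Y⁻² (GLS with Ω = diag(σ̂_Y) R diag(σ̂_Y) when an LD matrix is
    supplied) and tests θ₁ = … = θ_m = 0 with the m-df Wald statistic
    θ̂ᵀ cov(θ̂)⁻¹ θ̂. Requires more instruments than exposures; otherwise
    ``status = "insufficient_ivs"`` is returned instead of an estimate.
    """
    labels = list(qtls)
    m = len(labels)
    if m == 0:
        raise ValidationError("mvmr: no exposures supplied")
    snp_ids = gwas.snp_ids
    for label in labels:
        _check_aligned(qtls[label], gwas)
    p = len(snp_ids)
    design = np.column_stack([qtls[label].beta for label in labels])
    if p < m + 1 or np.linalg.matrix_rank(design) < m:
        return MVMRResult(labels, np.full(m, np.nan), np.full((m, m), np.nan),
                          np.nan, m, np.nan, status="insufficient_ivs")
    sy = gwas.se
    if ld is None:
        omega_inv = np.diag(1.0 / sy ** 2)
    else:
        sub = ld.submatrix(snp_ids)
        omega = sy[:, None] * sub.r * sy[None, :]
        omega_inv = _solve_spd(omega, "mvmr", snp_ids)
    xtwx = design.T @ omega_inv @ design
    xtwx_inv = _solve_spd(xtwx, "mvmr design")
    thetas = xtwx_inv @ design.T @ omega_inv @ gwas.beta
    joint = float(thetas @ xtwx @ thetas)
    pval = float(stats.chi2.sf(joint, df=m))
    return MVMRResult(labels, thetas, xtwx_inv, joint, m, max(pval, np.nextafter(0, 1)))
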