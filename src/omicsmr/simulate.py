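"""Generative benchmark model: genotypes, multi-omics exposures, outcomes.

The generator emulates a gene-scale multi-omics MR study. For each subject,
``p`` cis-SNP dosages are drawn Binomial(2, 0.3) with a configurable pairwise
LD target r²; three omics biomarkers X₁, X₂, X₃ are built from the SNPs, a
shared standard-normal confounder U and unit noise, under one of two causal
architectures:

vertical pleiotropy (exposures in series)::

    X₁ = (α/p) Σ_j Z_j + U + ε₁
    X₂ = 2 X₁ − U + ε₂
    X₃ = −0.5 X₂ + U + ε₃
    Y_C = β_X X₃ − U + ε_Y            logit P(Y_B=1) = −2 + β_X X₃ − U

horizontal pleiotropy (exposures in parallel)::

    X₁ = (α/p) Σ_{j=1..p} Z_j + U + ε₁
    X₂ = −(α/p) Σ_{j=1..⌊p/2⌋} Z_j − U + ε₂
    X₃ = (α/p) Σ_{j=⌊p/2⌋+1..p} Z_j − U + ε₃
    Y_C = β_X Σ_k X_k + U + ε_Y       logit P(Y_B=1) = −2 + β_X Σ_k X_k + U

Summary statistics are then computed exactly as a practitioner would: per-SNP
simple linear regressions for the QTLs (and for a continuous outcome) on the
respective study samples, per-SNP logistic regressions for a binary outcome,
and the empirical unsquared dosage correlation matrix as the LD estimate.
The degree of subject overlap between the QTL and GWAS samples is
configurable, reproducing one-sample/two-sample designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Optional

import numpy as np
import yaml
from scipy import optimize, stats

from .core_data import LDMatrix, SummaryStats, ValidationError

logger = logging.getLogger("omicsmr")

__all__ = [
    "SimulationConfig",
    "ReplicateData",
    "simulate_genotypes",
    "simulate_replicate",
    "compute_summary",
]

EXPOSURE_LABELS = ("X1", "X2", "X3")


@dataclass
class SimulationConfig:
    """Parameters of one simulation setting.

    Attributes
    ----------
    pleiotropy
        ``"vertical"`` (exposures in series) or ``"horizontal"`` (parallel).
    p
        Number of cis-SNPs used as instruments (5 or 20 in the benchmark).
    r2
        Target pairwise squared LD between SNPs (0, 0.01 or 0.2).
    alpha
        Instrument strength: total genetic effect on X₁ is α/p per SNP
        (0.5 weak, 1 moderate, 2 strong).
    beta_x
        Causal (pleiotropic) effect of the exposure block on the outcome;
        0 for type-I-error settings, 0.1 for power settings.
    outcome
        ``"continuous"`` or ``"binary"`` (case/control with logit
        intercept −2).
    overlap
        Fraction of QTL-study subjects shared with the GWAS study
        (0 two-sample, 1 one-sample).
    shared_qtl_samples
        Whether all three omics QTLs are computed on the same subject
        sample; independent per-omic samples require ``overlap = 0``.
    controls_only_qtl
        Binary outcome only: restrict the QTL sample to control subjects.
    n_per_arm
        Cases and controls per arm for a binary outcome (GWAS sample is
        2·n_per_arm; the QTL sample n_per_arm controls). Continuous studies
        use 2·n_per_arm subjects each.
    population_n
        Size of the oversampled population from which binary-outcome arms
        are drawn.
    maf
        Minor-allele frequency of every SNP.
    snp_effect_mode
        ``"constant"`` (all loadings α/p) or ``"beta_distributed"``
        (iid Beta(beta_a, beta_b) loadings scaled by α/p).
    """

    pleiotropy: str = "vertical"
    p: int = 5
    r2: float = 0.2
    alpha: float = 1.0
    beta_x: float = 0.0
    outcome: str = "continuous"
    overlap: float = 0.0
    shared_qtl_samples: bool = True
    controls_only_qtl: bool = False
    n_per_arm: int = 250
    population_n: int = 5000
    maf: float = 0.3
    snp_effect_mode: str = "constant"
    beta_a: float = 1.0
    beta_b: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pleiotropy not in ("vertical", "horizontal"):
            raise ValidationError(f"unknown pleiotropy model {self.pleiotropy!r}")
        if self.outcome not in ("continuous", "binary"):
            raise ValidationError(f"unknown outcome type {self.outcome!r}")
        if self.snp_effect_mode not in ("constant", "beta_distributed"):
            raise ValidationError(f"unknown snp_effect_mode {self.snp_effect_mode!r}")
        if self.p < 1:
            raise ValidationError("p must be at least 1")
        if not (0.0 <= self.r2 < 1.0):
            raise ValidationError("r2 must lie in [0, 1)")
        if not (0.0 < self.maf <= 0.5):
            raise ValidationError("maf must lie in (0, 0.5]")
        if not (0.0 <= self.overlap <= 1.0):
            raise ValidationError("overlap must lie in [0, 1]")
        if not self.shared_qtl_samples and self.overlap != 0.0:
            raise ValidationError(
                "independent per-omic QTL samples are defined only for the "
                "two-sample setting (overlap = 0)"
            )
        if self.controls_only_qtl and self.outcome != "binary":
            raise ValidationError("controls_only_qtl applies to binary outcomes only")

    @property
    def n_study(self) -> int:
        """Subjects in one continuous-outcome study (GWAS or one omic's QTL)."""
        return 2 * self.n_per_arm

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: expected a key: value mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


@dataclass
class ReplicateData:
    """One simulated cohort: individual-level data plus study membership."""

    genotypes: np.ndarray            # (n, p) dosages in {0, 1, 2}
    exposures: np.ndarray            # (n, 3) omics biomarkers X1..X3
    confounder: np.ndarray           # (n,) shared confounder U
    outcome: np.ndarray              # (n,) continuous, or 0/1 for binary
    gwas_idx: np.ndarray             # subject indices of the GWAS sample
    qtl_idx: dict[str, np.ndarray] = field(default_factory=dict)  # per exposure

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]


# ---------------------------------------------------------------------------
# Correlated genotypes via a Gaussian copula on haplotypes
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _latent_correlation(maf: float, r_target: float) -> float:
    """Latent normal correlation reproducing a Bernoulli(maf) correlation.

    Each haplotype allele is 1 when its latent normal falls below
    Φ⁻¹(maf); the dosage (sum of two iid haplotypes) then inherits the
    haplotype correlation exactly, with Binomial(2, maf) marginals.
    """
    if r_target == 0.0:
        return 0.0
    z = stats.norm.ppf(maf)

    def bernoulli_corr(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf([z, z], mean=[0, 0],
                                            cov=[[1, rho], [rho, 1]])
        return (p11 - maf ** 2) / (maf * (1 - maf))

    hi = 1.0 - 1e-9
    if bernoulli_corr(hi) < r_target:
        raise ValidationError(
            f"target dosage correlation {r_target:.3f} infeasible for maf {maf}")
    return float(optimize.brentq(lambda r: bernoulli_corr(r) - r_target,
                                 -hi, hi, xtol=1e-10))


def simulate_genotypes(
    rng: np.random.Generator,
    n: int,
    p: int,
    maf: float = 0.3,
    r2: float = 0.0,
) -> np.ndarray:
    """Draw an (n, p) dosage matrix with Binomial(2, maf) marginals and
    equicorrelated pairwise dosage correlation √r2."""
    if not (0.0 <= r2 < 1.0):
        raise ValidationError("r2 must lie in [0, 1)")
    if not (0.0 < maf <= 0.5):
        raise ValidationError("maf must lie in (0, 0.5]")
    r_target = float(np.sqrt(r2))
    rho = _latent_correlation(maf, r_target)
    z_thresh = stats.norm.ppf(maf)
    if rho == 0.0:
        latent = rng.standard_normal((2, n, p))
    else:
        shared = rng.standard_normal((2, n, 1))
        indep = rng.standard_normal((2, n, p))
        latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep
    return np.sum(latent < z_thresh, axis=0).astype(np.int8)


# ---------------------------------------------------------------------------
# Structural model
# ---------------------------------------------------------------------------

def _snp_loadings(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    base = config.alpha / config.p
    if config.snp_effect_mode == "constant":
        return np.full(config.p, base)
    return base * rng.beta(config.beta_a, config.beta_b, size=config.p)


def _structural(
    config: SimulationConfig,
    geno: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exposures, confounder and linear predictor of the outcome."""
    n, p = geno.shape
    u = rng.standard_normal(n)
    eps = rng.standard_normal((n, 4))
    load = _snp_loadings(config, rng)
    half = p // 2
    if config.pleiotropy == "vertical":
        x1 = geno @ load + u + eps[:, 0]
        x2 = 2.0 * x1 - u + eps[:, 1]
        x3 = -0.5 * x2 + u + eps[:, 2]
        lin = config.beta_x * x3 - u
    else:
        x1 = geno @ load + u + eps[:, 0]
        x2 = -geno[:, :half] @ load[:half] - u + eps[:, 1]
        x3 = geno[:, half:] @ load[half:] - u + eps[:, 2]
        lin = config.beta_x * (x1 + x2 + x3) + u
    exposures = np.column_stack([x1, x2, x3])
    return exposures, u, lin


def _overlapping_sample(
    rng: np.random.Generator,
    reference: np.ndarray,
    pool: np.ndarray,
    size: int,
    overlap: float,
) -> np.ndarray:
    """Draw ``size`` subjects sharing ``overlap``·size members with
    ``reference``; the remainder comes from ``pool`` minus reference."""
    n_shared = int(round(overlap * size))
    shared = rng.choice(reference, size=n_shared, replace=False) if n_shared else np.array([], dtype=int)
    fresh_pool = np.setdiff1d(pool, reference, assume_unique=False)
    n_fresh = size - n_shared
    if len(fresh_pool) < n_fresh:
        raise ValidationError(
            f"population exhausted: need {n_fresh} fresh subjects, have "
            f"{len(fresh_pool)}; increase population_n"
        )
    fresh = rng.choice(fresh_pool, size=n_fresh, replace=False) if n_fresh else np.array([], dtype=int)
    return np.sort(np.concatenate([shared, fresh]).astype(int))


def simulate_replicate(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> ReplicateData:
    """Simulate one cohort and assign GWAS/QTL study membership.

    Continuous outcome: a population of 2·n_per_arm GWAS subjects plus
    enough fresh subjects for the QTL sample(s) at the configured overlap.
    Binary outcome: a population of ``population_n`` subjects is oversampled,
    n_per_arm cases + n_per_arm controls form the GWAS sample, and the QTL
    sample is n_per_arm subjects (controls when ``controls_only_qtl``) with
    the configured overlap against the corresponding GWAS subjects.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_qtl_samples = 1 if config.shared_qtl_samples else 3

    if config.outcome == "continuous":
        n_study = config.n_study
        extra = (n_study - int(round(config.overlap * n_study))) * n_qtl_samples
        n_pop = n_study + extra
        geno = simulate_genotypes(rng, n_pop, config.p, config.maf, config.r2)
        exposures, u, lin = _structural(config, geno, rng)
        outcome = lin + rng.standard_normal(n_pop)
        gwas_idx = np.arange(n_study)
        pool = np.arange(n_pop)
        if config.shared_qtl_samples:
            qtl = _overlapping_sample(rng, gwas_idx, pool, n_study, config.overlap)
            qtl_idx = {lab: qtl for lab in EXPOSURE_LABELS}
        else:
            qtl_idx = {}
            used = gwas_idx.copy()
            for lab in EXPOSURE_LABELS:
                sample = _overlapping_sample(rng, used, pool, n_study, 0.0)
                qtl_idx[lab] = sample
                used = np.union1d(used, sample)
        return ReplicateData(geno, exposures, u, outcome, gwas_idx, qtl_idx)

    # binary outcome: oversample, then fill case/control quotas
    n_pop = config.population_n
    geno = simulate_genotypes(rng, n_pop, config.p, config.maf, config.r2)
    exposures, u, lin = _structural(config, geno, rng)
    tau = 1.0 / (1.0 + np.exp(-(-2.0 + lin)))
    outcome = (rng.uniform(size=n_pop) < tau).astype(np.int8)
    cases = np.flatnonzero(outcome == 1)
    controls = np.flatnonzero(outcome == 0)
    n_arm = config.n_per_arm
    if len(cases) < n_arm or len(controls) < n_arm:
        raise ValidationError(
            f"population exhausted: {len(cases)} cases / {len(controls)} controls "
            f"for quota {n_arm}; increase population_n"
        )
    gwas_cases = rng.choice(cases, size=n_arm, replace=False)
    gwas_controls = rng.choice(controls, size=n_arm, replace=False)
    gwas_idx = np.sort(np.concatenate([gwas_cases, gwas_controls]))
    if config.controls_only_qtl:
        reference, pool = np.sort(gwas_controls), controls
    else:
        reference, pool = gwas_idx, np.arange(n_pop)
    if config.shared_qtl_samples:
        qtl = _overlapping_sample(rng, reference, pool, n_arm, config.overlap)
        qtl_idx = {lab: qtl for lab in EXPOSURE_LABELS}
    else:
        qtl_idx = {}
        used = reference.copy()
        for lab in EXPOSURE_LABELS:
            sample = _overlapping_sample(rng, used, pool, n_arm, 0.0)
            qtl_idx[lab] = sample
            used = np.union1d(used, sample)
    return ReplicateData(geno, exposures, u, outcome, gwas_idx, qtl_idx)


# ---------------------------------------------------------------------------
# Summary-statistics computation
# ---------------------------------------------------------------------------

def _ols_per_snp(y: np.ndarray, geno: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form simple linear regression of y on each SNP column.

    Returns (slopes, standard errors, mask of estimable SNPs); a SNP is not
    estimable when monomorphic in the sample.
    """
    n = len(y)
    zc = geno - geno.mean(axis=0)
    yc = y - y.mean()
    szz = np.sum(zc ** 2, axis=0)
    ok = szz > 0
    szy = zc.T @ yc
    slope = np.where(ok, szy / np.where(ok, szz, 1.0), np.nan)
    rss = np.sum(yc ** 2) - np.where(ok, slope * szy, 0.0)
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.where(ok, np.sqrt(sigma2 / np.where(ok, szz, 1.0)), np.nan)
    ok = ok & (se > 0)
    return slope, se, ok


def _logistic_per_snp(
    y: np.ndarray, geno: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP logistic regression logit(y) ~ intercept + dosage.

    Newton-Raphson on the 2-parameter likelihood; non-converged or
    monomorphic SNPs are flagged out.
    """
    n, p = geno.shape
    slopes = np.full(p, np.nan)
    ses = np.full(p, np.nan)
    ok = np.zeros(p, dtype=bool)
    ybar = y.mean()
    if ybar <= 0 or ybar >= 1:
        return slopes, ses, ok
    b0_init = np.log(ybar / (1 - ybar))
    for j in range(p):
        zj = geno[:, j].astype(float)
        if zj.min() == zj.max():
            continue
        beta = np.array([b0_init, 0.0])
        X = np.column_stack([np.ones(n), zj])
        converged = False
        for _ in range(max_iter):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            grad = X.T @ (y - mu)
            hess = (X * w[:, None]).T @ X
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                break
            beta = beta + step
            if np.max(np.abs(step)) < tol:
                converged = True
                break
        if not converged:
            logger.warning("logistic fit did not converge for SNP %d; flagged", j)
            continue
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        hess = (X * w[:, None]).T @ X
        cov = np.linalg.inv(hess)
        slopes[j] = beta[1]
        ses[j] = np.sqrt(cov[1, 1])
        ok[j] = ses[j] > 0
    return slopes, ses, ok


def compute_summary(
    replicate: ReplicateData,
    config: SimulationConfig,
) -> tuple[dict[str, SummaryStats], SummaryStats, LDMatrix]:
    """Summary statistics of one replicate, as fed to the MR engines.

    Per SNP and exposure: simple linear regression X_k ~ Z_j on that
    exposure's QTL sample. Per SNP: linear (continuous) or logistic
    (binary) regression of the outcome on Z_j over the GWAS sample. The LD
    matrix is the empirical unsquared dosage correlation over all genotyped
    subjects in the replicate (the largest available reference). SNPs that
    are monomorphic in any involved subsample are excluded everywhere, with
    a warning.
    """
    p = replicate.genotypes.shape[1]
    snp_ids = [f"snp{j + 1}" for j in range(p)]
    geno_gwas = replicate.genotypes[replicate.gwas_idx].astype(float)
    y = replicate.outcome[replicate.gwas_idx].astype(float)
    if config.outcome == "binary":
        by, sy, ok_y = _logistic_per_snp(y, geno_gwas)
    else:
        by, sy, ok_y = _ols_per_snp(y, geno_gwas)

    raw: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    keep = ok_y.copy()
    for k, lab in enumerate(EXPOSURE_LABELS):
        idx = replicate.qtl_idx[lab]
        bx, sx, ok_x = _ols_per_snp(replicate.exposures[idx, k],
                                    replicate.genotypes[idx].astype(float))
        raw[lab] = (bx, sx)
        keep &= ok_x

    if not np.all(keep):
        dropped = [snp_ids[j] for j in np.flatnonzero(~keep)]
        logger.warning("compute_summary: excluding non-estimable SNP(s) %s", dropped)
    if not np.any(keep):
        raise ValidationError("compute_summary: no estimable SNPs")
    kept_ids = [snp_ids[j] for j in np.flatnonzero(keep)]

    n_qtl = {lab: len(replicate.qtl_idx[lab]) for lab in EXPOSURE_LABELS}
    qtls = {
        lab: SummaryStats(kept_ids, raw[lab][0][keep], raw[lab][1][keep],
                          n=n_qtl[lab], trait_label=lab)
        for lab in EXPOSURE_LABELS
    }
    gwas = SummaryStats(kept_ids, by[keep], sy[keep],
                        n=len(replicate.gwas_idx), trait_label="GWAS")

    # LD reference: all genotyped subjects in the replicate (the largest
    # sample available, as a practitioner would use a reference panel)
    gk = replicate.genotypes.astype(float)[:, keep]
    sd = gk.std(axis=0, ddof=1)
    zstd = (gk - gk.mean(axis=0)) / sd
    r_emp = (zstd.T @ zstd) / (gk.shape[0] - 1)
    r_emp = np.clip((r_emp + r_emp.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r_emp, 1.0)
    ld = LDMatrix(kept_ids, r_emp)
    return qtls, gwas, ld
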