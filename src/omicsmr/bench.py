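"""Gene-level analysis paths and the simulation benchmark.

:func:`analyze_gene` wires one engine × combiner pair end to end for a single
gene: optional per-exposure LD clumping, a per-exposure MR test, and a
gene-level combination P-value. :func:`run_benchmark` replays that path over
simulated replicates of configurable study designs and records empirical
rejection rates at a nominal level — the type-I-error / power benchmark.

Engine/combiner compatibility: Fisher's gamma-approximated combination needs
the correlation of the underlying z-statistics, which is only derivable for
the GLS engine; multivariable MR is itself a joint test and takes no
combiner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .combine import (
    combine_cauchy,
    combine_fisher_chisq,
    combine_fisher_gamma,
    combine_hmp,
    combine_minp,
    gls_z_correlation,
)
from .core_data import (
    CombinedResult,
    LDMatrix,
    MRResult,
    SummaryStats,
    ValidationError,
    ld_clump,
)
from .engines import (
    DegenerateInstrumentsError,
    InsufficientInstrumentsError,
    NearSingularError,
    MVMRResult,
    gls,
    gsmr,
    ivw,
    mvmr,
    smr_multi,
)
from .simulate import SimulationConfig, compute_summary, simulate_replicate

logger = logging.getLogger("omicsmr")

__all__ = [
    "ENGINES",
    "COMBINERS",
    "GeneAnalysis",
    "BenchmarkResult",
    "analyze_gene",
    "run_benchmark",
    "benchmark_to_frame",
    "parse_method_label",
]

ENGINES = ("ivw", "gls", "smr_singleSNP", "smr_allSNPs", "gsmr", "mvmr")
COMBINERS = ("cauchy", "hmp", "minp", "fisher_chisq", "fisher_gamma")

_RECOVERABLE = (InsufficientInstrumentsError, NearSingularError,
                DegenerateInstrumentsError)


@dataclass
class GeneAnalysis:
    """Outcome of one gene-level analysis with full provenance."""

    engine: str
    combiner: Optional[str]
    combined: Optional[CombinedResult]
    per_exposure: dict[str, list[MRResult]] = field(default_factory=dict)
    mvmr_result: Optional[MVMRResult] = None
    snps_used: dict[str, list[str]] = field(default_factory=dict)
    dropped_exposures: dict[str, str] = field(default_factory=dict)

    @property
    def pval(self) -> Optional[float]:
        if self.mvmr_result is not None:
            return None if self.mvmr_result.status != "ok" else self.mvmr_result.pval
        return None if self.combined is None else self.combined.pval


def _validate_pair(engine: str, combiner: Optional[str]) -> None:
    if engine not in ENGINES:
        raise ValidationError(f"unknown engine {engine!r}; choose from {ENGINES}")
    if engine == "mvmr":
        return  # joint test; combiner ignored
    if combiner not in COMBINERS:
        raise ValidationError(f"unknown combiner {combiner!r}; choose from {COMBINERS}")
    if combiner == "fisher_gamma" and engine != "gls":
        raise ValidationError(
            "incompatible engine/combiner pair: the gamma-approximated Fisher "
            "combination requires the GLS engine (the z-statistic correlation "
            "is only derived for GLS); valid pairs are any engine with "
            "cauchy/hmp/minp/fisher_chisq, and gls with fisher_gamma"
        )


def analyze_gene(
    qtls: dict[str, SummaryStats],
    gwas: SummaryStats,
    ld: LDMatrix,
    engine: str = "gls",
    combiner: Optional[str] = "cauchy",
    *,
    clump_r2: Optional[float] = None,
    clump_dist: float = 100_000,
    positions: Optional[dict[str, float]] = None,
    weights=None,
    gsmr_r2: float = 0.95,
    gsmr_chi2: float = 10.0,
    gsmr_min_snps: int = 10,
) -> GeneAnalysis:
    """Run one engine × combiner path for a gene.

    Per exposure the QTL statistics are (optionally) LD-clumped, the engine
    produces an MR P-value, and the m per-exposure P-values are combined.
    Exposures on which the engine fails recoverably (too few instruments,
    singular covariance) are dropped from the combination with a warning;
    when no exposure survives, ``combined`` is ``None``.

    Clumping runs when ``clump_r2`` is given; the distance rule additionally
    requires ``positions``.
    """
    _validate_pair(engine, combiner)
    result = GeneAnalysis(engine=engine, combiner=None if engine == "mvmr" else combiner,
                          combined=None)

    clumped: dict[str, SummaryStats] = {}
    for label, qtl in qtls.items():
        if clump_r2 is not None:
            kept = ld_clump(qtl, ld, r2_max=clump_r2, dist_max=clump_dist,
                            positions=positions)
            clumped[label] = qtl.subset(kept)
        else:
            clumped[label] = qtl
        result.snps_used[label] = list(clumped[label].snp_ids)

    if engine == "mvmr":
        common = [s for s in gwas.snp_ids
                  if all(s in c.snp_ids for c in clumped.values())]
        if not common:
            raise ValidationError("mvmr: no SNPs shared across exposures")
        aligned = {lab: c.subset(common) for lab, c in clumped.items()}
        result.mvmr_result = mvmr(aligned, gwas.subset(common), ld)
        return result

    per_pvals: list[float] = []
    per_labels: list[str] = []
    gamma_inputs: dict[str, SummaryStats] = {}
    for label, qtl in clumped.items():
        gwas_k = gwas.subset(qtl.snp_ids)
        try:
            if engine == "ivw":
                results = [ivw(qtl, gwas_k)]
            elif engine == "gls":
                results = [gls(qtl, gwas_k, ld)]
            elif engine == "gsmr":
                results = [gsmr(qtl, gwas_k, ld, r2_filter=gsmr_r2,
                                chi2_filter=gsmr_chi2, min_snps=gsmr_min_snps)]
            else:  # smr variants
                mode = "singleSNP" if engine == "smr_singleSNP" else "allSNPs"
                results = smr_multi({label: qtl}, gwas_k, mode=mode)[label]
        except _RECOVERABLE as exc:
            logger.warning("analyze_gene: exposure %s dropped (%s)", label, exc)
            result.dropped_exposures[label] = str(exc)
            continue
        result.per_exposure[label] = results
        for res in results:
            per_pvals.append(res.pval)
            per_labels.append(label if len(results) == 1 else f"{label}:{res.snp_ids[0]}")
        gamma_inputs[label] = qtl

    if not per_pvals:
        logger.warning("analyze_gene: no exposure produced a P-value; missing result")
        return result

    pvals = np.clip(np.asarray(per_pvals), np.nextafter(0, 1), 1.0 - 1e-16)
    if combiner == "cauchy":
        result.combined = combine_cauchy(pvals, weights)
    elif combiner == "hmp":
        result.combined = combine_hmp(pvals, weights)
    elif combiner == "minp":
        result.combined = combine_minp(pvals)
    elif combiner == "fisher_chisq":
        result.combined = combine_fisher_chisq(pvals)
    else:  # fisher_gamma (gls engine guaranteed by _validate_pair)
        zcorr = gls_z_correlation(gamma_inputs, gwas, ld)
        result.combined = combine_fisher_gamma(pvals, zcorr)
    return result


def parse_method_label(label: str) -> tuple[str, Optional[str]]:
    """Split a benchmark label like ``"GLS_Fisher_gamma"`` into
    (engine, combiner); engine names are matched case-insensitively and
    greedily (``smr_singleSNP`` before ``smr``)."""
    low = label.lower()
    if low == "mvmr":
        return "mvmr", None
    for engine in sorted(ENGINES, key=len, reverse=True):
        prefix = engine.lower() + "_"
        if low.startswith(prefix):
            combiner = low[len(prefix):]
            if combiner in COMBINERS:
                return engine, combiner
    raise ValidationError(f"cannot parse method label {label!r}")


@dataclass
class BenchmarkResult:
    """Empirical rejection rate of one method under one simulated setting."""

    setting: SimulationConfig
    method: str
    n_reps: int
    rejections: int
    n_failed: int
    rate: float
    mc_se: float

    def __post_init__(self) -> None:
        n_valid = self.n_reps - self.n_failed
        if not (0 <= self.rejections <= n_valid):
            raise ValidationError("rejections outside [0, n_valid]")
        if n_valid > 0 and abs(self.rate - self.rejections / n_valid) > 1e-12:
            raise ValidationError("rate inconsistent with counts")


def run_benchmark(
    grid: Sequence[SimulationConfig],
    methods: Sequence[str],
    n_reps: int,
    level: float = 0.05,
    seed: int = 0,
    gsmr_min_snps: int = 2,
    progress: bool = False,
) -> list[BenchmarkResult]:
    """Empirical type-I-error / power over a settings grid.

    For each setting and replicate: simulate a cohort, compute summary
    statistics, run every method on the same summary data, and record
    rejection at ``level``. Replicates on which a method produces no
    P-value (insufficient instruments on every exposure, singular
    covariance) are counted separately and excluded from that method's
    rate denominator. Per-replicate RNG streams derive from (seed, setting
    index, replicate index), so each cell is independently reproducible.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be at least 1")
    parsed = [parse_method_label(mth) for mth in methods]
    results: list[BenchmarkResult] = []
    for s_idx, config in enumerate(grid):
        rejections = np.zeros(len(methods), dtype=int)
        failed = np.zeros(len(methods), dtype=int)
        for rep in range(n_reps):
            rng = np.random.default_rng([seed, s_idx, rep])
            replicate = simulate_replicate(config, rng)
            qtls, gwas, ld = compute_summary(replicate, config)
            for m_idx, (engine, combiner) in enumerate(parsed):
                try:
                    analysis = analyze_gene(
                        qtls, gwas, ld, engine=engine, combiner=combiner,
                        gsmr_min_snps=gsmr_min_snps,
                    )
                    pval = analysis.pval
                except _RECOVERABLE as exc:  # e.g. singular MVMR design
                    logger.debug("replicate %d method %s failed: %s",
                                 rep, methods[m_idx], exc)
                    pval = None
                if pval is None:
                    failed[m_idx] += 1
                elif pval < level:
                    rejections[m_idx] += 1
            if progress and (rep + 1) % 500 == 0:
                logger.info("setting %d/%d: %d/%d replicates",
                            s_idx + 1, len(grid), rep + 1, n_reps)
        for m_idx, mth in enumerate(methods):
            n_valid = n_reps - int(failed[m_idx])
            rate = rejections[m_idx] / n_valid if n_valid else float("nan")
            mc_se = (np.sqrt(rate * (1 - rate) / n_valid) if n_valid else float("nan"))
            results.append(BenchmarkResult(
                setting=config, method=mth, n_reps=n_reps,
                rejections=int(rejections[m_idx]), n_failed=int(failed[m_idx]),
                rate=float(rate), mc_se=float(mc_se),
            ))
    return results


def benchmark_to_frame(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    """Tidy table of benchmark results (one row per setting × method)."""
    rows = []
    for res in results:
        cfg = res.setting
        rows.append({
            "pleiotropy": cfg.pleiotropy, "p": cfg.p, "r2": cfg.r2,
            "alpha": cfg.alpha, "beta_x": cfg.beta_x, "outcome": cfg.outcome,
            "overlap": cfg.overlap, "method": res.method,
            "n_reps": res.n_reps, "n_failed": res.n_failed,
            "rejections": res.rejections, "rate": res.rate, "mc_se": res.mc_se,
        })
    return pd.DataFrame(rows)
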