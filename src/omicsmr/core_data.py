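"""Core containers and I/O for summary-statistics based Mendelian randomization.

The whole toolkit operates on three kinds of summary data:

* :class:`SummaryStats` — per-SNP marginal association results for one trait
  (an omic exposure measured by QTL mapping, or the outcome measured by GWAS):
  effect size ``beta``, its standard error ``se``, the Wald ``z = beta/se``
  and a two-sided P-value.
* :class:`LDMatrix` — the *unsquared* linkage-disequilibrium correlation
  matrix ``R`` over the same SNPs.
* :class:`MRResult` / :class:`CombinedResult` — outputs of the per-exposure
  MR engines and of the gene-level P-value combination tests.

Files are plain UTF-8 tab-delimited tables (columns ``SNP  BETA  SE  [Z] [P]
[N]``) and plain square numeric matrices, so that summary statistics exported
from any GWAS/QTL pipeline can be used directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("omicsmr")

__all__ = [
    "FormatError",
    "ValidationError",
    "SummaryStats",
    "LDMatrix",
    "MRResult",
    "CombinedResult",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_matrix",
    "ld_clump",
]

_TINY_P = np.nextafter(0.0, 1.0)


class FormatError(ValueError):
    """A file does not follow the expected tabular/matrix layout."""


class ValidationError(ValueError):
    """Numerically well-formed input violates a statistical contract."""


def two_sided_p(z: np.ndarray) -> np.ndarray:
    """Two-sided P-value of a standard-normal statistic."""
    return 2.0 * stats.norm.sf(np.abs(z))


def _clamp_pvals(p: np.ndarray, context: str) -> np.ndarray:
    p = np.asarray(p, dtype=float).copy()
    if np.any(p == 0.0):
        logger.warning("%s: %d P-value(s) of exactly 0 clamped to %g",
                       context, int(np.sum(p == 0.0)), _TINY_P)
        p[p == 0.0] = _TINY_P
    return p


@dataclass
class SummaryStats:
    """Per-SNP association summary statistics for a single trait.

    Parameters
    ----------
    snp_ids
        Ordered SNP identifiers (unique).
    beta
        Marginal regression slopes of the trait on each SNP dosage.
    se
        Standard errors of ``beta`` (strictly positive).
    z, pval
        Wald statistics and two-sided P-values; filled from ``beta/se``
        when not supplied.
    n
        Optional per-study sample size.
    trait_label
        Name of the trait (e.g. ``"eQTL"``, ``"pQTL"``, ``"GWAS"``).
    """

    snp_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: Optional[np.ndarray] = None
    pval: Optional[np.ndarray] = None
    n: Optional[int] = None
    trait_label: str = ""

    def __post_init__(self) -> None:
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if len(self.snp_ids) == 0:
            raise ValidationError("SummaryStats requires at least one SNP")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("duplicate SNP identifiers")
        if self.beta.shape != (len(self.snp_ids),) or self.se.shape != self.beta.shape:
            raise ValidationError("beta/se length must match snp_ids")
        if not np.all(np.isfinite(self.beta)) or not np.all(np.isfinite(self.se)):
            raise ValidationError("non-finite beta or se")
        if np.any(self.se <= 0):
            raise ValidationError("standard errors must be strictly positive")
        if self.z is None:
            self.z = self.beta / self.se
        else:
            self.z = np.asarray(self.z, dtype=float)
            if self.z.shape != self.beta.shape:
                raise ValidationError("z length must match snp_ids")
            ref = self.beta / self.se
            scale = np.maximum(np.abs(ref), 1.0)
            if np.any(np.abs(self.z - ref) > 1e-10 * scale):
                raise ValidationError("z inconsistent with beta/se")
        if self.pval is None:
            self.pval = two_sided_p(self.z)
        else:
            self.pval = _clamp_pvals(self.pval, f"SummaryStats[{self.trait_label}]")
            if self.pval.shape != self.beta.shape:
                raise ValidationError("pval length must match snp_ids")
            if np.any(self.pval <= 0) or np.any(self.pval > 1):
                raise ValidationError("P-values must lie in (0, 1]")
            ref = two_sided_p(self.z)
            if np.any(np.abs(self.pval - ref) > 1e-6):
                raise ValidationError("P-values inconsistent with two-sided normal tail of z")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def index_of(self, snp_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise ValidationError(f"SNP {exc.args[0]!r} absent from {self.trait_label or 'SummaryStats'}")

    def subset(self, snp_ids: Sequence[str]) -> "SummaryStats":
        """Restrict (and reorder) to the given SNPs."""
        idx = self.index_of(snp_ids)
        return SummaryStats(
            snp_ids=[self.snp_ids[i] for i in idx],
            beta=self.beta[idx], se=self.se[idx],
            z=self.z[idx], pval=self.pval[idx],
            n=self.n, trait_label=self.trait_label,
        )


@dataclass
class LDMatrix:
    """Symmetric unsquared LD correlation matrix ``R`` over named SNPs."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.r = np.asarray(self.r, dtype=float)
        p = len(self.snp_ids)
        if self.r.shape != (p, p):
            raise ValidationError("LD matrix dimension does not match snp_ids")
        if len(set(self.snp_ids)) != p:
            raise ValidationError("duplicate SNP identifiers in LD matrix")
        if not np.all(np.isfinite(self.r)):
            raise ValidationError("non-finite LD entries")
        if np.max(np.abs(self.r - self.r.T)) > 1e-8:
            raise ValidationError("LD matrix is not symmetric")
        if np.max(np.abs(np.diag(self.r) - 1.0)) > 1e-8:
            raise ValidationError("LD matrix diagonal must be 1")
        if np.max(np.abs(self.r)) > 1.0 + 1e-8:
            raise ValidationError("LD correlations must lie in [-1, 1]")
        # exact symmetry/diagonal for downstream linear algebra
        self.r = (self.r + self.r.T) / 2.0
        np.fill_diagonal(self.r, 1.0)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def index_of(self, snp_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"SNP {exc.args[0]!r} absent from LD matrix")

    def submatrix(self, snp_ids: Sequence[str]) -> "LDMatrix":
        idx = self.index_of(snp_ids)
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])

    def cross(self, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
        """Cross-block ``R[rows, cols]`` (rows and cols may differ)."""
        ri = self.index_of(rows)
        ci = self.index_of(cols)
        return self.r[np.ix_(ri, ci)]


@dataclass
class MRResult:
    """Causal-effect estimate for one exposure from one MR engine."""

    exposure_label: str
    theta: float
    var_theta: float
    z: float
    pval: float
    method: str
    n_snps_used: int
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.var_theta > 0):
            raise ValidationError("var_theta must be positive")
        if not (0 < self.pval <= 1):
            raise ValidationError("pval must lie in (0, 1]")
        ref = self.theta / np.sqrt(self.var_theta)
        if abs(self.z - ref) > 1e-8 * max(1.0, abs(ref)):
            raise ValidationError("z inconsistent with theta and var_theta")


@dataclass
class CombinedResult:
    """Gene-level P-value aggregating per-exposure MR P-values."""

    pval: float
    statistic: float
    method: str
    weights: np.ndarray
    m: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not (0 < self.pval <= 1):
            raise ValidationError("combined pval must lie in (0, 1]")
        if self.weights.sum() <= 0:
            raise ValidationError("weights must sum to a positive value")
        if self.m != len(self.weights):
            raise ValidationError("m must equal the number of combined inputs")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {
    "snp": "SNP", "rsid": "SNP", "id": "SNP",
    "beta": "BETA", "b": "BETA", "effect": "BETA",
    "se": "SE", "stderr": "SE",
    "z": "Z", "zscore": "Z",
    "p": "P", "pval": "P", "pvalue": "P", "p_value": "P",
    "n": "N",
}


def read_summary_stats(path, trait_label: str = "") -> SummaryStats:
    """Read a tab-delimited summary-statistics table.

    Mandatory columns: SNP, BETA, SE (case-insensitive, common aliases
    accepted). Optional: Z, P, N. Z and P are filled from ``beta/se`` when
    absent.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    df = df.rename(columns=lambda c: _COLUMN_ALIASES.get(str(c).strip().lower(), str(c)))
    for col in ("SNP", "BETA", "SE"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    n = None
    if "N" in df.columns:
        n_vals = pd.unique(df["N"].dropna())
        if len(n_vals) == 1:
            n = int(n_vals[0])
    return SummaryStats(
        snp_ids=[str(s) for s in df["SNP"]],
        beta=df["BETA"].to_numpy(dtype=float),
        se=df["SE"].to_numpy(dtype=float),
        z=df["Z"].to_numpy(dtype=float) if "Z" in df.columns else None,
        pval=df["P"].to_numpy(dtype=float) if "P" in df.columns else None,
        n=n,
        trait_label=trait_label,
    )


def write_summary_stats(ss: SummaryStats, path) -> None:
    """Write a SummaryStats as a tab-delimited table (lossless round trip)."""
    df = pd.DataFrame({
        "SNP": ss.snp_ids,
        "BETA": ss.beta,
        "SE": ss.se,
        "Z": ss.z,
        "P": ss.pval,
    })
    if ss.n is not None:
        df["N"] = ss.n
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ld_matrix(path, snp_ids: Optional[Sequence[str]] = None) -> LDMatrix:
    """Read a square LD correlation matrix.

    The file is whitespace- or comma-delimited. An optional single header row
    carries SNP identifiers; without one, identifiers must be supplied via
    ``snp_ids`` in file order. When ``snp_ids`` is given and a header is
    present, rows/columns are reordered to match ``snp_ids``.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty LD matrix file")

    def split(line: str) -> list[str]:
        return line.replace(",", " ").split()

    first = split(lines[0])
    has_header = not all(_is_number(tok) for tok in first)
    header = first if has_header else None
    body = lines[1:] if has_header else lines
    try:
        rows = [[float(tok) for tok in split(ln)] for ln in body]
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix entry ({exc})") from exc
    p = len(rows)
    if any(len(row) != p for row in rows):
        raise FormatError(f"{path}: LD matrix is not square")
    if header is not None and len(header) != p:
        raise FormatError(f"{path}: header length does not match matrix dimension")
    ids = header if header is not None else (
        [str(s) for s in snp_ids] if snp_ids is not None
        else [f"snp{i + 1}" for i in range(p)]
    )
    if snp_ids is not None and len(snp_ids) != p:
        raise ValidationError(f"{path}: expected {len(snp_ids)} SNPs, found {p}")
    ld = LDMatrix(ids, np.array(rows))
    if snp_ids is not None and list(snp_ids) != ld.snp_ids:
        ld = ld.submatrix([str(s) for s in snp_ids])
    return ld


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def ld_clump(
    qtl: SummaryStats,
    ld: LDMatrix,
    r2_max: float = 0.2,
    dist_max: float = 100_000,
    positions: Optional[dict[str, float]] = None,
) -> list[str]:
    """Greedy LD clumping by ascending QTL P-value.

    SNPs are visited in ascending P (ties broken by lexicographically smaller
    identifier). A candidate is accepted only if, against every SNP already
    selected, its squared LD correlation is below ``r2_max`` *and* its
    distance exceeds ``dist_max``. The first SNP is always selected, so the
    result is never empty.

    Parameters
    ----------
    positions
        Mapping SNP id -> 1-based coordinate. When ``None``, the distance
        rule is skipped (summary data without genomic coordinates).
    """
    if len(qtl) == 0:
        raise ValidationError("ld_clump: empty input")
    if not (0.0 <= r2_max <= 1.0):
        raise ValidationError("r2_max must lie in [0, 1]")
    sub = ld.submatrix(qtl.snp_ids)
    order = sorted(range(len(qtl)), key=lambda i: (qtl.pval[i], qtl.snp_ids[i]))
    selected: list[int] = []
    for i in order:
        ok = True
        for j in selected:
            if sub.r[i, j] ** 2 >= r2_max:
                ok = False
                break
            if positions is not None:
                d = abs(positions[qtl.snp_ids[i]] - positions[qtl.snp_ids[j]])
                if d <= dist_max:
                    ok = False
                    break
        if ok:
            selected.append(i)
    if not selected:  # unreachable: the first visited SNP always passes
        selected = [order[0]]
    return [qtl.snp_ids[i] for i in selected]
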