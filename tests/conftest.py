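import numpy as np
import pytest

from omicsmr import LDMatrix, SummaryStats


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_summary(rng, snp_ids, scale=0.3, se_lo=0.02, se_hi=0.2, label=""):
    """Random well-formed SummaryStats over the given SNPs."""
    p = len(snp_ids)
    beta = scale * rng.standard_normal(p)
    se = rng.uniform(se_lo, se_hi, p)
    return SummaryStats(list(snp_ids), beta, se, trait_label=label)


def random_ld(rng, snp_ids, strength=0.3):
    """Random well-conditioned unsquared LD matrix over the given SNPs."""
    p = len(snp_ids)
    a = rng.standard_normal((p, p + 3))
    cov = a @ a.T + p * np.eye(p)
    d = np.sqrt(np.diag(cov))
    r = strength * (cov / np.outer(d, d)) + (1 - strength) * np.eye(p)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(list(snp_ids), r)


@pytest.fixture
def snp_ids():
    return [f"rs{i}" for i in range(1, 6)]
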