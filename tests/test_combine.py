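"""Combination tests: closed-form identities, independent oracles, calibration."""

import numpy as np
import pytest
from scipy import optimize, stats

from omicsmr import (
    LDMatrix,
    SummaryStats,
    ValidationError,
    ZCorrelation,
    combine_cauchy,
    combine_fisher_chisq,
    combine_fisher_gamma,
    combine_hmp,
    combine_minp,
    gls_z_correlation,
    landau_sf,
)
from conftest import random_summary

EULER = 0.5772156649015329


def _equicorr(m, rho):
    return np.full((m, m), rho) + (1 - rho) * np.eye(m)


class TestCauchy:
    def test_equal_pvalues_identity(self):
        for p in (0.3, 0.01, 0.75):
            res = combine_cauchy([p, p, p])
            assert res.pval == pytest.approx(p, rel=1e-12)

    def test_degenerate_m1(self):
        assert combine_cauchy([0.123]).pval == pytest.approx(0.123, rel=1e-12)

    def test_worked_example(self):
        res = combine_cauchy([0.01, 0.5])
        assert res.statistic == pytest.approx(15.9103, abs=1e-4)
        assert res.pval == pytest.approx(0.0200, abs=1e-4)

    def test_tail_expansion_continuous_with_arctan_form(self):
        # tiny p drives T huge; tail form must agree with arctan form
        res = combine_cauchy([1e-200, 0.4])
        direct = 1.0 / (res.statistic * np.pi)  # sum(w) = 1
        assert res.pval == pytest.approx(direct, rel=1e-6)
        assert 0 < res.pval < 1e-190

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.0, 0.5], [-0.1], [1.2]])
    def test_invalid_pvalues(self, bad):
        with pytest.raises(ValidationError):
            combine_cauchy(bad)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValidationError):
            combine_cauchy([0.1, 0.2], weights=[1.0, -1.0])


class TestHMP:
    def test_statistic_is_harmonic_mean(self):
        res = combine_hmp([0.2, 0.2, 0.2])
        assert res.statistic == pytest.approx(0.2, rel=1e-12)
        res = combine_hmp([0.1, 0.4], weights=[0.5, 0.5])
        assert res.statistic == pytest.approx(2.0 / (1 / 0.1 + 1 / 0.4), rel=1e-12)

    def test_levy_stable_oracle(self):
        # independent oracle: scipy's stable law in the S1 parameterization
        from scipy.stats import levy_stable
        levy_stable.parameterization = "S1"
        p = [0.01, 0.5]
        res = combine_hmp(p)
        m = 2
        s = sum(0.5 / pi for pi in p)
        loc = np.log(m) + 1 - EULER + np.log(np.pi / 2)
        expect = float(levy_stable.sf(s, 1, 1, loc=loc, scale=np.pi / 2))
        assert res.pval == pytest.approx(expect, rel=1e-6)

    def test_zero_p_rejected(self):
        with pytest.raises(ValidationError):
            combine_hmp([0.0, 0.5])

    def test_landau_sf_tail(self):
        # survival of the lambda = beta = 1 stable law decays like 1/x
        assert landau_sf(1e4) == pytest.approx(1e-4, rel=0.01)
        assert 0.99 < landau_sf(-30.0) <= 1.0


class TestMinP:
    def test_minimum(self):
        res = combine_minp([0.2, 0.05, 0.9])
        assert res.pval == res.statistic == 0.05

    def test_degenerate_and_permutation(self):
        assert combine_minp([0.7]).pval == 0.7
        a = combine_minp([0.3, 0.1, 0.6]).pval
        b = combine_minp([0.6, 0.3, 0.1]).pval
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            combine_minp([])


class TestFisherChisq:
    def test_m1_identity(self):
        assert combine_fisher_chisq([0.037]).pval == pytest.approx(0.037, rel=1e-10)

    def test_worked_example_closed_form(self):
        res = combine_fisher_chisq([0.05, 0.05])
        assert res.statistic == pytest.approx(11.9829, abs=1e-4)
        # chi-squared(4) survival has closed form exp(-T/2)(1 + T/2)
        t = res.statistic
        assert res.pval == pytest.approx(np.exp(-t / 2) * (1 + t / 2), rel=1e-10)
        assert res.pval == pytest.approx(0.0175, abs=1e-4)

    def test_boundary_all_ones(self):
        res = combine_fisher_chisq([1.0, 1.0, 1.0])
        assert res.statistic == 0.0
        assert res.pval == 1.0


class TestZCorrelation:
    def _setting(self, rng, p=4):
        ids = [f"rs{i}" for i in range(p)]
        gwas = random_summary(rng, ids, label="GWAS")
        r = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                r[i, j] = r[j, i] = 0.3 ** abs(i - j)
        return ids, gwas, LDMatrix(ids, r)

    def test_identical_exposures_correlation_one(self, rng):
        ids, gwas, ld = self._setting(rng)
        q1 = random_summary(rng, ids, label="X1")
        q2 = SummaryStats(ids, q1.beta, q1.se, trait_label="X2")
        zc = gls_z_correlation({"X1": q1, "X2": q2}, gwas, ld)
        assert zc.rho[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_sign_flip_correlation_minus_one(self, rng):
        ids, gwas, ld = self._setting(rng)
        q1 = random_summary(rng, ids, label="X1")
        q2 = SummaryStats(ids, -q1.beta, q1.se, trait_label="X2")
        zc = gls_z_correlation({"X1": q1, "X2": q2}, gwas, ld)
        assert zc.rho[0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_disjoint_blocks_correlation_zero(self, rng):
        ids = [f"rs{i}" for i in range(6)]
        r = np.eye(6)
        r[0:3, 0:3] = _equicorr(3, 0.4)
        r[3:6, 3:6] = _equicorr(3, 0.4)
        ld = LDMatrix(ids, r)
        gwas = random_summary(rng, ids, label="GWAS")
        q1 = random_summary(rng, ids[:3], label="X1")
        q2 = random_summary(rng, ids[3:], label="X2")
        zc = gls_z_correlation({"X1": q1, "X2": q2}, gwas, ld)
        assert zc.rho[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matrix_product_oracle_different_subsets(self, rng):
        # direct sandwich computation over overlapping SNP subsets
        ids, gwas, ld = self._setting(rng, p=5)
        q1 = random_summary(rng, ids[:4], label="X1")
        q2 = random_summary(rng, ids[2:], label="X2")
        zc = gls_z_correlation({"X1": q1, "X2": q2}, gwas, ld)

        def weight(q):
            sy = gwas.subset(q.snp_ids).se
            gamma = q.beta / sy
            r_sub = ld.submatrix(q.snp_ids).r
            a = np.linalg.solve(r_sub, gamma)
            return a / np.sqrt(gamma @ a)

        cross = ld.cross(q1.snp_ids, q2.snp_ids)
        expect = weight(q1) @ cross @ weight(q2)
        assert zc.rho[0, 1] == pytest.approx(expect, abs=1e-12)
        assert abs(zc.rho[0, 1]) <= 1 + 1e-8


class TestFisherGamma:
    def test_independence_reduces_to_chisq(self, rng):
        p = list(rng.uniform(0.001, 0.999, 4))
        zc = ZCorrelation(list("abcd"), np.eye(4))
        a = combine_fisher_gamma(p, zc)
        b = combine_fisher_chisq(p)
        assert a.pval == pytest.approx(b.pval, abs=1e-12)

    def test_perfect_correlation_exponential_reduction(self):
        # m=2, rho=1: c(1) = 3.263+0.710+0.027 = 4, gamma -> Exp(scale 4),
        # so the combined P of (q, q) is exactly q
        zc = ZCorrelation(["a", "b"], np.ones((2, 2)))
        for q in (0.001, 0.05, 0.4):
            res = combine_fisher_gamma([q, q], zc)
            assert res.pval == pytest.approx(q, rel=1e-6)

    def test_against_monte_carlo_null_oracle(self):
        # m=3 equicorrelated z's at rho=0.5; the two-moment gamma null is an
        # approximation, so agreement is coarse (factor < 2) but the
        # dependence correction must move the P the right way (larger than
        # the independence P).
        m, rho = 3, 0.5
        pvals = [0.01, 0.02, 0.03]
        zc = ZCorrelation(list("abc"), _equicorr(m, rho))
        res = combine_fisher_gamma(pvals, zc)
        rng = np.random.default_rng(42)
        L = np.linalg.cholesky(_equicorr(m, rho))
        t_obs = -2 * np.sum(np.log(pvals))
        n = 400_000
        z = rng.standard_normal((n, m)) @ L.T
        p2 = 2 * stats.norm.sf(np.abs(z))
        q_mc = np.mean(-2 * np.sum(np.log(p2), axis=1) > t_obs)
        assert 0.5 * q_mc < res.pval < 2.0 * q_mc
        assert res.pval > combine_fisher_chisq(pvals).pval

    def test_rho_above_one_clamped(self, caplog):
        rho = np.array([[1.0, 1.0 + 5e-7], [1.0 + 5e-7, 1.0]])
        zc = ZCorrelation(["a", "b"], rho)
        assert zc.rho[0, 1] == 1.0
        assert "clamped" in caplog.text

    def test_rho_far_above_one_rejected(self):
        with pytest.raises(ValidationError):
            ZCorrelation(["a", "b"], np.array([[1.0, 1.4], [1.4, 1.0]]))


class TestCombinerProperties:
    def test_monotonicity_in_each_pvalue(self, rng):
        zc = ZCorrelation(list("abc"), _equicorr(3, 0.4))
        combiners = [
            combine_cauchy,
            combine_hmp,
            combine_minp,
            combine_fisher_chisq,
            lambda p: combine_fisher_gamma(p, zc),
        ]
        for _ in range(20):
            p = rng.uniform(0.01, 0.99, 3)
            k = rng.integers(0, 3)
            q = p.copy()
            q[k] = p[k] * rng.uniform(0.05, 0.95)
            for comb in combiners:
                assert comb(q).pval <= comb(p).pval + 1e-12

    def test_permutation_invariance(self, rng):
        p = rng.uniform(0.001, 0.999, 4)
        w = rng.uniform(0.5, 2.0, 4)
        perm = rng.permutation(4)
        for comb in (combine_cauchy, combine_hmp):
            a = comb(p, w).pval
            b = comb(p[perm], w[perm]).pval
            assert a == pytest.approx(b, rel=1e-12)
        rho = _equicorr(4, 0.3)
        a = combine_fisher_gamma(p, ZCorrelation(list("abcd"), rho)).pval
        b = combine_fisher_gamma(p[perm],
                                 ZCorrelation(list("abcd"), rho[np.ix_(perm, perm)])).pval
        assert a == pytest.approx(b, rel=1e-12)

    def test_cauchy_and_hmp_agree_within_factor_two(self, rng):
        # the two dependence-robust combiners give similar combined P
        # throughout the interesting range
        count = 0
        for _ in range(300):
            m = rng.integers(2, 5)
            p = 10 ** rng.uniform(-7, -0.3, m)
            pc = combine_cauchy(p).pval
            if not (1e-6 <= pc <= 0.1):
                continue
            ph = combine_hmp(p).pval
            count += 1
            ratio = ph / pc
            assert 0.5 < ratio < 2.0
        assert count > 50  # the comparison actually exercised the range

    def test_calibration_under_correlated_nulls(self):
        """Type-I control logic: Cauchy/HMP/Fisher-gamma stay at or below
        the nominal level under dependence; MinP and Fisher-chisq blow up."""
        rng = np.random.default_rng(99)
        n, m, alpha = 100_000, 3, 0.05
        se3 = 3 * np.sqrt(alpha * (1 - alpha) / n)
        for rho in (0.0, 0.5, 0.9):
            L = np.linalg.cholesky(_equicorr(m, rho))
            z = rng.standard_normal((n, m)) @ L.T
            p = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1 - 1e-16)
            # statistics, vectorized (same formulas, independent of package)
            t_cauchy = np.mean(np.tan((0.5 - p) * np.pi), axis=1)
            s_hmp = np.mean(1.0 / p, axis=1)
            t_fisher = -2 * np.sum(np.log(p), axis=1)
            p_min = p.min(axis=1)
            # alpha thresholds obtained by inverting the package's p-value maps
            thr_cauchy = optimize.brentq(
                lambda t: (0.5 - np.arctan(t) / np.pi) - alpha, 0, 1e8)
            thr_hmp = optimize.brentq(
                lambda s: landau_sf(s - np.log(m) - (1 - EULER)) - alpha,
                np.log(m), 1e7)
            thr_fg = stats.gamma.isf(
                alpha,
                a=(2 * m) ** 2 / (4 * m + 2 * 3 * (3.263 * rho + 0.710 * rho ** 2
                                                   + 0.027 * rho ** 3)),
                scale=(4 * m + 2 * 3 * (3.263 * rho + 0.710 * rho ** 2
                                        + 0.027 * rho ** 3)) / (2 * m))
            thr_fc = stats.chi2.isf(alpha, 2 * m)
            rate_cauchy = np.mean(t_cauchy > thr_cauchy)
            rate_hmp = np.mean(s_hmp > thr_hmp)
            rate_fg = np.mean(t_fisher > thr_fg)
            rate_fc = np.mean(t_fisher > thr_fc)
            rate_minp = np.mean(p_min < alpha)
            # valid combiners never inflate materially
            for rate in (rate_cauchy, rate_hmp, rate_fg):
                assert rate <= 0.06
            if rho == 0.0:
                assert abs(rate_cauchy - alpha) <= se3
                assert abs(rate_fg - alpha) <= se3
                assert rate_hmp <= alpha + se3  # small-m conservatism
            if rho == 0.9:
                for rate in (rate_cauchy, rate_hmp, rate_fg):
                    assert rate <= 0.055
                # the disqualified combiners inflate beyond Monte-Carlo noise
                assert rate_minp > alpha + se3
                assert rate_fc > alpha + se3

    def test_thresholds_match_package_pvalues(self):
        # spot-check that the vectorized statistics used above agree with
        # the package's scalar combiners
        p = [0.02, 0.3, 0.6]
        assert combine_cauchy(p).statistic == pytest.approx(
            np.mean(np.tan((0.5 - np.array(p)) * np.pi)))
        assert combine_hmp(p).statistic == pytest.approx(
            1.0 / np.mean(1.0 / np.array(p)))
        assert combine_fisher_chisq(p).statistic == pytest.approx(
            -2 * np.sum(np.log(p)))
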