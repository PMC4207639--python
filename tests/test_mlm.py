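"""Mixed-model engine tests: GRM oracles, REML, score test, LOD intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from qtnscan import mlm, simdata
from qtnscan.containers import AssocResult, QTLInterval

from conftest import make_genotype_matrix


# ---------------------------------------------------------------------------
# GRM

def ibs_pair_oracle(a, b):
    """Per-pair mean shared-allele fraction over non-missing SNPs."""
    vals = [1.0 - abs(x - y) / 2.0 for x, y in zip(a, b)
            if not (np.isnan(x) or np.isnan(y))]
    return np.mean(vals)


class TestGRM:
    def test_duplicated_individuals_share_self_similarity(self):
        d = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]], dtype=float)
        g = make_genotype_matrix(d)
        grm = mlm.compute_grm(g)
        assert grm[0, 1] == pytest.approx(grm[0, 0])

    def test_toy_matches_brute_force_ibs(self):
        d = np.array([[0, 1, 2, 1], [2, 1, 0, np.nan], [1, 1, 1, 2]], dtype=float)
        g = make_genotype_matrix(d)
        grm = mlm.compute_grm(g)
        for i in range(3):
            for j in range(3):
                assert grm[i, j] == pytest.approx(
                    ibs_pair_oracle(d[i], d[j]), abs=1e-12)

    def test_random_offdiagonals_approach_population_mean_ibs(self):
        rng = np.random.default_rng(0)
        p = 0.5
        d = rng.binomial(2, p, size=(10, 4000)).astype(float)
        grm = mlm.compute_grm(make_genotype_matrix(d))
        # E|gi-gj| at p=0.5 is 0.5*1 + 0.125*2 = 0.75, so E[IBS] = 0.625
        off = grm[np.triu_indices(10, 1)]
        assert np.allclose(off, 0.625, atol=0.02)

    def test_vanraden_diagonal_near_one(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.4, size=(40, 500)).astype(float)
        grm = mlm.compute_grm(make_genotype_matrix(d), method="vanraden")
        assert np.mean(np.diag(grm)) == pytest.approx(1.0, abs=0.1)

    def test_all_missing_column_raises(self):
        d = np.array([[0, np.nan], [1, np.nan]])
        with pytest.raises(ValueError):
            mlm.compute_grm(make_genotype_matrix(d))


# ---------------------------------------------------------------------------
# polygenic REML

class TestFitPolygenic:
    def test_identity_kinship_recovers_ols_variance(self):
        rng = np.random.default_rng(4)
        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 2.0]) + rng.normal(0, 1.5, size=n)
        fit = mlm.fit_polygenic(y, X, np.eye(n))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        ols_var = resid @ resid / (n - 2)
        assert fit.sigma_a2 + fit.sigma_e2 == pytest.approx(ols_var, rel=1e-4)
        assert "kinship_degenerate" in fit.flags

    def test_h2_recovery_from_known_covariance(self):
        """Data generated at h2=0.5 yields estimates in a calibrated band."""
        rng = np.random.default_rng(12)
        n, inside = 120, 0
        n_rep = 25
        for _ in range(n_rep):
            A = rng.normal(size=(n, 60))
            G = A @ A.T / 60
            L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
            u = L @ rng.normal(size=n)
            y = 3.0 + u * np.sqrt(0.5 / np.var(u)) \
                + rng.normal(size=n) * np.sqrt(0.5)
            fit = mlm.fit_polygenic(y, np.ones((n, 1)), G)
            if 0.2 <= fit.h2 <= 0.8:
                inside += 1
        assert inside >= int(0.8 * n_rep)

    def test_constant_phenotype_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            mlm.fit_polygenic(np.ones(30), np.ones((30, 1)), np.eye(30))

    def test_non_psd_kinship_raises(self):
        G = -np.eye(10)
        with pytest.raises(ValueError, match="positive semi-definite"):
            mlm.fit_polygenic(np.random.default_rng(0).normal(size=10),
                              np.ones((10, 1)), G)


# ---------------------------------------------------------------------------
# score test

def trend_test_oracle(y, g):
    """Classical 1-df score (Armitage trend / OLS) chi-square with G=I."""
    n = len(y)
    gc = g - g.mean()
    r = y - y.mean()
    s2 = r @ r / (n - 1)
    score = gc @ r
    return score**2 / (gc @ gc) / s2


class TestScoreTest:
    def _toy_fit_and_matrix(self, seed=0, n=100, m=8):
        rng = np.random.default_rng(seed)
        d = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        g = make_genotype_matrix(d)
        y = 0.4 * d[:, 0] + rng.normal(size=n)
        fit = mlm.fit_polygenic(y, np.ones((n, 1)), np.eye(n),
                                samples=g.samples)
        return fit, g, y, d

    def test_agrees_with_trend_test_under_identity_kinship(self):
        fit, g, y, d = self._toy_fit_and_matrix()
        scan = mlm.score_test_scan(fit, g)
        for j in range(g.n_snps):
            expected = trend_test_oracle(y, d[:, j])
            assert scan.table["chisq"].iloc[j] == pytest.approx(
                expected, rel=0.01)

    def test_allele_label_swap_flips_sign_keeps_chisq(self):
        fit, g, y, d = self._toy_fit_and_matrix(seed=5)
        swapped = make_genotype_matrix(2.0 - d)
        scan = mlm.score_test_scan(fit, g)
        scan_sw = mlm.score_test_scan(fit, swapped)
        np.testing.assert_allclose(
            scan.table["chisq"], scan_sw.table["chisq"], rtol=1e-9)
        np.testing.assert_allclose(
            scan.table["beta"], -scan_sw.table["beta"], rtol=1e-9)

    def test_monomorphic_snp_flagged_with_p_one(self):
        fit, g, y, d = self._toy_fit_and_matrix(seed=2)
        d2 = d.copy()
        d2[:, 3] = 2.0
        scan = mlm.score_test_scan(fit, make_genotype_matrix(d2))
        row = scan.table.iloc[3]
        assert row["p"] == 1.0 and row["flag"] == "monomorphic"

    def test_sample_mismatch_raises(self):
        fit, g, *_ = self._toy_fit_and_matrix()
        g2 = g.subset(samples=g.samples[:-1])
        with pytest.raises(ValueError, match="different samples"):
            mlm.score_test_scan(fit, g2)

    def test_matches_fixed_covariance_likelihood_ratio_small_n(self):
        """Score chi-square vs explicit likelihood maximization, n=8.

        Both likelihoods are maximized over the mean parameters with the
        covariance fixed at the null REML fit, the regime where the score
        and likelihood-ratio tests coincide.
        """
        rng = np.random.default_rng(17)
        n = 8
        A = rng.normal(size=(n, 20))
        G = A @ A.T / 20
        y = rng.normal(size=n)
        d = rng.integers(0, 3, size=(n, 1)).astype(float)
        g = make_genotype_matrix(d)
        fit = mlm.fit_polygenic(y, np.ones((n, 1)), G, samples=g.samples)
        chisq = mlm.score_test_scan(fit, g).table["chisq"].iloc[0]

        V = fit.sigma_a2 * G + fit.sigma_e2 * np.eye(n)
        Vi = np.linalg.inv(V)
        sign, logdet = np.linalg.slogdet(V)

        def max_loglik(X):
            beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            r = y - X @ beta
            return -0.5 * (logdet + r @ Vi @ r + n * np.log(2 * np.pi))

        lrt = 2 * (max_loglik(np.column_stack([np.ones(n), d[:, 0]]))
                   - max_loglik(np.ones((n, 1))))
        assert chisq == pytest.approx(lrt, rel=0.10)


class TestConditionalScan:
    def test_conditioning_snp_excluded_and_must_be_polymorphic(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.5, size=(60, 5)).astype(float)
        d[:, 4] = 1.0
        g = make_genotype_matrix(d)
        y = d[:, 0] + rng.normal(size=60)
        fit = mlm.fit_polygenic(y, np.ones((60, 1)), np.eye(60),
                                samples=g.samples)
        cond = mlm.conditional_scan(fit, g, "snp0")
        assert "snp0" not in cond.table.index
        with pytest.raises(ValueError, match="monomorphic"):
            mlm.conditional_scan(fit, g, "snp4")

    def test_conditioning_on_unlinked_snp_preserves_peak(self):
        rng = np.random.default_rng(21)
        n = 300
        d = rng.binomial(2, 0.5, size=(n, 10)).astype(float)
        g = make_genotype_matrix(d)
        y = 1.0 * d[:, 2] + rng.normal(size=n)
        fit = mlm.fit_polygenic(y, np.ones((n, 1)), np.eye(n),
                                samples=g.samples)
        base_p = mlm.score_test_scan(fit, g).table.loc["snp2", "p"]
        cond_p = mlm.conditional_scan(fit, g, "snp7").table.loc["snp2", "p"]
        assert abs(np.log10(cond_p) - np.log10(base_p)) < 1.0


# ---------------------------------------------------------------------------
# thresholds, summaries, conversions

class TestScalars:
    def test_bonferroni_published_values(self):
        gw, sugg = mlm.bonferroni_thresholds(39414, 0.05)
        assert gw == pytest.approx(1.27e-6, rel=5e-3)
        assert sugg == pytest.approx(2.54e-5, rel=5e-3)
        assert mlm.bonferroni_thresholds(1) == (0.05, 1.0)
        with pytest.raises(ValueError):
            mlm.bonferroni_thresholds(0)

    def test_variance_explained_arithmetic(self):
        assert mlm.variance_explained(10.0, 8.0) == pytest.approx(0.2)
        assert mlm.variance_explained(5.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            mlm.variance_explained(0.0, 1.0)

    def test_lambda_gc_calibration(self):
        assert mlm.lambda_gc([0.5] * 99) == pytest.approx(1.0, abs=1e-6)
        rng = np.random.default_rng(0)
        assert 0.95 < mlm.lambda_gc(rng.uniform(size=100_000)) < 1.05
        assert mlm.lambda_gc([1e-6] * 9) > 10

    def test_pvalue_to_lod(self):
        assert mlm.pvalue_to_lod(1.0) == 0.0
        # independent oracle: R qchisq(1.27e-6, 1, lower=FALSE) = 23.468
        assert mlm.pvalue_to_lod(1.27e-6) == pytest.approx(5.096, abs=0.01)
        p_chi4 = float(stats.chi2.sf(4.0, 1))
        assert mlm.pvalue_to_lod(p_chi4) == pytest.approx(
            4.0 / (2 * np.log(10)), rel=1e-9)
        with pytest.raises(ValueError):
            mlm.pvalue_to_lod(0.0)


# ---------------------------------------------------------------------------
# intervals

def _assoc_from_lod(lods, positions, chrom="1"):
    lods = np.asarray(lods, dtype=float)
    chisq = lods * 2 * np.log(10)
    p = stats.chi2.sf(chisq, 1)
    table = pd.DataFrame(
        {"chrom": [chrom] * len(lods), "pos": positions, "beta": 0.0,
         "se": 1.0, "chisq": chisq, "p": p, "lod": lods, "flag": ""},
        index=pd.Index([f"m{i}" for i in range(len(lods))], name="id"))
    return AssocResult(table)


class TestIntervals:
    def test_hand_built_profile_bounds(self):
        res = _assoc_from_lod([5, 6, 9, 8, 6.9, 5],
                              [1e6, 2e6, 3e6, 4e6, 5e6, 6e6])
        iv = mlm.two_lod_interval(res, "1")
        assert (iv.start_bp, iv.end_bp) == (2_000_000, 5_000_000)
        assert iv.peak_snp == "m2" and iv.peak_lod == 9

    def test_single_snp_zero_width(self):
        res = _assoc_from_lod([4.2], [7_000_000])
        iv = mlm.two_lod_interval(res, "1")
        assert iv.start_bp == iv.end_bp == 7_000_000

    def test_peak_tie_breaks_to_smaller_position(self):
        res = _assoc_from_lod([3, 8, 8, 3], [1e6, 2e6, 3e6, 4e6])
        assert mlm.two_lod_interval(res, "1").peak_snp == "m1"

    def test_published_interval_geometry(self):
        f2 = QTLInterval("3", 16_920_000, 17_840_000, "pSNP", 20.0)
        sutai = QTLInterval("3", 16_470_000, 17_100_000, "pSNP2", 18.0)
        assert f2.width_bp == 920_000
        overlap = mlm.intersect_intervals(f2, sutai)
        assert (overlap.start_bp, overlap.end_bp) == (16_920_000, 17_100_000)
        assert overlap.width_bp == 180_000

    def test_intersection_identity_and_disjoint(self):
        i = QTLInterval("1", 5, 10, "x", 3.0)
        same = mlm.intersect_intervals(i, i)
        assert (same.start_bp, same.end_bp) == (5, 10)
        with pytest.raises(ValueError, match="disjoint"):
            mlm.intersect_intervals(QTLInterval("1", 1, 2, "x", 1.0),
                                    QTLInterval("1", 3, 4, "y", 1.0))
        with pytest.raises(ValueError, match="different chromosomes"):
            mlm.intersect_intervals(QTLInterval("1", 1, 2, "x", 1.0),
                                    QTLInterval("2", 1, 2, "y", 1.0))

    def test_lod_monotone_in_peak_p(self):
        ps = [1e-3, 1e-5, 1e-8]
        lods = [mlm.pvalue_to_lod(p) for p in ps]
        assert lods == sorted(lods)
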