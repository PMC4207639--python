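"""Mixed-linear-model single-marker association with a genomic relationship matrix.

The model for a phenotype vector *Y* is

    Y = mu + Xb + Sk + Zc + a + e,   a ~ N(0, G sigma_a^2),  e ~ N(0, I sigma_e^2)

where X holds fixed effects (sex, batch), S a weight covariate, Z the SNP
dosage whose allelic-substitution effect c is tested, and G a genomic
relationship matrix from genome-wide allele sharing. Variance components are
estimated once by REML on the null model (no SNP) via an eigendecomposition
of G and a one-dimensional search over the heritability ratio; each SNP is
then evaluated with a 1-df score test against that fitted covariance
(the mmscore strategy), which makes genome scans a single pass of matrix
algebra.

P values are converted to LOD scores through the 1-df chi-square quantile,
LOD = chi2_1(P) / (2 ln 10), and confidence intervals are delimited by the
2-LOD drop along the marker map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import AssocResult, GenotypeMatrix, QTLInterval

__all__ = [
    "PolygenicFit",
    "compute_grm",
    "build_design",
    "fit_polygenic",
    "score_test_scan",
    "conditional_scan",
    "bonferroni_thresholds",
    "variance_explained",
    "snp_variance_explained",
    "lambda_gc",
    "pvalue_to_lod",
    "two_lod_interval",
    "intersect_intervals",
]

_2LN10 = 2.0 * math.log(10.0)


# ---------------------------------------------------------------------------
# genomic relationship matrix

def compute_grm(g: GenotypeMatrix, method: str = "ibs") -> np.ndarray:
    """Genomic relationship matrix over the samples of ``g``.

    ``method='ibs'`` (default): mean over SNPs of the shared-allele fraction
    1 - |g_i - g_j| / 2, computed over pairwise-complete markers. The
    diagonal is identically 1, so the matrix already has mean diagonal 1.

    ``method='vanraden'``: centered/scaled cross-product
    ZZ' / (2 sum p(1-p)) with per-SNP mean imputation of missing calls.
    """
    if g.n_samples < 2:
        raise ValueError("GRM requires at least two samples")
    d = g.dosage
    missing = np.isnan(d)
    if missing.all(axis=0).any():
        raise ValueError("a SNP column is entirely missing")
    freq = g.alt_frequency()
    poly = (freq > 0) & (freq < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNP for the GRM")

    if method == "ibs":
        m = (~missing).astype(float)
        d0 = np.where(missing, 0.0, d)
        sq = d0**2
        ss = sq @ m.T + m @ sq.T - 2.0 * (d0 @ d0.T)
        a0 = ((d0 == 0.0) & ~missing).astype(float)
        a2 = ((d0 == 2.0) & ~missing).astype(float)
        cross = a0 @ a2.T + a2 @ a0.T
        n_pair = m @ m.T
        if (n_pair == 0).any():
            raise ValueError("a sample pair shares no non-missing SNP")
        abs_sum = ss - 2.0 * cross
        grm = 1.0 - abs_sum / (2.0 * n_pair)
        return (grm + grm.T) / 2.0
    if method == "vanraden":
        dz = np.where(missing, np.nanmean(d, axis=0), d)
        dz = dz[:, poly]
        p = freq[poly]
        z = dz - 2.0 * p
        denom = 2.0 * np.sum(p * (1.0 - p))
        grm = (z @ z.T) / denom
        return (grm + grm.T) / 2.0
    raise ValueError(f"unknown GRM method {method!r}")


# ---------------------------------------------------------------------------
# polygenic (null-model) REML fit

@dataclass
class PolygenicFit:
    """REML fit of the polygenic null model; caches the rotation for scans."""

    samples: list
    y: np.ndarray
    X: np.ndarray
    U: np.ndarray          # eigenvectors of G
    d: np.ndarray          # eigenvalues of G
    h2: float
    sigma2: float          # total variance sigma_a2 + sigma_e2
    sigma_a2: float
    sigma_e2: float
    beta: np.ndarray       # GLS fixed-effect estimates
    loglik: float          # restricted log-likelihood at the optimum
    flags: list = field(default_factory=list)
    # cached rotated quantities
    yt: np.ndarray = None
    Xt: np.ndarray = None
    w: np.ndarray = None       # per-eigenvalue marginal variances
    py: np.ndarray = None      # rotated projected phenotype P y

    @property
    def grammar_residuals(self) -> np.ndarray:
        """Environmental residuals y - X beta - BLUP(a) (GRAMMAR residuals)."""
        # a_hat = sigma_a2 * G V^-1 (y - X beta); in rotated space
        r = self.yt - self.Xt @ self.beta
        vinv_r = r / self.w
        a_rot = self.sigma_a2 * self.d * vinv_r
        return self.U @ (r - a_rot)

    @property
    def marginal_residuals(self) -> np.ndarray:
        return self.y - self.X @ self.beta


def build_design(pheno: pd.DataFrame, covariates=("sex", "batch"),
                 weight_col: str | None = "carcass_weight") -> np.ndarray:
    """Intercept + dummy-coded factors + optional weight covariate."""
    cols = [np.ones(len(pheno))]
    for c in covariates:
        dummies = pd.get_dummies(pheno[c], drop_first=True)
        for col in dummies.columns:
            cols.append(dummies[col].to_numpy(dtype=float))
    if weight_col is not None and weight_col in pheno:
        cols.append(pheno[weight_col].to_numpy(dtype=float))
    return np.column_stack(cols)


def _reml_neg_loglik(h: float, yt, Xt, d):
    n, p = Xt.shape
    w = h * d + (1.0 - h)
    if np.any(w <= 0):
        return np.inf
    wi = 1.0 / w
    xtwx = Xt.T @ (wi[:, None] * Xt)
    xtwy = Xt.T @ (wi * yt)
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return np.inf
    r = yt - Xt @ beta
    rss = float(r @ (wi * r))
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (
        (n - p) * math.log(sigma2) + np.sum(np.log(w)) + logdet_xtwx
        + (n - p)
    )
    return -ll


def fit_polygenic(y, X, G, samples=None, tol: float = 1e-8,
                  eig=None) -> PolygenicFit:
    """REML estimation of (sigma_a2, sigma_e2) under Y = Xb + a + e.

    Uses the spectral decomposition G = U D U' to reduce the restricted
    likelihood to a function of the single ratio h = sigma_a2 / sigma2,
    optimized by bounded scalar search to ``tol``. A precomputed
    ``eig=(d, U)`` of G may be passed to amortize the decomposition across
    phenotypes.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X have incompatible shapes")
    if np.ptp(y) == 0:
        raise ValueError("phenotype has zero variance")
    if n <= p + 2:
        raise ValueError("too few samples for the fixed-effect design")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")
    if eig is not None:
        d, U = eig
        d = np.asarray(d, dtype=float)
        U = np.asarray(U, dtype=float)
    else:
        G = np.asarray(G, dtype=float)
        d, U = np.linalg.eigh((G + G.T) / 2.0)
    if d.min() < -1e-6 * max(1.0, abs(d.max())):
        raise ValueError("G is not positive semi-definite")
    d = np.clip(d, 0.0, None)

    yt = U.T @ y
    Xt = U.T @ X

    flags = []
    if np.ptp(d) < 1e-10:
        flags.append("kinship_degenerate")

    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(1e-9, 1.0 - 1e-9), args=(yt, Xt, d),
        method="bounded", options={"xatol": tol},
    )
    h = float(res.x)
    # compare with the h = 0 boundary (no polygenic variance)
    if _reml_neg_loglik(1e-12, yt, Xt, d) <= res.fun:
        h = 0.0

    w0 = h * d + (1.0 - h)
    wi = 1.0 / w0
    xtwx = Xt.T @ (wi[:, None] * Xt)
    beta = np.linalg.solve(xtwx, Xt.T @ (wi * yt))
    r = yt - Xt @ beta
    sigma2 = float(r @ (wi * r)) / (n - p)
    sigma_a2 = h * sigma2
    sigma_e2 = (1.0 - h) * sigma2
    w = sigma_a2 * d + sigma_e2
    py = (r / w)

    return PolygenicFit(
        samples=list(samples) if samples is not None else list(range(n)),
        y=y, X=X, U=U, d=d, h2=h, sigma2=sigma2,
        sigma_a2=sigma_a2, sigma_e2=sigma_e2, beta=beta,
        loglik=-_reml_neg_loglik(max(h, 1e-12), yt, Xt, d),
        flags=flags, yt=yt, Xt=Xt, w=w, py=py,
    )


# ---------------------------------------------------------------------------
# score-test genome scan

def _scan_matrix(fit: PolygenicFit, dosage: np.ndarray):
    """1-df score statistics for each column of ``dosage`` under ``fit``."""
    d = dosage.copy()
    col_mean = np.nanmean(d, axis=0)
    nan_mask = np.isnan(d)
    d[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    gt = fit.U.T @ d
    wi = 1.0 / fit.w
    xtw = fit.Xt.T * wi  # p x n
    m_inv = np.linalg.inv(xtw @ fit.Xt)
    gwx = gt.T @ xtw.T       # m x p
    var = np.einsum("ij,ij->j", gt, gt * wi[:, None]) - np.einsum(
        "ij,ij->i", gwx @ m_inv, gwx)
    score = gt.T @ fit.py
    return score, var


def score_test_scan(fit: PolygenicFit, g: GenotypeMatrix,
                    exclude=()) -> AssocResult:
    """Single-marker score-test scan of every SNP in ``g`` under ``fit``.

    The effect estimate is the allelic-substitution effect of the ALT
    allele (score / information); monomorphic SNPs are reported with P = 1
    and flagged rather than raising.
    """
    if fit.samples != g.samples:
        raise ValueError("fit and genotype matrix have different samples")
    score, var = _scan_matrix(fit, g.dosage)
    freq = g.alt_frequency()
    mono = (freq <= 0.0) | (freq >= 1.0) | (var <= 1e-12)
    var_safe = np.where(mono, 1.0, var)
    chisq = np.where(mono, 0.0, score**2 / var_safe)
    p = stats.chi2.sf(chisq, df=1)
    p = np.where(mono, 1.0, p)
    beta = np.where(mono, 0.0, score / var_safe)
    se = np.where(mono, np.nan, 1.0 / np.sqrt(var_safe))
    lod = chisq / _2LN10
    lod = np.where(mono, 0.0, lod)
    table = pd.DataFrame(
        {
            "chrom": g.snps["chrom"].to_numpy(),
            "pos": g.snps["pos"].to_numpy(),
            "beta": beta, "se": se, "chisq": chisq, "p": p, "lod": lod,
            "flag": np.where(mono, "monomorphic", ""),
        },
        index=g.snps.index.copy(),
    )
    if len(exclude):
        table = table.drop(index=[s for s in exclude if s in table.index])
    return AssocResult(table)


def conditional_scan(fit: PolygenicFit, g: GenotypeMatrix,
                     covariate_snp: str) -> AssocResult:
    """Rescan with a named SNP's dosage fitted as a fixed covariate.

    Variance components are kept at the null-model estimates; the covariate
    SNP itself is excluded from the output.
    """
    j = g.snp_index(covariate_snp)
    cov = g.dosage[:, j].copy()
    cov[np.isnan(cov)] = np.nanmean(cov)
    if np.ptp(cov) == 0:
        raise ValueError("conditioning SNP is monomorphic")
    X_aug = np.column_stack([fit.X, cov])
    Xt_aug = np.column_stack([fit.Xt, fit.U.T @ cov])
    wi = 1.0 / fit.w
    xtwx = Xt_aug.T @ (wi[:, None] * Xt_aug)
    beta = np.linalg.solve(xtwx, Xt_aug.T @ (wi * fit.yt))
    r = fit.yt - Xt_aug @ beta
    aug = PolygenicFit(
        samples=fit.samples, y=fit.y, X=X_aug, U=fit.U, d=fit.d,
        h2=fit.h2, sigma2=fit.sigma2, sigma_a2=fit.sigma_a2,
        sigma_e2=fit.sigma_e2, beta=beta, loglik=fit.loglik,
        flags=list(fit.flags), yt=fit.yt, Xt=Xt_aug, w=fit.w, py=r / fit.w,
    )
    return score_test_scan(aug, g, exclude=(covariate_snp,))


# ---------------------------------------------------------------------------
# thresholds, summaries, intervals

def bonferroni_thresholds(n_tests: int, alpha: float = 0.05):
    """(genome-wide, suggestive) Bonferroni P thresholds: alpha/N and 1/N."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests, 1.0 / n_tests


def variance_explained(v_reduced: float, v_full: float) -> float:
    """Fraction of variance attributed to a term: (V_red - V_full) / V_red."""
    if v_reduced <= 0:
        raise ValueError("reduced-model variance must be positive")
    return (v_reduced - v_full) / v_reduced


def snp_variance_explained(fit: PolygenicFit, g: GenotypeMatrix,
                           snp_id: str) -> float:
    """Variance explained by one SNP via REML refits with/without its dosage.

    The model variance is sigma_a2 + sigma_e2 (everything not captured by
    fixed effects); the SNP enters the full model as a fixed covariate.
    """
    j = g.snp_index(snp_id)
    cov = g.dosage[:, j].copy()
    cov[np.isnan(cov)] = np.nanmean(cov)
    full = fit_polygenic(fit.y, np.column_stack([fit.X, cov]), None,
                         samples=fit.samples, eig=(fit.d, fit.U))
    v_red = fit.sigma_a2 + fit.sigma_e2
    v_full = full.sigma_a2 + full.sigma_e2
    return variance_explained(v_red, v_full)


def lambda_gc(p_values) -> float:
    """Genomic-control inflation factor from 1-df association P values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty P-value array")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


def pvalue_to_lod(p: float) -> float:
    """LOD = chi2_1 quantile at 1 - p, divided by 2 ln 10."""
    if not (0.0 < p <= 1.0):
        raise ValueError("P value must lie in (0, 1]")
    return float(stats.chi2.isf(p, df=1)) / _2LN10


def two_lod_interval(res: AssocResult, chrom) -> QTLInterval:
    """2-LOD drop support interval around the peak SNP on one chromosome.

    The peak is the maximum-LOD SNP (ties broken by smallest position). The
    interval extends outwards to the first SNP on each side whose LOD has
    dropped more than 2 below the peak (or to the outermost SNP if the drop
    never occurs); bounds are SNP positions, not interpolations.
    """
    t = res.on_chrom(chrom).sort_values("pos", kind="stable")
    lod = t["lod"].to_numpy()
    pos = t["pos"].to_numpy()
    peak_i = int(np.argmax(lod))  # argmax returns first index among ties
    cutoff = lod[peak_i] - 2.0
    left = 0
    for i in range(peak_i - 1, -1, -1):
        if lod[i] < cutoff:
            left = i
            break
    right = len(lod) - 1
    for i in range(peak_i + 1, len(lod)):
        if lod[i] < cutoff:
            right = i
            break
    return QTLInterval(
        chrom=chrom, start_bp=int(pos[left]), end_bp=int(pos[right]),
        peak_snp=str(t.index[peak_i]), peak_lod=float(lod[peak_i]),
    )


def intersect_intervals(i1: QTLInterval, i2: QTLInterval) -> QTLInterval:
    """Overlap of two support intervals on the same chromosome."""
    if i1.chrom != i2.chrom:
        raise ValueError("intervals lie on different chromosomes")
    start = max(i1.start_bp, i2.start_bp)
    end = min(i1.end_bp, i2.end_bp)
    if start > end:
        raise ValueError("intervals are disjoint")
    keep = i1 if i1.peak_lod >= i2.peak_lod else i2
    return QTLInterval(chrom=i1.chrom, start_bp=start, end_bp=end,
                       peak_snp=keep.peak_snp, peak_lod=keep.peak_lod)
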