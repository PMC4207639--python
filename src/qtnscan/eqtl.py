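"""Expression adjustment, cis-eQTL scanning and pQTL/eQTL colocalization.

Expression values are adjusted in two stages: a robust (Huber M-estimator)
regression on sex and batch removes technical shifts without being dragged
by count outliers, and the residuals are then polygenically residualized
against the genomic relationship matrix (the two-stage GRAMMAR strategy).
eQTL scans reuse the same mixed-model score-test engine as the phenotype
GWAS with expression as the response. Colocalization is judged exactly the
way a lead-SNP argument is made: the trait scan and the expression scan
must peak at the same SNP inside the gene's cis window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import mlm
from .containers import AssocResult, GenotypeMatrix

__all__ = [
    "CisWindow",
    "cis_window",
    "adjust_expression",
    "eqtl_scan",
    "colocalize",
    "expr_trait_correlation",
    "functional_vs_total_contrast",
]

CIS_MARGIN_BP = 2_000_000


@dataclass(frozen=True)
class CisWindow:
    """Gene body extended by the cis margin on each side (bp, clipped at 1)."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("empty cis window")


def cis_window(gene: str, chrom: str, gene_start: int, gene_end: int,
               margin: int = CIS_MARGIN_BP, chrom_end: int | None = None) -> CisWindow:
    start = max(1, gene_start - margin)
    end = gene_end + margin
    if chrom_end is not None:
        end = min(end, chrom_end)
    return CisWindow(gene=gene, chrom=chrom, start=start, end=end)


def adjust_expression(values, sex, batch, grm=None) -> np.ndarray:
    """Adjust an expression vector for sex, batch and kinship.

    Stage 1 is a Huber robust regression on intercept + sex + batch dummies;
    stage 2 residualizes the robust residuals against the GRM through the
    polygenic model (skipped when ``grm`` is None). A constant input vector
    is returned centered, with a warning.
    """
    y = np.asarray(values, dtype=float).ravel()
    if np.ptp(y) == 0:
        warnings.warn("constant expression vector; returning centered values")
        return y - y.mean()
    design = [np.ones(len(y))]
    for cov in (sex, batch):
        dummies = pd.get_dummies(pd.Series(np.asarray(cov)), drop_first=True)
        for col in dummies.columns:
            design.append(dummies[col].to_numpy(dtype=float))
    X = np.column_stack(design)
    rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
    resid = np.asarray(rlm.resid)
    if grm is None:
        return resid
    fit = mlm.fit_polygenic(resid, np.ones((len(resid), 1)), grm)
    return np.asarray(fit.grammar_residuals)


def eqtl_scan(adjusted_expr, g: GenotypeMatrix, grm=None,
              fit: mlm.PolygenicFit | None = None) -> AssocResult:
    """Mixed-model score-test scan with an expression vector as response.

    Either a precomputed polygenic ``fit`` of the expression vector or a
    ``grm`` (from which one is fitted with an intercept-only design) must be
    supplied.
    """
    y = np.asarray(adjusted_expr, dtype=float).ravel()
    if fit is None:
        if grm is None:
            raise ValueError("supply either grm or a polygenic fit")
        fit = mlm.fit_polygenic(y, np.ones((len(y), 1)), grm, samples=g.samples)
    return mlm.score_test_scan(fit, g)


def colocalize(pqtl: AssocResult, eqtl: AssocResult, window: CisWindow):
    """Lead-SNP colocalization inside a cis window.

    Returns (is_colocalized, pqtl_peak_id, eqtl_peak_id); the flag is true
    iff both scans attain their window-wide minimum P at the same SNP id
    (P ties broken by smallest position).
    """
    peaks = []
    for res in (pqtl, eqtl):
        t = res.table
        sub = t[(t["chrom"] == window.chrom)
                & (t["pos"] >= window.start) & (t["pos"] <= window.end)]
        if sub.empty:
            raise ValueError("scan has no SNP inside the cis window")
        best = sub[sub["p"] == sub["p"].min()].sort_values("pos", kind="stable")
        peaks.append(str(best.index[0]))
    return peaks[0] == peaks[1], peaks[0], peaks[1]


def expr_trait_correlation(expr_values, trait_values):
    """Pearson correlation (r, two-sided P) between expression and trait."""
    x = np.asarray(expr_values, dtype=float)
    y = np.asarray(trait_values, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired finite observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance vector in correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def functional_vs_total_contrast(expr_total, expr_functional, trait):
    """Trait correlation of the total-transcript vs functional-transcript tracks.

    A tag assay anchored upstream of a truncating lesion counts aberrant and
    functional transcripts alike; on calibrated splice/NMD simulations the
    functional track is the one that correlates with the trait. Returns
    (r_total, r_functional).
    """
    if expr_total is None or expr_functional is None:
        raise ValueError("both expression tracks are required")
    r_total, _ = expr_trait_correlation(expr_total, trait)
    r_functional, _ = expr_trait_correlation(expr_functional, trait)
    return r_total, r_functional
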