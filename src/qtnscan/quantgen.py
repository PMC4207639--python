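"""Quantitative-genetics trait arithmetic and small association models.

Collects the scalar formulas of the analysis: glycolytic potential from its
biochemical components, additive/dominance decomposition of genotype means,
percent contrasts, splice/NMD transcript-ratio arithmetic, comparative-Ct
fold changes, least-square genotype means from a covariate-adjusted GLM,
and allele-frequency tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TraitComponents",
    "GenotypeMeans",
    "glycolytic_potential",
    "additive_dominance",
    "percent_change",
    "nmd_degradation_fraction",
    "ddct_relative_expression",
    "genotype_trait_glm",
    "allele_frequency",
]


@dataclass(frozen=True)
class TraitComponents:
    """Glycogen-pathway components in µmol/g wet muscle."""

    residual_g: float   # glycogen + glucose
    g6p: float          # glucose-6-phosphate
    lactate: float

    def __post_init__(self) -> None:
        for name in ("residual_g", "g6p", "lactate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")


@dataclass(frozen=True)
class GenotypeMeans:
    mean_QQ: float
    mean_Qq: float
    mean_qq: float
    n_QQ: int = 1
    n_Qq: int = 1
    n_qq: int = 1


def glycolytic_potential(tc: TraitComponents) -> float:
    """GP = 2 x (residual glycogen&glucose + G-6-P) + lactate, in µmol/g."""
    return 2.0 * (tc.residual_g + tc.g6p) + tc.lactate


def additive_dominance(m: GenotypeMeans):
    """(a, d) from genotype means: a = (QQ - qq)/2, d = Qq - (QQ + qq)/2."""
    a = (m.mean_QQ - m.mean_qq) / 2.0
    d = m.mean_Qq - (m.mean_QQ + m.mean_qq) / 2.0
    return a, d


def percent_change(m_high: float, m_low: float) -> float:
    """100 x (m_high - m_low) / m_low."""
    if m_low <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (m_high - m_low) / m_low


def nmd_degradation_fraction(total_to_wt_ratio: float,
                             expected_mt_per_wt: float = 1.0) -> float:
    """Fraction of mutant transcript degraded by NMD.

    From a measured total:wild-type transcript ratio in heterozygotes, the
    surviving mutant fraction is (ratio - 1) / expected, where ``expected``
    is the mutant:wild-type ratio that equal allelic transcription would
    give before decay; the degraded fraction is its complement, clipped to
    [0, 1].
    """
    if expected_mt_per_wt <= 0:
        raise ValueError("expected mutant:wild-type ratio must be positive")
    if total_to_wt_ratio < 1.0:
        raise ValueError("total:wild-type ratio cannot be below 1")
    surviving = (total_to_wt_ratio - 1.0) / expected_mt_per_wt
    return float(np.clip(1.0 - surviving, 0.0, 1.0))


def ddct_relative_expression(ct_target_sample: float, ct_ref_sample: float,
                             ct_target_calibrator: float,
                             ct_ref_calibrator: float) -> float:
    """Comparative-Ct fold change 2^-ddCt."""
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))


def genotype_trait_glm(trait, genotype, sex, batch, carcass_weight):
    """Least-square genotype means with sex/batch factors and a weight covariate.

    Ordinary least squares of ``trait ~ C(genotype) + C(sex) + C(batch) +
    carcass_weight``; LS means are predictions per genotype class at the
    covariate mean averaged over the factor levels' observed distribution.
    Returns a dict with ``lsmeans`` (DataFrame: mean, se, n per genotype)
    and ``p_genotype`` (F-test for the genotype factor).
    """
    df = pd.DataFrame({
        "trait": np.asarray(trait, dtype=float),
        "genotype": pd.Categorical(genotype),
        "sex": pd.Categorical(sex),
        "batch": pd.Categorical(batch),
        "weight": np.asarray(carcass_weight, dtype=float),
    })
    levels = list(df["genotype"].cat.categories)
    counts = df["genotype"].value_counts()
    if len(levels) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 genotype classes with >= 2 observations")
    terms = ["C(genotype)"]
    for factor in ("sex", "batch"):
        if df[factor].nunique() > 1:
            terms.append(f"C({factor})")
    terms.append("weight")
    formula = "trait ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df)
    fit = model.fit()
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("rank-deficient design")
    anova = sm.stats.anova_lm(fit, typ=2)
    p_geno = float(anova.loc["C(genotype)", "PR(>F)"])

    rows = {}
    for lvl in levels:
        # average the design over the observed sex/batch distribution with
        # the weight covariate at its mean (population-marginal LS mean)
        ref = df.copy()
        ref["genotype"] = pd.Categorical([lvl] * len(df), categories=levels)
        ref["weight"] = df["weight"].mean()
        design = smf.ols(formula, data=ref).exog
        xbar = design.mean(axis=0)
        mean = float(xbar @ fit.params.to_numpy())
        se = float(np.sqrt(xbar @ fit.cov_params().to_numpy() @ xbar))
        rows[lvl] = {"mean": mean, "se": se, "n": int(counts[lvl])}
    lsmeans = pd.DataFrame(rows).T
    return {"lsmeans": lsmeans, "p_genotype": p_geno, "model": fit}


def allele_frequency(genotypes_by_population: dict) -> pd.DataFrame:
    """Mutant-allele frequency per population from 0/1/2 dosages.

    frequency = (2 n_hom_mut + n_het) / (2 n_typed); missing calls excluded.
    """
    rows = {}
    for pop, geno in genotypes_by_population.items():
        g = np.asarray(geno, dtype=float)
        g = g[~np.isnan(g)]
        if len(g) == 0:
            raise ValueError(f"population {pop!r} has no genotyped animal")
        freq = (2.0 * np.sum(g == 2) + np.sum(g == 1)) / (2.0 * len(g))
        rows[pop] = {"n": int(len(g)), "mutant_freq": float(freq)}
    return pd.DataFrame(rows).T
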