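"""Marker-assisted segregation analysis of sire QTL genotypes.

Offspring of a sire are grouped by which paternal haplotype they received
at the locus of interest; if the sire is heterozygous Qq at the QTL, the two
groups differ in mean phenotype. The evidence is summarized per sire as

    Z = log10( L(H1) / L(H0) )

where H1 is a two-mean common-variance normal model (one mean per
transmitted-haplotype class, maximum likelihood) and H0 a single-mean normal
model. With ML variance estimates the ratio collapses to a residual-sum-of-
squares form, Z = (n/2) * log10(RSS0 / RSS1). A sire is called Qq when
Z > 2, homozygous (QQ or qq) when Z < -2, and undetermined otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, SireFamily

__all__ = [
    "SegregationResult",
    "build_sire_family",
    "infer_transmitted_haplotype",
    "sire_zscore",
    "classify_sire",
    "analyze_sire",
    "concordance_test",
]


@dataclass
class SegregationResult:
    sire_id: str
    z: float
    call: str                     # 'Qq', 'homozygous' or 'undetermined'
    labels: pd.Series             # per-offspring transmission label
    n_used: int = 0
    high_hap: int | None = None   # paternal haplotype with the higher mean


_TRANSMISSIBLE = {0.0: (0,), 1.0: (0, 1), 2.0: (1,)}


def build_sire_family(g: GenotypeMatrix, pedigree: pd.DataFrame,
                      phenotypes: pd.Series, sire_id: str,
                      chrom, start_bp: int, end_bp: int,
                      adjusted: bool = True) -> SireFamily:
    """Assemble one sire's regional family from phased genotypes + pedigree.

    ``phenotypes`` should already be residualized for fixed effects when
    ``adjusted`` phenotype comparisons are wanted. Requires phase for the
    sire (``g.haplotypes``).
    """
    if g.haplotypes is None:
        raise ValueError("phased haplotypes are required for segregation analysis")
    region = g.snps[(g.snps["chrom"] == chrom)
                    & (g.snps["pos"] >= start_bp) & (g.snps["pos"] <= end_bp)]
    if region.empty:
        raise ValueError("no markers in the requested region")
    cols = np.array([g.snp_index(s) for s in region.index])
    sidx = g.sample_indexer([sire_id])[0]
    sire_haps = g.haplotypes[sidx][cols].T  # (2, m)

    kids = [k for k in pedigree.index
            if pedigree.loc[k, "sire"] == sire_id and k in phenotypes.index]
    if not kids:
        raise ValueError(f"sire {sire_id} has no phenotyped offspring")
    kid_rows = g.sample_indexer(kids)
    off_dos = g.dosage[np.ix_(kid_rows, cols)]
    dam_dos = np.full_like(off_dos, np.nan)
    sample_set = {s: i for i, s in enumerate(g.samples)}
    for r, k in enumerate(kids):
        dam = pedigree.loc[k, "dam"]
        if dam in sample_set:
            dam_dos[r] = g.dosage[sample_set[dam], cols]
    return SireFamily(
        sire_id=sire_id,
        marker_ids=list(region.index),
        marker_pos=region["pos"].to_numpy(),
        sire_haps=sire_haps.astype(float),
        offspring_ids=kids,
        offspring_dosage=off_dos,
        dam_dosage=dam_dos,
        phenotypes=phenotypes.loc[kids].to_numpy(dtype=float),
    )


def _paternal_allele(off: float, dam: float) -> float | None:
    """Paternal transmitted allele if unambiguous, else None."""
    if np.isnan(off):
        return None
    if np.isnan(dam):
        # without the dam only homozygous offspring are unambiguous
        if off == 0.0:
            return 0.0
        if off == 2.0:
            return 1.0
        return None
    candidates = {
        off - a_d
        for a_d in _TRANSMISSIBLE.get(dam, ())
        if off - a_d in (0.0, 1.0)
    }
    if len(candidates) == 1:
        return candidates.pop()
    return None


def infer_transmitted_haplotype(family: SireFamily, position: int) -> pd.Series:
    """Label each offspring with the paternal haplotype it received.

    For each offspring, markers are visited in order of distance to
    ``position``; the first marker at which the sire is heterozygous and the
    transmitted paternal allele is unambiguous (given offspring and, where
    available, dam genotypes) assigns the label 'hap1' or 'hap2'. Offspring
    with no informative resolvable marker are labeled 'unknown'.
    """
    het = family.sire_haps[0] != family.sire_haps[1]
    if not het.any():
        raise ValueError("sire is homozygous at every regional marker")
    order = np.argsort(np.abs(family.marker_pos - position), kind="stable")
    order = [j for j in order if het[j]]
    labels = []
    for r in range(len(family.offspring_ids)):
        label = "unknown"
        for j in order:
            allele = _paternal_allele(family.offspring_dosage[r, j],
                                      family.dam_dosage[r, j])
            if allele is None:
                continue
            label = "hap1" if allele == family.sire_haps[0, j] else "hap2"
            break
        labels.append(label)
    return pd.Series(labels, index=family.offspring_ids, name="transmission")


def sire_zscore(phenotypes, labels) -> float:
    """Z = (n/2) log10(RSS0 / RSS1) for the two transmission classes.

    RSS0 is about the grand mean; RSS1 about the class means. Offspring
    labeled 'unknown' are excluded; each class must retain >= 2 offspring.
    """
    y = np.asarray(phenotypes, dtype=float)
    lab = np.asarray(labels)
    keep = lab != "unknown"
    y, lab = y[keep], lab[keep]
    n1 = int((lab == "hap1").sum())
    n2 = int((lab == "hap2").sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each transmission class needs >= 2 offspring")
    n = n1 + n2
    rss0 = float(np.sum((y - y.mean()) ** 2))
    rss1 = 0.0
    for cls in ("hap1", "hap2"):
        grp = y[lab == cls]
        rss1 += float(np.sum((grp - grp.mean()) ** 2))
    if rss1 <= 0:
        return math.inf if rss0 > rss1 else 0.0
    return (n / 2.0) * math.log10(rss0 / rss1)


def classify_sire(z: float) -> str:
    """Apply the published thresholds: Z>2 -> Qq, Z<-2 -> homozygous."""
    if not np.isfinite(z):
        raise ValueError("Z score must be finite")
    if z > 2.0:
        return "Qq"
    if z < -2.0:
        return "homozygous"
    return "undetermined"


def analyze_sire(family: SireFamily, position: int) -> SegregationResult:
    """Transmission labeling, Z score and genotype call for one sire."""
    labels = infer_transmitted_haplotype(family, position)
    z = sire_zscore(family.phenotypes, labels.to_numpy())
    keep = labels.to_numpy() != "unknown"
    y = family.phenotypes[keep]
    lab = labels.to_numpy()[keep]
    means = {cls: y[lab == cls].mean() for cls in ("hap1", "hap2")}
    high = 0 if means["hap1"] >= means["hap2"] else 1
    return SegregationResult(
        sire_id=family.sire_id, z=z, call=classify_sire(z),
        labels=labels, n_used=int(keep.sum()), high_hap=high,
    )


def concordance_test(candidate_genotypes: dict, results: list,
                     candidate_high_allele: dict | None = None):
    """Concordance between a candidate SNP and deduced sire QTL genotypes.

    ``candidate_genotypes`` maps sire id -> candidate dosage (0/1/2);
    ``results`` are per-sire SegregationResults. A sire is concordant iff
    the SNP's heterozygosity status matches the deduced status. When
    ``candidate_high_allele`` (sire id -> candidate allele carried on the
    phenotype-raising paternal haplotype) is given for Qq sires, the
    allele -> Q orientation must additionally be identical across sires for
    full concordance. Undetermined sires are excluded from the tally.
    """
    tested = [r for r in results if r.call != "undetermined"]
    if not tested:
        raise ValueError("every sire is of undetermined QTL genotype")
    n_concordant = 0
    orientations = set()
    for r in tested:
        dose = candidate_genotypes[r.sire_id]
        snp_het = dose == 1
        if (r.call == "Qq") == snp_het:
            n_concordant += 1
            if r.call == "Qq" and candidate_high_allele is not None:
                orientations.add(candidate_high_allele[r.sire_id])
    fully = n_concordant == len(tested) and len(orientations) <= 1
    return n_concordant, len(tested), fully
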