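"""Genotype and sample quality control.

Filters mirror standard SNP-chip practice for pedigreed populations:
samples must exceed a call-rate bound and stay below a Mendelian-error
bound; SNPs must exceed call-rate and minor-allele-frequency bounds and
pass an exact Hardy-Weinberg test. All bounds are strict inequalities.

The filter order is fixed and recorded in the report: sample call rate,
then Mendelian error, then SNP call rate, MAF and HWE (computed on the
samples that survived). HWE is tested on the full retained cohort even
though an intercross is not a random-mating population; this matches how
chip QC is typically run on such designs and is a documented caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import GenotypeMatrix

__all__ = ["QCThresholds", "QCReport", "hwe_test", "mendelian_error_rate", "apply_qc"]


@dataclass(frozen=True)
class QCThresholds:
    sample_call_rate: float = 0.9   # keep samples with call rate > this
    mendel_rate: float = 0.05       # keep samples with Mendelian error rate < this
    snp_call_rate: float = 0.9      # keep SNPs with call rate > this
    maf: float = 0.05               # keep SNPs with MAF > this
    hwe_p: float = 1e-5             # keep SNPs with exact HWE P > this


@dataclass
class QCReport:
    snp_metrics: pd.DataFrame       # call_rate, maf, hwe_p per input SNP
    sample_metrics: pd.DataFrame    # call_rate, mendel_rate per input sample
    removed_snps: pd.Series         # snp id -> primary removal reason
    removed_samples: pd.Series      # sample id -> primary removal reason
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    filter_order: tuple = (
        "sample_call_rate", "mendel_rate", "snp_call_rate", "maf", "hwe",
    )

    def summary(self) -> dict:
        return {
            "n_snps_removed": int(len(self.removed_snps)),
            "n_samples_removed": int(len(self.removed_samples)),
            "snp_reasons": self.removed_snps.value_counts().to_dict(),
            "sample_reasons": self.removed_samples.value_counts().to_dict(),
        }


def hwe_test(genotype_counts) -> float:
    """Exact Hardy-Weinberg test P value (no mid-P correction).

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the conditional probabilities of all configurations no
    more probable than the observed one (Wigginton-style two-sided exact
    test). Returns a value in (0, 1].
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    # heterozygote count shares parity with the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    # P(n_ab = h | allele counts) ∝ n! / (homr! h! homc!) * 2^h
    logp = (
        hets * np.log(2.0)
        - gammaln(homr + 1) - gammaln(hets + 1) - gammaln(homc + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = n_ab
    p_obs = probs[hets == observed]
    if len(p_obs) == 0:  # pragma: no cover - inconsistent input
        raise ValueError("observed heterozygote count inconsistent with alleles")
    p = probs[probs <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


_TRANSMISSIBLE = {0.0: (0,), 1.0: (0, 1), 2.0: (1,)}


def _trio_consistent(off: float, sire: float, dam: float) -> bool:
    return any(
        off == a_s + a_d
        for a_s in _TRANSMISSIBLE[sire]
        for a_d in _TRANSMISSIBLE[dam]
    )


def mendelian_error_rate(offspring: np.ndarray, sire: np.ndarray,
                         dam: np.ndarray) -> float:
    """Fraction of tested SNPs with a Mendelian-impossible trio genotype.

    A SNP is tested only when offspring, sire and dam are all non-missing;
    an error is any offspring dosage impossible under biallelic transmission
    from the parental dosages.
    """
    off = np.asarray(offspring, dtype=float)
    s = np.asarray(sire, dtype=float)
    d = np.asarray(dam, dtype=float)
    ok = ~(np.isnan(off) | np.isnan(s) | np.isnan(d))
    n_tested = int(ok.sum())
    if n_tested == 0:
        raise ValueError("no SNP with a complete non-missing trio genotype")
    errors = sum(
        0 if _trio_consistent(o, a, b) else 1
        for o, a, b in zip(off[ok], s[ok], d[ok])
    )
    return errors / n_tested


def _snp_metrics(g: GenotypeMatrix) -> pd.DataFrame:
    call_rate = g.call_rate_snp()
    freq = g.alt_frequency()
    maf = np.minimum(freq, 1.0 - freq)
    hwe = np.ones(g.n_snps)
    d = g.dosage
    for j in range(g.n_snps):
        col = d[:, j]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            hwe[j] = np.nan
            continue
        counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        hwe[j] = hwe_test(counts)
    return pd.DataFrame(
        {"call_rate": call_rate, "maf": maf, "hwe_p": hwe}, index=g.snps.index
    )


def apply_qc(g: GenotypeMatrix, pedigree: pd.DataFrame,
             thresholds: QCThresholds | None = None):
    """Apply sample-then-SNP QC filters; return (filtered matrix, report).

    ``pedigree`` is indexed by animal id with ``sire`` and ``dam`` columns
    ('0' for unknown). Mendelian error rates are computed only for samples
    whose both parents are genotyped.
    """
    th = thresholds or QCThresholds()
    idx = {s: i for i, s in enumerate(g.samples)}

    sample_cr = g.call_rate_sample()
    mendel = np.full(g.n_samples, np.nan)
    for i, sample in enumerate(g.samples):
        if sample not in pedigree.index:
            continue
        sire = pedigree.loc[sample, "sire"]
        dam = pedigree.loc[sample, "dam"]
        if sire in idx and dam in idx:
            try:
                mendel[i] = mendelian_error_rate(
                    g.dosage[i], g.dosage[idx[sire]], g.dosage[idx[dam]])
            except ValueError:
                mendel[i] = np.nan
    sample_metrics = pd.DataFrame(
        {"call_rate": sample_cr, "mendel_rate": mendel},
        index=pd.Index(g.samples, name="id"),
    )

    removed_samples = {}
    for sample, row in sample_metrics.iterrows():
        if not row["call_rate"] > th.sample_call_rate:
            removed_samples[sample] = "call_rate"
        elif np.isfinite(row["mendel_rate"]) and not row["mendel_rate"] < th.mendel_rate:
            removed_samples[sample] = "mendel_rate"
    kept_samples = [s for s in g.samples if s not in removed_samples]
    if not kept_samples:
        raise ValueError("no samples survive QC")
    g1 = g.subset(samples=kept_samples)

    snp_metrics = _snp_metrics(g1)
    removed_snps = {}
    for snp, row in snp_metrics.iterrows():
        if not row["call_rate"] > th.snp_call_rate:
            removed_snps[snp] = "call_rate"
        elif not row["maf"] > th.maf:
            removed_snps[snp] = "maf"
        elif not (np.isfinite(row["hwe_p"]) and row["hwe_p"] > th.hwe_p):
            removed_snps[snp] = "hwe"
    kept_snps = [s for s in g1.snp_ids if s not in removed_snps]
    if not kept_snps:
        raise ValueError("no SNPs survive QC")
    g2 = g1.subset(snps=kept_snps)

    report = QCReport(
        snp_metrics=snp_metrics,
        sample_metrics=sample_metrics,
        removed_snps=pd.Series(removed_snps, dtype=object),
        removed_samples=pd.Series(removed_samples, dtype=object),
        thresholds=th,
    )
    return g2, report
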