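import numpy as np
import pandas as pd
import pytest

from qtnscan import simdata
from qtnscan.containers import GenotypeMatrix


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale cross: one background chromosome, modest cohorts."""
    return simdata.SimConfig(
        n_f2=400, n_halfsib=150, n_chroms=2, n_snps_per_chrom=120, seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simdata.simulate_cross(small_config)


@pytest.fixture(scope="session")
def default_sim():
    """The full study-scale cross (930 F2, 434 half-sib)."""
    return simdata.simulate_cross(simdata.SimConfig(seed=3))


def make_genotype_matrix(dosage, chrom="1", pos=None, sample_prefix="s",
                         haplotypes=None):
    """Small helper to build a GenotypeMatrix from a plain dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if pos is None:
        pos = (np.arange(m) + 1) * 1_000_000
    snps = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": pos,
            "cm": np.asarray(pos) / 1e6,
            "ref": ["C"] * m,
            "alt": ["A"] * m,
        },
        index=pd.Index([f"snp{j}" for j in range(m)], name="id"),
    )
    return GenotypeMatrix(
        samples=[f"{sample_prefix}{i}" for i in range(n)],
        snps=snps, dosage=dosage, haplotypes=haplotypes,
    )
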