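"""Core in-memory containers shared across the pipeline.

Genotypes are held as additive dosages of the ALT allele (0/1/2, NaN for
missing) over samples x SNPs, alongside a marker table with both genetic
(cM) and physical (bp) coordinates. Phased haplotypes are carried when the
source provides phase (the simulator always does; real phased VCFs may).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "AssocResult",
    "QTLInterval",
    "SireFamily",
]


@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix with marker metadata.

    Parameters
    ----------
    samples : list of str
        Sample identifiers, one per row of ``dosage``.
    snps : pandas.DataFrame
        One row per marker, indexed by SNP id, with at least columns
        ``chrom``, ``pos`` (bp, 1-based), ``cm`` (genetic position),
        ``ref`` and ``alt``.
    dosage : ndarray of shape (n_samples, n_snps)
        ALT-allele dosage; ``NaN`` marks a missing call.
    haplotypes : ndarray of shape (n_samples, n_snps, 2), optional
        Phased ALT-allele indicators (-1 for missing); ``None`` when
        phase is unknown.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    def sample_indexer(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"sample {e} not in genotype matrix") from None

    def snp_index(self, snp_id: str) -> int:
        loc = self.snps.index.get_loc(snp_id)
        if not isinstance(loc, (int, np.integer)):
            raise KeyError(f"SNP id {snp_id!r} is not unique")
        return int(loc)

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given samples / SNP ids."""
        rows = np.arange(self.n_samples) if samples is None else self.sample_indexer(samples)
        if snps is None:
            cols = np.arange(self.n_snps)
        else:
            cols = np.array([self.snp_index(s) for s in snps], dtype=int)
        hap = None if self.haplotypes is None else self.haplotypes[np.ix_(rows, cols)]
        return GenotypeMatrix(
            samples=[self.samples[i] for i in rows],
            snps=self.snps.iloc[cols].copy(),
            dosage=self.dosage[np.ix_(rows, cols)].copy(),
            haplotypes=hap,
        )

    def alt_frequency(self) -> np.ndarray:
        """Per-SNP ALT allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def call_rate_snp(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosage), axis=0)

    def call_rate_sample(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosage), axis=1)


@dataclass
class AssocResult:
    """Per-SNP single-marker association results along the map.

    ``table`` columns: ``chrom``, ``pos``, ``beta``, ``se``, ``chisq``,
    ``p``, ``lod``, ``flag`` (e.g. 'monomorphic'), indexed by SNP id and
    sorted by (chrom, pos).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.sort_values(["chrom", "pos"], kind="stable")

    def on_chrom(self, chrom) -> pd.DataFrame:
        sub = self.table[self.table["chrom"] == chrom]
        if sub.empty:
            raise ValueError(f"no SNPs on chromosome {chrom!r}")
        return sub

    def peak(self, chrom=None) -> pd.Series:
        """Minimum-P SNP (ties broken by smallest genomic position)."""
        t = self.table if chrom is None else self.on_chrom(chrom)
        best_p = t["p"].min()
        hits = t[t["p"] == best_p].sort_values(["chrom", "pos"], kind="stable")
        return hits.iloc[0]


@dataclass(frozen=True)
class QTLInterval:
    """A LOD-drop support interval on one chromosome (bp, 1-based, inclusive)."""

    chrom: str
    start_bp: int
    end_bp: int
    peak_snp: str
    peak_lod: float

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("interval start exceeds end")

    @property
    def width_bp(self) -> int:
        return self.end_bp - self.start_bp

    def contains(self, chrom, pos: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos <= self.end_bp


@dataclass
class SireFamily:
    """One sire's phased regional haplotypes and its offspring records.

    Markers are ordered by genomic position. ``sire_haps`` rows are the two
    paternal haplotypes (ALT indicators). Dam dosages may be NaN when the
    dam is untyped; transmission is then resolved only where it is
    unambiguous from sire + offspring alone.
    """

    sire_id: str
    marker_ids: list[str]
    marker_pos: np.ndarray
    sire_haps: np.ndarray  # (2, n_markers)
    offspring_ids: list[str]
    offspring_dosage: np.ndarray  # (n_off, n_markers)
    dam_dosage: np.ndarray  # (n_off, n_markers), NaN allowed
    phenotypes: np.ndarray  # (n_off,)

    def __post_init__(self) -> None:
        self.marker_pos = np.asarray(self.marker_pos)
        self.sire_haps = np.asarray(self.sire_haps)
        if self.sire_haps.shape != (2, len(self.marker_ids)):
            raise ValueError("sire_haps must be (2, n_markers)")
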