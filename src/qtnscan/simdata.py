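"""Forward simulator for a two-breed F2 intercross plus an admixed half-sib line.

The generator emulates the data structure a glycogen-content QTN study relies
on: two divergent founder breeds fixed for alternate alleles at a biallelic
causal variant (QTN), an F2 intercross produced from a small number of F1
parents, and a separately admixed half-sib population. The causal variant acts
on residual glycogen (RG, µmol/g) with additive and dominance effects on the
observed trait scale, on top of a pedigree-transmitted polygenic term and
sex/batch/carcass-weight nuisance effects. Glucose-6-phosphate and lactate are
drawn independently of the QTN, and glycolytic potential is computed from its
defining formula, so only glycogen-pathway traits carry the signal.

Expression of the focal gene is generated through a splice-leakage /
nonsense-mediated-decay (NMD) mechanism: each mutant allele yields a fraction
``lambda`` of correctly spliced (functional) transcript plus a fraction
``(1 - lambda) * nu`` of aberrant transcript that survives NMD. The tag-count
assay measures the TOTAL transcript pool (it cannot distinguish aberrant from
functional), so the simulator emits both a total-count track (Poisson counts)
and a functional-level track, mirroring the distinction between a 5'-anchored
digital tag and a wild-type-specific qPCR assay.

Gametes recombine under the Haldane map function (no interference).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "SimConfig",
    "TruthSet",
    "ExpressionData",
    "SimResult",
    "splice_expression_level",
    "simulate_cross",
]

# lambda=2/33, nu=14/31 solve 1+(1-l)n/(1+l)=1.4 and 1+(1-l)n/l=8 exactly,
# i.e. heterozygote total:functional = 1.4 and mutant-homozygote = 8.
DEFAULT_LAMBDA = 2.0 / 33.0
DEFAULT_NU = 14.0 / 31.0


@dataclass
class SimConfig:
    """Study-design and generative parameters.

    Defaults reproduce the published study conditions: ~930 F2 animals bred
    from 2 x 17 founders through 9 F1 boars and 59 F1 sows, a 434-animal
    half-sib line from 4 sires, RG additive/dominance effects of 12.88 and
    -8.92 µmol/g, and splice/NMD parameters calibrated so the heterozygote
    total:functional transcript ratio is 1.4 and the mutant-homozygote ratio
    is 8.
    """

    n_f2: int = 930
    n_halfsib: int = 434
    n_snps_per_chrom: int = 300
    n_chroms: int = 3
    map_length_cM: float = 100.0
    qtn_chrom: str = "1"
    qtn_pos_bp: int = 45_000_000
    a_RG: float = 12.88          # additive effect, µmol/g
    d_RG: float = -8.92          # dominance effect, µmol/g
    mu_RG: float = 33.87         # mid-homozygote RG mean, µmol/g
    sigma_RG: float = 12.5       # non-QTN phenotypic SD, µmol/g
    h2_polygenic: float = 0.3    # polygenic share of non-QTN variance
    lambda_splice: float = DEFAULT_LAMBDA  # correct-splice leakage per mutant allele
    nu_nmd: float = DEFAULT_NU             # NMD survival of aberrant transcript
    mutant_transcription: float = 1.0      # pre-NMD output of a mutant allele
    founder_freq_divergence: float = 0.5   # breed allele-frequency contrast
    hs_admix_generations: int = 10         # ancestry-mosaic age of the half-sib line
    n_f1_boars: int = 9
    n_f1_sows: int = 59
    n_hs_sires: int = 4
    n_hs_dams: int = 55
    n_batches: int = 6
    n_background_genes: int = 30
    mean_focal_count: float = 25.0  # expected tag count per transcript unit
    sigma_expr: float = 0.4         # log-scale biological expression noise
    bp_per_cM: float = 1e6
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.lambda_splice <= 1.0):
            raise ValueError("lambda_splice must lie in [0, 1]")
        if not (0.0 <= self.nu_nmd <= 1.0):
            raise ValueError("nu_nmd must lie in [0, 1]")
        if not (0.0 <= self.h2_polygenic < 1.0):
            raise ValueError("h2_polygenic must lie in [0, 1)")
        if self.qtn_chrom not in {str(c + 1) for c in range(self.n_chroms)}:
            raise ValueError(f"QTN chromosome {self.qtn_chrom!r} is not simulated")
        if not (0 <= self.qtn_pos_bp <= self.map_length_cM * self.bp_per_cM):
            raise ValueError("QTN position lies off the simulated map")


@dataclass
class TruthSet:
    """Simulator ground truth for parameter-recovery tests."""

    qtn_id: str
    qtn_chrom: str
    qtn_pos_bp: int
    qtn_genotype: pd.Series          # per animal: mutant-allele count
    breeding_value: pd.Series        # per animal: polygenic value
    lambda_splice: float
    nu_nmd: float
    a_RG: float
    d_RG: float
    mu_RG: float
    sire_qtl_genotype: dict = field(default_factory=dict)  # sire -> QQ/Qq/qq

    def to_json(self, path) -> None:
        payload = {
            "qtn_id": self.qtn_id,
            "qtn_chrom": self.qtn_chrom,
            "qtn_pos_bp": int(self.qtn_pos_bp),
            "lambda_splice": self.lambda_splice,
            "nu_nmd": self.nu_nmd,
            "a_RG": self.a_RG,
            "d_RG": self.d_RG,
            "mu_RG": self.mu_RG,
            "qtn_genotype": {k: int(v) for k, v in self.qtn_genotype.items()},
            "breeding_value": {k: float(v) for k, v in self.breeding_value.items()},
            "sire_qtl_genotype": dict(self.sire_qtl_genotype),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class ExpressionData:
    """Tag counts plus the functional-transcript track the tag assay misses."""

    counts: pd.DataFrame        # genes x samples, integer tag counts
    genes: pd.DataFrame         # gene annotation: chrom, start, end, strand
    functional: pd.Series       # per-sample functional-transcript measure
    total_level: pd.Series      # per-sample noiseless total transcript level


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    pedigree: pd.DataFrame
    phenotypes: pd.DataFrame
    expression: ExpressionData
    truth: TruthSet


def splice_expression_level(qtn_genotype: int, lam: float, nu: float,
                            mutant_transcription: float = 1.0):
    """Functional and surviving-aberrant transcript levels for one genotype.

    Each wild-type allele contributes 1 unit of functional transcript. Each
    mutant allele transcribes ``mutant_transcription`` units, of which a
    fraction ``lam`` is spliced correctly (functional) and the remainder is
    aberrant; a fraction ``nu`` of the aberrant transcript survives NMD.

    Returns
    -------
    (functional, aberrant_surviving) : tuple of float
        Levels summed over both alleles.
    """
    if qtn_genotype not in (0, 1, 2):
        raise ValueError("genotype must be a mutant-allele count in {0, 1, 2}")
    if not (0.0 <= lam <= 1.0 and 0.0 <= nu <= 1.0):
        raise ValueError("lambda and nu must lie in [0, 1]")
    n_mut = qtn_genotype
    functional = (2 - n_mut) * 1.0 + n_mut * mutant_transcription * lam
    aberrant = n_mut * mutant_transcription * (1.0 - lam) * nu
    return functional, aberrant


# ---------------------------------------------------------------------------
# internals

def _marker_table(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for c in range(cfg.n_chroms):
        chrom = str(c + 1)
        cms = np.linspace(0.0, cfg.map_length_cM, cfg.n_snps_per_chrom)
        for i, cm in enumerate(cms):
            rows.append((f"c{chrom}_s{i:04d}", chrom, int(round(cm * cfg.bp_per_cM)) + 1, cm))
    snps = pd.DataFrame(rows, columns=["id", "chrom", "pos", "cm"]).set_index("id")
    qtn = pd.DataFrame(
        {"chrom": [cfg.qtn_chrom], "pos": [cfg.qtn_pos_bp],
         "cm": [cfg.qtn_pos_bp / cfg.bp_per_cM]},
        index=pd.Index(["qtn"], name="id"),
    )
    snps = pd.concat([snps, qtn]).sort_values(["chrom", "pos"], kind="stable")
    snps["ref"] = "C"
    snps["alt"] = "A"
    return snps


def _haldane_r(d_cm: np.ndarray) -> np.ndarray:
    """Recombination fraction between adjacent markers (Haldane, d in cM)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


class _Genome:
    def __init__(self, snps: pd.DataFrame):
        self.snps = snps
        self.chrom_slices = {}
        self.rec = {}
        chroms = snps["chrom"].to_numpy()
        for chrom in pd.unique(chroms):
            idx = np.flatnonzero(chroms == chrom)
            self.chrom_slices[chrom] = idx
            cm = snps["cm"].to_numpy()[idx]
            self.rec[chrom] = _haldane_r(np.diff(cm))

    def gamete(self, hap_pair: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw one recombinant gamete from a (2, n_snps) haplotype pair."""
        out = np.empty(hap_pair.shape[1], dtype=np.int8)
        for chrom, idx in self.chrom_slices.items():
            m = len(idx)
            switches = rng.random(m - 1) < self.rec[chrom]
            state = np.empty(m, dtype=np.int8)
            state[0] = rng.integers(2)
            state[1:] = (state[0] + np.cumsum(switches)) % 2
            out[idx] = hap_pair[state, idx]
        return out


def _founder_freqs(cfg: SimConfig, n_snps: int, qtn_col: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    base = rng.uniform(0.25, 0.75, size=n_snps)
    sign = rng.choice([-1.0, 1.0], size=n_snps)
    half = cfg.founder_freq_divergence / 2.0
    p_a = np.clip(base + sign * half, 0.02, 0.98)
    p_b = np.clip(base - sign * half, 0.02, 0.98)
    # breed A carries the mutant (ALT) allele fixed; breed B is wild-type
    p_a[qtn_col] = 1.0
    p_b[qtn_col] = 0.0
    return p_a, p_b


def simulate_cross(config: SimConfig) -> SimResult:
    """Generate genotypes, pedigree, phenotypes, expression and ground truth.

    The F2 design: 2 breed-A boars x 17 breed-B sows produce the F1
    generation; ``n_f1_boars`` F1 boars and ``n_f1_sows`` F1 sows are
    intercrossed at random to give ``n_f2`` offspring. The half-sib line is a
    single admixed generation: sires and dams carry haplotypes drawn from
    either breed pool with equal probability, and each half-sib offspring is
    bred from one of ``n_hs_sires`` sires.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    snps = _marker_table(cfg)
    genome = _Genome(snps)
    n_snps = len(snps)
    qtn_col = int(snps.index.get_loc("qtn"))
    p_a, p_b = _founder_freqs(cfg, n_snps, qtn_col, rng)

    ids: list[str] = []
    haps: list[np.ndarray] = []  # each (2, n_snps)
    ped_rows: list[tuple] = []
    id_of: dict[str, int] = {}

    def add(animal_id, sire, dam, sex, gen, hap_pair):
        id_of[animal_id] = len(ids)
        ids.append(animal_id)
        haps.append(hap_pair)
        ped_rows.append((animal_id, sire, dam, sex, gen))

    def breed_hap(p):
        return (rng.random((2, n_snps)) < p).astype(np.int8)

    # founders
    f0_boars = [f"WD_b{i}" for i in range(2)]
    f0_sows = [f"ER_s{i}" for i in range(17)]
    for a in f0_boars:
        add(a, "0", "0", 1, "F0", breed_hap(p_a))
    for a in f0_sows:
        add(a, "0", "0", 2, "F0", breed_hap(p_b))

    def offspring(animal_id, sire, dam, sex, gen):
        pair = np.stack([
            genome.gamete(haps[id_of[sire]], rng),
            genome.gamete(haps[id_of[dam]], rng),
        ])
        add(animal_id, sire, dam, sex, gen, pair)

    # F1
    f1_boars = [f"F1_b{i}" for i in range(cfg.n_f1_boars)]
    f1_sows = [f"F1_s{i}" for i in range(cfg.n_f1_sows)]
    for a in f1_boars:
        offspring(a, rng.choice(f0_boars), rng.choice(f0_sows), 1, "F1")
    for a in f1_sows:
        offspring(a, rng.choice(f0_boars), rng.choice(f0_sows), 2, "F1")

    # F2
    f2_ids = [f"F2_{i:04d}" for i in range(cfg.n_f2)]
    for a in f2_ids:
        offspring(a, rng.choice(f1_boars), rng.choice(f1_sows),
                  int(rng.integers(1, 3)), "F2")

    # half-sib line: parents carry ancestry-mosaic haplotypes, emulating a
    # 50/50 synthetic line after ``hs_admix_generations`` of recombination
    # (admixture LD decays with map distance; no drift/selection modeled)
    hs_sires = [f"HS_b{i}" for i in range(cfg.n_hs_sires)]
    hs_dams = [f"HS_d{i}" for i in range(cfg.n_hs_dams)]

    def admixed_hap():
        pair = np.empty((2, n_snps), dtype=np.int8)
        for k in range(2):
            state = np.empty(n_snps, dtype=np.int8)
            for chrom, idx in genome.chrom_slices.items():
                m = len(idx)
                t = 0.5 * (1.0 - np.exp(
                    -2.0 * cfg.hs_admix_generations
                    * np.diff(snps["cm"].to_numpy()[idx]) / 100.0))
                switches = rng.random(m - 1) < t
                s = np.empty(m, dtype=np.int8)
                s[0] = rng.integers(2)
                s[1:] = (s[0] + np.cumsum(switches)) % 2
                state[idx] = s
            p = np.where(state == 0, p_a, p_b)
            pair[k] = (rng.random(n_snps) < p).astype(np.int8)
        return pair

    for a in hs_sires:
        add(a, "0", "0", 1, "HS0", admixed_hap())
    for a in hs_dams:
        add(a, "0", "0", 2, "HS0", admixed_hap())
    hs_ids = [f"HS_{i:04d}" for i in range(cfg.n_halfsib)]
    for a in hs_ids:
        offspring(a, rng.choice(hs_sires), rng.choice(hs_dams),
                  int(rng.integers(1, 3)), "HS1")

    hap_arr = np.stack(haps)  # (n_animals, 2, n_snps)
    dosage = hap_arr.sum(axis=1).astype(float)
    gmat = GenotypeMatrix(
        samples=ids, snps=snps, dosage=dosage,
        haplotypes=np.transpose(hap_arr, (0, 2, 1)),
    )
    pedigree = pd.DataFrame(
        ped_rows, columns=["id", "sire", "dam", "sex", "generation"]
    ).set_index("id")

    # --- phenotypes (F2 and half-sib offspring are the phenotyped cohorts)
    qtn_g = pd.Series(dosage[:, qtn_col].astype(int), index=ids)

    sigma_a2 = cfg.h2_polygenic * cfg.sigma_RG**2
    sigma_e2 = (1.0 - cfg.h2_polygenic) * cfg.sigma_RG**2
    bv_map: dict[str, float] = {}
    for animal_id, sire, dam, _sex, _gen in ped_rows:
        if sire == "0":
            bv_map[animal_id] = rng.normal(0.0, np.sqrt(sigma_a2))
        else:
            bv_map[animal_id] = 0.5 * (bv_map[sire] + bv_map[dam]) + rng.normal(
                0.0, np.sqrt(sigma_a2 / 2.0))
    bv = pd.Series(bv_map, index=ids)

    pheno_ids = f2_ids + hs_ids
    n_ph = len(pheno_ids)
    sex = pedigree.loc[pheno_ids, "sex"].to_numpy()
    batch = rng.integers(0, cfg.n_batches, size=n_ph)
    batch_eff = rng.normal(0.0, 2.0, size=cfg.n_batches)
    weight = rng.normal(90.0, 8.0, size=n_ph) + 2.0 * (sex == 1)

    g = qtn_g[pheno_ids].to_numpy()
    qtn_effect = np.where(g == 2, cfg.a_RG, np.where(g == 1, cfg.d_RG, -cfg.a_RG))
    rg = (
        cfg.mu_RG + qtn_effect
        + 1.5 * (sex == 1)
        + batch_eff[batch]
        + 0.05 * (weight - 90.0)
        + bv[pheno_ids].to_numpy()
        + rng.normal(0.0, np.sqrt(sigma_e2), size=n_ph)
    )
    rg = np.maximum(rg, 0.0)
    g6p = np.maximum(rng.normal(0.17, 0.38, size=n_ph), 0.0)
    lactate = np.maximum(rng.normal(90.0, 22.0, size=n_ph), 0.0)
    gp = 2.0 * (rg + g6p) + lactate

    phenotypes = pd.DataFrame(
        {
            "rg": rg, "g6p": g6p, "lactate": lactate, "gp": gp,
            "sex": sex, "batch": batch, "carcass_weight": weight,
            "population": ["F2"] * len(f2_ids) + ["HS"] * len(hs_ids),
        },
        index=pd.Index(pheno_ids, name="id"),
    )

    # --- expression (F2 cohort; tag assay reads the TOTAL transcript pool)
    expr_ids = f2_ids
    g_e = qtn_g[expr_ids].to_numpy()
    func = np.empty(len(expr_ids))
    total = np.empty(len(expr_ids))
    for gt in (0, 1, 2):
        f_lvl, a_lvl = splice_expression_level(
            gt, cfg.lambda_splice, cfg.nu_nmd, cfg.mutant_transcription)
        func[g_e == gt] = f_lvl
        total[g_e == gt] = f_lvl + a_lvl
    noise = np.exp(rng.normal(0.0, cfg.sigma_expr, size=len(expr_ids)))
    focal_counts = rng.poisson(cfg.mean_focal_count * total * noise)
    functional_meas = func * np.exp(rng.normal(0.0, cfg.sigma_expr, size=len(expr_ids)))

    gene_rows = [("gene_focal", cfg.qtn_chrom,
                  max(1, cfg.qtn_pos_bp - 5_000), cfg.qtn_pos_bp + 5_000, "+")]
    counts = [focal_counts]
    for j in range(cfg.n_background_genes):
        chrom = str(int(rng.integers(1, cfg.n_chroms + 1)))
        start = int(rng.integers(1, int(cfg.map_length_cM * cfg.bp_per_cM)))
        gene_rows.append((f"gene_bg{j:03d}", chrom, start, start + 10_000, "+"))
        mean_j = float(np.exp(rng.normal(np.log(50.0), 1.0)))
        noise_j = np.exp(rng.normal(0.0, cfg.sigma_expr, size=len(expr_ids)))
        counts.append(rng.poisson(mean_j * noise_j))
    genes = pd.DataFrame(
        gene_rows, columns=["gene", "chrom", "start", "end", "strand"]
    ).set_index("gene")
    counts_df = pd.DataFrame(np.vstack(counts), index=genes.index, columns=expr_ids)

    expression = ExpressionData(
        counts=counts_df,
        genes=genes,
        functional=pd.Series(functional_meas, index=expr_ids, name="functional"),
        total_level=pd.Series(total, index=expr_ids, name="total_level"),
    )

    sire_geno = {}
    label = {0: "qq", 1: "Qq", 2: "QQ"}
    for s in f1_boars + hs_sires:
        sire_geno[s] = label[int(qtn_g[s])]

    truth = TruthSet(
        qtn_id="qtn", qtn_chrom=cfg.qtn_chrom, qtn_pos_bp=cfg.qtn_pos_bp,
        qtn_genotype=qtn_g, breeding_value=bv,
        lambda_splice=cfg.lambda_splice, nu_nmd=cfg.nu_nmd,
        a_RG=cfg.a_RG, d_RG=cfg.d_RG, mu_RG=cfg.mu_RG,
        sire_qtl_genotype=sire_geno,
    )
    return SimResult(gmat, pedigree, phenotypes, expression, truth)
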