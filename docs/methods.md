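# Methods

## Scope and design

`qtnscan` decomposes a QTL-to-QTN evidence chain into independently tested
operations: genotype/sample QC, mixed-linear-model (MLM) association with a
genomic relationship matrix (GRM), 2-LOD support intervals and their
cross-population intersection, cis-eQTL scanning and lead-SNP colocalization,
conditional analysis, marker-assisted sire segregation, Q/q haplotype
co-segregation, and quantitative trait arithmetic. A forward simulator
provides crosses with known truth so every stage — and the chain as a whole —
can be validated by parameter recovery rather than by re-fitting published
statistics.

## Simulator

**Populations.** Two divergent founder breeds are crossed: 2 breed-A boars
(fixed for the mutant QTN allele) × 17 breed-B sows (fixed wild-type), 9 F1
boars × 59 F1 sows intercrossed to 930 F2 animals; plus a 50/50 admixed
half-sib line (4 sires × 55 dams, 434 offspring). All haplotypes are tracked
with phase. Gametes recombine under the Haldane map function (no
interference) on a per-chromosome genetic map; by default 3 chromosomes of
100 cM with 300 markers each and 1 Mb/cM, one chromosome carrying the QTN at
45 Mb — one signal chromosome plus background keeps runs at desk scale while
leaving genuine multiple-testing burden.

**Half-sib ancestry mosaics.** Half-sib founder haplotypes are two-state
ancestry mosaics (Markov switching along the map at the rate implied by ~10
generations of admixture), with alleles drawn from the ancestral breed's
frequency at each marker. This matters: chromosomes that carry the
mutant-associated flanking haplotype but the wild-type QTN allele are exactly
what breaks co-segregation of non-causal linked variants. With single-draw
(non-mosaic) admixed haplotypes, a linked marker spuriously survived the
co-segregation filter in roughly one run in five.

**Trait model.** Residual glycogen (RG, µmol/g) is
`mu + {+a, d, −a}[QTN genotype] + sex + batch + 0.05·(weight−90) + u + e`
with defaults `mu = 33.87`, `a = 12.88`, `d = −8.92` (the scale of the
published genotype means) and non-QTN SD `sigma = 12.5` split 30% polygenic /
70% residual. The polygenic value `u` descends through the pedigree with
Mendelian-sampling variance `sigma_a^2/2`. G-6-P and lactate are drawn
independently of the QTN (the locus acts on glycogen turnover, not
glycolysis), and GP is computed from its defining formula, so GP inherits its
QTL signal entirely through RG.

**Expression mechanism.** Each wild-type allele yields 1 unit of functional
transcript. A mutant allele transcribes `mutant_transcription` units
(default 1 — equal allelic output is an assumption, so it is a parameter,
not a constant), of which a fraction λ is spliced correctly and the aberrant
remainder survives NMD with probability ν. Defaults λ = 2/33, ν = 14/31
solve `1 + (1−λ)ν/(1+λ) = 1.4` and `1 + (1−λ)ν/λ = 8`, the heterozygote and
mutant-homozygote total:functional ratios the mechanism is calibrated to.
The tag-count assay reads the **total** transcript pool (the tag sits
upstream of the truncating lesion), so the simulator emits both a Poisson
total-count track (mean 25 counts per transcript unit, log-normal biological
noise σ = 0.4) and a functional-level track; 30 unlinked background genes
give the eQTL scan something to ignore.

**What the simulator does not emulate.** Genotyping error (Mendelian error
rates are therefore ~0 and the QC threshold is exercised by construction
tests), missing calls, selection and drift in the half-sib line's history,
sequence-level reads, interference in crossing over, and G×E. Passing tests
demonstrate recovery under a correctly specified generative model, not
robustness to real-data artifacts.

## Quality control

Filter order is fixed and recorded: sample call rate > 0.9 → sample
Mendelian error rate < 0.05 (trio rule-table; a SNP is tested only when the
full trio is non-missing) → SNP call rate > 0.9 → MAF > 0.05 → exact HWE
P > 1e-5 (Wigginton-style enumeration, no mid-P). All bounds are strict, as
printed. HWE is computed on the retained cohort even though an intercross is
not a random-mating population — the standard chip-QC practice this module
mirrors — and is therefore a documented caveat, not a bug.

## Mixed-model engine

The GRM defaults to mean shared-allele fraction (IBS) over
pairwise-complete markers, with a VanRaden centered-cross-product
alternative. Note the IBS matrix has a large constant baseline, so the REML
heritability ratio is not numerically comparable to a pedigree h²; it serves
as the covariance model for the score test, which is invariant to that
baseline up to the fitted weights.

REML uses the spectral decomposition of G and a bounded scalar search on the
variance ratio (tolerance 1e-8), with an explicit h = 0 boundary check. Each
SNP is then tested by the 1-df score test against the null-model covariance
(the `mmscore` strategy), fully vectorized across SNPs; missing dosages are
mean-imputed per SNP, and monomorphic SNPs report P = 1 with a flag rather
than erroring inside scans. The conditional scan appends the named SNP's
dosage to the fixed effects, keeps the null variance components, and drops
that SNP from the output.

`LOD = chi2_1(P)/(2 ln 10)`. The 2-LOD interval extends from the peak
(ties → smallest position) outward to the **first SNP at which the LOD has
dropped more than 2 below the peak** (or the chromosome end), with bounds at
SNP positions, not interpolations. Bonferroni thresholds are `alpha/N`
genome-wide and `1/N` suggestive. Variance explained by a SNP is
`(V_reduced − V_full)/V_reduced` where V is the REML `sigma_a^2 + sigma_e^2`
with and without the SNP as a fixed covariate.

## Expression and colocalization

DGE tags are 21-mers (CATG + 17 nt) at every NlaIII site on both strands of
each transcript; tags shared by ≥2 genes are ambiguous and never counted,
tags containing non-ACGT bases never match. Observed tags map exactly first,
then to a unique ≤1-mismatch neighbour; equal-distance hits in different
genes are discarded. TPM uses the per-sample **clean-tag** total as
denominator, so columns sum to <1e6 when tags go unmapped.

Expression adjustment is two-stage: Huber robust regression on sex + batch,
then polygenic residualization of the robust residuals against the GRM
(GRAMMAR-style; robust mixed models are ill-specified, and two-stage matches
"adjusted for kinship" semantics). Colocalization is deliberately the
lead-SNP argument — peak identity within the gene body ± 2 Mb — not a
Bayesian posterior; the cis window anchors on the gene body and the margin
is configurable.

## Segregation analysis

Offspring transmission labels come from the nearest informative marker: the
closest marker to the target position at which the sire is heterozygous and
the paternal allele is unambiguous given offspring (and, where available,
dam) genotypes; unresolvable offspring are dropped. Phenotypes are
pre-residualized for sex and batch.
`Z = (n/2) log10(RSS0/RSS1)` is the exact log10 likelihood ratio of the
two-mean vs one-mean common-variance normal ML fits. Because RSS1 ≤ RSS0
algebraically, Z ≥ 0: the printed `Z < −2 → homozygous` branch of the
classifier is unreachable under this likelihood, and truly homozygous sires
emerge as `undetermined` (Z ≈ 0). The classifier applies the printed
thresholds verbatim regardless; the asymmetry is inherent to the RSS form.

Concordance requires the candidate's heterozygosity status to match each
determined sire's deduced status, plus a consistent allele→Q orientation
(the candidate allele on every Qq sire's phenotype-raising haplotype must be
identical) for full concordance.

In the pipeline, Q/q chromosome labels for co-segregation come from Qq sires
(phenotype-raising haplotype = Q); a sire deduced homozygous would contribute
two same-label chromosomes labeled by its family mean relative to the grand
mean.

## Numerical and degenerate-input choices

* Exact HWE: probabilities accumulated in normalized space with a 1e-12
  relative slack on the "as extreme" comparison to absorb rounding.
* LD r²: EM over the double-heterozygote phase ambiguity, tolerance 1e-10,
  frequencies floored at 1e-12 inside the EM ratio; output clipped to [0, 1].
* UPGMA: tie merges resolve in input order; heights are merge distance / 2;
  distances are proportions of discordant non-missing sites with an optional
  indel exclusion mask.
* Constant phenotype, empty chromosome, all-missing SNP, monomorphic
  conditioning SNP, disjoint intervals: explicit `ValueError`s; constant
  expression vectors are centered with a warning instead (an expression
  matrix routinely contains dead genes).
* Fixed seed ⇒ bit-identical simulation and byte-identical pipeline report
  (no timestamps in the report body).

## Problem sizes used in validation

Recovery checks run at the design scale (930 F2 / 434 half-sib; ~900
markers); the score-test size calibration uses 20 replicates of a 300-animal,
300-marker null cross, interval coverage 20 replicates at 500 F2, and the
end-to-end identification 10 replicates at full scale. These sizes give
stable rates while keeping a full validation run in minutes on one core.

## Known limitations

* The score test assumes the null covariance is well estimated; at very
  small n the LOD/interval machinery is nominal only.
* Co-segregation treats any missing allele as disqualifying — conservative,
  and appropriate only for small curated regional panels.
* The trio Mendelian check ignores half-missing trios rather than using
  single-parent impossibilities.
* No trans-eQTL, no multi-QTL segregation models, no permutation thresholds,
  no genotype imputation beyond per-SNP mean dosage inside the GRM/scan.
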