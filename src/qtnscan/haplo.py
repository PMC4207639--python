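"""Regional haplotype analytics: LD, Q/q co-segregation, consensus, UPGMA.

Sire chromosomes carrying a deduced QTL allele (Q = trait-raising, q =
wild-type) are compared across a candidate-variant panel. A variant
co-segregates with the QTL iff one of its alleles is carried by every Q
chromosome and by none of the q chromosomes; a missing allele on any
chromosome disqualifies the variant (conservative). Haplotype relatedness
is summarized by a UPGMA tree on the proportion of discordant non-missing
sites, with indels optionally excluded from the distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LabeledChromosome",
    "ld_r2",
    "cosegregation_filter",
    "shared_haplotype",
    "pairwise_distances",
    "upgma_tree",
]


@dataclass
class LabeledChromosome:
    """One phased chromosome over a regional variant panel.

    ``alleles`` holds ALT indicators per variant (-1 for missing/unclear);
    ``label`` is the deduced QTL allele 'Q' or 'q'; ``origin`` a free-form
    provenance tag (breed / line).
    """

    name: str
    alleles: np.ndarray
    label: str
    origin: str = ""

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=int)
        if self.label not in ("Q", "q"):
            raise ValueError("label must be 'Q' or 'q'")


# ---------------------------------------------------------------------------
# linkage disequilibrium

def ld_r2(g1, g2, max_iter: int = 100, tol: float = 1e-10) -> float:
    """Haplotype-frequency r^2 between two SNPs from unphased dosages.

    Two-locus haplotype frequencies are estimated by EM over the
    double-heterozygote phase ambiguity (Hill's gene-counting algorithm),
    then r^2 = D^2 / (pA pa pB pb).
    """
    x = np.asarray(g1, dtype=float)
    y = np.asarray(g2, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("LD requires two polymorphic SNPs on shared samples")
    n = len(x)
    p1 = x.mean() / 2.0  # ALT frequency at SNP 1
    p2 = y.mean() / 2.0
    # counts of the nine genotype combinations
    n_dh = int(np.sum((x == 1) & (y == 1)))  # double heterozygotes
    # phase-certain count of ALT-ALT haplotypes from unambiguous genotypes
    c11 = sum(_certain_11(xi, yi) for xi, yi in zip(x, y)
              if not (xi == 1 and yi == 1))
    f11 = (c11 + 0.5 * n_dh) / (2.0 * n)  # start with half the ambiguous mass
    for _ in range(max_iter):
        f10 = p1 - f11
        f01 = p2 - f11
        f00 = 1.0 - f11 - f10 - f01
        f11c, f10c, f01c, f00c = (max(v, 1e-12) for v in (f11, f10, f01, f00))
        denom = f11c * f00c + f10c * f01c
        frac = f11c * f00c / denom  # P(coupling phase | double het)
        new_f11 = (c11 + n_dh * frac) / (2.0 * n)
        if abs(new_f11 - f11) < tol:
            f11 = new_f11
            break
        f11 = new_f11
    d_coef = f11 - p1 * p2
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    return float(np.clip(d_coef**2 / denom, 0.0, 1.0))


def _certain_11(xi: float, yi: float) -> float:
    """Number of ALT-ALT haplotypes in a phase-unambiguous genotype pair."""
    # genotypes 0/1/2 at two loci; except the 1/1 case the haplotype split
    # is deterministic: each locus distributes its ALT copies across the two
    # haplotypes with hets contributing one ALT to one haplotype.
    if xi == 2 and yi == 2:
        return 2.0
    if (xi == 2 and yi == 1) or (xi == 1 and yi == 2):
        return 1.0
    if xi == 2 or yi == 2:
        return 0.0 if min(xi, yi) == 0 else 1.0
    return 0.0


# ---------------------------------------------------------------------------
# co-segregation and consensus

def cosegregation_filter(chroms: list, variant_ids: list) -> list:
    """Variants whose alleles perfectly partition Q from q chromosomes.

    A variant survives iff all Q chromosomes carry one identical non-missing
    allele and no q chromosome carries that allele; any missing allele fails
    the variant.
    """
    q_chroms = [c for c in chroms if c.label == "Q"]
    w_chroms = [c for c in chroms if c.label == "q"]
    if not q_chroms or not w_chroms:
        raise ValueError("need at least one Q and one q chromosome")
    survivors = []
    for j, vid in enumerate(variant_ids):
        q_alleles = {int(c.alleles[j]) for c in q_chroms}
        w_alleles = {int(c.alleles[j]) for c in w_chroms}
        if -1 in q_alleles or -1 in w_alleles:
            continue
        if len(q_alleles) != 1:
            continue
        if q_alleles & w_alleles:
            continue
        survivors.append(vid)
    return survivors


def shared_haplotype(chroms: list):
    """Site-wise consensus of a chromosome set and an identity flag.

    Consensus is the majority non-missing allele (ties -> -1). The flag is
    true iff no site shows discordant non-missing alleles.
    """
    if not chroms:
        raise ValueError("empty chromosome set")
    alleles = np.stack([c.alleles for c in chroms])
    m = alleles.shape[1]
    consensus = np.full(m, -1, dtype=int)
    identical = True
    for j in range(m):
        col = alleles[:, j]
        col = col[col >= 0]
        if len(col) == 0:
            continue
        vals, counts = np.unique(col, return_counts=True)
        if len(vals) > 1:
            identical = False
        top = counts.max()
        winners = vals[counts == top]
        consensus[j] = int(winners[0]) if len(winners) == 1 else -1
    return consensus, identical


# ---------------------------------------------------------------------------
# UPGMA

def pairwise_distances(chroms: list, exclude_mask=None) -> np.ndarray:
    """Proportion of discordant non-missing sites for every chromosome pair.

    ``exclude_mask`` marks sites (e.g. indels) left out of the distance.
    """
    alleles = np.stack([c.alleles for c in chroms])
    if exclude_mask is not None:
        alleles = alleles[:, ~np.asarray(exclude_mask, dtype=bool)]
    n = len(chroms)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = alleles[i], alleles[j]
            ok = (a >= 0) & (b >= 0)
            if not ok.any():
                raise ValueError("a chromosome pair shares no scored site")
            dist[i, j] = dist[j, i] = np.mean(a[ok] != b[ok])
    return dist


def upgma_tree(chroms: list, exclude_mask=None) -> str:
    """UPGMA agglomeration of labeled chromosomes; returns a newick string.

    Distances are proportions of discordant non-missing sites; equal-distance
    merges are resolved in input order. Branch lengths are ultrametric
    (node height = half the merge distance).
    """
    if len(chroms) < 2:
        raise ValueError("UPGMA needs at least two chromosomes")
    dist = pairwise_distances(chroms, exclude_mask)
    active = {i: ([c.name for c in chroms][i], 0.0, 1) for i in range(len(chroms))}
    # value: (newick, height, n_leaves)
    d = {(i, j): dist[i, j] for i in range(len(chroms))
         for j in range(i + 1, len(chroms))}
    next_id = len(chroms)
    while len(active) > 1:
        (i, j), dij = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        ni, hi, si = active[i]
        nj, hj, sj = active[j]
        height = dij / 2.0
        newick = f"({ni}:{height - hi:.6g},{nj}:{height - hj:.6g})"
        new = next_id
        next_id += 1
        for k in list(active):
            if k in (i, j):
                continue
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            d[tuple(sorted((new, k)))] = (si * dik + sj * djk) / (si + sj)
        for key in [k for k in d if i in k or j in k]:
            del d[key]
        del active[i], active[j]
        active[new] = (newick, height, si + sj)
    (newick, _h, _s) = next(iter(active.values()))
    return newick + ";"
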